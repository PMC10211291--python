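"""Overrepresentation of query CpGs in curated catalog CpG sets.

Two statistics are reported side by side for each set: a one-sided
Fisher exact (hypergeometric upper tail) p with a Haldane-corrected
odds ratio, and a pre-ranked weighted running-sum enrichment score with
a permutation-normalized NES. The query/reference orientation is a
parameter: either the query CpGs or the catalog sets can play the role
of the ranked universe's annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from methylcell.methio.core import ValidationError

logger = logging.getLogger(__name__)

ARRAY_BONFERRONI = {"450k": 0.05 / 450000, "EPIC": 0.05 / 850000}

CATALOG_COLUMNS = ["set_name", "trait", "cpg_id", "p", "array", "n"]


@dataclass
class CatalogSet:
    name: str
    trait: str
    cpg_ids: tuple[str, ...]
    array: str = "450k"
    n: int = 0

    def __post_init__(self) -> None:
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError(f"duplicate CpG ids within set {self.name!r}")
        self.cpg_ids = tuple(self.cpg_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    trait: str
    overlap: int
    odds_ratio: float
    fisher_p: float
    es: float
    nes: float
    perm_fdr_q: float = np.nan
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "set": self.set_name,
            "trait": self.trait,
            "overlap": self.overlap,
            "odds_ratio": self.odds_ratio,
            "fisher_p": self.fisher_p,
            "es": self.es,
            "nes": self.nes,
            "q": self.perm_fdr_q,
        }


# ---------------------------------------------------------------------------
# catalog filtering
# ---------------------------------------------------------------------------

def filter_catalog(associations: pd.DataFrame, n_min: int = 100) -> list[CatalogSet]:
    """Apply the array-specific Bonferroni rule and the study-size rule.

    Associations must carry per-row p, array label (450k or EPIC) and
    population size n. p must be strictly below 0.05/450000 (450k) or
    0.05/850000 (EPIC); n strictly above ``n_min``. Sets left empty are
    dropped. Unknown array labels are an error.
    """
    unknown = set(associations["array"].unique()) - set(ARRAY_BONFERRONI)
    if unknown:
        raise ValidationError(f"unknown array labels: {sorted(unknown)}")
    thresholds = associations["array"].map(ARRAY_BONFERRONI)
    kept = associations[(associations["p"] < thresholds) & (associations["n"] > n_min)]
    sets = []
    for (name, trait), group in kept.groupby(["set_name", "trait"], sort=True):
        ids = tuple(dict.fromkeys(group["cpg_id"]))
        if not ids:
            continue
        arrays = group["array"].mode()
        sets.append(
            CatalogSet(
                name=name,
                trait=trait,
                cpg_ids=ids,
                array=str(arrays.iloc[0]),
                n=int(group["n"].max()),
            )
        )
    return sets


# ---------------------------------------------------------------------------
# Fisher overlap
# ---------------------------------------------------------------------------

def fisher_overlap(query, target: CatalogSet | set, universe) -> tuple[int, float, float]:
    """One-sided (enrichment) hypergeometric overlap test.

    Returns (overlap, odds_ratio, p). Ids outside the universe are
    dropped with a warning; the odds ratio uses a Haldane 0.5
    correction when any 2x2 cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    target_ids = set(target.cpg_ids if isinstance(target, CatalogSet) else target)
    query = set(query)
    for label, ids in (("query", query), ("target", target_ids)):
        outside = ids - universe
        if outside:
            warnings.warn(
                f"{len(outside)} {label} ids outside the universe were dropped"
            )
    q = query & universe
    t = target_ids & universe
    overlap = len(q & t)
    M, K, n = len(universe), len(t), len(q)
    p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
    a = overlap
    b = len(q) - overlap
    c = len(t) - overlap
    d = M - len(q) - len(t) + overlap
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = float((a * d) / (b * c))
    return overlap, odds_ratio, min(p, 1.0)


# ---------------------------------------------------------------------------
# pre-ranked enrichment
# ---------------------------------------------------------------------------

def _running_sum_es(
    ordered_hits: np.ndarray, ordered_scores: np.ndarray, weight_exponent: float
) -> float:
    """Extremum of the weighted running sum over the ranked universe."""
    n = len(ordered_hits)
    n_hits = int(ordered_hits.sum())
    if n_hits == 0 or n_hits == n:
        return np.nan
    weights = np.abs(ordered_scores) ** weight_exponent
    hit_weights = weights * ordered_hits
    total = hit_weights.sum()
    if total == 0:  # all hit scores are zero: fall back to equal weights
        hit_weights = ordered_hits.astype(float)
        total = hit_weights.sum()
    increments = hit_weights / total - (1.0 - ordered_hits) / (n - n_hits)
    running = np.cumsum(increments)
    extremum = running[np.argmax(np.abs(running))]
    return float(extremum)


def preranked_es(
    scores: pd.Series,
    target: CatalogSet | set,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, np.ndarray]:
    """Pre-ranked enrichment of ``target`` in the universe ranked by ``scores``.

    The universe is ordered by descending score (ties broken by CpG id,
    so the ranking is deterministic). Hits increment the running sum by
    |score|^exponent normalized over hits; misses decrement by
    1/(N - |target|). ES is the running-sum extremum. NES = ES divided
    by the mean of same-sign ES from ``n_perm`` random sets of the same
    size (set-membership permutation). Returns (es, nes, permuted_es).
    """
    if rng is None:
        if seed is None:
            raise ValidationError("preranked_es requires an explicit seed or rng")
        rng = np.random.default_rng(seed)
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValidationError("scores must be finite")
    order = scores.reset_index()
    order.columns = ["cpg_id", "score"]
    order = order.sort_values("cpg_id", kind="mergesort")
    order = order.sort_values("score", ascending=False, kind="mergesort")
    universe = order["cpg_id"].to_numpy()
    ordered_scores = order["score"].to_numpy(dtype=float)

    target_ids = set(target.cpg_ids if isinstance(target, CatalogSet) else target)
    hits = np.isin(universe, list(target_ids)).astype(float)
    n_hits = int(hits.sum())
    if n_hits == 0:
        logger.warning("target set has no overlap with the universe; ES undefined")
        return np.nan, np.nan, np.array([])
    es = _running_sum_es(hits, ordered_scores, weight_exponent)

    n = len(universe)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        perm_hits = np.zeros(n)
        perm_hits[rng.choice(n, size=n_hits, replace=False)] = 1.0
        permuted[i] = _running_sum_es(perm_hits, ordered_scores, weight_exponent)
    finite = permuted[np.isfinite(permuted)]
    same_sign = finite[np.sign(finite) == np.sign(es)]
    nes = float(es / np.mean(np.abs(same_sign))) if len(same_sign) else np.nan
    return float(es), nes, permuted


def enrichment_analysis(
    query,
    sets: list[CatalogSet],
    scores: pd.Series,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fisher overlap plus pre-ranked NES for every catalog set.

    ``query`` is the CpG set tested for overrepresentation (Fisher);
    ``scores`` rank the tested universe (e.g. -log10 of the minimum
    EWAS p across cell types). The permutation FDR q compares each
    set's NES against the pooled permutation NES distribution.
    """
    if seed is None:
        raise ValidationError("enrichment_analysis requires an explicit seed")
    rng = np.random.default_rng(seed)
    universe = list(scores.index)
    results: list[EnrichmentResult] = []
    all_nes: list[float] = []
    pooled_perm_nes: list[float] = []
    for cat in sets:
        overlap, odds_ratio, fisher_p = fisher_overlap(query, cat, universe)
        es, nes, permuted = preranked_es(
            scores, cat, weight_exponent=weight_exponent, n_perm=n_perm, rng=rng
        )
        if len(permuted):
            norm = np.mean(np.abs(permuted[np.isfinite(permuted)]))
            if norm > 0:
                pooled_perm_nes.extend(
                    (permuted[np.isfinite(permuted)] / norm).tolist()
                )
        all_nes.append(nes)
        results.append(
            EnrichmentResult(cat.name, cat.trait, overlap, odds_ratio, fisher_p, es, nes)
        )
    observed = np.array([r.nes for r in results], dtype=float)
    pooled = np.array(pooled_perm_nes, dtype=float)
    for res in results:
        res.perm_fdr_q = _permutation_fdr(res.nes, observed, pooled)
    return pd.DataFrame([r.as_dict() for r in results])


def _permutation_fdr(nes: float, observed: np.ndarray, pooled: np.ndarray) -> float:
    """GSEA-style FDR: tail mass of pooled permutation NES beyond this
    NES, relative to the tail mass of observed NES values."""
    if not np.isfinite(nes) or len(pooled) == 0:
        return np.nan
    observed = observed[np.isfinite(observed)]
    if nes >= 0:
        null_tail = np.mean(pooled >= nes) if len(pooled) else np.nan
        obs_tail = np.mean(observed >= nes)
    else:
        null_tail = np.mean(pooled <= nes) if len(pooled) else np.nan
        obs_tail = np.mean(observed <= nes)
    if obs_tail == 0:
        return np.nan
    return float(min(1.0, null_tail / obs_tail))
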