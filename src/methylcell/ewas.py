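"""Per-CpG robust-regression EWAS within each cell fraction.

Betas are clamped and moved to the log2-ratio (M-value) scale, then each
CpG is fit by Huber M-estimation (tuning constant 1.345, MAD scale) of
M-value on smoking plus covariates (age, sex, ancestry one-hot, BMI)
and, when provided, contaminant cell-type proportions with the fraction's
own cell type dropped to avoid collinearity. Two-sided p values come
from the t distribution with df = n - parameters. Effect sizes on the
beta scale (delta_meth) are raw smoker-minus-nonsmoker mean differences,
never winsorized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from methylcell.deconv import ProportionTable
from methylcell.methio.core import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

HUBER_T = 1.345
DEFAULT_EPS = 1e-6

RESULT_COLUMNS = [
    "cpg_id",
    "coefficient",
    "se",
    "p",
    "delta_meth",
    "n_used",
    "converged",
]


@dataclass
class MValueMatrix:
    """CpG x sample matrix on the log2-ratio scale; finite everywhere."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("M-value matrix contains non-finite values")
        self.df = self.df.astype(float)
        self.df.index.name = "cpg_id"


@dataclass
class SpecificityCall:
    cpg_id: str
    significant_in: frozenset
    cell_type_specific: bool
    highly_specific: bool
    best_cell_type: str | None


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def mvalue_transform(beta: BetaMatrix, eps: float = DEFAULT_EPS) -> MValueMatrix:
    """log2(beta / (1 - beta)) after clamping beta to [eps, 1 - eps]."""
    if not 0.0 < eps < 0.5:
        raise ValidationError("eps must lie in (0, 0.5)")
    b = np.clip(beta.df.to_numpy(dtype=float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return MValueMatrix(pd.DataFrame(m, index=beta.df.index, columns=beta.df.columns))


def inverse_mvalue(m: MValueMatrix) -> BetaMatrix:
    """Inverse of the M transform: beta = 2^m / (1 + 2^m)."""
    x = np.exp2(m.df.to_numpy(dtype=float))
    return BetaMatrix(pd.DataFrame(x / (1.0 + x), index=m.df.index, columns=m.df.columns))


def winsorize_rows(m: MValueMatrix, total_fraction: float = 0.10) -> MValueMatrix:
    """Per-CpG winsorization: clamp each row at the (f/2, 1 - f/2) quantiles.

    Quantiles by linear interpolation (type 7). ``total_fraction`` is
    the total mass moved (e.g. 0.10 clamps at the 5% and 95% quantiles).
    """
    if not 0.0 <= total_fraction < 0.5:
        raise ValidationError("total_fraction must lie in [0, 0.5)")
    if total_fraction == 0.0:
        return MValueMatrix(m.df.copy())
    values = m.df.to_numpy(dtype=float)
    lo = np.quantile(values, total_fraction / 2.0, axis=1, method="linear")
    hi = np.quantile(values, 1.0 - total_fraction / 2.0, axis=1, method="linear")
    clipped = np.clip(values, lo[:, None], hi[:, None])
    return MValueMatrix(pd.DataFrame(clipped, index=m.df.index, columns=m.df.columns))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(
    sheet: SampleSheet,
    contamination: ProportionTable | None = None,
    own_cell_type: str | None = None,
    covariates: tuple[str, ...] = ("age", "sex", "ancestry", "bmi"),
) -> pd.DataFrame:
    """Assemble the EWAS design matrix (intercept, smoking, covariates).

    Categorical covariates are one-hot encoded with the first level
    (sorted) dropped. Contaminant proportions drop the fraction's own
    cell type. Raises on rank deficiency, naming the aliased columns.
    """
    df = sheet.df.set_index("sample_id")
    X = pd.DataFrame({"intercept": 1.0, "smoking": df["smoking"].astype(float)})
    for cov in covariates:
        col = df[cov]
        if col.dtype == object:
            levels = sorted(col.unique())
            for level in levels[1:]:
                X[f"{cov}_{level}"] = (col == level).astype(float)
        else:
            X[cov] = col.astype(float)
    if contamination is not None:
        contam = contamination.proportions().loc[X.index]
        for cell_type in contam.columns:
            if cell_type == own_cell_type:
                continue
            X[f"prop_{cell_type}"] = contam[cell_type].astype(float)
    _check_rank(X)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, R, piv = _qr_pivot(A)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[p] for p in piv[len(diag):]]
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"aliased columns: {aliased}"
        )


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


# ---------------------------------------------------------------------------
# per-CpG fits
# ---------------------------------------------------------------------------

def fit_ewas(
    m: MValueMatrix,
    beta: BetaMatrix,
    sheet: SampleSheet,
    contamination: ProportionTable | None = None,
    own_cell_type: str | None = None,
    winsorize: bool = False,
    winsorize_fraction: float = 0.10,
    covariates: tuple[str, ...] = ("age", "sex", "ancestry", "bmi"),
) -> pd.DataFrame:
    """Huber robust regression of M-values on smoking, per CpG.

    Returns one row per CpG with columns cpg_id, coefficient (M scale),
    se, p, delta_meth (beta scale, smoker - nonsmoker), n_used and
    converged. CpGs whose IRLS does not converge within 100 iterations
    fall back to ordinary least squares and are flagged.
    """
    if list(m.df.columns) != list(beta.df.columns):
        raise ValidationError("M-value and beta matrices have different samples")
    sub = sheet.for_samples(m.df.columns)
    if len(sub.df) < 10:
        raise ValidationError("need >= 10 samples for EWAS")
    X = build_design(sub, contamination, own_cell_type, covariates)
    X = X.loc[list(m.df.columns)]
    Xa = X.to_numpy(dtype=float)
    n, k = Xa.shape
    df_resid = n - k

    work = winsorize_rows(m, winsorize_fraction) if winsorize else m
    Y = work.df.to_numpy(dtype=float)

    smoking = sub.df.set_index("sample_id").loc[list(m.df.columns), "smoking"].to_numpy()
    sm_mask = smoking == 1
    B = beta.df.to_numpy(dtype=float)
    delta = B[:, sm_mask].mean(axis=1) - B[:, ~sm_mask].mean(axis=1)

    smoking_idx = list(X.columns).index("smoking")
    huber = sm.robust.norms.HuberT(HUBER_T)
    rows = []
    for i in range(Y.shape[0]):
        y = Y[i]
        converged = True
        try:
            res = sm.RLM(y, Xa, M=huber).fit(
                scale_est="mad", conv="coefs", tol=1e-8, maxiter=100
            )
            if res.fit_history["iteration"] >= 100 or not np.isfinite(
                res.bse[smoking_idx]
            ):
                raise ValueError("IRLS did not converge")
            coef = float(res.params[smoking_idx])
            se = float(res.bse[smoking_idx])
        except (ValueError, np.linalg.LinAlgError):
            converged = False
            ols = sm.OLS(y, Xa).fit()
            coef = float(ols.params[smoking_idx])
            se = float(ols.bse[smoking_idx])
        if se > 0:
            p = float(2.0 * stats.t.sf(abs(coef / se), df_resid))
        else:
            p = 1.0
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append((m.df.index[i], coef, se, p, float(delta[i]), n, converged))

    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    disagree = (np.sign(out["delta_meth"]) != np.sign(out["coefficient"])) & (
        out["delta_meth"].abs() > 0.01
    )
    for cpg in out.loc[disagree, "cpg_id"]:
        logger.warning("delta_meth and coefficient disagree in sign at %s", cpg)
    return out


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int, alpha: float = 0.05, sig_figs: int | None = None) -> float:
    """Family-wise threshold alpha / n_tests, optionally rounded to
    ``sig_figs`` significant figures (as printed in reports)."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    threshold = alpha / n_tests
    if sig_figs is not None:
        exponent = np.floor(np.log10(threshold))
        threshold = round(threshold / 10**exponent, sig_figs - 1) * 10**exponent
    return float(threshold)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone, ties preserved)."""
    p = np.asarray(p, dtype=float)
    m_tests = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m_tests / np.arange(1, m_tests + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m_tests)
    q[order] = np.minimum(ranked, 1.0)
    return q


def multiple_testing(
    results: pd.DataFrame, n_tests: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach BH q values and Bonferroni flags to an EWAS result table.

    ``n_tests`` overrides the Bonferroni denominator (e.g. the array's
    probe count); BH is always computed over the tested CpGs.
    """
    out = results.copy()
    if n_tests is None:
        n_tests = len(out)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["bonferroni"] = out["p"] < bonferroni_threshold(n_tests, alpha)
    return out


# ---------------------------------------------------------------------------
# specificity and concordance
# ---------------------------------------------------------------------------

def classify_specificity(
    cpg_id: str,
    p_by_type: dict[str, float],
    significant_by_type: dict[str, bool],
    ratio: float = 1e4,
) -> SpecificityCall:
    """Call cell-type specificity for one CpG.

    ``cell_type_specific``: significant at the chosen threshold in
    exactly one cell type. ``highly_specific``: the min-p cell type
    satisfies p_best * ratio <= p_other for every other cell type (ties
    for best -> not highly specific).
    """
    available = {t: p for t, p in p_by_type.items() if p is not None and np.isfinite(p)}
    dropped = set(p_by_type) - set(available)
    if dropped:
        logger.info("specificity for %s excludes cell types %s", cpg_id, sorted(dropped))
    if len(available) < 2:
        raise ValidationError("specificity needs p values in >= 2 cell types")
    significant_in = frozenset(
        t for t in available if significant_by_type.get(t, False)
    )
    specific = len(significant_in) == 1
    best = min(sorted(available), key=lambda t: available[t])
    p_best = available[best]
    tied = sum(1 for p in available.values() if p == p_best) > 1
    if tied:
        logger.info("tied best p for %s; not highly specific", cpg_id)
        highly = False
        best_out = None
    else:
        highly = all(
            p_best * ratio <= available[t] for t in available if t != best
        )
        best_out = best
    return SpecificityCall(cpg_id, significant_in, specific, highly, best_out)


def directional_concordance(delta_by_type: dict[str, float]) -> tuple[int, str]:
    """Count cell types sharing the majority sign of delta_meth.

    Zero deltas count as neither sign. An exact tie reports sign '+-'.
    """
    if len(delta_by_type) < 2:
        raise ValidationError("concordance needs >= 2 cell types")
    signs = [np.sign(d) for d in delta_by_type.values()]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = sum(1 for s in signs if s < 0)
    if n_pos > n_neg:
        return n_pos, "+"
    if n_neg > n_pos:
        return n_neg, "-"
    return n_pos, "+-"


def specificity_table(
    results_by_type: dict[str, pd.DataFrame],
    threshold: str = "BF",
    ratio: float = 1e4,
) -> pd.DataFrame:
    """Combine per-cell-type EWAS tables into per-CpG specificity calls.

    ``threshold``: 'BF' uses the bonferroni flag, 'FDR5' uses q < 0.05.
    """
    if threshold not in ("BF", "FDR5"):
        raise ValidationError(f"unknown threshold {threshold!r}")
    indexed = {t: r.set_index("cpg_id") for t, r in results_by_type.items()}
    all_cpgs = sorted(set().union(*[set(r.index) for r in indexed.values()]))
    rows = []
    for cpg in all_cpgs:
        p_by_type, sig_by_type, delta_by_type = {}, {}, {}
        for cell_type, r in indexed.items():
            if cpg not in r.index:
                continue
            rec = r.loc[cpg]
            p_by_type[cell_type] = float(rec["p"])
            if threshold == "BF":
                sig_by_type[cell_type] = bool(rec["bonferroni"])
            else:
                sig_by_type[cell_type] = bool(rec["q"] < 0.05)
            delta_by_type[cell_type] = float(rec["delta_meth"])
        if len(p_by_type) < 2:
            continue
        call = classify_specificity(cpg, p_by_type, sig_by_type, ratio)
        count, sign = directional_concordance(delta_by_type)
        rows.append(
            {
                "cpg_id": cpg,
                "significant_in": ",".join(sorted(call.significant_in)),
                "specific": call.cell_type_specific,
                "highly_specific": call.highly_specific,
                "best_cell_type": call.best_cell_type or "",
                "concordant_n": count,
                "majority_sign": sign,
            }
        )
    return pd.DataFrame(rows)
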