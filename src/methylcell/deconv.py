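"""Reference-based cell-type / subtype proportion estimation.

Proportions are obtained by constrained projection of a sample's beta
profile onto reference mean profiles: nonnegative least squares with a
sum <= 1 constraint by default (sum == 1 offered as an option). The
subtype-shift test regresses estimated proportions on smoking status,
with and without covariate adjustment.

Proportions are reported on [0, 1]; percent formatting happens only at
the reporting layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from methylcell.methio.core import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-9


@dataclass
class ReferencePanel:
    """Per-cell-type mean beta profiles over a (signature) CpG set.

    ``profiles`` is CpG x cell-type; ``signature`` optionally maps each
    cell type to the CpG ids flagged as its signature.
    """

    profiles: pd.DataFrame
    signature: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        df = self.profiles
        if df.columns.has_duplicates:
            raise ValidationError("duplicate cell-type names in reference panel")
        if df.index.has_duplicates:
            raise ValidationError("duplicate CpG ids in reference panel")
        values = df.to_numpy(dtype=float)
        if values.size and ((values < 0) | (values > 1)).any():
            raise ValidationError("reference profiles must lie in [0, 1]")
        self.profiles = df.astype(float)
        self.profiles.index.name = "cpg_id"

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.profiles.index)

    def restrict(self, cpg_ids) -> "ReferencePanel":
        return ReferencePanel(self.profiles.loc[list(cpg_ids)], self.signature)


@dataclass
class ProportionTable:
    """Estimated proportions per sample plus the residual norm of the fit."""

    df: pd.DataFrame  # index sample_id; one column per cell type + 'residual'

    def __post_init__(self) -> None:
        self.df.index.name = "sample_id"

    @property
    def cell_types(self) -> list[str]:
        return [c for c in self.df.columns if c != "residual"]

    def proportions(self) -> pd.DataFrame:
        return self.df[self.cell_types]


@dataclass
class ShiftTestResult:
    subtype: str
    mean_ns: float
    se_ns: float
    mean_sm: float
    se_sm: float
    diff: float  # smoker mean - nonsmoker mean, percentage points
    p: float
    p_adjusted_covariates: float | None

    def as_dict(self) -> dict:
        return {
            "subtype": self.subtype,
            "mean_ns": self.mean_ns,
            "se_ns": self.se_ns,
            "mean_sm": self.mean_sm,
            "se_sm": self.se_sm,
            "diff": self.diff,
            "p": self.p,
            "p_adjusted_covariates": self.p_adjusted_covariates,
        }


# ---------------------------------------------------------------------------
# signature selection
# ---------------------------------------------------------------------------

def select_signature_cpgs(panel_full: ReferencePanel, k_per_type: int) -> ReferencePanel:
    """One-vs-rest signature selection.

    For each cell type, keep the ``k_per_type`` CpGs with the largest
    |mean(own) - mean(others)|, taking half from each sign where
    available (hyper- and hypo-methylated markers). Ties break on
    cpg_id lexicographic order, so the selection is deterministic.
    """
    if k_per_type < 1:
        raise ValidationError("k_per_type must be >= 1")
    profiles = panel_full.profiles
    selected: dict[str, list[str]] = {}
    union: list[str] = []
    for cell_type in profiles.columns:
        others = profiles.drop(columns=cell_type).mean(axis=1)
        contrast = profiles[cell_type] - others
        order = sorted(
            profiles.index, key=lambda c: (-abs(contrast[c]), str(c))
        )
        pos = [c for c in order if contrast[c] > 0]
        neg = [c for c in order if contrast[c] < 0]
        if k_per_type > len(profiles.index):
            warnings.warn(
                f"k_per_type={k_per_type} exceeds panel size "
                f"{len(profiles.index)}; keeping all CpGs for {cell_type}"
            )
        n_pos = min(len(pos), (k_per_type + 1) // 2)
        n_neg = min(len(neg), k_per_type - n_pos)
        if n_pos + n_neg < k_per_type:  # top up from whichever sign has spares
            n_pos = min(len(pos), k_per_type - n_neg)
        chosen = pos[:n_pos] + neg[:n_neg]
        selected[cell_type] = chosen
        union.extend(c for c in chosen if c not in union)
    union_sorted = [c for c in profiles.index if c in set(union)]
    return ReferencePanel(profiles.loc[union_sorted], signature=selected)


# ---------------------------------------------------------------------------
# constrained projection
# ---------------------------------------------------------------------------

def _solve_qp(A: np.ndarray, b: np.ndarray, equality: bool) -> np.ndarray:
    """min ||Ax - b||^2 s.t. x >= 0 and sum(x) == 1 (or <= 1)."""
    k = A.shape[1]
    AtA = A.T @ A
    Atb = A.T @ b

    def fun(x):
        return 0.5 * x @ AtA @ x - Atb @ x

    def jac(x):
        return AtA @ x - Atb

    x0, _ = optimize.nnls(A, b)
    total = x0.sum()
    if total > 1.0:
        x0 = x0 / total
    elif equality and total < 1.0:
        x0 = np.full(k, 1.0 / k) if total == 0 else x0 + (1.0 - total) / k
    constraint = {
        "type": "eq" if equality else "ineq",
        "fun": lambda x: 1.0 - x.sum(),
        "jac": lambda x: -np.ones(k),
    }
    res = optimize.minimize(
        fun,
        x0,
        jac=jac,
        bounds=[(0.0, None)] * k,
        constraints=[constraint],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    x = np.clip(res.x, 0.0, None)
    if equality and x.sum() > 0:
        x = x / x.sum()
    return x


def estimate_proportions(
    beta: BetaMatrix,
    panel: ReferencePanel,
    constraint: str = "sum_le_1",
) -> ProportionTable:
    """Project each sample's betas onto the panel profiles.

    Solves, per sample, nonnegative least squares subject to the chosen
    sum constraint (default ``sum_le_1``, tolerating unmodeled cell
    content). Output is deterministic.
    """
    if constraint not in ("sum_le_1", "sum_eq_1"):
        raise ValidationError(f"unknown constraint {constraint!r}")
    common = [c for c in panel.cpg_ids if c in set(beta.cpg_ids)]
    if not common:
        raise ValidationError("no overlap between beta matrix and panel CpGs")
    if len(common) < 0.5 * len(panel.cpg_ids):
        warnings.warn(
            f"only {len(common)}/{len(panel.cpg_ids)} panel CpGs present in "
            "the beta matrix"
        )
    A = panel.profiles.loc[common].to_numpy()
    k = A.shape[1]
    if np.linalg.matrix_rank(A) < k:
        raise ValidationError(
            "reference panel is rank-deficient on the overlapping CpG set"
        )
    B = beta.df.loc[common].to_numpy()
    rows = []
    for j in range(B.shape[1]):
        b = B[:, j]
        x, _ = optimize.nnls(A, b)
        total = x.sum()
        if constraint == "sum_le_1":
            if total > 1.0 + _SUM_TOL:
                x = _solve_qp(A, b, equality=False)
        else:
            if abs(total - 1.0) > _SUM_TOL:
                x = _solve_qp(A, b, equality=True)
        residual = float(np.linalg.norm(A @ x - b))
        rows.append(np.concatenate([x, [residual]]))
    df = pd.DataFrame(
        rows,
        index=pd.Index(beta.sample_ids, name="sample_id"),
        columns=[*panel.cell_types, "residual"],
    )
    return ProportionTable(df)


# ---------------------------------------------------------------------------
# subtype shift test
# ---------------------------------------------------------------------------

def subtype_shift_test(
    props: ProportionTable,
    sheet: SampleSheet,
    subtype: str,
    adjust: tuple[str, ...] = (),
    renormalize: bool = False,
    lineage: tuple[str, ...] | None = None,
) -> ShiftTestResult:
    """OLS of subtype proportion (percent) on smoking status.

    ``diff`` is smoker mean minus nonsmoker mean, in percentage points.
    With ``renormalize`` the subtype proportion is first expressed as a
    percent of the lineage total (e.g. naive + memory for B cells);
    default is the raw estimated percent of the fraction.
    """
    if subtype not in props.cell_types:
        raise ValidationError(f"subtype {subtype!r} not in proportion table")
    sheet_df = sheet.df.set_index("sample_id").loc[props.df.index]
    y = props.df[subtype].to_numpy(dtype=float)
    if renormalize:
        if not lineage:
            raise ValidationError("renormalize=True requires a lineage tuple")
        denom = props.df[list(lineage)].sum(axis=1).to_numpy(dtype=float)
        if (denom <= 0).any():
            raise ValidationError("lineage total is zero for some sample")
        y = y / denom
    y = 100.0 * y  # percentage points
    smoking = sheet_df["smoking"].to_numpy(dtype=float)
    for group in (0, 1):
        if (smoking == group).sum() < 3:
            raise ValidationError("need >= 3 samples per smoking group")

    ns, sm_ = y[smoking == 0], y[smoking == 1]
    mean_ns, mean_sm = float(ns.mean()), float(sm_.mean())
    se_ns = float(ns.std(ddof=1) / np.sqrt(len(ns)))
    se_sm = float(sm_.std(ddof=1) / np.sqrt(len(sm_)))

    if np.ptp(y) == 0:
        warnings.warn(f"constant proportions for {subtype}; p undefined, set to 1")
        return ShiftTestResult(subtype, mean_ns, se_ns, mean_sm, se_sm, 0.0, 1.0, 1.0)

    def _fit(covariates: tuple[str, ...]) -> tuple[float, float]:
        X = pd.DataFrame({"smoking": smoking}, index=props.df.index)
        for cov in covariates:
            if cov not in sheet_df.columns:
                raise ValidationError(f"unknown covariate {cov!r}")
            col = sheet_df[cov]
            if col.dtype == object:
                dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
                X = pd.concat([X, dummies.astype(float)], axis=1)
            else:
                X[cov] = col.astype(float)
        X = sm.add_constant(X, has_constant="add")
        fit = sm.OLS(y, X.to_numpy()).fit()
        idx = list(X.columns).index("smoking")
        return float(fit.params[idx]), float(fit.pvalues[idx])

    coef, p = _fit(())
    p_adj = None
    if adjust:
        _, p_adj = _fit(tuple(adjust))
    return ShiftTestResult(subtype, mean_ns, se_ns, mean_sm, se_sm, coef, p, p_adj)


def shift_test_table(
    props: ProportionTable,
    sheet: SampleSheet,
    subtypes,
    adjust: tuple[str, ...] = ("age", "ancestry", "sex", "bmi"),
    renormalize: bool = False,
    lineage: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Run the shift test for several subtypes and stack the results."""
    rows = [
        subtype_shift_test(props, sheet, s, adjust, renormalize, lineage).as_dict()
        for s in subtypes
    ]
    return pd.DataFrame(rows)
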