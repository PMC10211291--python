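"""Whole-blood effects as proportion-weighted sums of cell-type effects.

The composite effect for a CpG is the sum over cell types of the
cell-type delta_meth times the cohort-average cell-type proportion. The
default weights are the printed coefficients (sum 1.007; not
renormalized unless asked). Myeloid and lymphoid sub-composites use the
full-blood weights, so they add up to the all-cell-type composite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from methylcell.methio.core import ValidationError

DEFAULT_WEIGHTS = {
    "Bcell": 0.073,
    "Gran": 0.55,
    "Mono": 0.037,
    "NK": 0.060,
    "CD4T": 0.20,
    "CD8T": 0.087,
}

MYELOID = ("Gran", "Mono")
LYMPHOID = ("Bcell", "NK", "CD4T", "CD8T")


@dataclass
class CompositeWeights:
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    renormalize: bool = False

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("composite weights must be nonnegative")
        if self.renormalize:
            total = sum(self.weights.values())
            self.weights = {k: w / total for k, w in self.weights.items()}

    def subset_types(self, subset: str) -> tuple[str, ...]:
        if subset == "all":
            return tuple(self.weights)
        if subset == "myeloid":
            return tuple(t for t in MYELOID if t in self.weights)
        if subset == "lymphoid":
            return tuple(t for t in LYMPHOID if t in self.weights)
        raise ValidationError(f"unknown subset {subset!r}")


def composite_delta(
    delta_by_celltype: pd.DataFrame,
    weights: CompositeWeights | None = None,
    subset: str = "all",
) -> pd.Series:
    """Weighted sum of per-cell-type delta_meth over the chosen subset.

    ``delta_by_celltype`` is CpG x cell type. Weights are the
    full-blood proportions even for subsets, so myeloid + lymphoid
    composites sum to the all-composite.
    """
    weights = weights or CompositeWeights()
    types = weights.subset_types(subset)
    missing = [t for t in types if t not in delta_by_celltype.columns]
    if missing:
        raise ValidationError(f"missing cell types for subset {subset!r}: {missing}")
    values = sum(
        weights.weights[t] * delta_by_celltype[t] for t in types
    )
    values.name = f"composite_{subset}"
    return values


def compare_to_wholeblood(
    composite: pd.Series,
    wb_delta: pd.Series,
    cpg_set=None,
) -> dict:
    """Pearson r (t-transform p) and OLS slopes between composite and
    whole-blood delta_meth over ``cpg_set`` (default: shared CpGs).

    Both regression orientations are reported because the printed
    scatter's orientation is ambiguous.
    """
    if cpg_set is None:
        cpg_set = composite.index.intersection(wb_delta.index)
    cpgs = [c for c in cpg_set if c in composite.index and c in wb_delta.index]
    if len(cpgs) < 3:
        raise ValidationError("need >= 3 CpGs to compare composite to whole blood")
    x = wb_delta.loc[cpgs].to_numpy(dtype=float)
    y = composite.loc[cpgs].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return {
            "n": len(cpgs),
            "r": np.nan,
            "p": np.nan,
            "slope_composite_on_wb": np.nan,
            "slope_wb_on_composite": np.nan,
        }
    r, p = stats.pearsonr(x, y)
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    return {
        "n": len(cpgs),
        "r": float(r),
        "p": float(p),
        "slope_composite_on_wb": float(sxy / sxx),
        "slope_wb_on_composite": float(sxy / syy),
    }


def composite_table(
    delta_by_celltype: pd.DataFrame,
    wb_delta: pd.Series,
    weights: CompositeWeights | None = None,
) -> pd.DataFrame:
    """Per-CpG composite values for all/myeloid/lymphoid next to WB delta."""
    weights = weights or CompositeWeights()
    out = pd.DataFrame(index=delta_by_celltype.index)
    for subset in ("all", "myeloid", "lymphoid"):
        out[f"composite_{subset}"] = composite_delta(delta_by_celltype, weights, subset)
    out["wb_delta"] = wb_delta.reindex(out.index)
    out.index.name = "cpg_id"
    return out
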