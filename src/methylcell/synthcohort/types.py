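"""Specification types for the synthetic cohort generator."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from methylcell.methio.core import ValidationError


@dataclass
class CellTypeSpec:
    """One blood cell type: its whole-blood share, the purity of its
    isolated fraction, and optional within-lineage subtype shares.

    ``subtypes`` are (label, within-lineage fraction) pairs; fractions
    must sum to <= 1 and are renormalized to 1 when composing the pure
    lineage profile.
    """

    name: str
    mean_proportion: float
    purity: float = 1.0
    subtypes: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_proportion <= 1.0:
            raise ValidationError(f"{self.name}: mean_proportion outside [0, 1]")
        if not 0.0 <= self.purity <= 1.0:
            raise ValidationError(f"{self.name}: purity outside [0, 1]")
        total = sum(f for _, f in self.subtypes)
        if total > 1.0 + 1e-9:
            raise ValidationError(f"{self.name}: subtype fractions sum to {total} > 1")
        labels = [s for s, _ in self.subtypes]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"{self.name}: duplicate subtype labels")

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        """Subtype labels if present, else the type's own name."""
        return tuple(s for s, _ in self.subtypes) or (self.name,)

    def lineage_shares(self) -> dict[str, float]:
        """Within-lineage subtype shares, renormalized to sum to 1."""
        if not self.subtypes:
            return {self.name: 1.0}
        total = sum(f for _, f in self.subtypes)
        return {s: f / total for s, f in self.subtypes}


@dataclass
class EffectSpec:
    """A direct smoking effect: a beta-scale delta added to smokers'
    profile of one cell type (or all) at one CpG before mixing."""

    cpg_id: str
    cell_type: str  # a cell-type label or "all"
    delta: float  # smoker - nonsmoker, beta scale
    mechanism: str = "direct"

    def __post_init__(self) -> None:
        if not -1.0 <= self.delta <= 1.0:
            raise ValidationError(f"effect delta {self.delta} outside [-1, 1]")
        if self.mechanism not in ("direct", "subtype_shift"):
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "subtype_shift" and self.delta != 0.0:
            raise ValidationError(
                "subtype_shift effects arise via proportion changes only; "
                "per-CpG delta must be 0"
            )


@dataclass
class TruthBundle:
    """Ground truth recorded by the generators for recovery tests."""

    true_proportions: pd.DataFrame | None = None  # subject x cell type
    true_subtype_shares: pd.DataFrame | None = None  # subject x leaf (shifted type)
    true_effects: list[EffectSpec] = field(default_factory=list)
    true_mqtl_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    true_eqtl_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    true_eqtm_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def validate_ids(self, cpg_ids, snp_ids=(), gene_ids=()) -> None:
        """Every id referenced by the truth must exist in the outputs."""
        cpg_ids, snp_ids, gene_ids = set(cpg_ids), set(snp_ids), set(gene_ids)
        for eff in self.true_effects:
            if eff.cpg_id not in cpg_ids:
                raise ValidationError(f"truth references unknown CpG {eff.cpg_id!r}")
        for snp, cpg, _ in self.true_mqtl_pairs:
            if snp not in snp_ids or cpg not in cpg_ids:
                raise ValidationError(f"truth references unknown mQTL pair ({snp}, {cpg})")
        for snp, gene, _ in self.true_eqtl_pairs:
            if snp not in snp_ids or gene not in gene_ids:
                raise ValidationError(f"truth references unknown eQTL pair ({snp}, {gene})")
        for cpg, gene, _ in self.true_eqtm_pairs:
            if cpg not in cpg_ids or gene not in gene_ids:
                raise ValidationError(f"truth references unknown eQTM pair ({cpg}, {gene})")


def default_cell_type_specs() -> tuple[CellTypeSpec, ...]:
    """The six isolated fractions with whole-blood shares matching the
    composite weights and subtype structure for the 12-subtype panel.

    Whole-blood shares sum to 1.007 as printed; the Dirichlet sampler
    renormalizes. Within-lineage subtype shares are chosen so that
    purity x share reproduces the reported subtype percentages of each
    isolated fraction (e.g. naive B 0.91 x 0.659 ~= 60% of the B
    fraction).
    """
    return (
        CellTypeSpec("Bcell", 0.073, purity=0.91, subtypes=(("NaiveB", 0.659), ("MemB", 0.341))),
        CellTypeSpec("Gran", 0.55, purity=0.95, subtypes=(("Neu", 0.996), ("Bas", 0.003), ("Eos", 0.001))),
        CellTypeSpec("Mono", 0.037, purity=0.94, subtypes=(("MonoS", 1.0),)),
        CellTypeSpec("NK", 0.060, purity=0.90, subtypes=(("NKS", 1.0),)),
        CellTypeSpec("CD4T", 0.20, purity=0.93, subtypes=(("NaiveCD4T", 0.392), ("MemCD4T", 0.549), ("Treg", 0.059))),
        CellTypeSpec("CD8T", 0.087, purity=0.93, subtypes=(("NaiveCD8T", 0.451), ("MemCD8T", 0.549))),
    )
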