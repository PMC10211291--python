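"""Synthetic reference methylation panels.

Profiles are drawn from a two-component Beta mixture (modes near 0.1
and 0.9) because array betas are bimodal. Each leaf cell type (subtype
where defined) receives dedicated signature CpGs whose beta is
separated by at least 0.5 from every other leaf.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from methylcell.deconv import ReferencePanel
from methylcell.methio.core import CpGAnnotation, ValidationError
from methylcell.synthcohort.types import CellTypeSpec

_CHROM = "chr1"
_GENOME_SPAN = 10_000_000


def _require_seed(seed) -> np.random.Generator:
    if seed is None or not isinstance(seed, (int, np.integer)):
        raise ValidationError("all generators require an explicit integer seed")
    return np.random.default_rng(int(seed))


def make_reference_panel(
    n_cpgs: int,
    specs: tuple[CellTypeSpec, ...],
    n_signature_per_type: int,
    seed: int,
) -> tuple[ReferencePanel, CpGAnnotation]:
    """Generate leaf-level reference profiles plus CpG positions.

    Returns a panel whose columns are the leaf labels (subtypes where a
    spec defines them, the type itself otherwise), with
    ``n_signature_per_type`` flagged signature CpGs per leaf, and a CpG
    annotation with sorted unique positions on a synthetic chromosome.
    """
    rng = _require_seed(seed)
    if not specs:
        raise ValidationError("specs must be non-empty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate cell-type names")
    leaves: list[str] = []
    for spec in specs:
        leaves.extend(spec.leaf_labels)
    if len(set(leaves)) != len(leaves):
        raise ValidationError("duplicate leaf labels across specs")
    n_leaves = len(leaves)
    if n_cpgs < n_leaves * n_signature_per_type:
        raise ValidationError(
            f"n_cpgs={n_cpgs} < {n_leaves} leaves x {n_signature_per_type} signatures"
        )

    n_signature = n_leaves * n_signature_per_type
    profiles = np.empty((n_cpgs, n_leaves))

    # background: bimodal consensus shared across leaves plus small jitter
    n_background = n_cpgs - n_signature
    low_mode = rng.random(n_background) < 0.5
    consensus = np.where(
        low_mode,
        rng.beta(2.0, 18.0, n_background),
        rng.beta(18.0, 2.0, n_background),
    )
    background = consensus[:, None] + rng.normal(0.0, 0.02, (n_background, n_leaves))
    profiles[:n_background] = np.clip(background, 0.02, 0.98)

    # signature rows: own leaf far from every other leaf (gap >= 0.5)
    signature_rows: dict[str, list[int]] = {leaf: [] for leaf in leaves}
    row = n_background
    for j, leaf in enumerate(leaves):
        for i in range(n_signature_per_type):
            hyper = i % 2 == 0  # alternate hyper-/hypo-methylated markers
            others = rng.uniform(0.05, 0.25, n_leaves)
            own = rng.uniform(0.80, 0.95)
            if not hyper:
                others = 1.0 - others
                own = 1.0 - own
            values = others
            values[j] = own
            profiles[row] = values
            signature_rows[leaf].append(row)
            row += 1

    # spread signature CpGs over the chromosome deterministically
    perm = rng.permutation(n_cpgs)
    profiles = profiles[perm]
    inverse = np.argsort(perm)

    positions = np.sort(rng.choice(_GENOME_SPAN, size=n_cpgs, replace=False))
    cpg_ids = [f"cg{i:07d}" for i in range(n_cpgs)]
    signature = {
        leaf: sorted(cpg_ids[inverse[r]] for r in rows)
        for leaf, rows in signature_rows.items()
    }
    panel = ReferencePanel(
        pd.DataFrame(profiles, index=pd.Index(cpg_ids, name="cpg_id"), columns=leaves),
        signature=signature,
    )
    annot = CpGAnnotation(
        pd.DataFrame({"cpg_id": cpg_ids, "chrom": _CHROM, "pos": positions})
    )
    return panel, annot


def collapse_to_types(
    panel: ReferencePanel, specs: tuple[CellTypeSpec, ...]
) -> ReferencePanel:
    """Collapse a leaf-level panel to cell-type profiles via the
    within-lineage subtype shares."""
    columns = {}
    for spec in specs:
        shares = spec.lineage_shares()
        missing = [s for s in shares if s not in panel.profiles.columns]
        if missing:
            raise ValidationError(f"panel lacks leaf profiles {missing} for {spec.name}")
        columns[spec.name] = sum(
            share * panel.profiles[leaf] for leaf, share in shares.items()
        )
    profiles = pd.DataFrame(columns, index=panel.profiles.index)
    signature = None
    if panel.signature is not None:
        signature = {
            spec.name: sorted(
                set().union(*[set(panel.signature.get(l, [])) for l in spec.leaf_labels])
            )
            for spec in specs
        }
    return ReferencePanel(profiles, signature=signature)
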