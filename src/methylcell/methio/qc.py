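"""Sample- and probe-level QC on beta matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from methylcell.methio.core import BetaMatrix, ValidationError


@dataclass
class QcReport:
    dropped_samples: dict[str, str] = field(default_factory=dict)
    dropped_cpgs: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "dropped_samples": dict(self.dropped_samples),
            "dropped_cpgs": dict(self.dropped_cpgs),
            "n_samples_dropped": len(self.dropped_samples),
            "n_cpgs_dropped": len(self.dropped_cpgs),
        }


def apply_qc(
    beta: BetaMatrix,
    detection_fail: pd.DataFrame | None = None,
    blacklist=(),
    sample_fail_frac: float = 0.05,
) -> tuple[BetaMatrix, QcReport]:
    """Drop failing samples, blacklisted CpGs and CpGs with residual failures.

    Order of operations: samples whose fraction of failed probes exceeds
    ``sample_fail_frac`` are removed first; then blacklisted CpGs; then
    any CpG still carrying a detection failure in a retained sample.
    """
    report = QcReport()
    df = beta.df

    if detection_fail is not None:
        if list(detection_fail.index) != list(df.index) or list(
            detection_fail.columns
        ) != list(df.columns):
            raise ValidationError(
                "detection failure indicator is not aligned with the beta matrix"
            )
        fail = detection_fail.astype(bool)
        frac = fail.mean(axis=0)
        for sample in df.columns[frac.to_numpy() > sample_fail_frac]:
            report.dropped_samples[str(sample)] = (
                f"failure fraction {frac[sample]:.4f} > {sample_fail_frac}"
            )
        keep_samples = [s for s in df.columns if s not in report.dropped_samples]
        if not keep_samples:
            raise ValidationError("QC dropped all samples")
        df = df[keep_samples]
        fail = fail[keep_samples]
    else:
        fail = None

    blacklist = set(blacklist)
    for cpg in df.index:
        if cpg in blacklist:
            report.dropped_cpgs[str(cpg)] = "blacklisted"
    if fail is not None:
        residual = fail.any(axis=1)
        for cpg in df.index[residual.to_numpy()]:
            report.dropped_cpgs.setdefault(str(cpg), "detection failure")
    keep_cpgs = [c for c in df.index if c not in report.dropped_cpgs]
    return BetaMatrix(df.loc[keep_cpgs]), report
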