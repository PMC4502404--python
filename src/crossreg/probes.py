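"""Cross-species methylation-probe orthology filtering.

Decides, per 450K array probe, whether it is retained for cross-species
analysis.  A probe designed on the human genome is kept only if it maps
uniquely to the chimpanzee genome with at most small, CpG-distal sequence
divergence and no common SNP near the assayed CpG in either species:

* exactly one unique mapping location in the chimpanzee genome;
* a perfect match, or 1-2 mismatches all outside the 3' 5 bp closest to
  the CpG (for a 50-mer: within the first 45 bp);
* no human SNP with MAF >= 0.05 and no chimpanzee SNP with MAF >= 0.15
  within the 5 bp closest to the CpG;
* detection p <= 0.01 in every sample.

Each dropped probe is attributed to the first failing rule in the fixed
order above, so reason counts partition the probe set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

#: bases at the CpG-proximal probe end where divergence is disallowed
CPG_EXCLUSION_BP = 5

REASONS = (
    "KEEP",
    "MULTI_OR_NO_MAP",
    "TOO_MANY_MISMATCHES",
    "MISMATCH_NEAR_CPG",
    "HUMAN_SNP_NEAR_CPG",
    "CHIMP_SNP_NEAR_CPG",
    "DETECTION_FAIL",
)


@dataclass
class ProbeAlignmentRecord:
    """One probe's cross-species mapping evidence.

    ``mismatch_offsets`` are 1-based positions from the probe's 5' end;
    SNPs are ``(offset_from_cpg_end, maf)`` pairs with offsets 1-based
    from the CpG-proximal end.
    """

    probe_id: str
    n_unique_hits: int
    mismatch_offsets: list[int] = field(default_factory=list)
    human_snps: list[tuple[int, float]] = field(default_factory=list)
    chimp_snps: list[tuple[int, float]] = field(default_factory=list)
    probe_length: int = 50
    design_type: str = "II"

    def validate(self) -> None:
        if self.n_unique_hits < 0:
            raise ValidationError(f"{self.probe_id}: negative hit count")
        for off in self.mismatch_offsets:
            if not 1 <= off <= self.probe_length:
                raise ValidationError(
                    f"{self.probe_id}: mismatch offset {off} outside probe"
                )
        for name, snps in (("human", self.human_snps), ("chimp", self.chimp_snps)):
            for off, maf in snps:
                if not 1 <= off <= self.probe_length:
                    raise ValidationError(
                        f"{self.probe_id}: {name} SNP offset {off} outside probe"
                    )
                if not 0 <= maf <= 0.5:
                    raise ValidationError(
                        f"{self.probe_id}: {name} SNP MAF {maf} outside [0, 0.5]"
                    )


@dataclass
class ProbeFilterDecision:
    probe_id: str
    keep: bool
    reason: str


def classify_probe(
    record: ProbeAlignmentRecord,
    human_maf_min: float = 0.05,
    chimp_maf_min: float = 0.15,
) -> ProbeFilterDecision:
    """Apply the sequence-level retention rules to one probe.

    Rules are checked in a fixed order (mapping, mismatch count, mismatch
    position, human SNP, chimpanzee SNP) and the first failure is
    reported.
    """
    record.validate()
    cpg_distal_max = record.probe_length - CPG_EXCLUSION_BP
    reason = "KEEP"
    if record.n_unique_hits != 1:
        reason = "MULTI_OR_NO_MAP"
    elif len(record.mismatch_offsets) > 2:
        reason = "TOO_MANY_MISMATCHES"
    elif any(off > cpg_distal_max for off in record.mismatch_offsets):
        reason = "MISMATCH_NEAR_CPG"
    elif any(
        off <= CPG_EXCLUSION_BP and maf >= human_maf_min
        for off, maf in record.human_snps
    ):
        reason = "HUMAN_SNP_NEAR_CPG"
    elif any(
        off <= CPG_EXCLUSION_BP and maf >= chimp_maf_min
        for off, maf in record.chimp_snps
    ):
        reason = "CHIMP_SNP_NEAR_CPG"
    return ProbeFilterDecision(record.probe_id, reason == "KEEP", reason)


def filter_detection(detection_p: pd.DataFrame, threshold: float = 0.01) -> pd.Series:
    """Probe-level keep mask from per-sample detection p-values.

    A probe failing detection (p > threshold, strict) in *any* sample is
    dropped globally, so all downstream analyses share one probe universe.
    Boundary p == threshold is retained.
    """
    if detection_p.isna().any().any():
        raise ValidationError("NaN detection p-value")
    if ((detection_p < 0) | (detection_p > 1)).any().any():
        raise ValidationError("detection p-values must lie in [0, 1]")
    return (detection_p <= threshold).all(axis=1)


def apply_probe_filters(
    records: list[ProbeAlignmentRecord],
    detection_p: pd.DataFrame,
    human_maf_min: float = 0.05,
    chimp_maf_min: float = 0.15,
    detection_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.Series]:
    """Combine sequence-level and detection filters.

    Returns ``(decisions, reason_counts)``: a per-probe decision table
    (probe_id, keep, reason) and a count per reason summing to the number
    of input probes.  Detection failure is reported only for probes that
    pass all sequence rules.
    """
    ids = [r.probe_id for r in records]
    missing = sorted(set(ids) - set(detection_p.index))
    if missing:
        raise ValidationError(f"probes missing from detection matrix: {missing}")
    det_keep = filter_detection(detection_p.loc[ids], detection_threshold) if ids \
        else pd.Series(dtype=bool)
    rows = []
    for rec in records:
        d = classify_probe(rec, human_maf_min, chimp_maf_min)
        if d.keep and not det_keep[rec.probe_id]:
            d = ProbeFilterDecision(rec.probe_id, False, "DETECTION_FAIL")
        rows.append((d.probe_id, d.keep, d.reason))
    decisions = pd.DataFrame(rows, columns=["probe_id", "keep", "reason"])
    counts = (
        decisions["reason"].value_counts().reindex(REASONS, fill_value=0)
    )
    return decisions, counts
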