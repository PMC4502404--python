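"""Cross-species histone-mark comparison at orthologous TSSs.

Covers the filters and scores used to compare H3K27ac / H3K27me3 ChIP-seq
signal between two species on a shared coordinate system:

* 200-bp orthologous windows are kept only if >= 80% of bases are
  uniquely mappable (20-bp k-mers) in *both* species;
* peaks are dropped when >= 80% of their bases fail to align to the
  other genome;
* a two-step cutoff calls a region shared when it passes a stringent
  threshold in one species and a relaxed one in the other (H3K27ac:
  FDR < 5% / < 15%; H3K27me3: domain score >= 20 / any enriched call),
  buffering incomplete peak-calling power across species;
* an input-normalised TSS enrichment score
  ``(RPKM_mark - RPKM_input) / (genome_mean_mark - genome_mean_input)``
  summarises signal in a 4-kb window centred on each orthologous TSS;
  a gene is "enriched" when its mean score across individuals exceeds 1
  (strictly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

WINDOW_BP = 200
MAPPABLE_MIN_FRACTION = 0.8
UNALIGNED_DROP_FRACTION = 0.8
H3K27AC_STRINGENT_FDR = 0.05
H3K27AC_RELAXED_FDR = 0.15
H3K27ME3_STRINGENT_SCORE = 20.0
TSS_WINDOW_BP = 4000


@dataclass
class OrthoWindow:
    """A 200-bp orthologous window with per-base k-mer uniqueness flags
    for each species."""

    window_id: str
    chrom: str
    start: int
    end: int
    mappable_a: np.ndarray
    mappable_b: np.ndarray

    def __post_init__(self) -> None:
        if self.end - self.start != WINDOW_BP:
            raise ValidationError(
                f"{self.window_id}: window must span {WINDOW_BP} bp"
            )
        for flags in (self.mappable_a, self.mappable_b):
            if len(flags) != self.end - self.start:
                raise ValidationError(
                    f"{self.window_id}: flag vector length != window length"
                )


@dataclass
class PeakCall:
    """One peak or enriched region called in one individual.

    ``score_kind`` is 'fdr' for H3K27ac (MACS) and 'domain_score' for
    H3K27me3 (HMM domain caller: sum of per-bin posterior scores).
    """

    peak_id: str
    species: str
    individual: str
    chrom: str
    start: int
    end: int
    mark: str
    score_kind: str
    score: float

    def __post_init__(self) -> None:
        if self.score_kind == "fdr" and not 0 <= self.score <= 1:
            raise ValidationError(f"{self.peak_id}: FDR outside [0, 1]")
        if self.score_kind == "domain_score" and self.score < 0:
            raise ValidationError(f"{self.peak_id}: negative domain score")


def window_mappable_fraction(window: OrthoWindow) -> tuple[float, float, bool]:
    """Per-species mappable fraction and the joint >= 80% pass flag."""
    frac_a = float(np.mean(np.asarray(window.mappable_a, bool)))
    frac_b = float(np.mean(np.asarray(window.mappable_b, bool)))
    ok = frac_a >= MAPPABLE_MIN_FRACTION and frac_b >= MAPPABLE_MIN_FRACTION
    return frac_a, frac_b, ok


def peak_align_fraction(
    peak: PeakCall, ortholog_map: pd.DataFrame
) -> tuple[float, bool]:
    """Fraction of peak bases failing to align to the other genome and
    the keep flag (drop when >= 80% fail).

    ``ortholog_map`` has columns ``chrom, start, end, aligned`` (0-based
    half-open segments in the peak's genome); bases not covered by any
    segment count as unaligned.  A peak entirely outside the map is
    treated as fully unaligned, with a warning.
    """
    seg = ortholog_map[ortholog_map["chrom"] == peak.chrom]
    length = peak.end - peak.start
    if length <= 0:
        raise ValidationError(f"{peak.peak_id}: empty peak")
    aligned = 0
    overlapped = False
    for _, s in seg.iterrows():
        lo, hi = max(peak.start, int(s["start"])), min(peak.end, int(s["end"]))
        if hi > lo:
            overlapped = True
            if bool(s["aligned"]):
                aligned += hi - lo
    if not overlapped:
        warnings.warn(
            f"peak {peak.peak_id} outside ortholog map; treated as unaligned",
            stacklevel=2,
        )
    failed = 1.0 - aligned / length
    return failed, failed < UNALIGNED_DROP_FRACTION


def two_step_classify(
    calls_by_species: dict[str, list[PeakCall]],
    mark: str,
    species_pair: tuple[str, str] | None = None,
) -> str:
    """Two-step cross-species retention for one orthologous region.

    ``calls_by_species`` maps each species to the (possibly empty) list of
    its retained calls overlapping the region.  Returns ``'shared'``,
    ``'<species>_only'`` or ``'absent'``.  For H3K27ac, stringent means
    FDR < 5% and relaxed FDR < 15%; for H3K27me3, stringent means domain
    score >= 20 and relaxed means any enriched call at all.
    """
    if species_pair is None:
        species_pair = tuple(sorted(calls_by_species))  # type: ignore[assignment]
    if len(species_pair) != 2:
        raise ValidationError("exactly two species required")

    def levels(calls: list[PeakCall]) -> tuple[bool, bool]:
        stringent = relaxed = False
        for call in calls:
            if mark == "H3K27ac":
                if call.score_kind != "fdr":
                    raise ValidationError(
                        f"{call.peak_id}: H3K27ac requires FDR scores"
                    )
                stringent |= call.score < H3K27AC_STRINGENT_FDR
                relaxed |= call.score < H3K27AC_RELAXED_FDR
            elif mark == "H3K27me3":
                if call.score_kind != "domain_score":
                    raise ValidationError(
                        f"{call.peak_id}: H3K27me3 requires domain scores"
                    )
                stringent |= call.score >= H3K27ME3_STRINGENT_SCORE
                relaxed = True  # any enriched call passes the relaxed step
            else:
                raise ValidationError(f"unknown mark {mark!r}")
        return stringent, relaxed

    a, b = species_pair
    sa, ra = levels(calls_by_species.get(a, []))
    sb, rb = levels(calls_by_species.get(b, []))
    if (sa and rb) or (sb and ra):
        return "shared"
    if sa:
        return f"{a}_only"
    if sb:
        return f"{b}_only"
    return "absent"


def tss_enrichment_score(
    rpkm_mark,
    rpkm_input,
    genome_mean_mark: float,
    genome_mean_input: float,
):
    """Input-normalised enrichment score at a TSS window.

    ``(RPKM_mark - RPKM_input) / (genome_mean_mark - genome_mean_input)``.
    A score > 0 means more mark than input reads; > 1 means an excess
    beyond the genome-wide mark-over-input average.
    """
    denom = genome_mean_mark - genome_mean_input
    if denom == 0:
        raise ValidationError(
            "genome-wide mark and input means are equal: degenerate background"
        )
    return (np.asarray(rpkm_mark, float) - np.asarray(rpkm_input, float)) / denom


def classify_gene_enrichment(scores, threshold: float = 1.0) -> bool:
    """A gene is enriched when the mean score across individuals is
    strictly greater than ``threshold``."""
    scores = np.asarray(scores, float)
    if scores.size == 0:
        raise ValidationError("empty score list")
    return bool(scores.mean() > threshold)


def rpkm(counts, total_reads, length_bp: float):
    """Reads per kilobase of window per million mapped reads."""
    counts = np.asarray(counts, float)
    total = np.asarray(total_reads, float)
    return counts / (length_bp / 1000.0) / (total / 1e6)


def score_tss_windows(
    mark_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    mark_totals: pd.Series,
    input_totals: pd.Series,
    window_bp: int = TSS_WINDOW_BP,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene enrichment scores and flags from TSS-window read counts.

    ``mark_counts``/``input_counts`` are gene x individual matrices of
    reads in the 4-kb TSS window; ``*_totals`` are mapped-read totals per
    individual.  The genome-wide mean RPKM is taken as the mean over all
    scored windows per individual.  Returns a DataFrame with per-
    individual scores, the gene mean score and the enriched flag.
    """
    if list(mark_counts.columns) != list(input_counts.columns):
        raise ValidationError("mark and input individuals differ")
    rp_mark = pd.DataFrame(
        rpkm(mark_counts.to_numpy(), mark_totals[mark_counts.columns].to_numpy(),
             window_bp),
        index=mark_counts.index, columns=mark_counts.columns,
    )
    rp_input = pd.DataFrame(
        rpkm(input_counts.to_numpy(), input_totals[input_counts.columns].to_numpy(),
             window_bp),
        index=input_counts.index, columns=input_counts.columns,
    )
    scores = {}
    for ind in mark_counts.columns:
        scores[ind] = tss_enrichment_score(
            rp_mark[ind], rp_input[ind],
            float(rp_mark[ind].mean()), float(rp_input[ind].mean()),
        )
    out = pd.DataFrame(scores, index=mark_counts.index)
    out["gene_mean_score"] = out.mean(axis=1)
    out["enriched"] = out["gene_mean_score"] > threshold
    out.attrs["threshold"] = threshold
    return out


@dataclass
class OverlapResult:
    """2x2 cross-species enrichment overlap with a chi-square test."""

    both: int
    a_only: int
    b_only: int
    neither: int
    chi2: float
    p: float
    warnings: list[str] = field(default_factory=list)

    @property
    def shared_fraction(self) -> float:
        """Fraction of genes enriched in both species among genes
        enriched in at least one."""
        at_least_one = self.both + self.a_only + self.b_only
        return self.both / at_least_one if at_least_one else float("nan")


def species_overlap_table(flags_a: pd.Series, flags_b: pd.Series) -> OverlapResult:
    """Cross-tabulate per-gene enrichment flags of two species and test
    association with a Pearson chi-square (1 df, no continuity
    correction)."""
    if set(flags_a.index) != set(flags_b.index):
        raise ValidationError("flag series must share one gene universe")
    fa = flags_a.astype(bool)
    fb = flags_b.loc[fa.index].astype(bool)
    both = int((fa & fb).sum())
    a_only = int((fa & ~fb).sum())
    b_only = int((~fa & fb).sum())
    neither = int((~fa & ~fb).sum())
    table = np.array([[both, a_only], [b_only, neither]], float)
    warn: list[str] = []
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    if (expected < 1).any():
        warn.append("expected cell count < 1; chi-square approximation is poor")
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return OverlapResult(both, a_only, b_only, neither, float(chi2), float(p), warn)
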