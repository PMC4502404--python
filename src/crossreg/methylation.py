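"""Methylation-array normalisation, DM testing and DMR calling.

Works on matrices of beta values (methylation fraction in [0, 1]) at CpG
probes shared across species.  Normalisation is quantile normalisation
across samples plus a monotone type-II -> type-I quantile map that
harmonises the two Infinium probe chemistries within each sample.
Differential methylation uses the shared moderated linear model; probes
passing the FDR and effect-size (|delta beta| >= 0.1) filters are grouped
into differentially methylated regions (DMRs): runs of >= 2 same-direction
DM probes whose consecutive CpGs are < 1 kb apart.

Delta beta follows the expression sign convention: chimpanzee mean minus
human mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import linmod
from .errors import ConfigurationError, ValidationError
from .expression import bh_fdr

PROMOTER_FEATURES = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
GENIC_FEATURES = frozenset({"Body", "3UTR"})


@dataclass
class BetaMatrix:
    """Probe x sample beta values with probe coordinates and annotation.

    Attributes
    ----------
    beta : DataFrame, probes x samples, values in [0, 1]
    probes : DataFrame indexed by probe id with columns ``chrom``,
        ``pos`` (1-based CpG coordinate), ``design_type`` ('I'/'II') and
        ``sex_chromosome`` (bool)
    samples : DataFrame indexed by sample id (``species``, ``sex``, ...)
    annotations : optional long DataFrame (probe_id, gene_id, feature)
    """

    beta: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame | None = None
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        b = self.beta.to_numpy()
        if np.isnan(b).any() or (b < 0).any() or (b > 1).any():
            raise ValidationError("beta values must lie in [0, 1]")
        # keep probes sorted by genomic coordinate
        order = self.probes.sort_values(["chrom", "pos"]).index
        self.probes = self.probes.loc[order]
        self.beta = self.beta.loc[order]


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalisation across samples.

    Each sample's sorted values are replaced by the rank-wise mean across
    samples; tied values share the mean of their rank range.  With a
    single sample this is the identity (with a warning).
    """
    if beta.shape[1] < 2:
        warnings.warn("single sample: quantile normalisation is the identity",
                      stacklevel=2)
        return beta.copy()
    arr = beta.to_numpy(float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    ranks = np.arange(1, arr.shape[0] + 1, dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        r = rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(r, ranks, mean_sorted)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def adjust_type2(beta: pd.DataFrame, design_type: pd.Series) -> pd.DataFrame:
    """Monotone quantile map of type-II probe values onto the type-I
    distribution, per sample.

    The two Infinium chemistries have systematically different beta
    distributions; this maps each sample's type-II values onto the
    empirical distribution of that sample's type-I values, leaving type-I
    values unchanged.  Intended for autosomal data only.
    """
    design_type = design_type.reindex(beta.index)
    if design_type.isna().any():
        raise ValidationError("missing design-type annotation for some probes")
    is2 = (design_type == "II").to_numpy()
    if not is2.any():
        return beta.copy()
    if not (~is2).any():
        raise ValidationError("no type-I probes to map onto")
    out = beta.copy().astype(float)
    n2 = int(is2.sum())
    q2 = (rankdata(out.loc[is2].to_numpy(), method="average", axis=0) - 0.5) / n2
    t1_sorted = np.sort(out.loc[~is2].to_numpy(float), axis=0)
    n1 = t1_sorted.shape[0]
    q1 = (np.arange(1, n1 + 1) - 0.5) / n1
    mapped = np.empty((n2, out.shape[1]))
    for j in range(out.shape[1]):
        mapped[:, j] = np.interp(q2[:, j], q1, t1_sorted[:, j])
    out.loc[is2] = mapped
    return out


def normalize_beta(bm: BetaMatrix) -> BetaMatrix:
    """Full normalisation: quantile normalise autosomes across all
    samples and X probes within each sex separately; then apply the
    type-II adjustment to autosomal data only."""
    sexchr = bm.probes["sex_chromosome"].astype(bool)
    beta = bm.beta.copy().astype(float)
    auto = quantile_normalize(beta.loc[~sexchr.to_numpy()])
    auto = adjust_type2(auto, bm.probes.loc[~sexchr, "design_type"])
    beta.loc[~sexchr.to_numpy()] = auto
    if sexchr.any():
        for sex, members in bm.samples.groupby("sex"):
            cols = [c for c in beta.columns if c in members.index]
            if cols:
                beta.loc[sexchr.to_numpy(), cols] = quantile_normalize(
                    beta.loc[sexchr.to_numpy(), cols]
                )
    return BetaMatrix(beta=beta, probes=bm.probes, samples=bm.samples,
                      annotations=bm.annotations, detection_p=bm.detection_p)


def dm_test(
    beta: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str] = ("chimp", "human"),
    fdr_threshold: float = 0.01,
    prior_df: float | None = None,
    m_values: bool = False,
) -> pd.DataFrame:
    """Moderated differential-methylation test per probe.

    ``design`` is a factor over samples: species-only for the reduced
    iPSC model or the six species/cell-type groups for the full model.
    The model is fitted on beta directly by default; ``m_values=True``
    fits logit-transformed beta (0.01 clamp) instead, but delta beta is
    always reported on the beta scale from group means.
    """
    design = pd.Series(design).loc[beta.columns]
    if (design.value_counts() < 2).any():
        raise ConfigurationError("each design cell needs >= 2 samples")
    y = beta.to_numpy(float)
    if m_values:
        clamped = np.clip(y, 0.01, 0.99)
        y = np.log2(clamped / (1 - clamped))
    X, c, _ = linmod.design_from_factor(design, contrast)
    fit = linmod.fit_moderated(y, X, c, prior_df=prior_df)
    q = bh_fdr(fit.p)
    g0 = design[design.astype(str) == str(contrast[0])].index
    g1 = design[design.astype(str) == str(contrast[1])].index
    delta = beta.loc[:, g0].mean(axis=1) - beta.loc[:, g1].mean(axis=1)
    res = pd.DataFrame(
        {
            "p": fit.p,
            "q": q,
            "delta_beta": delta.to_numpy(),
            "direction": np.sign(delta.to_numpy()),
            "dm_flag": q < fdr_threshold,
        },
        index=beta.index.rename("probe_id"),
    )
    res.attrs["fdr_threshold"] = fdr_threshold
    res.attrs["prior_df"] = fit.prior_df
    return res


def effect_filter(results: pd.DataFrame, min_delta: float = 0.1) -> pd.DataFrame:
    """Retain DM-flagged probes with |delta beta| >= ``min_delta``
    (boundary included)."""
    keep = results["dm_flag"] & (results["delta_beta"].abs() >= min_delta)
    return results.loc[keep]


@dataclass
class DMR:
    """A differentially methylated region.

    ``start``/``end`` are the coordinates of the first and last member
    CpG; ``direction`` is +1/-1 (chimpanzee minus human sign).
    """

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    direction: int
    mean_delta_beta: float
    gene_id: str | None = None
    position_class: str | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def call_dmrs(
    dm_probes: pd.DataFrame,
    max_gap: int = 1000,
    min_probes: int = 2,
) -> list[DMR]:
    """Greedy left-to-right grouping of filtered DM probes into DMRs.

    ``dm_probes`` must carry columns ``chrom``, ``pos``, ``delta_beta``
    and be sorted by (chrom, pos).  The current run is extended while the
    next probe is on the same chromosome, < ``max_gap`` bp (strict) from
    the previous member, and changes in the same direction; runs with at
    least ``min_probes`` members are emitted.
    """
    for col in ("chrom", "pos", "delta_beta"):
        if col not in dm_probes.columns:
            raise ValidationError(f"dm_probes lacks column {col!r}")
    by_pos = dm_probes[["chrom", "pos"]]
    if not by_pos.equals(by_pos.sort_values(["chrom", "pos"])):
        raise ValidationError("probes must be sorted by (chrom, pos)")

    regions: list[DMR] = []
    run: list[tuple[str, str, int, float]] = []  # (probe, chrom, pos, delta)

    def flush() -> None:
        if len(run) >= min_probes:
            deltas = [d for *_, d in run]
            regions.append(
                DMR(
                    chrom=run[0][1],
                    start=run[0][2],
                    end=run[-1][2],
                    probe_ids=[p for p, *_ in run],
                    direction=int(np.sign(deltas[0])),
                    mean_delta_beta=float(np.mean(deltas)),
                )
            )
        run.clear()

    for probe_id, row in dm_probes.iterrows():
        chrom, pos, delta = row["chrom"], int(row["pos"]), float(row["delta_beta"])
        if run:
            _, pchrom, ppos, pdelta = run[-1]
            if chrom != pchrom or pos - ppos >= max_gap or np.sign(delta) != np.sign(pdelta):
                flush()
        run.append((str(probe_id), chrom, pos, delta))
    flush()
    return regions


def associate_gene(dmr: DMR, annotations: pd.DataFrame) -> DMR | None:
    """Attach the single gene annotated to a DMR's member probes.

    The gene set is the union over member probes of their annotated
    genes; the DMR is kept iff exactly one distinct gene is found,
    otherwise ``None`` is returned (multiple or no genes).
    """
    hits = annotations[annotations["probe_id"].isin(dmr.probe_ids)]
    genes = set(hits["gene_id"])
    if len(genes) != 1:
        return None
    dmr.gene_id = genes.pop()
    return dmr


def classify_dmr_position(dmr: DMR, annotations: pd.DataFrame) -> str:
    """Classify a single-gene DMR as promoter, genic or mixed from its
    member probes' feature annotations."""
    hits = annotations[
        annotations["probe_id"].isin(dmr.probe_ids)
        & (annotations["gene_id"] == dmr.gene_id)
    ]
    features = set(hits["feature"].dropna())
    n_annotated = hits["probe_id"].nunique()
    if n_annotated < len(dmr.probe_ids) or not features:
        warnings.warn(
            f"DMR {dmr.chrom}:{dmr.start}-{dmr.end}: missing feature annotation;"
            " classified as mixed",
            stacklevel=2,
        )
        dmr.position_class = "mixed"
        return "mixed"
    if features <= PROMOTER_FEATURES:
        cls = "promoter"
    elif features <= GENIC_FEATURES:
        cls = "genic"
    else:
        cls = "mixed"
    dmr.position_class = cls
    return cls


def annotate_dmrs(dmrs: list[DMR], annotations: pd.DataFrame) -> list[DMR]:
    """Single-gene association plus positional classification; DMRs with
    multiple or no genes are discarded."""
    out = []
    for d in dmrs:
        kept = associate_gene(d, annotations)
        if kept is not None:
            classify_dmr_position(kept, annotations)
            out.append(kept)
    return out


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Tabular view of a DMR list."""
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "n_probes": [d.n_probes for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "mean_delta_beta": [d.mean_delta_beta for d in dmrs],
            "gene_id": [d.gene_id for d in dmrs],
            "position_class": [d.position_class for d in dmrs],
            "probe_ids": [",".join(d.probe_ids) for d in dmrs],
        }
    )
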