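"""Orthologous-gene expression pipeline.

Filtering, normalisation, species-specific RPKM and moderated
differential-expression testing between two species measured on a shared
set of one-to-one orthologous genes.  Because orthologous genes are not
constrained to have the same exonic length in both genomes, RPKM is always
computed with the gene length of the sample's own species before any
cross-species comparison.

The fixed pipeline order is: blacklist removal -> CPM -> expression filter
-> cyclic loess normalisation -> RPKM -> moderated DE test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import linmod
from .errors import ConfigurationError, ValidationError

#: pseudo-count added before taking log2 of RPKM, avoids log(0)
LOG_OFFSET = 0.25


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample metadata and gene lengths.

    Attributes
    ----------
    counts : DataFrame, genes x samples, non-negative integers
    samples : DataFrame indexed by sample id with columns
        ``species``, ``cell_type``, ``individual``, ``sex``
    lengths : DataFrame indexed by gene id with one positive length
        column per species (bp)
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValidationError("gene ids must be unique")
        if "species" not in self.samples.columns:
            raise ValidationError("sample sheet must have a 'species' column")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        if (self.lengths <= 0).any().any():
            raise ValidationError("gene lengths must be positive")

    @property
    def species(self) -> pd.Series:
        return self.samples.loc[self.counts.columns, "species"]


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column scaled to sum to 10^6."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {list(zero.index)}")
    return counts / totals * 1e6


def remove_blacklist(cm: CountMatrix, blacklist: set[str]) -> CountMatrix:
    """Drop blacklisted genes (e.g. ribosomal genes and pseudogenes).

    Ids absent from the matrix are ignored with a warning.
    """
    blacklist = set(blacklist)
    present = blacklist & set(cm.counts.index)
    absent = blacklist - present
    if absent:
        warnings.warn(
            f"{len(absent)} blacklisted id(s) not in the count matrix", stacklevel=2
        )
    keep = ~cm.counts.index.isin(present)
    return CountMatrix(
        counts=cm.counts.loc[keep],
        samples=cm.samples,
        lengths=cm.lengths.loc[cm.lengths.index.isin(cm.counts.index[keep])],
    )


def filter_expressed(
    cpm: pd.DataFrame,
    species: pd.Series,
    min_samples: int = 4,
    log2_cpm_min: float = 1.0,
) -> pd.Series:
    """Keep genes with > ``log2_cpm_min`` log2 CPM (strict) in at least
    ``min_samples`` samples of at least one species."""
    species = species.loc[cpm.columns]
    counts_per_species = species.value_counts()
    too_small = counts_per_species[counts_per_species < min_samples]
    if len(too_small):
        raise ConfigurationError(
            f"species with fewer than min_samples={min_samples} samples: "
            f"{list(too_small.index)}"
        )
    above = cpm > 2.0**log2_cpm_min
    keep = pd.Series(False, index=cpm.index)
    for sp in counts_per_species.index:
        keep |= above.loc[:, species[species == sp].index].sum(axis=1) >= min_samples
    return keep


def _ma_trend(m: np.ndarray, a: np.ndarray, df: int = 8) -> np.ndarray:
    """Smooth trend of M against A, fitted by least squares on a cubic
    truncated-power spline basis with quantile-spaced interior knots.

    Being an orthogonal projection, the fit of its own residuals is zero
    to machine precision, which makes the MA detrending idempotent.
    """
    n_knots = max(df - 4, 0)
    cols = [np.ones_like(a), a, a**2, a**3]
    if n_knots:
        knots = np.quantile(a, np.linspace(0, 1, n_knots + 2)[1:-1])
        for k in knots:
            cols.append(np.maximum(a - k, 0.0) ** 3)
    basis = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(basis, m, rcond=None)
    return basis @ coef


def cyclic_loess_normalize(
    log_cpm: pd.DataFrame,
    grouping: pd.Series,
    df: int = 8,
    iterations: int = 2,
) -> pd.DataFrame:
    """Pairwise cyclic MA-trend normalisation within sample groups.

    For every pair of samples in a group, a smooth curve of
    M = x_i - x_j against A = (x_i + x_j)/2 is fitted (regression-spline
    smoother, ``df`` degrees of freedom) and half the fitted trend is
    subtracted from one sample and added to the other; the cycle over
    pairs is repeated ``iterations`` times.  A stays invariant under the
    symmetric update, and the smoother is a least-squares projection, so
    for a sample pair the operation is idempotent.  Groups of size 1 are
    left unchanged with a warning; identical columns remain identical.
    """
    out = log_cpm.copy().astype(float)
    grouping = pd.Series(grouping).loc[log_cpm.columns]
    for group, members in grouping.groupby(grouping):
        cols = list(members.index)
        if len(cols) < 2:
            warnings.warn(f"group {group!r} has a single sample; left unchanged",
                          stacklevel=2)
            continue
        vals = out.loc[:, cols].to_numpy()
        for _ in range(iterations):
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    m = vals[:, i] - vals[:, j]
                    a = 0.5 * (vals[:, i] + vals[:, j])
                    if np.allclose(m, 0):
                        continue
                    fit = _ma_trend(m, a, df=df)
                    vals[:, i] -= fit / 2.0
                    vals[:, j] += fit / 2.0
        out.loc[:, cols] = vals
    return out


def compute_rpkm(
    cpm: pd.DataFrame, lengths: pd.DataFrame, species: pd.Series
) -> pd.DataFrame:
    """Reads per kilobase per million, with species-specific gene lengths.

    ``lengths`` has one column per species (bp); each sample is divided by
    the lengths of its own species.
    """
    lengths = lengths.loc[cpm.index]
    if (lengths <= 0).any().any():
        raise ValidationError("gene lengths must be positive")
    species = species.loc[cpm.columns]
    unknown = set(species.unique()) - set(lengths.columns)
    if unknown:
        raise ValidationError(f"no length column for species: {sorted(unknown)}")
    out = {}
    for s in cpm.columns:
        out[s] = cpm[s] / (lengths[species[s]] / 1000.0)
    return pd.DataFrame(out, index=cpm.index)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1, returned in the input
    order.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if np.isnan(p).any():
        raise ValidationError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def moderated_de_test(
    log2_rpkm: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str] = ("chimp", "human"),
    fdr_threshold: float = 0.01,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated differential-expression test between two factor levels.

    ``design`` is a categorical factor over samples (two species, or the
    six species/cell-type groups of the combined-tissue model, fitted as
    fixed effects).  The tested effect is
    ``contrast[0] - contrast[1]`` (default chimpanzee minus human, so
    positive log2 fold changes mean higher expression in chimpanzee).

    Returns a DataFrame with one row per gene: ``log2_fc``,
    ``moderated_t``, ``p``, ``q`` (BH), per-level mean RPKM for the two
    contrasted groups, and ``de_flag`` (q < ``fdr_threshold``, strict).
    """
    design = pd.Series(design).loc[log2_rpkm.columns]
    level_counts = design.value_counts()
    if (level_counts < 2).any():
        raise ConfigurationError(
            f"each design cell needs >= 2 samples, got {level_counts.to_dict()}"
        )
    X, c, _ = linmod.design_from_factor(design, contrast)
    fit = linmod.fit_moderated(log2_rpkm.to_numpy(), X, c, prior_df=prior_df)
    q = bh_fdr(fit.p)
    rpkm_lin = np.maximum(2.0**log2_rpkm - LOG_OFFSET, 0.0)
    res = pd.DataFrame(
        {
            "log2_fc": fit.coef,
            "moderated_t": fit.t,
            "p": fit.p,
            "q": q,
            "de_flag": q < fdr_threshold,
        },
        index=log2_rpkm.index.rename("gene_id"),
    )
    for lv in contrast:
        cols = design[design.astype(str) == str(lv)].index
        res[f"mean_rpkm_{lv}"] = rpkm_lin.loc[:, cols].mean(axis=1)
    res.attrs["fdr_threshold"] = fdr_threshold
    res.attrs["prior_df"] = fit.prior_df
    res.attrs["contrast"] = tuple(map(str, contrast))
    return res


@dataclass
class ExpressionPipelineResult:
    """Outputs of :func:`run_expression_pipeline`."""

    de_table: pd.DataFrame
    rpkm: pd.DataFrame
    kept_genes: pd.Index
    log: dict = field(default_factory=dict)


def run_expression_pipeline(
    cm: CountMatrix,
    blacklist: set[str] | None = None,
    min_samples: int = 4,
    log2_cpm_min: float = 1.0,
    fdr_threshold: float = 0.01,
    contrast: tuple[str, str] = ("chimp", "human"),
    normalize: bool = True,
    prior_df: float | None = None,
) -> ExpressionPipelineResult:
    """Run the full DE pipeline in its fixed order.

    blacklist -> CPM -> expression filter -> cyclic loess (within species)
    -> species-specific RPKM -> moderated DE test with BH-FDR.
    """
    log: dict = {"order": "blacklist,cpm,filter,loess,rpkm,de"}
    if blacklist:
        n_before = len(cm.counts)
        cm = remove_blacklist(cm, blacklist)
        log["blacklist_removed"] = n_before - len(cm.counts)
    cpm = compute_cpm(cm.counts)
    keep = filter_expressed(cpm, cm.species, min_samples, log2_cpm_min)
    cpm = cpm.loc[keep]
    log["genes_kept"] = int(keep.sum())
    log_cpm = np.log2(cpm + LOG_OFFSET)
    if normalize:
        log_cpm = cyclic_loess_normalize(log_cpm, cm.species)
    cpm_norm = np.maximum(2.0**log_cpm - LOG_OFFSET, 0.0)
    rpkm = compute_rpkm(cpm_norm, cm.lengths, cm.species)
    log2_rpkm = np.log2(rpkm + LOG_OFFSET)
    de = moderated_de_test(
        log2_rpkm, cm.species, contrast=contrast,
        fdr_threshold=fdr_threshold, prior_df=prior_df,
    )
    return ExpressionPipelineResult(
        de_table=de, rpkm=rpkm, kept_genes=cpm.index, log=log
    )
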