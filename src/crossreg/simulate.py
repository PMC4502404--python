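"""Synthetic-data generator for every pipeline input.

Generates count matrices, methylation beta matrices, probe-alignment
records and ChIP window counts with *known ground truth*, so each
downstream stage can be tested end-to-end without external data.  The
default configuration mirrors the study design the pipeline targets: two
species with 7 iPSC lines each, ~12,171 orthologous expressed genes with
~38% differentially expressed, ~335,307 retained CpG probes with planted
contiguous differentially methylated regions, and ~26,115 orthologous
TSSs with three ChIP individuals per species.

Each ``simulate_*`` call derives its own child random stream from
``(seed, table-id)``, so adding one output table never perturbs another
and a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .chip import OrthoWindow, PeakCall
from .errors import ConfigurationError
from .expression import CountMatrix
from .methylation import BetaMatrix
from .probes import ProbeAlignmentRecord

# child-stream ids, one per simulated table
_STREAM_EXPRESSION = 1
_STREAM_METHYLATION = 2
_STREAM_ALIGNMENT = 3
_STREAM_CHIP = 4

FEATURES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults describe the emulated study: sample sizes, DE fraction and
    probe/TSS universe sizes as reported for the real data; purely
    statistical parameters (dispersion, beta precision) are fixed choices
    documented in the methods note.
    """

    seed: int = 0
    # expression
    n_genes: int = 12_171
    samples_per_species: int = 7
    de_fraction: float = 0.379
    lfc_sd: float = 0.8
    nb_dispersion: float = 0.05
    mean_log_expression: float = 5.0
    # methylation
    n_probes: int = 335_307
    dm_region_count: int = 3_529
    dm_delta_beta: float = 0.2
    beta_precision: float = 30.0
    # probe alignment
    probe_mismatch_rate: float = 0.3
    snp_rate: float = 0.05
    # ChIP
    n_tss: int = 26_115
    chip_enriched_fraction: float = 0.3
    chip_fold: float = 5.0
    window_depth: float = 50.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("de_fraction", "chip_enriched_fraction",
                     "probe_mismatch_rate", "snp_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "samples_per_species", "n_probes", "n_tss"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.dm_region_count < 0:
            raise ConfigurationError("dm_region_count must be >= 0")
        if not 0 < self.dm_delta_beta < 1:
            raise ConfigurationError(
                f"dm_delta_beta must lie in (0, 1), got {self.dm_delta_beta}"
            )
        for name in ("lfc_sd", "nb_dispersion", "beta_precision",
                     "chip_fold", "window_depth"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class TruthSet:
    """Planted ground truth for one simulated dataset."""

    de_genes: dict[str, float] = field(default_factory=dict)
    dm_probes: dict[str, float] = field(default_factory=dict)
    dmr_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    probe_keep_flags: dict[str, bool] = field(default_factory=dict)
    chip_enriched_genes: set[str] = field(default_factory=set)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _sample_sheet(config: SimulationConfig, cell_type: str = "iPSC") -> pd.DataFrame:
    rows = []
    for species in ("chimp", "human"):
        for i in range(config.samples_per_species):
            rows.append(
                {
                    "sample_id": f"{species}_{cell_type}_{i + 1}",
                    "species": species,
                    "cell_type": cell_type,
                    "individual": f"{species[0].upper()}{i + 1}",
                    "sex": "F" if i % 2 == 0 else "M",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_expression(config: SimulationConfig) -> tuple[CountMatrix, TruthSet]:
    """Negative-binomial RNA-seq counts with planted DE genes.

    A ``de_fraction`` subset of genes gets a species log2 fold change
    drawn N(0, lfc_sd) (positive = higher in chimpanzee).  Library sizes
    are log-normal (sd 0.2 on the log) to make CPM normalisation
    non-trivial; per-species gene lengths differ by small indel offsets.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPRESSION)
    n = config.n_genes
    genes = pd.Index([f"G{i:06d}" for i in range(n)], name="gene_id")
    samples = _sample_sheet(config)
    is_chimp = (samples["species"] == "chimp").to_numpy()

    base_log2_cpm = rng.normal(config.mean_log_expression, 2.0, n)
    de_mask = rng.random(n) < config.de_fraction
    lfc = np.zeros(n)
    lfc[de_mask] = rng.normal(0.0, config.lfc_sd, int(de_mask.sum()))

    lib = 1e7 * np.exp(rng.normal(0.0, 0.2, len(samples)))
    log2_cpm = base_log2_cpm[:, None] + lfc[:, None] * is_chimp[None, :]
    mu = 2.0**log2_cpm / 1e6 * lib[None, :]
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    len_human = rng.integers(300, 5001, n)
    len_chimp = np.maximum(len_human + rng.integers(-30, 31, n), 50)
    lengths = pd.DataFrame(
        {"human": len_human, "chimp": len_chimp}, index=genes
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples.index),
        samples=samples,
        lengths=lengths,
    )
    truth = TruthSet(
        de_genes={genes[i]: float(lfc[i]) for i in np.flatnonzero(de_mask)}
    )
    return cm, truth


def _place_probes(
    rng: np.random.Generator, n_probes: int, x_fraction: float = 0.02
) -> pd.DataFrame:
    """Probe coordinates on synthetic chromosomes.

    60% of adjacent gaps are < 1 kb (clusters) and 40% are >= 1 kb, so
    DMR grouping exercises both branches of the gap rule.
    """
    n_x = int(round(n_probes * x_fraction))
    n_auto = n_probes - n_x
    chrom_sizes = [n_auto - 4 * (n_auto // 5)] + [n_auto // 5] * 4
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for ci, size in enumerate(chrom_sizes, start=1):
        short = rng.random(size) < 0.6
        gaps = np.where(
            short,
            rng.integers(50, 1000, size),
            rng.integers(1000, 20_000, size),
        )
        positions.append(1000 + np.cumsum(gaps))
        chroms.extend([f"chr{ci}"] * size)
    if n_x:
        gaps = rng.integers(200, 20_000, n_x)
        positions.append(1000 + np.cumsum(gaps))
        chroms.extend(["chrX"] * n_x)
    probes = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.concatenate(positions),
            "design_type": rng.choice(["I", "II"], n_probes, p=[0.28, 0.72]),
        },
        index=pd.Index([f"cg{i:07d}" for i in range(n_probes)], name="probe_id"),
    )
    probes["sex_chromosome"] = probes["chrom"] == "chrX"
    return probes


def simulate_methylation(config: SimulationConfig) -> tuple[BetaMatrix, TruthSet]:
    """Beta-distributed methylation values with planted contiguous DM
    regions.

    Baseline probe means are a bimodal mixture; ``dm_region_count``
    contiguous autosomal probe runs (>= 2 probes, consecutive gaps < 1 kb
    by construction) shift the chimpanzee group mean by +-
    ``dm_delta_beta`` with a consistent sign per region.  At most one
    region is planted per natural < 1-kb probe cluster, so planted
    boundaries are recoverable exactly.
    """
    config.validate()
    rng = _rng(config, _STREAM_METHYLATION)
    probes = _place_probes(rng, config.n_probes)
    samples = _sample_sheet(config)
    n = len(probes)
    is_chimp = (samples["species"] == "chimp").to_numpy()

    comp = rng.choice(3, n, p=[0.4, 0.2, 0.4])
    means = np.where(
        comp == 0,
        rng.uniform(0.03, 0.2, n),
        np.where(comp == 1, rng.uniform(0.2, 0.8, n), rng.uniform(0.8, 0.97, n)),
    )

    # natural <1 kb clusters on autosomes
    auto = ~probes["sex_chromosome"].to_numpy()
    pos = probes["pos"].to_numpy()
    chrom = probes["chrom"].to_numpy()
    new_cluster = np.ones(n, bool)
    same = (chrom[1:] == chrom[:-1]) & (pos[1:] - pos[:-1] < 1000) & auto[1:] & auto[:-1]
    new_cluster[1:] = ~same
    cluster_id = np.cumsum(new_cluster) - 1
    sizes = np.bincount(cluster_id)
    eligible = np.flatnonzero(sizes >= 2)
    eligible = eligible[auto[np.searchsorted(cluster_id, eligible)]]
    n_regions = min(config.dm_region_count, len(eligible))
    chosen = rng.choice(eligible, n_regions, replace=False) if n_regions else []

    delta = np.zeros(n)
    truth = TruthSet()
    cluster_start = np.searchsorted(cluster_id, np.arange(sizes.size))
    for cid in chosen:
        start = int(cluster_start[cid])
        size = int(sizes[cid])
        run_len = int(min(size, rng.integers(2, 7)))
        offset = int(rng.integers(0, size - run_len + 1))
        lo = start + offset
        hi = lo + run_len
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if sign > 0:
            means[lo:hi] = rng.uniform(0.05, 0.95 - config.dm_delta_beta, run_len)
        else:
            means[lo:hi] = rng.uniform(0.05 + config.dm_delta_beta, 0.95, run_len)
        delta[lo:hi] = sign * config.dm_delta_beta
        ids = probes.index[lo:hi]
        truth.dm_probes.update({p: float(sign * config.dm_delta_beta) for p in ids})
        truth.dmr_intervals.append(
            (
                str(chrom[lo]),
                int(pos[lo]),
                int(pos[hi - 1]),
                "+" if sign > 0 else "-",
            )
        )

    mean_matrix = means[:, None] + delta[:, None] * is_chimp[None, :]
    kappa = config.beta_precision
    a = np.clip(mean_matrix * kappa, 1e-3, None)
    b = np.clip((1.0 - mean_matrix) * kappa, 1e-3, None)
    beta = rng.beta(a, b)

    detection = rng.uniform(0.0, 0.005, size=beta.shape)
    fail = rng.random(beta.shape) < 0.002
    detection[fail] = rng.uniform(0.02, 0.3, int(fail.sum()))

    # gene annotation: 50-kb blocks share a gene; one feature per probe
    gene_block = (pos // 50_000).astype(int)
    gene_ids = np.array(
        [f"MG_{c}_{b}" for c, b in zip(chrom, gene_block)], dtype=object
    )
    features = rng.choice(FEATURES, n, p=[0.15, 0.15, 0.1, 0.1, 0.4, 0.1])
    annotations = pd.DataFrame(
        {"probe_id": probes.index, "gene_id": gene_ids, "feature": features}
    )

    bm = BetaMatrix(
        beta=pd.DataFrame(beta, index=probes.index, columns=samples.index),
        probes=probes,
        samples=samples,
        annotations=annotations,
        detection_p=pd.DataFrame(
            detection, index=probes.index, columns=samples.index
        ),
    )
    return bm, truth


def _truth_keep(
    n_unique_hits: int,
    mismatch_offsets: list[int],
    human_snps: list[tuple[int, float]],
    chimp_snps: list[tuple[int, float]],
    probe_length: int = 50,
) -> bool:
    """Literal transcription of the probe-retention rules, kept
    independent of :func:`crossreg.probes.classify_probe` on purpose so
    the two implementations can check each other."""
    if n_unique_hits != 1:
        return False
    if len(mismatch_offsets) > 2:
        return False
    # 1-2 mismatches allowed only in the first (probe_length - 5) bases
    for off in mismatch_offsets:
        if off > probe_length - 5:
            return False
    for off, maf in human_snps:
        if off <= 5 and maf >= 0.05:
            return False
    for off, maf in chimp_snps:
        if off <= 5 and maf >= 0.15:
            return False
    return True


def simulate_probe_alignments(
    config: SimulationConfig,
) -> tuple[list[ProbeAlignmentRecord], TruthSet]:
    """Probe-alignment records with configurable mismatch and SNP rates.

    Truth keep/drop flags are computed by an independent literal
    transcription of the filtering rules.
    """
    config.validate()
    rng = _rng(config, _STREAM_ALIGNMENT)
    records: list[ProbeAlignmentRecord] = []
    truth = TruthSet()
    for i in range(config.n_probes):
        pid = f"cg{i:07d}"
        u = rng.random()
        hits = 1 if u < 0.9 else (0 if u < 0.95 else 2)
        mism: list[int] = []
        if rng.random() < config.probe_mismatch_rate:
            k = int(rng.integers(1, 4))
            mism = sorted(int(x) for x in rng.choice(50, k, replace=False) + 1)
        hsnp: list[tuple[int, float]] = []
        if rng.random() < config.snp_rate:
            hsnp = [(int(rng.integers(1, 51)), float(rng.uniform(0, 0.5)))]
        csnp: list[tuple[int, float]] = []
        if rng.random() < config.snp_rate:
            csnp = [(int(rng.integers(1, 51)), float(rng.uniform(0, 0.5)))]
        records.append(
            ProbeAlignmentRecord(
                probe_id=pid,
                n_unique_hits=hits,
                mismatch_offsets=mism,
                human_snps=hsnp,
                chimp_snps=csnp,
            )
        )
        truth.probe_keep_flags[pid] = _truth_keep(hits, mism, hsnp, csnp)
    return records, truth


@dataclass
class ChipSimulation:
    """Simulated ChIP inputs: per-individual TSS-window counts for the
    mark and input channels, peak calls, orthology structures and
    truth."""

    mark_counts: pd.DataFrame
    input_counts: pd.DataFrame
    mark_totals: pd.Series
    input_totals: pd.Series
    individuals: pd.DataFrame
    tss: pd.DataFrame
    peaks: list[PeakCall]
    ortholog_map: pd.DataFrame
    windows: list[OrthoWindow]
    truth: TruthSet


def simulate_chip(config: SimulationConfig) -> ChipSimulation:
    """Poisson ChIP window counts with planted enriched genes.

    Enriched genes receive ``chip_fold`` x background intensity in the
    mark channel only, in both species (three individuals per species).
    The ortholog map contains unaligned segments and the 200-bp windows
    contain poorly mappable stretches, exercising both cross-species
    filters.
    """
    config.validate()
    rng = _rng(config, _STREAM_CHIP)
    n = config.n_tss
    genes = pd.Index([f"T{i:05d}" for i in range(n)], name="gene_id")
    individuals = pd.DataFrame(
        {
            "species": ["chimp"] * 3 + ["human"] * 3,
        },
        index=pd.Index(
            [f"chimp_{i}" for i in range(1, 4)] + [f"human_{i}" for i in range(1, 4)],
            name="individual",
        ),
    )
    enriched = rng.random(n) < config.chip_enriched_fraction
    fold = np.where(enriched, config.chip_fold, 1.0)
    depth = config.window_depth
    mark = rng.poisson(depth * fold[:, None], (n, 6))
    inp = rng.poisson(depth, (n, 6))
    mark_counts = pd.DataFrame(mark, index=genes, columns=individuals.index)
    input_counts = pd.DataFrame(inp, index=genes, columns=individuals.index)
    # library sizes are independent of the planted signal: a mark library
    # concentrates reads in enriched windows rather than growing overall
    lib = n * depth * 20.0
    mark_totals = pd.Series(
        lib * np.exp(rng.normal(0.0, 0.2, 6)), index=individuals.index
    )
    input_totals = pd.Series(
        lib * np.exp(rng.normal(0.0, 0.2, 6)), index=individuals.index
    )

    tss = pd.DataFrame(
        {"chrom": "chr1", "pos": 10_000 * np.arange(n) + 5_000}, index=genes
    )

    peaks: list[PeakCall] = []
    map_rows = []
    windows: list[OrthoWindow] = []
    for i, gene in enumerate(genes):
        pos = int(tss.loc[gene, "pos"])
        start, end = pos - 2000, pos + 2000
        # ortholog map: one aligned segment, occasionally an unaligned chunk
        if rng.random() < 0.1:
            cut = int(rng.integers(start + 200, end - 200))
            aligned_first = bool(rng.random() < 0.5)
            map_rows.append(("chr1", start, cut, aligned_first))
            map_rows.append(("chr1", cut, end, not aligned_first))
        else:
            map_rows.append(("chr1", start, end, True))
        # one 200-bp orthologous window per TSS with k-mer flags
        p_map = 0.97 if rng.random() < 0.9 else 0.5
        windows.append(
            OrthoWindow(
                window_id=f"W{i:05d}",
                chrom="chr1",
                start=pos - 100,
                end=pos + 100,
                mappable_a=rng.random(200) < p_map,
                mappable_b=rng.random(200) < p_map,
            )
        )
        for species in ("chimp", "human"):
            if enriched[i]:
                fdr = float(rng.uniform(0.0, 0.04))
            elif rng.random() < 0.05:
                fdr = float(rng.uniform(0.2, 1.0))
            else:
                continue
            peaks.append(
                PeakCall(
                    peak_id=f"P{i:05d}_{species}",
                    species=species,
                    individual=f"{species}_1",
                    chrom="chr1",
                    start=start,
                    end=end,
                    mark="H3K27ac",
                    score_kind="fdr",
                    score=fdr,
                )
            )
    ortholog_map = pd.DataFrame(
        map_rows, columns=["chrom", "start", "end", "aligned"]
    )
    truth = TruthSet(
        chip_enriched_genes={genes[i] for i in np.flatnonzero(enriched)}
    )
    return ChipSimulation(
        mark_counts=mark_counts,
        input_counts=input_counts,
        mark_totals=mark_totals,
        input_totals=input_totals,
        individuals=individuals,
        tss=tss,
        peaks=peaks,
        ortholog_map=ortholog_map,
        windows=windows,
        truth=truth,
    )
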