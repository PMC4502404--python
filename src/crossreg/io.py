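"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are TSV; genomic intervals are BED-like (0-based, half-open).
These helpers exist so simulated datasets and results round-trip through
the same on-disk formats real inputs would use.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .expression import CountMatrix
from .methylation import DMR
from .probes import ProbeAlignmentRecord
from .simulate import SimulationConfig, TruthSet


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_lengths_tsv(lengths: pd.DataFrame, path: str | Path) -> None:
    out = lengths.rename(
        columns={"human": "length_human_bp", "chimp": "length_chimp_bp"}
    )
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_lengths_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.rename(
        columns={"length_human_bp": "human", "length_chimp_bp": "chimp"}
    )


def write_sample_sheet_tsv(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_beta_tsv(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_probe_bed(probes: pd.DataFrame, path: str | Path) -> None:
    """Probe CpG coordinates as BED (0-based half-open single bases)."""
    bed = pd.DataFrame(
        {
            "chrom": probes["chrom"],
            "start": probes["pos"] - 1,
            "end": probes["pos"],
            "name": probes.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_alignment_records_tsv(
    records: list[ProbeAlignmentRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "probe_id": r.probe_id,
                "probe_length": r.probe_length,
                "n_unique_hits": r.n_unique_hits,
                "mismatch_offsets": ",".join(map(str, r.mismatch_offsets)),
                "human_snps": ";".join(f"{o}:{m!r}" for o, m in r.human_snps),
                "chimp_snps": ";".join(f"{o}:{m!r}" for o, m in r.chimp_snps),
                "design_type": r.design_type,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignment_records_tsv(path: str | Path) -> list[ProbeAlignmentRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)

    def snps(cell: str) -> list[tuple[int, float]]:
        if not cell:
            return []
        return [
            (int(part.split(":")[0]), float(part.split(":")[1]))
            for part in str(cell).split(";")
        ]

    records = []
    for _, row in df.iterrows():
        off = str(row["mismatch_offsets"])
        records.append(
            ProbeAlignmentRecord(
                probe_id=row["probe_id"],
                probe_length=int(row["probe_length"]),
                n_unique_hits=int(row["n_unique_hits"]),
                mismatch_offsets=[int(x) for x in off.split(",") if x],
                human_snps=snps(row["human_snps"]),
                chimp_snps=snps(row["chimp_snps"]),
                design_type=str(row["design_type"]),
            )
        )
    return records


def write_dmr_bed(dmrs: list[DMR], path: str | Path) -> None:
    """DMRs as BED with name=gene, score=floor(1000*|mean delta beta|)
    and extra columns direction/class/probe count."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = int(min(abs(d.mean_delta_beta), 1.0) * 1000)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            d.chrom,
                            d.start - 1,
                            d.end,
                            d.gene_id or ".",
                            score,
                            "+" if d.direction > 0 else "-",
                            d.position_class or ".",
                            d.n_probes,
                        ],
                    )
                )
                + "\n"
            )


def write_ortholog_map_tsv(ortholog_map: pd.DataFrame, path: str | Path) -> None:
    ortholog_map.to_csv(path, sep="\t", index=False)


def write_truth_json(truth: TruthSet, path: str | Path) -> None:
    payload = {
        "de_genes": truth.de_genes,
        "dm_probes": truth.dm_probes,
        "dmr_intervals": [list(t) for t in truth.dmr_intervals],
        "probe_keep_flags": truth.probe_keep_flags,
        "chip_enriched_genes": sorted(truth.chip_enriched_genes),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_config_json(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_json())


def read_config_json(path: str | Path) -> SimulationConfig:
    return SimulationConfig.from_json(Path(path).read_text())
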