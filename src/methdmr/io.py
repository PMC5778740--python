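"""Readers and writers for the pipeline's tabular formats.

Manifest, beta/detection matrices and sample sheets are plain TSV; regions
go out both as BED (0-based half-open, converted here from the internal
1-based inclusive coordinates — this is the only place the conversion
happens) and as a TSV mirroring the DMR summary table. Gene sets are read
from standard GMT (set name, description, then member genes, tab-separated).
"""
from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import MANIFEST_COLUMNS, DMRegion, MethylationDataset, QCReport, SpikeSpec
from .windows import regions_to_frame

__all__ = [
    "read_manifest", "write_manifest",
    "read_matrix", "write_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_dataset", "write_dataset",
    "write_regions_bed", "write_regions_tsv", "read_bed",
    "write_truth_bed", "read_gmt", "write_gmt", "write_qc_report",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    _require_columns(df, MANIFEST_COLUMNS, path)
    df["nearest_gene"] = df["nearest_gene"].where(df["nearest_gene"].notna(), None)
    df["dnase_hs"] = df["dnase_hs"].astype(bool)
    df["pos"] = df["pos"].astype(int)
    if df["pos"].min() < 1:
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    return df[MANIFEST_COLUMNS]


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA", float_format="%.6g")


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chip": str, "chip_position": str})
    _require_columns(df, ["sample_id"], path)
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_dataset(ds: MethylationDataset, out_dir: str, prefix: str = "") -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_manifest(ds.manifest, os.path.join(out_dir, f"{prefix}manifest.tsv"))
    write_matrix(ds.beta, os.path.join(out_dir, f"{prefix}beta.tsv"))
    if ds.detection_p is not None:
        write_matrix(ds.detection_p, os.path.join(out_dir, f"{prefix}detection_p.tsv"))
    write_sample_sheet(ds.samples, os.path.join(out_dir, f"{prefix}samples.tsv"))


def read_dataset(out_dir: str, prefix: str = "") -> MethylationDataset:
    manifest = read_manifest(os.path.join(out_dir, f"{prefix}manifest.tsv"))
    beta = read_matrix(os.path.join(out_dir, f"{prefix}beta.tsv"))
    det_path = os.path.join(out_dir, f"{prefix}detection_p.tsv")
    detection = read_matrix(det_path) if os.path.exists(det_path) else None
    samples = read_sample_sheet(os.path.join(out_dir, f"{prefix}samples.tsv"))
    return MethylationDataset(manifest=manifest, samples=samples, beta=beta, detection_p=detection)


def write_regions_bed(regions: Sequence[DMRegion], path: str) -> None:
    """Internal 1-based inclusive [start, end] becomes BED `start-1  end`."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = f"DMR{i + 1:04d}_{r.direction}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.n_probes}\n")


def write_regions_tsv(regions: Sequence[DMRegion], path: str) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def read_bed(path: str) -> pd.DataFrame:
    """Read BED into internal 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            rows.append((parts[0], start + 1, end, parts[3] if len(parts) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_truth_bed(spikes: Sequence[SpikeSpec], path: str) -> None:
    """Ground-truth regions as BED plus a delta_beta column."""
    with open(path, "w") as fh:
        for sp in spikes:
            fh.write(f"{sp.chrom}\t{sp.start - 1}\t{sp.end}\ttruth\t{sp.delta_beta:+.4f}\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    """GMT: set name, description, member genes (trailing tabs tolerated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs name, description, genes")
            genes = [g for g in parts[2:] if g.strip()]
            sets[parts[0]] = genes
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_qc_report(report: QCReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "metric\tvalue\n"
            f"n_probes_in\t{report.n_probes_in}\n"
            f"n_removed_missing\t{report.n_removed_missing}\n"
            f"n_removed_detection\t{report.n_removed_detection}\n"
            f"n_removed_total\t{report.n_removed_total}\n"
            f"n_probes_out\t{report.n_probes_out}\n"
            f"max_missing\t{report.max_missing}\n"
            f"max_detection_fail\t{report.max_detection_fail}\n"
            f"detection_alpha\t{report.detection_alpha}\n"
        )
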