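"""Readers and writers for the standard text formats the package consumes.

FASTA via Biopython; BED/bedGraph/TSV via pandas.  Coordinates are 0-based
half-open throughout, matching BED and bedGraph conventions.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .landscape import FreeEnergyTrack

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record) FASTA into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6; returns whichever of the 6 columns are present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def genes_from_bed6(bed: pd.DataFrame) -> pd.DataFrame:
    """Gene table (gene_id, chrom, tss, strand) from BED6 single-gene records.

    The TSS is the interval start for "+" genes and end-1 for "-" genes.
    """
    if "strand" not in bed.columns:
        raise ValueError("gene BED must have 6 columns (strand required)")
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    return pd.DataFrame(
        {
            "gene_id": bed["name"].astype(str),
            "chrom": bed["chrom"],
            "tss": tss.astype(int),
            "strand": bed["strand"],
        }
    )


def read_genes_gff3(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Gene table from GFF3 ``gene`` records (ID attribute as gene_id)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{chrom}:{start}-{end}")
            tss = start - 1 if strand == "+" else end - 1  # GFF3 is 1-based closed
            rows.append((gid, chrom, tss, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def write_bedgraph(track: FreeEnergyTrack, path: str | Path) -> None:
    """Write a track's defined positions as run-length-merged bedGraph lines."""
    vals = track.values
    defined = ~np.isnan(vals)
    with open(path, "w") as fh:
        if not defined.any():
            return
        idx = np.flatnonzero(defined)
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1 or vals[i] != vals[prev]:
                fh.write(
                    f"{track.chrom}\t{track.start + run_start}\t{track.start + prev + 1}\t{vals[prev]:.6g}\n"
                )
                run_start = i
            prev = i
        fh.write(
            f"{track.chrom}\t{track.start + run_start}\t{track.start + prev + 1}\t{vals[prev]:.6g}\n"
        )


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Expand a bedGraph into {chrom: per-position array} (NaN where undefined)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    if chrom_sizes is None:
        chrom_sizes = df.groupby("chrom")["end"].max().to_dict()
    out = {c: np.full(int(n), np.nan) for c, n in chrom_sizes.items()}
    for row in df.itertuples(index=False):
        out[row.chrom][row.start : row.end] = row.value
    return out


def read_pbm_table(path: str | Path) -> pd.DataFrame:
    """Read a PBM probe table: TSV with header ``probe_id sequence intensity``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"probe_id", "sequence", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"PBM table lacks columns {sorted(missing)}")
    lengths = df["sequence"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"all probes must share one length, got {sorted(lengths)}")
    if (df["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")
    return df


def load_config(path: str | Path) -> dict:
    """YAML key-value config; values supply defaults for CLI flags."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of option names to values")
    return cfg
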