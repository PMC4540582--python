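"""Metagene (TSS-aligned) profiles of genomic tracks.

Rows of a gene-profile matrix are track values on a TSS-relative grid,
oriented 5'->3' of each gene: coordinate 0 is the TSS base, negative
coordinates are upstream for both strands (minus-strand rows are
coordinate-reversed).  Averaging over genes gives the metagene profile;
error bars come from splitting genes into random subgroups and taking the
standard deviation of subgroup means.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .landscape import FreeEnergyTrack

logger = logging.getLogger(__name__)


@dataclass
class GeneProfileMatrix:
    """Genes x TSS-relative-positions matrix of track values."""

    positions: np.ndarray
    matrix: np.ndarray = field(repr=False)
    gene_ids: list[str] = field(default_factory=list)
    n_excluded: int = 0


def _track_arrays(track) -> Mapping[str, np.ndarray]:
    """Normalize a track argument to {chrom: per-position array}."""
    if isinstance(track, FreeEnergyTrack):
        if track.start != 0:
            vals = np.concatenate([np.full(track.start, np.nan), track.values])
        else:
            vals = track.values
        return {track.chrom: vals}
    if isinstance(track, Mapping):
        return {c: np.asarray(v, dtype=float) for c, v in track.items()}
    return {"chr": np.asarray(track, dtype=float)}


def _check_genes(genes: pd.DataFrame) -> pd.DataFrame:
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table lacks columns {sorted(missing)}")
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {genes.loc[bad, 'strand'].unique()}")
    return genes


def gene_aligned_matrix(
    track,
    genes: pd.DataFrame,
    flank: int,
    step: int = 1,
) -> GeneProfileMatrix:
    """Extract track values on the grid -flank..+flank (step) around each TSS.

    ``genes`` needs columns gene_id, chrom, tss (0-based), strand.  Rows with
    any grid position out of chromosome bounds (or genes on chromosomes absent
    from the track) are excluded and counted in ``n_excluded``.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if step < 1:
        raise ValueError("step must be >= 1")
    genes = _check_genes(genes)
    arrays = _track_arrays(track)
    offsets = np.arange(-flank, flank + 1, step)
    rows, ids = [], []
    n_excluded = 0
    for g in genes.itertuples(index=False):
        vals = arrays.get(g.chrom)
        if vals is None:
            n_excluded += 1
            continue
        idx = g.tss + offsets if g.strand == "+" else g.tss - offsets
        if idx.min() < 0 or idx.max() >= len(vals):
            n_excluded += 1
            continue
        rows.append(vals[idx])
        ids.append(str(g.gene_id))
    if n_excluded:
        logger.info("excluded %d genes with out-of-bounds windows", n_excluded)
    matrix = np.array(rows) if rows else np.empty((0, len(offsets)))
    return GeneProfileMatrix(offsets, matrix, ids, n_excluded)


def average_profile(
    matrix: GeneProfileMatrix,
    n_subgroups: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Metagene mean with subgroup-scatter error bars.

    Genes are split at random into ``n_subgroups`` near-equal subgroups
    (seeded); the error bar at each position is the standard deviation of
    the subgroup means.  Positions missing in some genes contribute to means
    over the defined entries only.
    """
    if n_subgroups < 2:
        raise ValueError("n_subgroups must be >= 2")
    n_genes = matrix.matrix.shape[0]
    if n_genes < n_subgroups:
        raise ValueError(f"fewer genes ({n_genes}) than subgroups ({n_subgroups})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    groups = np.array_split(order, n_subgroups)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(matrix.matrix, axis=0)
        sub_means = np.array([np.nanmean(matrix.matrix[g], axis=0) for g in groups])
    err = sub_means.std(axis=0, ddof=1)
    return pd.DataFrame({"position": matrix.positions, "mean": mean, "err": err})


def per_gene_min_f(
    track,
    genes: pd.DataFrame,
    interval: tuple[int, int] = (-1000, 1000),
    window: int = 100,
) -> pd.DataFrame:
    """Per-gene minimum track value in non-overlapping TSS-relative windows.

    The interval ``[lo, hi)`` is tiled with ``window``-bp bins (a trailing
    partial bin is dropped).  Windows that are entirely missing for a gene
    are dropped.  Returns columns gene_id, window_start, f_min.
    """
    lo, hi = interval
    if hi <= lo:
        raise ValueError("interval must be increasing")
    if window < 1:
        raise ValueError("window must be >= 1")
    n_windows = (hi - lo) // window
    if n_windows == 0:
        raise ValueError("interval shorter than one window")
    flank = max(abs(lo), abs(hi - 1))
    mat = gene_aligned_matrix(track, genes, flank=flank, step=1)
    pos0 = lo + flank  # column index of interval start
    out = []
    for r, gid in enumerate(mat.gene_ids):
        row = mat.matrix[r]
        for w in range(n_windows):
            start = pos0 + w * window
            seg = row[start : start + window]
            if np.all(np.isnan(seg)):
                continue
            out.append((gid, lo + w * window, np.nanmin(seg)))
    return pd.DataFrame(out, columns=["gene_id", "window_start", "f_min"])
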