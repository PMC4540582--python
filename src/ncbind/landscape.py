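"""Genome-wide nonconsensus free-energy tracks.

A track assigns to (the centre of) every sliding window along a chromosome
the ensemble-averaged free energy per bp, f = <F>/M, in kBT/bp.  The
shuffle-normalized variant reports df = (<F> - <F_rand>)/M, where F_rand is
the mean free energy of within-window composition-preserving shuffles; this
removes the contribution of plain nucleotide content and isolates the effect
of repetitive sequence *arrangement*.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .energy import (
    BinderEnsemble,
    ModelParams,
    _as_codes,
    sample_binder_ensemble,
    sliding_contact_counts,
    sliding_mean_free_energy,
)

logger = logging.getLogger(__name__)


@dataclass
class FreeEnergyTrack:
    """Per-position track of <f> (kBT/bp) along one chromosome.

    ``values`` spans the chromosome from ``start``; positions without a fully
    contained window (flanks, ambiguous-base windows, off-stride positions)
    hold NaN.
    """

    chrom: str
    start: int
    values: np.ndarray = field(repr=False)

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def positions(self) -> np.ndarray:
        """Absolute coordinates of defined positions."""
        return self.start + np.flatnonzero(self.defined())

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined()]


def window_center_offset(L: int) -> int:
    """Offset of the centre bp within a window: L//2 for odd L, L/2-1 for even."""
    return L // 2 - 1 if L % 2 == 0 else L // 2


def landscape_track(
    chrom_seq: str,
    params: ModelParams,
    stride: int = 1,
    ensemble: BinderEnsemble | None = None,
    chrom: str = "chr",
) -> FreeEnergyTrack:
    """Per-bp nonconsensus free energy f = <F>/M along a chromosome.

    One shared binder ensemble (seeded from ``params.seed`` unless supplied)
    is used for every window, so identical inputs give bitwise-identical
    tracks.  Sequences shorter than L yield an empty (all-NaN) track.
    """
    codes = _as_codes(chrom_seq)
    values = np.full(len(codes), np.nan)
    if len(codes) < params.L:
        logger.warning(
            "sequence %s (%d bp) shorter than window L=%d: empty track",
            chrom, len(codes), params.L,
        )
        return FreeEnergyTrack(chrom, 0, values)
    if ensemble is None:
        ensemble = sample_binder_ensemble(params)
    centers, F = sliding_mean_free_energy(
        codes, ensemble.K, params.M, params.L, params.kBT, stride
    )
    values[centers] = F / params.M
    return FreeEnergyTrack(chrom, 0, values)


def normalized_track(
    chrom_seq: str,
    params: ModelParams,
    stride: int = 1,
    n_shuffles: int = 25,
    ensemble: BinderEnsemble | None = None,
    seed: int | None = None,
    chrom: str = "chr",
) -> FreeEnergyTrack:
    """Shuffle-normalized track df = (<F> - <F_rand>)/M.

    Per window, ``F_rand`` averages the ensemble-mean free energy of
    ``n_shuffles`` uniform random permutations of the window's bases (fixed
    nucleotide content).  Each window's shuffles are seeded from
    ``(seed, window centre)`` so tracks are reproducible and independent of
    evaluation order.  A homopolymer window gives exactly 0.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    codes = _as_codes(chrom_seq)
    values = np.full(len(codes), np.nan)
    if len(codes) < params.L:
        logger.warning(
            "sequence %s (%d bp) shorter than window L=%d: empty track",
            chrom, len(codes), params.L,
        )
        return FreeEnergyTrack(chrom, 0, values)
    if ensemble is None:
        ensemble = sample_binder_ensemble(params)
    if seed is None:
        seed = params.seed
    K = ensemble.K
    L, M, kBT = params.L, params.M, params.kBT
    off = window_center_offset(L)
    first = off + (-off % stride)
    centers = np.arange(first, len(codes) - L + off + 1, stride)
    n_starts = L - M + 1

    for c in centers:
        w = codes[c - off : c - off + L]
        if np.any(w < 0):
            continue
        rng = np.random.default_rng([seed, int(c)])
        seqs = np.empty((n_shuffles + 1, L), dtype=np.int8)
        seqs[0] = w
        seqs[1:] = rng.permuted(np.broadcast_to(w, (n_shuffles, L)), axis=1)
        # one-hot -> M-bp sliding contact counts per variant
        onehot = (seqs[:, :, None] == np.arange(4, dtype=np.int8)).astype(np.float64)
        cs = np.cumsum(onehot, axis=1)
        counts = np.concatenate([cs[:, M - 1 : M], cs[:, M:] - cs[:, :-M]], axis=1)
        U = -np.einsum("swk,bk->swb", counts, K)  # (S+1, n_starts, n_binders)
        m = U.min(axis=1)
        with np.errstate(under="ignore"):
            F = m - kBT * np.log(
                np.exp(-(U - m[:, None, :]) / kBT).sum(axis=1)
            )  # (S+1, n_binders)
        meanF = F.mean(axis=1)
        values[c] = (meanF[0] - meanF[1:].mean()) / M
    return FreeEnergyTrack(chrom, 0, values)


def _nan_moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """NaN-aware centred moving average; mostly-missing spans stay NaN."""
    m = ~np.isnan(values)
    x = np.where(m, values, 0.0)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(m.astype(float), kernel, mode="same")
    out = num / np.maximum(den, 1.0)
    out[den < 0.5 * width] = np.nan
    return out


def robustness_sweep(
    chrom_seq: str,
    M_list,
    L_list,
    stride: int = 1,
    base_params: ModelParams | None = None,
    smooth: int = 0,
) -> pd.DataFrame:
    """Pairwise Spearman correlations between tracks across (M, L) settings.

    Tracks for every (M, L) in the cartesian product are computed with one
    shared ensemble seed, restricted to their commonly defined positions, and
    rank-correlated.  Returns a labelled square DataFrame.

    ``smooth`` (bp, 0 = off) applies a NaN-aware moving average to every
    track before correlating.  Tracks computed with different window widths
    resolve different scales, so their raw per-bp rank agreement is
    intrinsically limited by fine-scale fluctuations below the larger L;
    smoothing to a common resolution (>= the largest L) compares the
    landscapes like-for-like.
    """
    M_list, L_list = list(M_list), list(L_list)
    if base_params is None:
        base_params = ModelParams()
    if min(L_list) < max(M_list):
        raise ValueError(
            f"all L must be >= max(M): L={L_list}, M={M_list}"
        )
    combos = list(itertools.product(M_list, L_list))
    tracks = {}
    for M, L in combos:
        p = ModelParams(
            M=M, L=L, sigma=base_params.sigma, kBT=base_params.kBT,
            n_binders=base_params.n_binders, seed=base_params.seed,
            T_kelvin=base_params.T_kelvin,
        )
        vals = landscape_track(chrom_seq, p, stride=stride).values
        if smooth:
            # smooth on the stride grid, in units of samples
            grid = vals[:: stride] if stride > 1 else vals
            sm = _nan_moving_average(grid, max(1, smooth // stride))
            vals = np.full_like(vals, np.nan)
            vals[:: stride] = sm
        tracks[(M, L)] = vals
    common = np.ones(len(next(iter(tracks.values()))), dtype=bool)
    for v in tracks.values():
        common &= ~np.isnan(v)
    if not common.any():
        raise ValueError("no commonly defined positions across parameter settings")
    labels = [f"M={M},L={L}" for M, L in combos]
    mat = np.eye(len(combos))
    for i, a in enumerate(combos):
        for j in range(i + 1, len(combos)):
            rho = spearmanr(tracks[a][common], tracks[combos[j]][common]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=labels, columns=labels)
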