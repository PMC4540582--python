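"""Motif-context analysis: bound vs unbound motif instances.

All exact occurrences of a consensus motif are located on both genome
strands; each gets a flanking window centred on the motif, oriented by the
motif strand.  Sites overlapping experimentally bound intervals form the
"bound" group, the rest the "unbound" group.  The statistic is the
integrated difference of the group-mean per-bp free-energy profiles within a
motif-relative interval, and its significance comes from a group-label
permutation test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .energy import BinderEnsemble, ModelParams, encode_sequence, sample_binder_ensemble, sliding_mean_free_energy

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifSiteSet:
    """Exact motif occurrences with oriented flanking windows."""

    motif: str
    sites: pd.DataFrame  # chrom, start, strand, bound
    windows: list[str] = field(repr=False)
    flank: int = 400

    @property
    def group_sizes(self) -> tuple[int, int]:
        n_bound = int(self.sites["bound"].sum())
        return n_bound, len(self.sites) - n_bound

    def split(self) -> tuple[list[str], list[str]]:
        """(bound windows, unbound windows)."""
        bound = self.sites["bound"].to_numpy()
        return (
            [w for w, b in zip(self.windows, bound) if b],
            [w for w, b in zip(self.windows, bound) if not b],
        )


def _find_exact(seq: str, query: str) -> list[int]:
    """All (overlapping) exact match start positions of query in seq."""
    hits, i = [], seq.find(query)
    while i != -1:
        hits.append(i)
        i = seq.find(query, i + 1)
    return hits


def _overlaps(start: int, end: int, ivs: np.ndarray) -> bool:
    """ivs: (n, 2) sorted by start; half-open overlap test."""
    if len(ivs) == 0:
        return False
    i = np.searchsorted(ivs[:, 0], end)
    return bool(np.any(ivs[:i, 1] > start))


def collect_motif_windows(
    genome: Mapping[str, str],
    motif: str,
    bound_intervals: Sequence[tuple[str, int, int]] = (),
    flank: int = 400,
) -> MotifSiteSet:
    """Scan a genome for exact motif matches and extract oriented windows.

    Matches are found on both strands (reverse-complement matches reported on
    "-"; palindromic double-hits deduplicated).  A site is *bound* iff its
    motif interval overlaps any bound interval.  Windows span
    ``flank + len(motif) + flank`` bp around the motif and are
    reverse-complemented for minus-strand sites, so coordinates are
    motif-relative for every site; sites whose window would run off the
    chromosome are dropped with a log message.  Overlapping windows from
    nearby sites are all kept.
    """
    motif = motif.upper()
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    rc = reverse_complement(motif)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, s, e in bound_intervals:
        by_chrom.setdefault(chrom, []).append((s, e))  # type: ignore[attr-defined]
    by_chrom = {c: np.array(sorted(v)) for c, v in by_chrom.items()}

    rows, windows, n_dropped = [], [], 0
    for chrom, seq in genome.items():
        seq = seq.upper()
        hits = [(p, "+") for p in _find_exact(seq, motif)]
        if rc != motif:
            hits += [(p, "-") for p in _find_exact(seq, rc)]
        ivs = by_chrom.get(chrom, np.empty((0, 2), dtype=int))
        for pos, strand in sorted(hits):
            lo, hi = pos - flank, pos + len(motif) + flank
            if lo < 0 or hi > len(seq):
                n_dropped += 1
                continue
            w = seq[lo:hi]
            if strand == "-":
                w = reverse_complement(w)
            rows.append((chrom, pos, strand, _overlaps(pos, pos + len(motif), ivs)))
            windows.append(w)
    if n_dropped:
        logger.info("dropped %d motif sites with partial flanking windows", n_dropped)
    if not rows:
        raise ValueError(
            f"no exact matches of motif {motif!r} with full flanking windows in the genome"
        )
    sites = pd.DataFrame(rows, columns=["chrom", "start", "strand", "bound"])
    return MotifSiteSet(motif, sites, windows, flank)


def window_profiles(
    windows: Sequence[str],
    params: ModelParams,
    ensemble: BinderEnsemble | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window per-bp free-energy profiles on a motif-relative grid.

    All windows must share one length; coordinate 0 is the motif midpoint.
    Returns ``(rel_positions, matrix)`` where matrix is (n_windows, n_pos)
    with NaN at undefined (ambiguous-base) windows' positions.
    """
    if len(windows) == 0:
        raise ValueError("empty window list")
    n = len(windows[0])
    if any(len(w) != n for w in windows):
        raise ValueError("all windows must have equal length")
    if ensemble is None:
        ensemble = sample_binder_ensemble(params)
    mats, centers = [], None
    for w in windows:
        c, F = sliding_mean_free_energy(
            encode_sequence(w), ensemble.K, params.M, params.L, params.kBT, stride=1
        )
        centers = c
        mats.append(F / params.M)
    return centers - n // 2, np.array(mats)


def integrated_profile_values(
    rel_positions: np.ndarray,
    matrix: np.ndarray,
    interval: tuple[int, int] = (-400, 400),
) -> np.ndarray:
    """Per-window sum of profile values over the motif-relative interval."""
    lo, hi = interval
    cols = (rel_positions >= lo) & (rel_positions <= hi)
    if not cols.any():
        raise ValueError("interval contains no defined profile positions")
    return matrix[:, cols].sum(axis=1)


class GroupDifference(NamedTuple):
    profile_a: pd.DataFrame
    profile_b: pd.DataFrame
    delta: float
    integrated: np.ndarray  # per-window integrals, group a first
    n_a: int


def group_profiles_and_difference(
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: ModelParams,
    interval: tuple[int, int] = (-400, 400),
    ensemble: BinderEnsemble | None = None,
) -> GroupDifference:
    """Mean <f> profiles of two window groups and their integrated difference.

    ``delta = sum over interval of (mean_a - mean_b)``; negative when group a
    (conventionally the bound group) has the lower free energy.  The
    per-window integrals are returned so a permutation test can reuse them.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if ensemble is None:
        ensemble = sample_binder_ensemble(params)
    pos, mat = window_profiles(list(group_a) + list(group_b), params, ensemble)
    n_a = len(group_a)
    integ = integrated_profile_values(pos, mat, interval)
    mean_a, mean_b = mat[:n_a].mean(axis=0), mat[n_a:].mean(axis=0)
    delta = float(integ[:n_a].mean() - integ[n_a:].mean())
    prof_a = pd.DataFrame({"position": pos, "mean_f": mean_a})
    prof_b = pd.DataFrame({"position": pos, "mean_f": mean_b})
    return GroupDifference(prof_a, prof_b, delta, integ, n_a)


class PermutationResult(NamedTuple):
    p: float
    n_extreme: int
    n_perm: int

    @property
    def bound_str(self) -> str:
        if self.n_extreme == 0:
            return f"p < {1.0 / self.n_perm:g}"
        return f"p = {self.p:g}"


def permutation_pvalue(
    integrated: np.ndarray,
    group_sizes: tuple[int, int],
    observed_delta: float,
    n_perm: int = 100_000,
    seed: int = 0,
    alternative: str = "less",
) -> PermutationResult:
    """Group-label permutation test on precomputed per-window integrals.

    Permuted deltas are ``mean(first n1 of shuffled) - mean(rest)``.  With
    ``alternative="less"`` (the model's expected direction: bound group lower)
    p is the fraction of permutations with delta <= observed; "greater" and
    "two-sided" are also available.  No pseudo-count is added, so a zero
    count is reported as the bound p < 1/n_perm via ``bound_str``.
    """
    integrated = np.asarray(integrated, dtype=float)
    n1, n2 = group_sizes
    if n1 + n2 != len(integrated):
        raise ValueError(f"group sizes {group_sizes} do not sum to {len(integrated)} windows")
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-value resolution is poor")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    total = integrated.sum()
    deltas = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(integrated), size=n1, replace=False)
        s1 = integrated[pick].sum()
        deltas[i] = s1 / n1 - (total - s1) / n2
    if alternative == "less":
        n_extreme = int(np.sum(deltas <= observed_delta))
    elif alternative == "greater":
        n_extreme = int(np.sum(deltas >= observed_delta))
    else:
        n_extreme = int(np.sum(np.abs(deltas) >= abs(observed_delta)))
    return PermutationResult(n_extreme / n_perm, n_extreme, n_perm)
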