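"""Combined occupancy tracks and binned-scatter / linear-correlation statistics."""
from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    """Raised when a correlation is requested on constant input."""


class LinearAssociation(NamedTuple):
    R: float
    p: float
    n: int


def combined_occupancy(
    interval_sets: Mapping[str, Iterable[tuple[str, int, int]]],
    chrom_sizes: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Number of distinct factors bound at each genomic position.

    ``interval_sets`` maps a factor name to its (chrom, start, end) intervals,
    0-based half-open.  A factor counts at most once per position even where
    its own intervals overlap.  Returns {chrom: integer array}.
    """
    occ = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_sizes.items()}
    for tf, intervals in interval_sets.items():
        per_chrom: dict[str, np.ndarray] = {}
        for rec_i, (chrom, start, end) in enumerate(intervals):
            if start >= end:
                raise ValueError(
                    f"malformed interval for {tf!r} (record {rec_i}): "
                    f"{chrom}:{start}-{end}"
                )
            if chrom not in occ:
                raise ValueError(f"interval for {tf!r} on unknown chromosome {chrom!r}")
            if start < 0 or end > chrom_sizes[chrom]:
                raise ValueError(
                    f"interval for {tf!r} outside {chrom} bounds: {start}-{end}"
                )
            diff = per_chrom.setdefault(chrom, np.zeros(chrom_sizes[chrom] + 1, dtype=np.int32))
            diff[start] += 1
            diff[end] -= 1
        for chrom, diff in per_chrom.items():
            occ[chrom] += np.cumsum(diff[:-1]) > 0
    return occ


def binned_means(x, y, n_bins: int) -> pd.DataFrame:
    """Equal-count binning of (x, y) points sorted by x, with per-bin means.

    Bin sizes differ by at most one; ties are broken by stable sort order.
    Returns columns bin, x_mean, y_mean, count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if n_bins < 1 or n_bins > len(x):
        raise ValueError(f"n_bins={n_bins} invalid for {len(x)} points")
    order = np.argsort(x, kind="stable")
    rows = []
    for b, idx in enumerate(np.array_split(order, n_bins)):
        rows.append((b, x[idx].mean(), y[idx].mean(), len(idx)))
    return pd.DataFrame(rows, columns=["bin", "x_mean", "y_mean", "count"])


def linear_association(x, y) -> LinearAssociation:
    """Pearson correlation of a linear fit, with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector")
    res = stats.pearsonr(x, y)
    return LinearAssociation(float(res.statistic), float(res.pvalue), len(x))
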