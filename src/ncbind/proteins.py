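"""Repetitive amino-acid pattern statistics for protein groups.

Counts gapped repeat patterns [aa], [aXa], [aXXa], [aXXXa] (a = a fixed
residue, X = any residue) in protein sequences, overlapping occurrences
included, and compares two protein groups feature-by-feature with two-sample
Kolmogorov-Smirnov tests.  Features are the 20x4 pattern frequencies plus
the 20 residue composition fractions; p-values are reported raw (no
multiple-testing correction).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_GAP = 3


@dataclass(frozen=True)
class PatternSpec:
    """A gapped residue-repeat pattern: residue ``a`` twice, ``gap`` X's between."""

    residue: str
    gap: int

    def __post_init__(self) -> None:
        if self.residue not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {self.residue!r}")
        if not 0 <= self.gap <= MAX_GAP:
            raise ValueError(f"gap must be in 0..{MAX_GAP}, got {self.gap}")

    @property
    def name(self) -> str:
        return f"[{self.residue}{'X' * self.gap}{self.residue}]"


def all_pattern_specs() -> list[PatternSpec]:
    return [PatternSpec(a, g) for a in AMINO_ACIDS for g in range(MAX_GAP + 1)]


def pattern_count(seq: str, spec: PatternSpec, normalize: bool = False) -> float:
    """Overlapping occurrences of a(X^gap)a in a protein sequence.

    Non-standard letters are logged and never match.  With ``normalize``,
    the count is divided by the number of candidate positions
    ``len(seq) - gap - 1`` (0.0 for sequences too short to hold the pattern).
    """
    if len(seq) == 0:
        raise ValueError("empty protein sequence")
    seq = seq.upper()
    invalid = set(seq) - set(AMINO_ACIDS)
    if invalid:
        logger.info("skipping non-standard residues %s", sorted(invalid))
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    a = ord(spec.residue)
    span = spec.gap + 1
    if len(arr) <= span:
        count = 0
    else:
        count = int(np.sum((arr[:-span] == a) & (arr[span:] == a)))
    if normalize:
        denom = len(seq) - span
        return count / denom if denom > 0 else 0.0
    return float(count)


def composition(seq: str) -> pd.Series:
    """Fractions of the 20 standard residues; sums to 1 over valid residues."""
    if len(seq) == 0:
        raise ValueError("empty protein sequence")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    counts = np.array([np.sum(arr == ord(a)) for a in AMINO_ACIDS], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard residues")
    return pd.Series(counts / total, index=list(AMINO_ACIDS))


def _as_seq_list(group) -> list[str]:
    if isinstance(group, Mapping):
        return list(group.values())
    return list(group)


def group_comparison(
    group1,
    group2,
    patterns: Sequence[PatternSpec] | None = None,
    normalize: bool = True,
    include_composition: bool = True,
) -> pd.DataFrame:
    """Per-feature two-sample KS comparison of two protein groups.

    Groups are sequence collections (lists or {id: seq} mappings) of at least
    5 proteins each.  Default features: all 80 gapped patterns (as
    length-normalized frequencies when ``normalize``, raw counts otherwise)
    plus the 20 composition fractions.  Returns a DataFrame with columns
    feature, mean1, mean2, ks_stat, p -- p-values are raw KS p-values.
    """
    seqs1, seqs2 = _as_seq_list(group1), _as_seq_list(group2)
    if len(seqs1) < 5 or len(seqs2) < 5:
        raise ValueError("each group needs at least 5 sequences")
    if patterns is None:
        patterns = all_pattern_specs()
    rows = []

    def ks_row(name: str, v1: np.ndarray, v2: np.ndarray) -> None:
        if np.ptp(np.concatenate([v1, v2])) == 0:
            stat, p = 0.0, 1.0  # all values tied across both groups
        else:
            res = ks_2samp(v1, v2)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((name, v1.mean(), v2.mean(), stat, p))

    for spec in patterns:
        v1 = np.array([pattern_count(s, spec, normalize) for s in seqs1])
        v2 = np.array([pattern_count(s, spec, normalize) for s in seqs2])
        ks_row(spec.name, v1, v2)
    if include_composition:
        comp1 = np.array([composition(s).to_numpy() for s in seqs1])
        comp2 = np.array([composition(s).to_numpy() for s in seqs2])
        for i, a in enumerate(AMINO_ACIDS):
            ks_row(f"frac({a})", comp1[:, i], comp2[:, i])
    logger.info("KS p-values are reported without multiple-testing correction")
    return pd.DataFrame(rows, columns=["feature", "mean1", "mean2", "ks_stat", "p"])
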