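"""Random-binder statistical mechanics of nonconsensus protein-DNA binding.

A "random binder" is a model transcription factor defined by four Gaussian
energy constants, one per nucleotide.  A binder contacting ``M`` consecutive
base pairs starting at position ``i`` of a sequence has energy

    U(i) = -sum_{j=i}^{i+M-1} K[base(j)]          (units of kBT)

Within a sliding window of width ``L`` bp the binder explores every fully
contained start position (``L - M + 1`` of them), giving a partition function
``Z = sum_i exp(-U(i)/kBT)`` and a window free energy ``F = -kBT ln Z``.
Averaging F over an ensemble of random binders yields the *nonconsensus*
binding free energy of the window: an entropy-dominated quantity that is low
wherever the sequence carries repetitive (low-complexity) patterns, because
repeats widen the binder energy spectrum.

This module is a pure computational kernel: no file I/O.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

BASES = "ACGT"

#: Boltzmann constant in kcal/(mol*K); used only for unit conversion.
KB_KCAL_PER_MOL_K = 1.987e-3

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class InvalidWindowError(ValueError):
    """Raised when a sequence window contains ambiguous bases (N etc.)."""


def kbt_to_kcal_per_mol(energy_kbt: float, T_kelvin: float = 300.0) -> float:
    """Convert an energy from kBT units to kcal/mol at temperature ``T_kelvin``."""
    return energy_kbt * KB_KCAL_PER_MOL_K * T_kelvin


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0, C=1, G=2, T=3; anything else -> -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    out = np.full(len(codes), ord("N"), dtype=np.uint8)
    valid = codes >= 0
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    out[valid] = lut[codes[valid]]
    return out.tobytes().decode("ascii")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the random-binder model.

    M          binder footprint: base-pair contacts per binding event.
    L          sliding-window width in bp (>= M).  Genomic default 50;
               protein-binding-microarray probes use L = 36 (the probe length).
    sigma      standard deviation of the Gaussian energy constants, in kBT.
    kBT        thermal energy unit; the internal unit system fixes it to 1.
    n_binders  size of the random-binder ensemble.
    seed       seed for drawing the ensemble.
    T_kelvin   temperature, used only when converting energies to kcal/mol.
    """

    M: int = 8
    L: int = 50
    sigma: float = 2.0
    kBT: float = 1.0
    n_binders: int = 250
    seed: int = 0
    T_kelvin: float = 300.0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"M must be a positive integer, got {self.M}")
        if self.L < self.M:
            raise ValueError(f"L must be >= M, got L={self.L}, M={self.M}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.kBT <= 0:
            raise ValueError(f"kBT must be > 0, got {self.kBT}")
        if self.n_binders < 1:
            raise ValueError(f"n_binders must be >= 1, got {self.n_binders}")

    @property
    def n_starts(self) -> int:
        """Number of fully contained binder start positions per window."""
        return self.L - self.M + 1

    def pbm(self, probe_length: int = 36) -> "ModelParams":
        """Variant of these parameters for fixed-length microarray probes."""
        return replace(self, L=probe_length)


@dataclass(frozen=True)
class RandomBinder:
    """One model protein: an energy constant per nucleotide, in kBT."""

    K: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.K) != set(BASES):
            raise ValueError(f"K must have exactly the keys {set(BASES)}, got {set(self.K)}")
        if not all(np.isfinite(v) for v in self.K.values()):
            raise ValueError("all energy constants must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.K[b] for b in BASES], dtype=float)


class BinderEnsemble:
    """A fixed ensemble of random binders, stored as an (n, 4) array of K values."""

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[1] != 4:
            raise ValueError("ensemble K must have shape (n_binders, 4)")
        if not np.all(np.isfinite(K)):
            raise ValueError("ensemble K must be finite")
        self.K = K

    def __len__(self) -> int:
        return self.K.shape[0]

    def __getitem__(self, i: int) -> RandomBinder:
        return RandomBinder(dict(zip(BASES, self.K[i])))

    def __iter__(self) -> Iterator[RandomBinder]:
        return (self[i] for i in range(len(self)))


def sample_binder_ensemble(params: ModelParams) -> BinderEnsemble:
    """Draw ``params.n_binders`` binders with iid zero-mean Gaussian constants.

    Reproducible: the ensemble is a pure function of ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    K = rng.normal(0.0, params.sigma, size=(params.n_binders, 4))
    return BinderEnsemble(K)


@dataclass(frozen=True)
class SequenceWindow:
    """A DNA window with per-position indicator encoding."""

    bases: str

    @property
    def codes(self) -> np.ndarray:
        return encode_sequence(self.bases)

    @property
    def encoding(self) -> np.ndarray:
        """(len, 4) one-hot indicators; rows for ambiguous bases are all zero."""
        codes = self.codes
        onehot = np.zeros((len(codes), 4), dtype=np.int8)
        valid = codes >= 0
        onehot[np.arange(len(codes))[valid], codes[valid]] = 1
        return onehot

    @property
    def is_valid(self) -> bool:
        return bool(np.all(self.codes >= 0))

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class EnergyProfile:
    """Binding energies U(i), one per fully contained binder start in a window."""

    U: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        if not np.all(np.isfinite(U)):
            raise ValueError("energy profile must be finite")
        object.__setattr__(self, "U", U)

    def __len__(self) -> int:
        return len(self.U)


def _as_codes(window) -> np.ndarray:
    if isinstance(window, SequenceWindow):
        return window.codes
    if isinstance(window, str):
        return encode_sequence(window)
    return np.asarray(window, dtype=np.int8)


def _as_K_matrix(ensemble) -> np.ndarray:
    """Accept BinderEnsemble, RandomBinder, or bare arrays; return (n, 4)."""
    if isinstance(ensemble, BinderEnsemble):
        return ensemble.K
    if isinstance(ensemble, RandomBinder):
        return ensemble.as_array()[None, :]
    K = np.asarray(ensemble, dtype=float)
    if K.ndim == 1:
        K = K[None, :]
    return K


def sliding_contact_counts(codes: np.ndarray, M: int):
    """Per-start nucleotide contact counts within an M-bp footprint.

    Returns ``(counts, valid)`` where ``counts`` has shape (n_starts, 4) and
    ``valid`` marks starts whose M bases are all unambiguous.
    """
    n = len(codes)
    if n < M:
        raise ValueError(f"sequence of length {n} is shorter than footprint M={M}")
    onehot = np.zeros((n + 1, 5), dtype=np.int32)
    np.add.at(onehot, (np.arange(1, n + 1), np.where(codes >= 0, codes, 4)), 1)
    cs = np.cumsum(onehot, axis=0)
    win = cs[M:] - cs[:-M]
    return win[:, :4], win[:, 4] == 0


def energy_profile(binder, window, M: int) -> EnergyProfile:
    """Binding energies of one binder at every fully contained start of a window.

    ``U(i) = -sum_{j=i}^{i+M-1} K[base(j)]``.
    """
    codes = _as_codes(window)
    if len(codes) < M:
        raise ValueError(f"window of length {len(codes)} is shorter than M={M}")
    if np.any(codes < 0):
        raise InvalidWindowError("window contains ambiguous bases")
    K = _as_K_matrix(binder)[0]
    counts, _ = sliding_contact_counts(codes, M)
    return EnergyProfile(-(counts @ K))


def window_free_energy(profile, kBT: float = 1.0) -> float:
    """Free energy F = -kBT ln sum_i exp(-U(i)/kBT) of one window's profile.

    Computed with log-sum-exp stabilization; satisfies F <= min_i U(i).
    """
    U = np.asarray(profile.U if isinstance(profile, EnergyProfile) else profile, dtype=float)
    if U.size == 0:
        raise ValueError("empty energy profile")
    return float(-kBT * logsumexp(-U / kBT))


def binder_free_energies(codes: np.ndarray, K: np.ndarray, M: int, kBT: float = 1.0) -> np.ndarray:
    """Window free energy of each binder for one window (all starts contained)."""
    counts, valid = sliding_contact_counts(codes, M)
    if not np.all(valid):
        raise InvalidWindowError("window contains ambiguous bases")
    U = -(counts @ K.T)  # (n_starts, n_binders)
    return -kBT * logsumexp(-U / kBT, axis=0)


def mean_free_energy(ensemble, window, params: ModelParams):
    """Ensemble-averaged window free energy <F> and the per-bp value f = <F>/M.

    The whole supplied window is treated as the sliding window, so the binder
    explores ``len(window) - M + 1`` start positions (e.g. 43 for L=50, M=8;
    29 for a 36-bp probe).  Returns ``(F_mean, f)``.
    """
    codes = _as_codes(window)
    if len(codes) < params.M:
        raise ValueError("window shorter than the binder footprint")
    if np.any(codes < 0):
        raise InvalidWindowError("window contains ambiguous bases")
    K = _as_K_matrix(ensemble)
    F = binder_free_energies(codes, K, params.M, params.kBT)
    F_mean = float(F.mean())
    return F_mean, F_mean / params.M


def tract_to_iid_width_ratio(M: int) -> float:
    """Closed-form ratio sigma_U(homo-tracts) / sigma_U(iid) = 2/sqrt(1 + 3/M).

    For an iid uniform sequence the contact counts are multinomial, giving
    Var U = sigma^2 (M^2 + 3M)/4; a binder fully inside a homonucleotide tract
    sees Var U = sigma^2 M^2.  The ratio tends to 2 as M grows.
    """
    return 2.0 / np.sqrt(1.0 + 3.0 / M)


def _tract_sequence(n: int, M: int, tract_length: int | None = None) -> np.ndarray:
    """Alternating poly(A)/poly(T) tracts, each much longer than the footprint."""
    if tract_length is None:
        tract_length = 20 * M
    n_tracts = int(np.ceil(n / tract_length))
    blocks = [np.full(tract_length, 0 if t % 2 == 0 else 3, dtype=np.int8) for t in range(n_tracts)]
    return np.concatenate(blocks)[:n]


def spectrum_width(
    sequence_spec: str,
    params: ModelParams,
    n_samples: int = 100_000,
    seed: int | None = None,
    tract_length: int | None = None,
) -> float:
    """Standard deviation of the binder energy spectrum U over positions x binders.

    ``sequence_spec`` selects the sequence class:
      * ``"iid-random"``     -- iid uniform ACGT;
      * ``"two-type-tracts"``-- alternating poly(A)/poly(T) tracts (default
        length 20*M each), the idealized low-complexity limit.

    ``n_samples`` is the minimum number of (position, binder) energy draws.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_positions = max(int(np.ceil(n_samples / params.n_binders)), 1)
    n = n_positions + params.M - 1
    if sequence_spec == "iid-random":
        codes = rng.integers(0, 4, size=n, dtype=np.int8)
    elif sequence_spec == "two-type-tracts":
        codes = _tract_sequence(n, params.M, tract_length)
    else:
        raise ValueError(f"unknown sequence_spec {sequence_spec!r}")
    K = rng.normal(0.0, params.sigma, size=(params.n_binders, 4))
    counts, _ = sliding_contact_counts(codes, params.M)
    counts = counts.astype(float)
    # accumulate moments in binder chunks to bound memory at large ensembles
    chunk = max(1, 20_000_000 // max(1, counts.shape[0]))
    total, s1, s2 = 0, 0.0, 0.0
    for b0 in range(0, params.n_binders, chunk):
        U = -(counts @ K[b0 : b0 + chunk].T)
        total += U.size
        s1 += U.sum()
        s2 += np.square(U).sum()
    var = (s2 - s1**2 / total) / (total - 1)
    return float(np.sqrt(var))


def sliding_mean_free_energy(
    codes: np.ndarray,
    K: np.ndarray,
    M: int,
    L: int,
    kBT: float = 1.0,
    stride: int = 1,
    max_chunk_elems: int = 30_000_000,
):
    """Ensemble-mean window free energy <F> along a sequence.

    Windows are placed so that their centre positions fall on the absolute
    grid ``{0, stride, 2*stride, ...}`` (for even L the centre is the
    left-of-middle base, offset L/2 - 1), which keeps centre grids of
    different L values comparable.  Windows containing ambiguous bases give
    NaN.  Returns ``(centers, F_mean)``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(codes)
    if n < L:
        return np.empty(0, dtype=int), np.empty(0)
    off = L // 2 - 1 if L % 2 == 0 else L // 2
    first = off + (-off % stride)
    centers = np.arange(first, n - L + off + 1, stride)
    if len(centers) == 0:
        return centers, np.empty(0)
    starts = centers - off
    n_starts = L - M + 1

    counts, valid = sliding_contact_counts(codes, M)
    # window is valid iff all its M-footprints are valid
    bad = np.cumsum(np.concatenate([[0], (~valid).astype(np.int64)]))
    window_ok = (bad[starts + n_starts] - bad[starts]) == 0

    n_binders = K.shape[0]
    F_sum = np.zeros(len(starts))
    chunk = max(1, min(n_binders, max_chunk_elems // max(1, len(starts) * n_starts)))
    idx = starts[:, None] + np.arange(n_starts)[None, :]
    for b0 in range(0, n_binders, chunk):
        Kc = K[b0 : b0 + chunk]
        U = -(counts @ Kc.T)  # (n_pos, chunk)
        Uw = U[idx]  # (n_windows, n_starts, chunk)
        m = Uw.min(axis=1)
        with np.errstate(under="ignore"):
            F = m - kBT * np.log(np.exp(-(Uw - m[:, None, :]) / kBT).sum(axis=1))
        F_sum += F.sum(axis=1)
    F_mean = F_sum / n_binders
    F_mean[~window_ok] = np.nan
    return centers, F_mean
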