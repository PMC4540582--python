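"""Protein-binding-microarray (PBM) analysis.

Each probe is a fixed-length (typically 36-bp) DNA sequence; the binder
ensemble assigns it a single per-bp free energy <f> (no sliding of the
window, since the probe *is* the window).  Per factor, probes are binned by
<f> into equal-count bins, bin-mean intensity is regressed on bin-mean <f>,
and the factor is classified by the sign and significance of the
correlation: "negative" factors bind low-free-energy (repeat-rich) probes
more strongly, as the nonconsensus model predicts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import DegenerateInputError, binned_means, linear_association
from .energy import BinderEnsemble, InvalidWindowError, ModelParams, mean_free_energy

logger = logging.getLogger(__name__)

CLASSES = ("negative", "positive", "ns")


@dataclass(frozen=True)
class PBMRecord:
    """Per-factor association between probe free energy and binding intensity."""

    tf_id: str
    R: float
    p: float
    label: str
    R_unbinned: float
    p_unbinned: float
    n_probes: int


def probe_free_energy(probe: str, ensemble: BinderEnsemble, params: ModelParams) -> float:
    """Per-bp free energy <f> of one probe; NaN for probes with ambiguous bases."""
    try:
        _, f = mean_free_energy(ensemble, probe, params)
    except InvalidWindowError:
        logger.info("skipping probe with ambiguous bases: %s", probe)
        return np.nan
    return f


def probe_free_energies(
    probes: Sequence[str], ensemble: BinderEnsemble, params: ModelParams
) -> np.ndarray:
    """Vector of <f> values for a probe list (NaN where a probe is skipped)."""
    return np.array([probe_free_energy(p, ensemble, params) for p in probes])


def classify(R: float, p: float, alpha: float = 0.05) -> str:
    if p < alpha:
        return "negative" if R < 0 else "positive"
    return "ns"


def tf_association(
    table: pd.DataFrame,
    energies: np.ndarray,
    n_bins: int = 50,
    alpha: float = 0.05,
    tf_id: str = "",
) -> PBMRecord:
    """Classify one factor from its probe intensities and probe free energies.

    ``table`` needs an ``intensity`` column aligned with ``energies``.  Probes
    whose energy is NaN are dropped.  The headline R and p come from the
    ``n_bins`` equal-count binned means; the unbinned correlation is kept for
    diagnostics.  Constant intensities give class "ns" with a warning.
    """
    intensity = np.asarray(table["intensity"], dtype=float)
    energies = np.asarray(energies, dtype=float)
    if len(intensity) != len(energies):
        raise ValueError("table and energies are not aligned")
    keep = ~np.isnan(energies)
    f, y = energies[keep], intensity[keep]
    try:
        binned = binned_means(f, y, min(n_bins, len(f)))
        R, p, _ = linear_association(binned["x_mean"], binned["y_mean"])
        Ru, pu, _ = linear_association(f, y)
    except DegenerateInputError:
        logger.warning("degenerate intensities for %s: classified ns", tf_id)
        return PBMRecord(tf_id, np.nan, np.nan, "ns", np.nan, np.nan, len(f))
    return PBMRecord(tf_id, R, p, classify(R, p, alpha), Ru, pu, len(f))


def panel_summary(
    records: Sequence[PBMRecord],
    energies_by_tf: Mapping[str, np.ndarray] | None = None,
    intensities_by_tf: Mapping[str, np.ndarray] | None = None,
    pooled_bins: int = 25,
    standardize: bool = True,
):
    """Class counts for a factor panel, plus a pooled intensity-vs-<f> curve.

    The pooled curve bins (probe <f>, intensity) pairs from every factor into
    ``pooled_bins`` equal-count bins; intensities are z-scored per factor
    before pooling when ``standardize`` (raw pooling otherwise).  Returns
    ``(counts, curve)``; ``curve`` is None when no probe data are supplied.
    """
    if len(records) == 0:
        raise ValueError("empty record list")
    counts = {c: sum(r.label == c for r in records) for c in CLASSES}
    curve = None
    if energies_by_tf and intensities_by_tf:
        fs, ys = [], []
        for tf in energies_by_tf:
            f = np.asarray(energies_by_tf[tf], dtype=float)
            y = np.asarray(intensities_by_tf[tf], dtype=float)
            keep = ~np.isnan(f)
            f, y = f[keep], y[keep]
            if standardize:
                sd = y.std()
                y = (y - y.mean()) / sd if sd > 0 else y - y.mean()
            fs.append(f)
            ys.append(y)
        curve = binned_means(np.concatenate(fs), np.concatenate(ys), pooled_bins)
    return counts, curve
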