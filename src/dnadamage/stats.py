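"""Dose accounting, site-hit probability and uncertainty estimation.

All stochastic quantities carry one standard deviation of the mean (SEM).
The site-hit probability is the ratio of strand breaks to in-ROI inelastic
events; its SEM comes from per-batch ratios (ten equal batches for uniform
event sets, per-history batches for track sets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import EV_TO_JOULE
from .events import ELECTRON, EventSet
from .geometry import ROIParams, roi_mass

__all__ = [
    "RunStats",
    "in_roi_mask",
    "absorbed_dose",
    "site_hit_probability",
    "site_hit_sem",
    "electron_fractions",
    "batch_sem",
]


def in_roi_mask(positions: np.ndarray, roi: ROIParams) -> np.ndarray:
    """Half-open annulus membership of lab-frame points."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    r = np.hypot(positions[:, 0], positions[:, 1])
    z = positions[:, 2]
    return (r >= roi.inner_radius) & (r < roi.outer_radius) & (z >= 0.0) & (z < roi.height)


def absorbed_dose(events: EventSet, roi: ROIParams) -> float:
    """Absorbed dose in Gy: in-ROI energy deposits over the ROI mass."""
    mask = in_roi_mask(events.positions, roi)
    energy_ev = float(events.energies[mask].sum())
    return energy_ev * EV_TO_JOULE / roi_mass(roi)


def site_hit_probability(n_tsb: int, n_events: int) -> float:
    """Strand breaks over in-ROI inelastic events."""
    if n_events <= 0:
        raise ValueError("site-hit probability undefined for zero events")
    return n_tsb / n_events


def batch_sem(values) -> float:
    """One standard deviation of the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two batch values for a SEM")
    return float(values.std(ddof=1) / math.sqrt(values.size))


def site_hit_sem(
    hit_flags: np.ndarray,
    histories: np.ndarray | None = None,
    n_batches: int = 10,
) -> float:
    """SEM of the site-hit probability from batch ratios.

    With ``histories`` given, each primary history is one batch (histories
    without events carry no ratio); otherwise events are split into
    ``n_batches`` equal contiguous batches.
    """
    hit_flags = np.asarray(hit_flags, dtype=bool)
    if histories is not None:
        histories = np.asarray(histories)
        ratios = [
            float(hit_flags[histories == h].mean())
            for h in np.unique(histories)
            if np.any(histories == h)
        ]
    else:
        ratios = [float(chunk.mean()) for chunk in np.array_split(hit_flags, n_batches) if chunk.size]
    if len(ratios) < 2:
        return float("nan")
    return batch_sem(ratios)


def electron_fractions(events: EventSet, roi: ROIParams) -> tuple[float, float]:
    """(event fraction, dose fraction) carried by secondary electrons in the ROI."""
    mask = in_roi_mask(events.positions, roi)
    if not mask.any():
        return float("nan"), float("nan")
    particles = events.particles[mask]
    energies = events.energies[mask]
    f_events = float(np.mean(particles == ELECTRON))
    total = float(energies.sum())
    f_dose = float(energies[particles == ELECTRON].sum() / total) if total > 0 else float("nan")
    return f_events, f_dose


@dataclass(frozen=True)
class RunStats:
    """Summary statistics of one simulated run."""

    dose: float  # Gy
    n_events: int
    n_events_electron: int
    electron_event_fraction: float
    electron_dose_fraction: float
    site_hit_probability: float
    site_hit_sem: float
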