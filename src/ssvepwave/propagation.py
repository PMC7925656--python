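"""Phase topography → traveling-wave propagation estimates.

Per condition, the mean phase lag of every channel relative to the source
(circular mean over a 5-cycle window and over trials) is regressed on
great-circle distance from the source over a parieto-occipital-to-frontal
electrode set.  The fitted gradient k (rad/cm) gives the scalp phase
velocity

    v = 2π f / k      (converted to m/s)

and the wavelength λ = 100·v/f (cm).  Lags are unwrapped along electrodes
sorted by increasing distance before the fit, since a gradient exceeding π
between neighbours would otherwise alias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .montage import Montage
from .phase_locking import PhaseSeries, phase_difference

__all__ = [
    "PhaseLagMap",
    "GradientFit",
    "VelocityEstimate",
    "FrequencyTrend",
    "GRADIENT_ELECTRODES",
    "windowed_phase_lag",
    "fit_phase_gradient",
    "phase_velocity",
    "velocity_from_slope",
    "wavelength",
    "estimate_velocity",
    "velocity_frequency_trend",
]

# Electrode set covering the sites implicated by the source analysis,
# ordered by increasing distance from the Pz source.
GRADIENT_ELECTRODES = (
    "O1", "O2", "Oz", "PO3", "PO4", "P3", "Pz", "P4",
    "CP1", "CP2", "Cz", "FC1", "FC2", "Fz",
)


@dataclass
class PhaseLagMap:
    """Per-channel mean phase lag relative to the source (wrapped radians)."""

    lags: dict[str, float]
    source: str
    window_center: float
    n_cycles: int
    condition: float


@dataclass
class GradientFit:
    """First-order polynomial fit of unwrapped lag vs distance."""

    slope: float        # rad/cm
    intercept: float    # rad
    r: float
    p: float
    electrode_subset: tuple[str, ...]
    window_center: float


@dataclass
class VelocityEstimate:
    """Scalp phase velocity and wavelength for one stimulation condition."""

    velocity: float     # m/s
    wavelength: float   # cm
    condition: float    # Hz
    gradient: GradientFit
    folding_factor_applied: float | None = None


@dataclass
class FrequencyTrend:
    """Linear trend of phase velocity across stimulation frequencies."""

    slope: float        # (m/s) / Hz
    intercept: float    # m/s
    r: float
    p: float


def windowed_phase_lag(
    phases: PhaseSeries,
    source: str,
    window_center: float = 0.25,
    n_cycles: int = 5,
) -> PhaseLagMap:
    """Circular-mean lag of each channel behind the source in a short window.

    The window spans ``n_cycles`` of the condition frequency, centered at
    ``window_center`` seconds from onset; the lag is the circular mean over
    that window's samples and over trials of φ_source − φ_channel, so a
    channel further along the propagation path has a larger positive lag.
    """
    f = phases.condition
    half = (n_cycles / f) / 2.0
    times = phases.times
    mask = (times >= window_center - half) & (times <= window_center + half)
    if not mask.any():
        raise ValueError(f"no samples in window centered at {window_center} s")
    if not phases.valid_mask[mask].all():
        t_ok = times[phases.valid_mask]
        raise ValueError(
            f"window at {window_center} s touches filter-edge samples; "
            f"valid span is [{t_ok[0]:.3f}, {t_ok[-1]:.3f}] s — use a later window"
        )
    si = phases.channel_index(source)
    dphi = phase_difference(
        np.broadcast_to(phases.phase[:, si:si + 1, :], phases.phase.shape),
        phases.phase,
    )
    z = np.exp(1j * dphi[:, :, mask]).mean(axis=(0, 2))
    lags = {ch: float(np.angle(z[ci])) for ci, ch in enumerate(phases.channel_names)}
    lags[source] = 0.0
    return PhaseLagMap(lags, source, window_center, n_cycles, f)


def fit_phase_gradient(
    lag_map: PhaseLagMap,
    distances: dict[str, float],
    subset: tuple[str, ...] = GRADIENT_ELECTRODES,
) -> GradientFit:
    """OLS line of distance-ordered, unwrapped lag (rad) vs distance (cm)."""
    missing = [ch for ch in subset if ch not in lag_map.lags or ch not in distances]
    if missing:
        raise KeyError(f"subset channels missing from lag map or distances: {missing}")
    if len(subset) < 3:
        raise ValueError("gradient fit needs at least 3 electrodes")
    d = np.array([distances[ch] for ch in subset])
    lag = np.array([lag_map.lags[ch] for ch in subset])
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    if np.ptp(d_sorted) == 0:
        raise ValueError("all electrodes at the same distance; gradient undefined")
    lag_unwrapped = np.unwrap(lag[order])
    fit = stats.linregress(d_sorted, lag_unwrapped)
    return GradientFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        electrode_subset=tuple(np.asarray(subset)[order]),
        window_center=lag_map.window_center,
    )


def phase_velocity(f: float, distance_cm: float, phase_rad: float) -> float:
    """v = 2πf·Δδ/Δφ for one electrode pair (Δδ in cm → result in m/s)."""
    if phase_rad == 0:
        raise ZeroDivisionError(
            "zero phase difference implies infinite phase velocity"
        )
    return 2.0 * np.pi * f * (distance_cm / 100.0) / phase_rad


def velocity_from_slope(f: float, slope_rad_per_cm: float) -> float:
    """v = 2πf/k from the fitted spatial gradient k (rad/cm → m/s)."""
    if slope_rad_per_cm == 0:
        raise ZeroDivisionError("zero phase gradient implies infinite phase velocity")
    return 2.0 * np.pi * f / (slope_rad_per_cm * 100.0)


def wavelength(v: float, f: float) -> float:
    """λ = 100·v/f in cm (v in m/s, f in Hz)."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return 100.0 * v / f


def estimate_velocity(
    lag_map: PhaseLagMap,
    montage: Montage,
    subset: tuple[str, ...] = GRADIENT_ELECTRODES,
    folding_factor: float | None = None,
) -> VelocityEstimate:
    """Gradient fit → phase velocity and wavelength for one condition.

    ``folding_factor`` optionally multiplies the reported velocity (and
    wavelength) by a cortical-folding correction (~2.2 in the literature);
    default is no correction, matching scalp-surface estimates.
    """
    distances = montage.distance_matrix(lag_map.source)
    fit = fit_phase_gradient(lag_map, distances, subset)
    v = velocity_from_slope(lag_map.condition, fit.slope)
    if folding_factor is not None:
        v *= folding_factor
    return VelocityEstimate(
        velocity=v,
        wavelength=wavelength(v, lag_map.condition),
        condition=lag_map.condition,
        gradient=fit,
        folding_factor_applied=folding_factor,
    )


def velocity_frequency_trend(estimates: list[VelocityEstimate]) -> FrequencyTrend:
    """Least-squares line of velocity on stimulation frequency."""
    usable = [e for e in estimates if np.isfinite(e.velocity)]
    if len(usable) < 3:
        raise ValueError("trend fit needs at least 3 conditions with finite velocity")
    f = np.array([e.condition for e in usable])
    v = np.array([e.velocity for e in usable])
    fit = stats.linregress(f, v)
    return FrequencyTrend(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), p=float(fit.pvalue),
    )
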