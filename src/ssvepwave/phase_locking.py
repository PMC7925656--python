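"""Narrowband phase extraction and stimulus-locked phase statistics.

The chain is: equiripple linear-phase FIR bandpass around the stimulation
frequency (Parks-McClellan; pass band f±1 Hz, stop bands beyond f±3 Hz,
ripples δ_pass = 0.058, δ_stop = 1e-4) applied with its constant group
delay compensated, then the analytic-signal (Hilbert) instantaneous phase.

The phase-locking value between a channel and the stimulus trace is the
modulus of the trial-averaged unit phasor of their phase difference,

    PLV(t) = | (1/N) Σ_n exp(j Δφ(t, n)) |  ∈ [0, 1].

Its significance (PLS) is a surrogate statistic: the observed PLV is
compared against PLVs computed after re-pairing the channel's trials with
trial-shuffled stimulus phases from a *different* stimulation condition;
PLS is the fraction of surrogates exceeding the observation.  A channel is
considered locked where PLV > 0.5 and PLS ≤ 0.05, and the locking delay is
the time from stimulus onset to the first such sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .montage import Montage
from .preprocess import EpochSet

__all__ = [
    "BandFilterSpec",
    "PhaseSeries",
    "PLVSeries",
    "FilterDesignError",
    "UndefinedPhaseError",
    "design_bandpass",
    "apply_zero_delay",
    "instantaneous_phase",
    "phase_difference",
    "plv",
    "epoch_phases",
    "plv_series",
    "pls_surrogate",
    "locking_delays",
    "select_source",
]


class FilterDesignError(RuntimeError):
    """The equiripple spec could not be met at the given sampling rate."""


class UndefinedPhaseError(ValueError):
    """Instantaneous phase requested for an identically zero signal."""


@dataclass(frozen=True)
class BandFilterSpec:
    """Designed equiripple bandpass and its verified properties."""

    center: float
    rate: float
    pass_width: float
    stop_width: float
    dpass: float
    dstop: float
    grid_density: int
    taps: np.ndarray = field(repr=False)

    @property
    def n_taps(self) -> int:
        return len(self.taps)

    @property
    def group_delay(self) -> int:
        """Constant group delay of the linear-phase filter, samples."""
        return (len(self.taps) - 1) // 2

    def response(self, n_grid: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """Magnitude response |H(f)| on a dense frequency grid."""
        w, h = sps.freqz(self.taps, worN=n_grid, fs=self.rate)
        return w, np.abs(h)


def _ripple_ok(spec_like: tuple, taps: np.ndarray, n_grid: int = 4096) -> bool:
    center, rate, pw, sw, dpass, dstop = spec_like
    w, h = sps.freqz(taps, worN=n_grid, fs=rate)
    mag = np.abs(h)
    stop = (w <= center - sw) | (w >= center + sw)
    pb = (w >= center - pw) & (w <= center + pw)
    return bool(
        mag[stop].max() <= dstop * (1 + 1e-3)
        and np.abs(mag[pb] - 1).max() <= dpass * (1 + 1e-3)
    )


@lru_cache(maxsize=64)
def _design_cached(
    center: float, rate: float, pass_width: float, stop_width: float,
    dpass: float, dstop: float, grid_density: int,
) -> BandFilterSpec:
    nyq = rate / 2.0
    if center + stop_width >= nyq:
        raise FilterDesignError(
            f"upper stop edge {center + stop_width} Hz >= Nyquist {nyq} Hz"
        )
    if center - stop_width <= 0:
        raise FilterDesignError(f"lower stop edge {center - stop_width} Hz <= 0")
    # Kaiser-style order estimate for the equiripple design, then grow
    # until the verified response meets the ripple spec.
    trans = (stop_width - pass_width) / rate
    atten = -20.0 * np.log10(np.sqrt(dpass * dstop))
    n_est = int(np.ceil((atten - 13.0) / (14.6 * trans)))
    n = n_est if n_est % 2 else n_est + 1
    key = (center, rate, pass_width, stop_width, dpass, dstop)
    bands = [0.0, center - stop_width, center - pass_width,
             center + pass_width, center + stop_width, nyq]
    last_err: Exception | None = None
    for n_taps in range(max(n - 40, 11), n + 400, 2):
        try:
            taps = sps.remez(
                n_taps, bands, [0.0, 1.0, 0.0],
                weight=[1.0 / dstop, 1.0 / dpass, 1.0 / dstop],
                fs=rate, grid_density=grid_density, maxiter=100,
            )
        except Exception as exc:  # remez convergence failure at some orders
            last_err = exc
            continue
        if not np.all(np.isfinite(taps)):
            continue
        if _ripple_ok(key, taps):
            return BandFilterSpec(
                center, rate, pass_width, stop_width, dpass, dstop,
                grid_density, taps,
            )
    raise FilterDesignError(
        f"no equiripple design up to {n + 400} taps met "
        f"(dpass={dpass}, dstop={dstop}) at {center} Hz / {rate} Hz; "
        f"last remez error: {last_err}"
    )


def design_bandpass(
    center: float,
    rate: float,
    pass_width: float = 1.0,
    stop_width: float = 3.0,
    dpass: float = 0.058,
    dstop: float = 1e-4,
    grid_density: int = 20,
) -> BandFilterSpec:
    """Design (and verify) the narrowband equiripple bandpass at ``center`` Hz."""
    return _design_cached(
        float(center), float(rate), float(pass_width), float(stop_width),
        float(dpass), float(dstop), int(grid_density),
    )


def apply_zero_delay(x: np.ndarray, spec: BandFilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Filter along the last axis with the group delay compensated.

    Returns the filtered signal (same shape) and a boolean per-sample
    validity mask excluding the (n_taps−1)/2 edge samples at each end,
    where the finite impulse response has not fully entered the data.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n <= spec.n_taps:
        raise ValueError(f"signal of {n} samples not longer than {spec.n_taps}-tap filter")
    kernel = spec.taps.reshape((1,) * (x.ndim - 1) + (-1,))
    # 'same' with an odd symmetric kernel centers it: output already
    # advanced by the constant group delay.
    y = sps.oaconvolve(x, kernel, mode="same", axes=-1)
    valid = np.ones(n, dtype=bool)
    gd = spec.group_delay
    valid[:gd] = False
    valid[n - gd:] = False
    return y, valid


def instantaneous_phase(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic-signal phase (wrapped to (−π, π]) and envelope, last axis = time."""
    x = np.asarray(x, dtype=np.float64)
    if not np.any(x):
        raise UndefinedPhaseError("instantaneous phase of an identically zero signal")
    analytic = sps.hilbert(x, axis=-1)
    return np.angle(analytic), np.abs(analytic)


def phase_difference(phase1: np.ndarray, phase2: np.ndarray) -> np.ndarray:
    """Wrapped phase difference arg(e^{j(φ₁−φ₂)}) ∈ (−π, π]."""
    phase1, phase2 = np.asarray(phase1), np.asarray(phase2)
    if phase1.shape != phase2.shape:
        raise ValueError(f"shape mismatch {phase1.shape} vs {phase2.shape}")
    return np.angle(np.exp(1j * (phase1 - phase2)))


def plv(phase_diffs: np.ndarray, axis: int = 0) -> np.ndarray:
    """Phase-locking value: modulus of the mean unit phasor over trials."""
    phase_diffs = np.asarray(phase_diffs)
    if phase_diffs.shape[axis] < 2:
        raise ValueError("PLV needs at least 2 trials (degenerate at 1 otherwise)")
    return np.abs(np.exp(1j * phase_diffs).mean(axis=axis))


@dataclass
class PhaseSeries:
    """Instantaneous phase/envelope of narrowband-filtered epochs."""

    phase: np.ndarray          # trials × channels × samples
    amplitude: np.ndarray
    valid_mask: np.ndarray     # per-sample, filter edge transients excluded
    rate: float
    t0_offset: float
    condition: float
    channel_names: list[str]
    stim_phase: np.ndarray | None = None   # trials × samples, same chain

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.phase.shape[-1]) / self.rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown channel {name!r}") from exc


def epoch_phases(
    epochs: EpochSet,
    stim_trials: np.ndarray | None = None,
    spec: BandFilterSpec | None = None,
) -> PhaseSeries:
    """Filter + Hilbert chain for an epoch set (and optionally its stimulus).

    The stimulus trace goes through the identical filter chain so both
    signals share whatever phase distortion remains.
    """
    if spec is None:
        spec = design_bandpass(epochs.condition, epochs.rate)
    filtered, valid = apply_zero_delay(epochs.data, spec)
    phase, amp = instantaneous_phase(filtered)
    stim_phase = None
    if stim_trials is not None:
        stim_f, _ = apply_zero_delay(np.asarray(stim_trials, dtype=np.float64), spec)
        stim_phase, _ = instantaneous_phase(stim_f)
    return PhaseSeries(
        phase, amp, valid, epochs.rate, epochs.t0_offset, epochs.condition,
        list(epochs.channel_names), stim_phase,
    )


@dataclass
class PLVSeries:
    """Stimulus-locked PLV (and surrogate PLS) per channel over time."""

    plv: np.ndarray            # channels × samples
    pls: np.ndarray | None     # channels × samples, or None before pls_surrogate
    n_trials: int
    valid_mask: np.ndarray
    rate: float
    t0_offset: float
    condition: float
    channel_names: list[str]
    plv_min: float = 0.5
    pls_max: float = 0.05

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.plv.shape[-1]) / self.rate


def plv_series(phases: PhaseSeries) -> PLVSeries:
    """Observed stimulus-locked PLV for every channel."""
    if phases.stim_phase is None:
        raise ValueError("PhaseSeries carries no stimulus phase; pass stim_trials")
    dphi = phase_difference(
        phases.phase,
        np.broadcast_to(phases.stim_phase[:, None, :], phases.phase.shape),
    )
    return PLVSeries(
        plv(dphi, axis=0), None, phases.phase.shape[0], phases.valid_mask,
        phases.rate, phases.t0_offset, phases.condition, list(phases.channel_names),
    )


def pls_surrogate(
    phases: PhaseSeries,
    other_stim_phases: list[np.ndarray],
    n_surrogates: int = 200,
    rng: np.random.Generator | int | None = None,
) -> PLVSeries:
    """Surrogate phase-locking statistics against other-condition stimuli.

    Each surrogate pairs the target condition's per-trial channel phases
    with a trial-shuffled stimulus-phase set drawn from a randomly chosen
    *other* stimulation condition, destroying any true locking while
    preserving the marginal phase statistics.  PLS(t) is the fraction of
    surrogate PLVs above the observed PLV.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for a 0.05-level test")
    if not other_stim_phases:
        raise ValueError("no other stimulation condition available for surrogates")
    if phases.stim_phase is None:
        raise ValueError("PhaseSeries carries no stimulus phase")
    rng = np.random.default_rng(rng)
    series = plv_series(phases)
    n_trials, _, n_samples = phases.phase.shape
    e_ch = np.exp(1j * phases.phase)                       # trials × ch × samples
    e_others = [np.exp(-1j * np.asarray(p)) for p in other_stim_phases]
    counts = np.zeros_like(series.plv)
    cond_choice = rng.integers(len(e_others), size=n_surrogates)
    for k in range(n_surrogates):
        e_s = e_others[cond_choice[k]]
        if e_s.shape[0] >= n_trials:
            idx = rng.permutation(e_s.shape[0])[:n_trials]
        else:
            idx = rng.integers(e_s.shape[0], size=n_trials)
        surr = np.abs(
            np.mean(e_ch * e_s[idx][:, None, :], axis=0)
        )
        counts += surr > series.plv
    series.pls = counts / n_surrogates
    return series


def locking_delays(series: PLVSeries) -> dict[str, float]:
    """Per-channel time from onset to the first locked sample (NaN if never).

    Locked means PLV > plv_min and PLS ≤ pls_max on a valid (non-edge)
    post-onset sample.
    """
    if series.pls is None:
        raise ValueError("run pls_surrogate first; locking requires significance")
    times = series.times
    eligible = series.valid_mask & (times >= 0)
    locked = (series.plv > series.plv_min) & (series.pls <= series.pls_max) & eligible
    out: dict[str, float] = {}
    for ci, ch in enumerate(series.channel_names):
        hits = np.flatnonzero(locked[ci])
        out[ch] = float(times[hits[0]]) if hits.size else float("nan")
    return out


def select_source(
    delays_per_condition: dict[float, dict[str, float]],
    montage: Montage,
    override: str | None = None,
) -> str:
    """Channel that locks first in the plurality of conditions.

    Ties are broken by smaller mean delay across conditions, then by
    posterior-first channel order (most posterior electrode wins).  An
    ``override`` pins the choice regardless of the data.
    """
    if override is not None:
        if override not in montage:
            raise KeyError(f"override source {override!r} not in montage")
        return override
    wins: dict[str, int] = {}
    sums: dict[str, list[float]] = {}
    for delays in delays_per_condition.values():
        defined = {ch: d for ch, d in delays.items() if np.isfinite(d)}
        if not defined:
            continue
        best = min(defined.values())
        for ch, d in defined.items():
            sums.setdefault(ch, []).append(d)
            if d == best:
                wins[ch] = wins.get(ch, 0) + 1
    if not wins:
        raise ValueError("no channel has a defined locking delay in any condition")

    def posterior_rank(ch: str) -> float:
        # smaller y (toward the inion) ranks first
        return float(montage[ch].unit_vector[1])

    return min(
        wins,
        key=lambda ch: (-wins[ch], float(np.mean(sums[ch])), posterior_rank(ch), ch),
    )
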