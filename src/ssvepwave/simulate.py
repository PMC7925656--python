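"""Synthetic traveling-wave SSVEP sessions with known ground truth.

The generator realizes the simplest scalp model consistent with a
stimulus-locked oscillation propagating spherically from a single
parieto-occipital source: during each stimulation window every channel
carries a sinusoid at the condition frequency f whose phase lags the source
by

    Δφ_ch = 2π f d(source, ch) / v(f),

with amplitude decaying exponentially with great-circle distance d and an
onset envelope (latency + linear ramp).  The oscillation rides on 1/f
background noise plus power-line interference, and a photodiode-equivalent
square-wave stimulus trace is co-recorded.

All randomness flows from a single integer seed (``NoiseModel.seed``) with
fixed substream allocation: trial order, inter-stimulus intervals,
background noise, line phase.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .montage import Montage, default_montage
from .recording import ContinuousRecording

__all__ = [
    "StimulationProtocol",
    "WavePropagationModel",
    "NoiseModel",
    "make_stimulus_signal",
    "simulate_recording",
    "visual_angle_deg",
    "averaging_snr_gain",
    "DEFAULT_FREQUENCIES",
]

# 40-60 Hz in 2 Hz steps, excluding the 50 Hz line frequency
DEFAULT_FREQUENCIES = (40.0, 42.0, 44.0, 46.0, 48.0, 52.0, 54.0, 56.0, 58.0, 60.0)


@dataclass(frozen=True)
class StimulationProtocol:
    """Photic stimulation protocol: frequencies, trial counts and timing."""

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    trials_per_condition: int = 10
    stim_duration: float = 2.0
    isi_range: tuple[float, float] = (3.0, 6.0)
    duty_cycle: float = 0.5
    modulation_depth: float = 1.0
    block_size: int = 10
    block_break: float = 10.0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("stimulation frequencies must be positive")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty_cycle must be in (0, 1]")
        if self.isi_range[0] > self.isi_range[1]:
            raise ValueError("isi_range must be (lo, hi) with lo <= hi")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")

    @property
    def n_trials(self) -> int:
        return len(self.frequencies) * self.trials_per_condition


@dataclass(frozen=True)
class WavePropagationModel:
    """Ground-truth propagation: source, velocity law, amplitude topography.

    velocity_v0/velocity_slope parameterize the linear velocity law
    v(f) = v0 + slope * (f - 40 Hz) in m/s; amplitude decays as
    exp(-d / amplitude_decay_cm) from the source; the onset transient is a
    latency followed by a linear ramp, reaching steady state by
    latency + ramp (~250 ms with the defaults).
    """

    source: str = "Pz"
    velocity_v0: float = 8.6
    velocity_slope: float = 0.24
    amplitude_uv: float = 2.0
    amplitude_decay_cm: float = 10.0
    onset_latency: float = 0.1
    onset_ramp: float = 0.15
    harmonic_weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.onset_latency < 0 or self.onset_ramp < 0:
            raise ValueError("onset_latency and onset_ramp must be >= 0")
        if self.amplitude_decay_cm <= 0:
            raise ValueError("amplitude_decay_cm must be positive")

    def velocity(self, f: float) -> float:
        """Phase velocity v(f) in m/s."""
        v = self.velocity_v0 + self.velocity_slope * (f - 40.0)
        if v <= 0:
            raise ValueError(f"velocity law yields non-positive v at {f} Hz")
        return v

    def snapshot(self) -> dict:
        d = asdict(self)
        d["harmonic_weights"] = list(d["harmonic_weights"])  # JSON-plain
        return d


@dataclass(frozen=True)
class NoiseModel:
    """Additive background: 1/f^exponent noise plus power-line interference.

    ``spatial_scale_cm`` optionally correlates the background across
    channels with a Gaussian spatial kernel of that scale (None = channels
    independent), emulating spatially distributed ongoing activity seen
    through volume conduction; ``sensor_rms`` adds white per-channel
    measurement noise on top (never spatially mixed).
    """

    background_exponent: float = 1.0
    background_rms: float = 2.0
    line_freq: float = 50.0
    line_rms: float = 1.0
    seed: int = 0
    spatial_scale_cm: float | None = None
    sensor_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.background_rms < 0 or self.line_rms < 0 or self.sensor_rms < 0:
            raise ValueError("rms values must be >= 0")


def visual_angle_deg(extent_cm: float, distance_cm: float) -> float:
    """Full visual angle subtended by a stimulus of ``extent_cm`` at ``distance_cm``."""
    if extent_cm <= 0 or distance_cm <= 0:
        raise ValueError("extent and distance must be positive")
    return float(np.degrees(2.0 * np.arctan2(extent_cm / 2.0, distance_cm)))


def averaging_snr_gain(n_trials: int) -> float:
    """SNR improvement factor from averaging ``n_trials`` trials (√N)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return float(np.sqrt(n_trials))


def make_stimulus_signal(
    f: float, duration: float, rate: float, duty: float = 0.5
) -> np.ndarray:
    """0/1 square wave at frequency ``f`` with the given duty cycle."""
    if f >= rate / 2:
        raise ValueError(f"stimulus frequency {f} Hz >= Nyquist {rate / 2} Hz")
    if not 0 < duty <= 1:
        raise ValueError("duty cycle must be in (0, 1]")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    return ((f * t) % 1.0 < duty).astype(np.float64)


def _pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, rate: float,
    exponent: float, rms: float,
) -> np.ndarray:
    """1/f^exponent Gaussian noise, flattened below 0.5 Hz, unit-rms scaled."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.maximum(freqs, 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    out = np.empty((n_channels, n_samples))
    for ch in range(n_channels):
        spec = (rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)) * shape
        x = np.fft.irfft(spec, n=n_samples)
        out[ch] = x * (rms / np.sqrt(np.mean(x**2)))
    return out


def _spatial_mix(noise: np.ndarray, montage: Montage, names: list[str], scale_cm: float) -> np.ndarray:
    """Correlate channel noise with a Gaussian great-circle kernel (rms preserved)."""
    n = len(names)
    dist = np.zeros((n, n))
    for i, a in enumerate(names):
        row = montage.distance_matrix(a)
        dist[i] = [row[b] for b in names]
    kernel = np.exp(-(dist**2) / (2.0 * scale_cm**2))
    kernel /= np.sqrt((kernel**2).sum(axis=1, keepdims=True))  # unit L2 rows
    return kernel @ noise


def _onset_envelope(t_rel: np.ndarray, latency: float, ramp: float) -> np.ndarray:
    """0 before ``latency``, linear rise over ``ramp``, 1 thereafter."""
    if ramp == 0:
        return (t_rel >= latency).astype(np.float64)
    return np.clip((t_rel - latency) / ramp, 0.0, 1.0)


def simulate_recording(
    protocol: StimulationProtocol = StimulationProtocol(),
    wave: WavePropagationModel = WavePropagationModel(),
    noise: NoiseModel = NoiseModel(),
    montage: Montage | None = None,
    rate: float = 2048.0,
) -> ContinuousRecording:
    """Simulate a full stimulation session as a continuous recording.

    Returns a :class:`ContinuousRecording` whose ``ground_truth`` holds the
    wave-model snapshot, including the per-condition velocities.
    """
    if montage is None:
        montage = default_montage()
    if wave.source not in montage:
        raise ValueError(f"wave source {wave.source!r} not in montage")
    nyq = rate / 2.0
    max_harm = len(wave.harmonic_weights)
    for f in protocol.frequencies:
        if f * 1 >= nyq:
            raise ValueError(f"condition frequency {f} Hz >= Nyquist {nyq} Hz")

    ss = np.random.SeedSequence(noise.seed)
    rng_order, rng_isi, rng_noise, rng_line, rng_sensor = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # --- trial schedule -------------------------------------------------
    conditions = np.repeat(protocol.frequencies, protocol.trials_per_condition)
    order = rng_order.permutation(len(conditions))
    schedule_f = conditions[order]
    isis = rng_isi.uniform(*protocol.isi_range, size=len(conditions))

    lead_in, tail = 2.0, 4.0
    onsets_s: list[float] = []
    t_cursor = lead_in
    for i, isi in enumerate(isis):
        if i > 0 and protocol.block_size and i % protocol.block_size == 0:
            t_cursor += protocol.block_break
        t_cursor += isi
        onsets_s.append(t_cursor)
        t_cursor += protocol.stim_duration
    total_s = t_cursor + tail
    n_samples = int(np.ceil(total_s * rate))

    names = montage.channel_names
    n_ch = len(names)
    dist = montage.distance_matrix(wave.source)
    d_cm = np.array([dist[n] for n in names])
    amp = wave.amplitude_uv * np.exp(-d_cm / wave.amplitude_decay_cm)

    # --- background + line noise ---------------------------------------
    data = _pink_noise(
        rng_noise, n_ch, n_samples, rate, noise.background_exponent, noise.background_rms
    )
    if noise.spatial_scale_cm is not None and noise.background_rms > 0:
        data = _spatial_mix(data, montage, names, noise.spatial_scale_cm)
    if noise.sensor_rms > 0:
        data += noise.sensor_rms * rng_sensor.standard_normal(data.shape)
    if noise.line_rms > 0:
        t_all = np.arange(n_samples) / rate
        phase0 = rng_line.uniform(0, 2 * np.pi)
        data += noise.line_rms * np.sqrt(2.0) * np.sin(
            2 * np.pi * noise.line_freq * t_all + phase0
        )

    # --- stimulus-locked traveling wave ---------------------------------
    stim = np.zeros(n_samples)
    events: list[tuple[int, float]] = []
    n_stim = int(round(protocol.stim_duration * rate))
    offset = (1.0 - protocol.modulation_depth) / 2.0
    for onset_s, f in zip(onsets_s, schedule_f):
        onset = int(round(onset_s * rate))
        sl = slice(onset, onset + n_stim)
        t_rel = np.arange(n_stim) / rate
        square = make_stimulus_signal(f, protocol.stim_duration, rate, protocol.duty_cycle)
        stim[sl] = offset + protocol.modulation_depth * square
        env = _onset_envelope(t_rel, wave.onset_latency, wave.onset_ramp)
        burst = np.zeros((n_ch, n_stim))
        for k, w in enumerate(wave.harmonic_weights, start=1):
            if w == 0:
                continue
            fk = k * f
            if fk >= nyq:
                continue
            lag = 2 * np.pi * fk * (d_cm / 100.0) / wave.velocity(fk)
            burst += w * np.sin(2 * np.pi * fk * t_rel[None, :] - lag[:, None])
        data[:, sl] += amp[:, None] * env[None, :] * burst
        events.append((onset, float(f)))

    ground_truth = wave.snapshot()
    ground_truth["velocities"] = {
        str(f): wave.velocity(f) for f in protocol.frequencies
    }
    ground_truth["distances_cm"] = {n: float(dist[n]) for n in names}
    return ContinuousRecording(
        data=data,
        rate=rate,
        channel_names=names,
        stim_channel=stim,
        events=events,
        ground_truth=ground_truth,
    )
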