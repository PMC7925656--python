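"""Short-time Fourier power and event-related synchronization (ERS).

ERS is the percent power change at the stimulation frequency in 250 ms
post-onset windows, referenced to the 250 ms immediately before onset:
ERS = 100 · (P_win − P_base) / P_base, with power averaged over trials
before the ratio.

The short-time grid follows a fixed *count* of windows rather than a fixed
hop: a 126-sample Hann window slides over the epoch on an exact fractional
grid (hop (N−126)/199 ≈ 4.51 samples for a 1024-sample epoch), each start
rounded to the nearest sample, giving exactly 200 windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = ["STFTPower", "ERSMap", "stft_power", "ers_map", "nearest_bin"]


@dataclass
class STFTPower:
    """Short-time power: trials × channels × windows × frequency bins."""

    power: np.ndarray
    times: np.ndarray      # window centers, s relative to stimulus onset
    freqs: np.ndarray      # FFT bin frequencies, Hz
    channel_names: list[str]
    condition: float

    @property
    def n_windows(self) -> int:
        return self.power.shape[2]


@dataclass
class ERSMap:
    """Percent power change per channel in 250 ms windows around onset."""

    values: np.ndarray          # channels × windows, percent
    window_edges: np.ndarray    # seconds, len = windows + 1
    frequency: float
    channel_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channel_names):
            for wi in range(self.values.shape[1]):
                rows.append(
                    {
                        "channel": ch,
                        "window_start_ms": 1000.0 * self.window_edges[wi],
                        "window_end_ms": 1000.0 * self.window_edges[wi + 1],
                        "frequency_hz": self.frequency,
                        "percent_change": self.values[ci, wi],
                    }
                )
        return pd.DataFrame(rows)


def nearest_bin(freqs: np.ndarray, f: float) -> int:
    """Index of the FFT bin closest to frequency ``f``."""
    return int(np.argmin(np.abs(np.asarray(freqs) - f)))


def stft_power(
    epochs: EpochSet, win_samples: int = 126, n_windows: int = 200
) -> STFTPower:
    """Hann-tapered short-time power on the exact fractional start grid."""
    n = epochs.n_samples
    if win_samples > n:
        raise ValueError(f"window of {win_samples} samples exceeds epoch of {n}")
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    starts = np.round(
        np.arange(n_windows) * (n - win_samples) / (n_windows - 1)
    ).astype(int)
    taper = np.hanning(win_samples)
    segs = np.stack(
        [epochs.data[:, :, s:s + win_samples] for s in starts], axis=2
    )  # trials x channels x windows x win_samples
    spec = np.fft.rfft(segs * taper, axis=-1)
    power = (np.abs(spec) ** 2) / (taper**2).sum()
    freqs = np.fft.rfftfreq(win_samples, d=1.0 / epochs.rate)
    centers = epochs.t0_offset + (starts + (win_samples - 1) / 2.0) / epochs.rate
    return STFTPower(power, centers, freqs, list(epochs.channel_names), epochs.condition)


def ers_map(
    stft: STFTPower,
    frequency: float | None = None,
    baseline: tuple[float, float] = (-0.25, 0.0),
    window_len: float = 0.25,
    n_response_windows: int = 4,
    n_bins: int = 1,
    trial_average_first: bool = True,
) -> ERSMap:
    """ERS at the (nearest-bin) stimulation frequency in 250 ms windows.

    By default power is averaged over trials before the baseline ratio
    (``trial_average_first=False`` instead forms the ratio per trial and
    averages the percent changes); either way power is pooled over all
    short-time windows whose centers fall in each 250 ms span, and the
    baseline window's own value is identically 0.  ``n_bins`` > 1 sums
    power over that many bins centered on the fundamental.
    """
    f = stft.condition if frequency is None else frequency
    bin0 = nearest_bin(stft.freqs, f)
    half = (n_bins - 1) // 2
    sel = slice(max(bin0 - half, 0), bin0 + half + 1)
    per_trial = stft.power[:, :, :, sel].sum(axis=-1)  # trials x channels x windows
    if not trial_average_first:
        maps = [
            ers_map(
                STFTPower(per_trial[i][None, :, :, None], stft.times,
                          stft.freqs[sel][:1], stft.channel_names, stft.condition),
                frequency=stft.freqs[sel][0], baseline=baseline,
                window_len=window_len, n_response_windows=n_response_windows,
            ).values
            for i in range(per_trial.shape[0])
        ]
        edges = baseline[0] + window_len * np.arange(n_response_windows + 2)
        return ERSMap(np.mean(maps, axis=0), edges, f, list(stft.channel_names))
    p = per_trial.mean(axis=0)  # channels x windows
    edges = baseline[0] + window_len * np.arange(n_response_windows + 2)
    values = np.empty((p.shape[0], n_response_windows + 1))
    base_mask = (stft.times >= baseline[0]) & (stft.times < baseline[1])
    if not base_mask.any():
        raise ValueError("no short-time windows fall inside the baseline interval")
    p_base = p[:, base_mask].mean(axis=1)
    if np.any(p_base <= 0):
        bad = [stft.channel_names[i] for i in np.flatnonzero(p_base <= 0)]
        raise ZeroDivisionError(f"zero baseline power in channels {bad}")
    for wi in range(n_response_windows + 1):
        lo, hi = edges[wi], edges[wi + 1]
        mask = (stft.times >= lo) & (stft.times < hi)
        if not mask.any():
            raise ValueError(f"no short-time windows in [{lo}, {hi}) s")
        values[:, wi] = 100.0 * (p[:, mask].mean(axis=1) - p_base) / p_base
    return ERSMap(values, edges, f, list(stft.channel_names))
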