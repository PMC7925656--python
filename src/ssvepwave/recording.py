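"""Continuous multichannel recordings and their on-disk fixture format.

A :class:`ContinuousRecording` bundles the EEG data (channels × samples,
µV), the co-recorded stimulus (photodiode-equivalent) trace, and the event
list marking stimulation onsets.  The fixture container is a NumPy ``.npz``
bundle with named entries, losslessly roundtrippable.  EDF/BDF files can be
imported through MNE's native readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ContinuousRecording", "RecordingError", "write_recording", "read_recording", "read_edf"]

_FORMAT_VERSION = 1


class RecordingError(ValueError):
    """Malformed recording file or inconsistent recording contents."""


@dataclass
class ContinuousRecording:
    """Continuous EEG + stimulus channel + stimulation events.

    Attributes
    ----------
    data : (n_channels, n_samples) float array, µV (or µV/cm² post-Laplacian)
    rate : sampling frequency, Hz
    channel_names : channel labels, one per data row
    stim_channel : photodiode-equivalent trace, same length as data
    events : list of (onset_sample, condition_frequency_hz)
    ground_truth : optional dict snapshot of the generating wave model
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    stim_channel: np.ndarray
    events: list[tuple[int, float]] = field(default_factory=list)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.stim_channel = np.asarray(self.stim_channel, dtype=np.float64)
        if self.data.ndim != 2:
            raise RecordingError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise RecordingError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} rows"
            )
        if self.stim_channel.shape != (self.data.shape[1],):
            raise RecordingError("stim_channel length must equal data length")
        for onset, f in self.events:
            if not 0 <= onset < self.n_samples:
                raise RecordingError(f"event onset {onset} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def conditions(self) -> list[float]:
        """Distinct condition frequencies, ascending."""
        return sorted({f for _, f in self.events})

    def copy_with(self, **kwargs) -> "ContinuousRecording":
        base = dict(
            data=self.data,
            rate=self.rate,
            channel_names=list(self.channel_names),
            stim_channel=self.stim_channel,
            events=list(self.events),
            ground_truth=self.ground_truth,
        )
        base.update(kwargs)
        return ContinuousRecording(**base)


def write_recording(rec: ContinuousRecording, path: str | Path) -> None:
    """Write the fixture container (lossless ``.npz`` bundle)."""
    import json

    events = np.array(
        [(int(s), float(f)) for s, f in rec.events], dtype=np.float64
    ).reshape(-1, 2)
    np.savez(
        Path(path),
        format_version=np.int64(_FORMAT_VERSION),
        data=rec.data,
        rate=np.float64(rec.rate),
        channel_names=np.array(rec.channel_names, dtype="U16"),
        stim=rec.stim_channel,
        events=events,
        ground_truth=np.array(
            json.dumps(rec.ground_truth) if rec.ground_truth is not None else ""
        ),
    )


def read_recording(path: str | Path) -> ContinuousRecording:
    """Read the fixture container written by :func:`write_recording`."""
    import json
    import zipfile

    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as npz:
            required = {"format_version", "data", "rate", "channel_names", "stim", "events"}
            missing = required - set(npz.files)
            if missing:
                raise RecordingError(f"{path}: missing entries {sorted(missing)}")
            gt_raw = str(npz["ground_truth"]) if "ground_truth" in npz.files else ""
            rec = ContinuousRecording(
                data=npz["data"],
                rate=float(npz["rate"]),
                channel_names=[str(n) for n in npz["channel_names"]],
                stim_channel=npz["stim"],
                events=[(int(s), float(f)) for s, f in npz["events"]],
                ground_truth=json.loads(gt_raw) if gt_raw else None,
            )
    except (OSError, ValueError, KeyError, EOFError, zipfile.BadZipFile) as exc:
        if isinstance(exc, RecordingError):
            raise
        raise RecordingError(f"{path}: not a readable recording file ({exc})") from exc
    return rec


def read_edf(path: str | Path, stim_channel: str) -> ContinuousRecording:
    """Import an EDF/BDF recording, taking ``stim_channel`` as the photodiode trace.

    Stimulation events must be reconstructed downstream (e.g. from
    annotations or by thresholding the stimulus trace); this reader only
    splits EEG rows from the stimulus row.
    """
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="ERROR")
    names = list(raw.ch_names)
    if stim_channel not in names:
        raise RecordingError(f"{path}: no channel named {stim_channel!r}")
    data = raw.get_data() * 1e6  # MNE returns volts
    stim_idx = names.index(stim_channel)
    eeg_idx = [i for i in range(len(names)) if i != stim_idx]
    return ContinuousRecording(
        data=data[eeg_idx],
        rate=float(raw.info["sfreq"]),
        channel_names=[names[i] for i in eeg_idx],
        stim_channel=data[stim_idx],
        events=[],
    )
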