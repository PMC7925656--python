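"""Shared fixtures: small simulated sessions reused across test modules.

The "small" session trades the full protocol (10 conditions × 10 trials,
3-6 s inter-stimulus intervals) for a 4-condition, 6-trial session with
short ISIs so that integration tests stay fast; generator physics
(velocity law, amplitude decay, onset transient) is unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest

import ssvepwave as sw
from ssvepwave import preprocess as pre


SMALL_FREQS = (40.0, 44.0, 52.0, 60.0)


def small_protocol(trials: int = 6) -> sw.StimulationProtocol:
    return sw.StimulationProtocol(
        frequencies=SMALL_FREQS,
        trials_per_condition=trials,
        isi_range=(1.5, 2.5),
        block_break=0.0,
    )


@pytest.fixture(scope="session")
def montage() -> sw.Montage:
    return sw.default_montage()


@pytest.fixture(scope="session")
def small_session(montage) -> sw.ContinuousRecording:
    """Default-noise traveling-wave session, 4 conditions × 6 trials."""
    return sw.simulate_recording(
        small_protocol(), sw.WavePropagationModel(), sw.NoiseModel(seed=5),
        montage, rate=2048.0,
    )


@pytest.fixture(scope="session")
def noise_free_session(montage) -> sw.ContinuousRecording:
    return sw.simulate_recording(
        small_protocol(),
        sw.WavePropagationModel(),
        sw.NoiseModel(background_rms=0.0, line_rms=0.0, seed=5),
        montage,
        rate=2048.0,
    )


def _preprocessed(rec, montage, laplacian=False):
    rec = pre.notch_filter(rec)
    rec = pre.downsample(rec, 256.0)
    if laplacian:
        rec = pre.surface_laplacian(rec, montage)
    return rec


@pytest.fixture(scope="session")
def small_epochs(small_session, montage):
    """Notch+downsampled epochs and stimulus epochs (no Laplacian)."""
    rec = _preprocessed(small_session, montage)
    return pre.epoch_extract(rec), pre.epoch_stimulus(rec)


@pytest.fixture(scope="session")
def noise_free_epochs(noise_free_session, montage):
    rec = _preprocessed(noise_free_session, montage)
    return pre.epoch_extract(rec), pre.epoch_stimulus(rec)


@pytest.fixture(scope="session")
def phases_44(small_epochs):
    epochs, stim = small_epochs
    return sw.epoch_phases(epochs[44.0], stim_trials=stim[44.0])


@pytest.fixture(scope="session")
def noise_free_phases_44(noise_free_epochs):
    epochs, stim = noise_free_epochs
    return sw.epoch_phases(epochs[44.0], stim_trials=stim[44.0])
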