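"""Stimulus-locked phase analysis: PLV, surrogate PLS, locking delays.

Each channel and the photodiode trace go through the same narrowband
equiripple filter + Hilbert chain; the phase-locking value (PLV) is the
trial-coherence of their phase difference, and the surrogate PLS guards
against spurious locking.  The channel that locks first (smallest delay)
marks the propagation source.
"""

import numpy as np

import ssvepwave as sw
from ssvepwave import phase_locking as pl
from ssvepwave import preprocess as pre

montage = sw.default_montage()
rec = sw.simulate_recording(
    sw.StimulationProtocol(frequencies=(40.0, 44.0, 52.0, 60.0),
                           trials_per_condition=6, isi_range=(1.5, 2.5),
                           block_break=0.0),
    sw.WavePropagationModel(),
    sw.NoiseModel(seed=5),
)
rec = pre.downsample(pre.notch_filter(rec), 256.0)
epochs, stim = pre.epoch_extract(rec), pre.epoch_stimulus(rec)

phases = {f: sw.epoch_phases(epochs[f], stim_trials=stim[f]) for f in epochs}
delays = {}
for f in sorted(epochs):
    others = [phases[g].stim_phase for g in epochs if g != f]
    series = pl.pls_surrogate(phases[f], others, n_surrogates=200,
                              rng=np.random.default_rng(0))
    delays[f] = pl.locking_delays(series)
    in_stim = series.valid_mask & (series.times >= 0.3) & (series.times <= 1.8)
    ipz = series.channel_names.index("Pz")
    print(f"{f:4.0f} Hz: Pz PLV (in-stimulation) = {series.plv[ipz, in_stim].mean():.3f}, "
          f"locking delay Pz = {1000 * delays[f]['Pz']:.0f} ms, "
          f"Fz = {1000 * delays[f]['Fz']:.0f} ms")

source = pl.select_source(delays, montage, override=None)
dist = montage.distance_matrix("Pz")[source]
print(f"first-locking channel across conditions: {source} "
      f"({dist:.1f} cm from the generator at Pz — with few trials the "
      "winner can be a close neighbour of the true source; a full session "
      "pins it down)")
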