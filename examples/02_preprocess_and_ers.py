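"""Preprocess a simulated session and map event-related synchronization.

Runs the zero-phase preprocessing chain (50 Hz notch, downsample to 256 Hz,
spherical-spline surface Laplacian), epochs the data around stimulus onset,
and prints the percent power change at the stimulation frequency (ERS) for
a few channels: positive ERS marks channels driven by the flicker, and the
posterior dominance reflects the parieto-occipital source.
"""

import ssvepwave as sw
from ssvepwave import preprocess as pre
from ssvepwave.spectral import ers_map, stft_power

montage = sw.default_montage()
rec = sw.simulate_recording(
    sw.StimulationProtocol(frequencies=(44.0, 60.0), trials_per_condition=6,
                           isi_range=(1.5, 2.5), block_break=0.0),
    sw.WavePropagationModel(),
    sw.NoiseModel(seed=1),
)

rec = pre.notch_filter(rec)                  # zero-phase 50 Hz notch
rec = pre.downsample(rec, 256.0)             # anti-aliased, events re-indexed
rec = pre.surface_laplacian(rec, montage)    # reference-free spatial sharpening
epochs = pre.epoch_extract(rec)              # [-1, +3] s around each onset

ep = epochs[44.0]
ers = ers_map(stft_power(ep))
print("ERS at 44 Hz (percent power change vs the 250 ms pre-onset baseline):")
print(f"{'channel':>8} " + " ".join(f"{int(1000 * t):>7d}ms"
                                    for t in ers.window_edges[:-1]))
for ch in ("Pz", "Oz", "P3", "Cz", "Fz", "Fp1"):
    row = ers.values[ers.channel_names.index(ch)]
    print(f"{ch:>8} " + " ".join(f"{v:9.0f}" for v in row))
print("Window 1 is the baseline (0 by construction); the response grows "
      "posteriorly (Pz, Oz) and is sustained after the ~250 ms transient.")
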