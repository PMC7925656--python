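# Methods

## The propagation model

The package treats the high-frequency SSVEP as a narrowband oscillation
emitted at a single parieto-occipital source and propagating isotropically
over the scalp.  During a stimulation window at frequency f, channel *ch*
at great-circle distance d from the source carries

    x_ch(t) = A · exp(−d / d₀) · env(t) · sin(2πf·t − Δφ_ch) + noise,
    Δφ_ch   = 2πf · d / v(f),

where v(f) is the frequency-dependent phase velocity and env(t) an onset
envelope (latency, then a linear ramp to steady state).  This is the
simplest generative model consistent with a progressive phase shift in all
directions from the source; it deliberately matches the estimator's
assumptions exactly in the noise-free limit, so that parameter recovery is
a sharp test of the estimation chain rather than of model mismatch.  No
biophysical forward model (dipoles, lead fields, volume conduction) is
attempted.

Geometry lives on a spherical head of radius 9 cm; electrode positions are
the idealized spherical angles of the 32-channel 10–20 extension (latitude
from the equatorial plane, Cz at +90°), and distances are great-circle
(haversine).  Scalp distances are *not* corrected for cortical folding; an
optional multiplicative `folding_factor` (≈2.2 in the literature) can be
applied to reported velocities, off by default.

## Generator defaults and what they emulate

| parameter | default | meaning |
|---|---|---|
| frequencies | 40–60 Hz step 2, no 50 | flicker conditions (50 Hz is the line frequency) |
| trials_per_condition | 10 | 2 s stimulation per trial |
| isi_range | 3–6 s (uniform) | inter-stimulus intervals |
| rate | 2048 Hz | acquisition rate; analysis at 256 Hz |
| velocity law | v(f) = 8.6 + 0.24·(f−40) m/s | scalp phase velocity per condition |
| amplitude | 2 µV at source | SSVEP fundamental amplitude |
| amplitude_decay_cm | 10 cm | exponential spatial falloff |
| onset latency / ramp | 0.10 s / 0.15 s | steady state by ~250 ms |
| background | 1/f, 2 µV rms per channel | ongoing EEG stand-in |
| line | 50 Hz, 1 µV rms, common | power-line interference |

The waveform on the scalp is sinusoidal at the fundamental even though the
stimulus is a square wave: the analysis is narrowband per condition, so
harmonic content is outside the estimation path (harmonic weights are
configurable but default to the fundamental only).

The noise defaults were chosen once as a realistic high-frequency-SSVEP
regime: after the ±1 Hz bandpass the per-trial amplitude SNR at the
farthest electrode of the gradient subset is ≈2, which makes single trials
visibly noisy while 10-trial phase averaging still supports gradient fits
with r well above 0.85.  Two optional fields extend the model when
spatially structured noise matters: `spatial_scale_cm` correlates the
background across channels with a Gaussian great-circle kernel
(volume-conduction-like smooth fields), and `sensor_rms` adds white
per-channel measurement noise.  Both default off/0.

What the generator does **not** emulate: ocular and muscle artifacts (the
ICA cleaning step of a real pipeline is therefore out of scope), harmonic
and subharmonic response structure, inter-subject variability, realistic
(non-spherical) head geometry, and any perceptual nonlinearity near the
flicker-fusion threshold.  Passing tests consequently show that the
estimation chain is correct and well calibrated under the stated model —
not that real recordings satisfy the model.

All randomness flows from one integer seed with fixed substream
allocation (trial order, ISIs, background, line phase, sensor noise), so
identical configurations reproduce bitwise-identical sessions.

## Numerical choices

**Notch.**  Second-order IIR notch applied forward–backward (zero phase).
Q defaults to 45: after the forward–backward pass this keeps the passband
flat to <0.7 dB beyond ±2 Hz from the line frequency while attenuation at
the line frequency remains effectively complete.

**Resampling.**  Polyphase FIR (linear phase); events keep their onset
time and are re-indexed on the new grid.

**Surface Laplacian.**  Spherical-spline current-source density (spline
stiffness 4, Tikhonov λ = 1e-5, 50 Legendre terms) evaluated by MNE on the
package's 9 cm sphere; the transform matrix is extracted once (the CSD is
a fixed linear map) and applied to recordings or epochs.  It is
reference-free: adding any constant across channels leaves the output
unchanged to numerical precision.

An important measured property: for a traveling wave whose wavelength
(~22 cm) is comparable to the head size, the discrete spline Laplacian
*steepens* the lag-vs-distance gradient by roughly 20%.  The wave occupies
low spherical-harmonic degrees (n ≈ 2–4), and the Laplacian's n(n+1) gain
re-weights that mixture, distorting the phase topography.  The Laplacian
therefore stays in the default full pipeline (where its job is spatial
sharpening and suppression of spatially smooth background, as in standard
practice), but the quantitative velocity-recovery path runs with
`laplacian: false` so that recovered velocities can be compared to the
generator's ground truth; noise-free recovery is then exact to <0.1%.

**Bandpass.**  Parks–McClellan equiripple design per condition (pass
f±1 Hz, stop beyond f±3 Hz, δ_pass 0.058, δ_stop 1e-4, grid density 20).
The order is not fixed a priori: a Kaiser-style estimate seeds the search
and the order grows (odd, type-I) until the verified magnitude response
meets the ripple spec on a 4096-point grid — 367 taps at 44 Hz / 256 Hz.
Filtering uses a centered convolution, which compensates the constant
group delay exactly; a per-sample validity mask excludes the (taps−1)/2
edge samples at each end where the impulse response has not fully entered
the data.  At 256 Hz this masks ≈0.72 s at each epoch edge, so the first
analyzable instant is ≈ −0.28 s relative to onset.

**Hilbert phase.**  Frequency-domain analytic signal; agrees with direct
convolution against the truncated 1/(πt) kernel to <0.01 rad on interior
samples.  An identically zero signal raises an explicit undefined-phase
error rather than propagating NaNs.

**ERS.**  The short-time grid fixes the window *count*: 200 starts on an
exact fractional grid ((N−126)/199 ≈ 4.51-sample hop for the 1024-sample
epoch), each rounded to the nearest sample.  The printed protocol's
"126 samples (500 ms)" is self-contradictory at 256 Hz (126 samples =
492 ms); the sample count is treated as normative.  Power at the
fundamental is the nearest FFT bin (a 3-bin sum is available), averaged
over trials before the baseline ratio (the per-trial-ratio order is
config-exposed).  Two small-sample facts matter when interpreting ERS:
(i) windows centered 250–500 ms after onset still integrate part of the
onset transient through their 492 ms support, so even noise-free ERS dips
a few percent there relative to the fully steady windows; (ii) the
baseline ratio is Jensen-biased upward by ≈100·CV²(baseline power), about
+5% at 10 trials — the noise-only calibration test debiases by exactly
this delta-method estimate.

**PLS.**  200 surrogates by default (resolution 0.005 against the 0.05
threshold).  Surrogates re-pair the target condition's trial phases with
trial-shuffled stimulus phases from a randomly chosen *other* condition;
the stimulus reference always passes through the same filter+Hilbert chain
as the channels.  The threshold is PLS ≤ 0.05.  Being a discrete
exchangeability test, its exact size at the threshold is
(⌊0.05·200⌋+1)/201 ≈ 5.5%, which the calibration check accounts for.
Locking delays are the first valid post-onset sample with PLV > 0.5 and
significant PLS; note that the long FIR smears stimulus-locked energy
~0.7 s backwards, so with very low noise the locking delay can reach 0 —
in realistic noise, delays are positive and grow with distance from the
source on average.

**Gradient fit.**  Lags are unwrapped along electrodes sorted by distance
from the source before the ordinary least-squares fit (a gradient
exceeding π between neighbours would otherwise alias; at λ ≈ 22 cm the
montage rarely triggers it, but correctness demands it).  The fit uses the
signed lag with a free intercept; velocity comes from the fitted slope,
v = 2πf/k, not from pairwise ratios.  The headline window is centered
250 ms after onset, when the steady state is established.  Multi-session
aggregation averages fitted velocities, never phases across sessions.

## Design decisions that were genuinely open

- **Source pinning.**  The pipeline computes locking delays and the
  first-locking channel, but by default pins the propagation source to Pz
  (config `source_override`), mirroring the analysis convention; with
  pinning disabled the plurality-of-conditions rule applies, with ties
  broken by mean delay and then by most-posterior position.
- **Averaging order.**  Phase lags use circular means over trials within a
  session; ERS averages power over trials before the baseline ratio.  Both
  orders are config-exposed where ambiguity exists.
- **Standardized positions.**  Inter-electrode distances use the idealized
  montage, not subject-specific digitization.

## Problem sizes used in the test suite

Unit and property tests run on reduced sessions (typically 4 conditions ×
6 trials with 1.5–2.5 s ISIs) that keep the generator physics unchanged;
the acceptance checks run the full protocol (10 conditions × 10 trials,
3–6 s ISIs) across 20 session seeds and 500 null simulations × 200
surrogates for the PLS calibration.

## Known limitations

- The spline-Laplacian phase-gradient bias (~20% for head-scale
  wavelengths) means velocities estimated *through* the Laplacian are
  systematically low relative to the underlying wave; comparisons across
  preprocessing variants should hold the reference scheme fixed.
- The PLS surrogate scheme needs at least one other stimulation condition
  recorded at the same rate and epoch grid.
- EDF/BDF files can be imported (via MNE's readers), but the fixture
  format is the lossless `.npz` container; EDF export is not provided.
- Velocity estimation assumes a single dominant source; two simultaneous
  sources or standing-wave mixtures violate the linear lag-distance model
  and will show up as low fit correlations rather than as errors.
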