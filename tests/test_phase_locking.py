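"""Narrowband filtering, instantaneous phase, PLV, surrogate PLS,
locking delays and source selection."""

import numpy as np
import pytest

import ssvepwave as sw
from ssvepwave import phase_locking as pl
from ssvepwave.phase_locking import FilterDesignError, UndefinedPhaseError


@pytest.fixture(scope="module")
def spec44():
    return pl.design_bandpass(44.0, 256.0)


class TestFilterDesign:
    def test_meets_printed_ripple_spec(self, spec44):
        w, mag = spec44.response(4096)
        stop = (w <= 41.0) | (w >= 47.0)
        pb = (w >= 43.0) & (w <= 45.0)
        assert mag[stop].max() <= 1e-4 * 1.001
        assert np.abs(mag[pb] - 1.0).max() <= 0.058 * 1.001

    def test_linear_phase_symmetry(self, spec44):
        assert np.allclose(spec44.taps, spec44.taps[::-1])
        assert spec44.n_taps % 2 == 1
        assert spec44.group_delay == (spec44.n_taps - 1) // 2

    def test_stopband_beyond_nyquist_rejected(self):
        with pytest.raises(FilterDesignError, match="Nyquist"):
            pl.design_bandpass(60.0, 122.0)


class TestZeroDelayFiltering:
    def test_probe_sinusoid_phase_preserved(self, spec44):
        t = np.arange(1024) / 256.0
        x = np.sin(2 * np.pi * 44.0 * t)
        y, valid = pl.apply_zero_delay(x, spec44)
        ph_x, _ = pl.instantaneous_phase(x)
        ph_y, _ = pl.instantaneous_phase(y)
        dphi = np.abs(np.angle(np.exp(1j * (ph_y - ph_x))))[valid]
        assert dphi.max() < 0.01

    def test_zero_lag_by_cross_correlation(self, spec44):
        t = np.arange(2048) / 256.0
        x = np.sin(2 * np.pi * 44.0 * t)
        y, valid = pl.apply_zero_delay(x, spec44)
        xi, yi = x[valid], y[valid]
        lags = np.arange(-5, 6)
        cc = [np.dot(xi[5:-5], yi[5 + l:len(yi) - 5 + l]) for l in lags]
        assert lags[np.argmax(cc)] == 0

    def test_white_noise_band_limited(self, spec44):
        from scipy.signal import periodogram

        rng = np.random.default_rng(0)
        x = rng.standard_normal(4096)
        y, valid = pl.apply_zero_delay(x, spec44)
        freqs, spec = periodogram(y[valid], fs=256.0, window="hann")
        inband = (freqs >= 41.0) & (freqs <= 47.0)
        assert spec[inband].sum() / spec.sum() >= 0.999

    def test_zero_input_zero_output(self, spec44):
        y, _ = pl.apply_zero_delay(np.zeros(1024), spec44)
        assert np.allclose(y, 0.0)

    def test_signal_shorter_than_filter_rejected(self, spec44):
        with pytest.raises(ValueError, match="not longer"):
            pl.apply_zero_delay(np.zeros(spec44.n_taps), spec44)

    def test_valid_mask_excludes_group_delay_edges(self, spec44):
        _, valid = pl.apply_zero_delay(np.zeros(1024) + 1.0, spec44)
        gd = spec44.group_delay
        assert not valid[:gd].any() and not valid[-gd:].any()
        assert valid[gd:-gd].all()


class TestInstantaneousPhase:
    def test_cosine_phase_ramp(self):
        t = np.arange(1024) / 256.0
        ph, _ = pl.instantaneous_phase(np.cos(2 * np.pi * 10.0 * t))
        expected = np.angle(np.exp(1j * 2 * np.pi * 10.0 * t))
        err = np.abs(np.angle(np.exp(1j * (ph - expected))))[32:-32]
        assert ph[0] == pytest.approx(0.0, abs=1e-6)
        assert err.max() < 0.01

    def test_envelope_recovers_amplitude(self):
        t = np.arange(1024) / 256.0
        _, amp = pl.instantaneous_phase(3.0 * np.cos(2 * np.pi * 10.0 * t))
        interior = amp[64:-64]
        assert np.abs(interior - 3.0).max() < 0.03

    def test_fft_hilbert_matches_direct_convolution(self):
        """Frequency-domain analytic signal vs truncated 1/(πt) kernel."""
        rng = np.random.default_rng(3)
        t = np.arange(2048) / 256.0
        x = np.sin(2 * np.pi * 44.0 * t) + 0.2 * np.sin(2 * np.pi * 43.0 * t + 1.0)
        ph_fft, _ = pl.instantaneous_phase(x)
        m = 301
        n = np.arange(-m, m + 1)
        with np.errstate(divide="ignore"):
            kernel = np.where(n % 2 != 0, 2.0 / (np.pi * n), 0.0)
        xh = np.convolve(x, kernel, mode="same")
        ph_conv = np.angle(x + 1j * xh)
        interior = slice(m, len(x) - m)
        err = np.abs(np.angle(np.exp(1j * (ph_fft - ph_conv))))[interior]
        assert err.max() < 0.01

    def test_all_zero_signal_flagged(self):
        with pytest.raises(UndefinedPhaseError):
            pl.instantaneous_phase(np.zeros(128))


class TestPhaseDifferenceAndPLV:
    def test_wrapping_conventions(self):
        assert pl.phase_difference(np.array(1.0), np.array(1.0)) == 0.0
        assert pl.phase_difference(np.array(3 * np.pi / 2), np.array(0.0)) == pytest.approx(
            -np.pi / 2
        )
        assert pl.phase_difference(np.array(np.pi), np.array(0.0)) == pytest.approx(np.pi)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pl.phase_difference(np.zeros(3), np.zeros(4))

    def test_identical_diffs_give_one(self):
        assert pl.plv(np.full((5, 10), 0.7)) == pytest.approx(1.0)

    def test_antipodal_cancellation(self):
        d = np.array([0.0, np.pi, 0.0, np.pi])[:, None]
        assert pl.plv(d)[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            pl.plv(np.zeros((1, 10)))

    def test_common_phase_offset_invariance(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(-np.pi, np.pi, (8, 50))
        assert np.allclose(pl.plv(d), pl.plv(d + 1.234), atol=1e-12)

    def test_rayleigh_resultant_for_uniform_phases(self):
        """Mean PLV of N=100 uniform phases ≈ √π/2·N^(-1/2) ≈ 0.0886."""
        rng = np.random.default_rng(12)
        d = rng.uniform(-np.pi, np.pi, (100, 10_000))
        assert pl.plv(d).mean() == pytest.approx(np.sqrt(np.pi) / 2 / 10.0, abs=0.002)


def _null_phase_series(n_trials=10, n_samples=300, n_ch=1, seed=0):
    rng = np.random.default_rng(seed)
    phase = rng.uniform(-np.pi, np.pi, (n_trials, n_ch, n_samples))
    stim = rng.uniform(-np.pi, np.pi, (n_trials, n_samples))
    return pl.PhaseSeries(
        phase, np.ones_like(phase), np.ones(n_samples, bool), 256.0, -1.0,
        44.0, [f"c{i}" for i in range(n_ch)], stim,
    )


class TestSurrogatePLS:
    def test_perfect_locking_gives_pls_zero(self):
        n, s = 8, 100
        rng = np.random.default_rng(1)
        stim = rng.uniform(-np.pi, np.pi, (n, s))
        phase = stim[:, None, :].copy()  # channel == stimulus: PLV = 1
        ps = pl.PhaseSeries(phase, np.ones_like(phase), np.ones(s, bool),
                            256.0, 0.0, 44.0, ["c0"], stim)
        others = [rng.uniform(-np.pi, np.pi, (n, s))]
        series = pl.pls_surrogate(ps, others, n_surrogates=50, rng=2)
        assert np.all(series.plv == pytest.approx(1.0))
        assert np.all(series.pls == 0.0)

    def test_null_pls_calibrated(self):
        """Independent phases: P(PLS ≤ α) stays within α + 0.02 for
        α ∈ {0.01, 0.05, 0.10} (surrogate test is valid, not anticonservative
        beyond its discreteness)."""
        ps = _null_phase_series(n_samples=500, seed=10)
        others = [np.random.default_rng(11).uniform(-np.pi, np.pi, (10, 500))]
        series = pl.pls_surrogate(ps, others, n_surrogates=200, rng=12)
        for alpha in (0.01, 0.05, 0.10):
            frac = (series.pls[0] <= alpha).mean()
            assert frac <= alpha + 0.02 + 2 * np.sqrt(alpha * (1 - alpha) / 500)

    def test_too_few_surrogates_rejected(self):
        ps = _null_phase_series()
        with pytest.raises(ValueError, match="19"):
            pl.pls_surrogate(ps, [np.zeros((10, 300))], n_surrogates=0)

    def test_no_other_condition_rejected(self):
        ps = _null_phase_series()
        with pytest.raises(ValueError, match="other stimulation condition"):
            pl.pls_surrogate(ps, [], n_surrogates=50)

    def test_seeded_reproducibility(self):
        ps = _null_phase_series(seed=4)
        others = [np.random.default_rng(5).uniform(-np.pi, np.pi, (10, 300))]
        a = pl.pls_surrogate(ps, others, n_surrogates=40, rng=6)
        b = pl.pls_surrogate(ps, others, n_surrogates=40, rng=6)
        assert np.array_equal(a.pls, b.pls)


def _series(plv_vals, pls_vals, rate=256.0, t0=-0.5):
    n = len(plv_vals)
    return pl.PLVSeries(
        np.asarray(plv_vals)[None, :], np.asarray(pls_vals)[None, :], 10,
        np.ones(n, bool), rate, t0, 44.0, ["Pz"],
    )


class TestLockingDelay:
    def test_immediate_lock_gives_zero_delay(self):
        s = _series(np.full(256, 0.9), np.full(256, 0.01))
        d = pl.locking_delays(s)
        assert d["Pz"] == pytest.approx(0.0, abs=1e-9)

    def test_never_significant_gives_nan(self):
        s = _series(np.full(256, 0.9), np.full(256, 1.0))
        assert np.isnan(pl.locking_delays(s)["Pz"])

    def test_pls_required(self):
        s = _series(np.full(256, 0.9), np.full(256, 0.01))
        s.pls = None
        with pytest.raises(ValueError, match="pls_surrogate"):
            pl.locking_delays(s)


class TestSelectSource:
    def test_plurality_winner(self, montage):
        delays = {}
        for i, f in enumerate(sw.DEFAULT_FREQUENCIES):
            if i < 7:
                delays[f] = {"Pz": 0.05, "Oz": 0.10, "Fz": 0.20}
            else:
                delays[f] = {"Pz": 0.15, "Oz": 0.08, "Fz": 0.20}
        assert pl.select_source(delays, montage, override=None) == "Pz"

    def test_all_equal_tie_breaks_to_most_posterior(self, montage):
        delays = {44.0: {"Oz": 0.1, "Pz": 0.1, "Fz": 0.1}}
        assert pl.select_source(delays, montage, override=None) == "Oz"

    def test_override_pins_choice(self, montage):
        delays = {44.0: {"Oz": 0.1}}
        assert pl.select_source(delays, montage, override="Pz") == "Pz"

    def test_no_defined_delays_rejected(self, montage):
        delays = {44.0: {"Pz": float("nan")}}
        with pytest.raises(ValueError, match="no channel"):
            pl.select_source(delays, montage, override=None)
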