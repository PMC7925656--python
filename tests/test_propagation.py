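"""Phase-lag maps, gradient fits, velocity/wavelength arithmetic, trend."""

import numpy as np
import pytest
from scipy import stats

import ssvepwave as sw
from ssvepwave import propagation as prop


class TestWindowedPhaseLag:
    def test_source_lag_is_zero(self, phases_44):
        lm = prop.windowed_phase_lag(phases_44, "Pz", 0.25)
        assert lm.lags["Pz"] == 0.0

    def test_noise_free_lags_match_velocity_law(self, noise_free_phases_44, montage):
        wave = sw.WavePropagationModel()
        dm = montage.distance_matrix("Pz")
        lm = prop.windowed_phase_lag(noise_free_phases_44, "Pz", 0.25)
        f = 44.0
        for ch in prop.GRADIENT_ELECTRODES:
            expected = 2 * np.pi * f * (dm[ch] / 100.0) / wave.velocity(f)
            wrapped = np.angle(np.exp(1j * expected))
            assert lm.lags[ch] == pytest.approx(wrapped, abs=1e-2)

    def test_constant_offset_equivariance(self, noise_free_phases_44):
        import copy

        ps = copy.deepcopy(noise_free_phases_44)
        ci = ps.channel_index("Oz")
        base = prop.windowed_phase_lag(ps, "Pz", 0.25).lags["Oz"]
        ps.phase[:, ci, :] -= 0.5  # channel phase shifted back => lag +0.5
        shifted = prop.windowed_phase_lag(ps, "Pz", 0.25).lags["Oz"]
        assert np.angle(np.exp(1j * (shifted - base - 0.5))) == pytest.approx(0.0, abs=1e-9)

    def test_window_in_filter_transient_rejected(self, phases_44):
        with pytest.raises(ValueError, match="later window"):
            prop.windowed_phase_lag(phases_44, "Pz", window_center=-0.9)


class TestGradientFit:
    def make_map(self, lags):
        return prop.PhaseLagMap(lags, "Pz", 0.25, 5, 44.0)

    def test_exact_line_recovered(self, montage):
        dm = montage.distance_matrix("Pz")
        k = 0.21
        lags = {ch: np.angle(np.exp(1j * k * dm[ch])) for ch in prop.GRADIENT_ELECTRODES}
        fit = prop.fit_phase_gradient(self.make_map(lags), dm)
        assert fit.slope == pytest.approx(k, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_constant_lags_give_zero_slope(self, montage):
        dm = montage.distance_matrix("Pz")
        lags = {ch: 0.4 for ch in prop.GRADIENT_ELECTRODES}
        fit = prop.fit_phase_gradient(self.make_map(lags), dm)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_unwrapping_beats_naive_fit_for_short_wavelength(self, montage):
        """λ = 10 cm ⇒ lags wrap within the montage; distance-ordered
        unwrapping recovers the true gradient, a naive wrapped fit cannot."""
        dm = montage.distance_matrix("Pz")
        k = 2 * np.pi / 10.0  # rad/cm
        lags = {ch: np.angle(np.exp(1j * k * dm[ch])) for ch in prop.GRADIENT_ELECTRODES}
        fit = prop.fit_phase_gradient(self.make_map(lags), dm)
        assert fit.slope == pytest.approx(k, rel=1e-6)
        d = np.array([dm[ch] for ch in prop.GRADIENT_ELECTRODES])
        lag_arr = np.array([lags[ch] for ch in prop.GRADIENT_ELECTRODES])
        naive = stats.linregress(d, lag_arr).slope
        assert abs(naive - k) / k > 0.5

    def test_too_few_points_rejected(self, montage):
        dm = montage.distance_matrix("Pz")
        with pytest.raises(ValueError, match="3 electrodes"):
            prop.fit_phase_gradient(self.make_map({"Pz": 0, "Oz": 1}), dm, ("Pz", "Oz"))

    def test_degenerate_distances_rejected(self):
        lags = {"a": 0.0, "b": 0.1, "c": 0.2}
        dm = {"a": 5.0, "b": 5.0, "c": 5.0}
        with pytest.raises(ValueError, match="same distance"):
            prop.fit_phase_gradient(
                prop.PhaseLagMap(lags, "a", 0.25, 5, 44.0), dm, ("a", "b", "c")
            )


class TestVelocityArithmetic:
    def test_worked_example_40hz(self):
        # one full cycle of lag over 21.6 cm at 40 Hz -> 8.64 m/s
        assert prop.phase_velocity(40.0, 21.6, 2 * np.pi) == pytest.approx(8.64)

    def test_velocity_equals_f_lambda_identity(self):
        for lam in (10.0, 22.0, 30.0):
            v = prop.phase_velocity(44.0, lam / 2.0, np.pi)
            assert v == pytest.approx(44.0 * lam / 100.0)

    def test_zero_phase_difference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            prop.phase_velocity(44.0, 10.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            prop.velocity_from_slope(44.0, 0.0)

    def test_wavelength_values(self):
        assert prop.wavelength(8.64, 40.0) == pytest.approx(21.6)
        assert prop.wavelength(0.0, 40.0) == 0.0
        assert prop.wavelength(12.0, 60.0) == pytest.approx(20.0)

    def test_slope_form_consistent_with_pairwise_form(self):
        k = 0.25  # rad/cm
        v1 = prop.velocity_from_slope(44.0, k)
        v2 = prop.phase_velocity(44.0, 7.0, k * 7.0)
        assert v1 == pytest.approx(v2)


class TestTrend:
    def fake_estimate(self, f, v):
        fit = prop.GradientFit(0.1, 0.0, 1.0, 0.0, prop.GRADIENT_ELECTRODES, 0.25)
        return prop.VelocityEstimate(v, prop.wavelength(v, f), f, fit)

    def test_exact_linear_trend(self):
        est = [self.fake_estimate(f, 2.0 + 0.3 * f) for f in (40.0, 44.0, 48.0, 52.0)]
        tr = prop.velocity_frequency_trend(est)
        assert tr.slope == pytest.approx(0.3)
        assert tr.r == pytest.approx(1.0)

    def test_constant_velocities_zero_slope(self):
        est = [self.fake_estimate(f, 9.0) for f in (40.0, 44.0, 48.0)]
        assert prop.velocity_frequency_trend(est).slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_conditions_rejected(self):
        est = [self.fake_estimate(40.0, 9.0), self.fake_estimate(44.0, 9.5)]
        with pytest.raises(ValueError, match="3 conditions"):
            prop.velocity_frequency_trend(est)


class TestEndToEndRecovery:
    def test_noise_free_velocity_within_one_percent(
        self, noise_free_epochs, montage
    ):
        """Laplacian-free estimation chain recovers v(f) to <1% noise-free."""
        epochs, _ = noise_free_epochs
        wave = sw.WavePropagationModel()
        for f, ep in epochs.items():
            ps = sw.epoch_phases(ep)
            lm = prop.windowed_phase_lag(ps, "Pz", 0.25)
            est = prop.estimate_velocity(lm, montage)
            assert est.velocity == pytest.approx(wave.velocity(f), rel=0.01)
            assert est.wavelength == pytest.approx(
                100.0 * est.velocity / f, abs=1e-9
            )  # v = f·λ identity

    def test_velocity_doubles_when_generator_velocity_doubles(self, montage):
        """Monotone equivariance of the estimator (noise-free)."""
        from conftest import small_protocol

        vels = {}
        for scale in (1.0, 2.0):
            wave = sw.WavePropagationModel(
                velocity_v0=8.6 * scale, velocity_slope=0.24 * scale
            )
            rec = sw.simulate_recording(
                small_protocol(trials=3), wave,
                sw.NoiseModel(background_rms=0.0, line_rms=0.0, seed=2),
                montage,
            )
            from ssvepwave import preprocess as pre

            rec = pre.downsample(pre.notch_filter(rec), 256.0)
            ep = pre.epoch_extract(rec)[44.0]
            lm = prop.windowed_phase_lag(sw.epoch_phases(ep), "Pz", 0.25)
            vels[scale] = prop.estimate_velocity(lm, montage).velocity
        assert vels[2.0] / vels[1.0] == pytest.approx(2.0, rel=0.01)

    def test_default_noise_gradient_fit_strong(self, phases_44, montage):
        lm = prop.windowed_phase_lag(phases_44, "Pz", 0.25)
        fit = prop.fit_phase_gradient(lm, montage.distance_matrix("Pz"))
        assert fit.r >= 0.85
        assert fit.p < 0.01


class TestReferenceContrast:
    def test_laplacian_suppresses_spurious_gradients_vs_car(self, montage):
        """Spatially correlated background without any stimulus: the common
        average reference keeps smooth volume-conducted phase fields (high
        spurious |r| of the gradient fit), the surface Laplacian reduces
        them."""
        from ssvepwave import preprocess as pre, phase_locking as pl

        proto = sw.StimulationProtocol(
            frequencies=(40.0, 44.0, 48.0, 52.0, 56.0, 60.0),
            trials_per_condition=8, isi_range=(1.5, 2.5), block_break=0.0,
        )
        mean_abs_r = {"car": [], "lap": []}
        for seed in range(3):
            rec = sw.simulate_recording(
                proto,
                sw.WavePropagationModel(amplitude_uv=0.0),
                sw.NoiseModel(seed=seed, spatial_scale_cm=12.0, line_rms=0.5,
                              sensor_rms=0.5),
                montage,
            )
            rec = pre.downsample(pre.notch_filter(rec), 256.0)
            for name, variant in (
                ("car", pre.common_average_reference(rec)),
                ("lap", pre.surface_laplacian(rec, montage)),
            ):
                for f, ep in pre.epoch_extract(variant).items():
                    lm = prop.windowed_phase_lag(sw.epoch_phases(ep), "Pz", 0.25)
                    mean_abs_r[name].append(
                        abs(prop.fit_phase_gradient(lm, montage.distance_matrix("Pz")).r)
                    )
        assert np.mean(mean_abs_r["lap"]) < np.mean(mean_abs_r["car"]) - 0.05
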