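import numpy as np
import pytest

from litt import (
    CorruptionModel,
    DoseMap,
    DriftCorrector,
    KalmanConfig,
    accumulate_cem43,
    build_reference,
    compute_snr_mask,
    init_kalman,
    kalman_update,
    prf_phase_factor,
    reconstruct_temperature,
)
from litt.mrisynth import wrap_phase

GRID = (16, 16, 4)


class TestReference:
    def test_identical_frames_reference_is_their_phase(self, protocol):
        frame = 50.0 * np.exp(1j * 0.3) * np.ones(GRID)
        stack = np.stack([frame] * 12, axis=-1)
        np.testing.assert_allclose(build_reference(stack), 0.3, atol=1e-12)

    def test_only_first_ten_frames_used(self, protocol):
        rng = np.random.default_rng(0)
        stack = 50 * np.exp(1j * rng.random(GRID + (15,)))
        altered = stack.copy()
        altered[..., 10:] *= np.exp(1j * 1.0)
        np.testing.assert_array_equal(build_reference(stack),
                                      build_reference(altered))

    def test_requires_ten_frames(self):
        with pytest.raises(ValueError):
            build_reference(np.zeros(GRID + (9,), dtype=complex))

    def test_averaging_reduces_phase_variance_tenfold(self):
        rng = np.random.default_rng(42)
        n_vox, n_rep = 1000, 400
        sig = 100.0
        noise = 5.0 * (rng.standard_normal((n_vox, n_rep, 10, 2)))
        frames = sig + noise[..., 0] + 1j * noise[..., 1]
        single_var = np.var(np.angle(frames[:, :, 0]))
        ref_var = np.var(np.angle(frames.mean(axis=2)))
        assert ref_var == pytest.approx(single_var / 10, rel=0.1)


class TestReconstruction:
    def test_zero_when_phase_equals_reference(self, protocol):
        ref = np.full(GRID, 0.7)
        frame = np.exp(1j * ref)
        np.testing.assert_allclose(
            reconstruct_temperature(frame, ref, protocol), 0.0, atol=1e-12
        )

    def test_constructed_ten_degree_shift(self, protocol):
        ref = np.zeros(GRID)
        frame = np.exp(1j * prf_phase_factor(protocol) * 10.0) * np.ones(GRID)
        np.testing.assert_allclose(
            reconstruct_temperature(frame, ref, protocol), 10.0, atol=1e-9
        )


class TestSnrMask:
    def test_uniform_magnitude_all_included(self):
        assert compute_snr_mask(np.ones(GRID + (20,))).all()

    def test_threshold_straddle_at_five_percent(self):
        window = np.full(GRID + (20,), 100.0)
        window[0, 0, 0] = 4.0
        window[0, 0, 1] = 6.0
        mask = compute_snr_mask(window)
        assert not mask[0, 0, 0]
        assert mask[0, 0, 1]


def run_drift_window(corrector, phases, temps, mask, start=0):
    out = None
    for i in range(phases.shape[-1]):
        out, coeffs = corrector.update(start + i, phases[..., i],
                                       temps[..., i], mask)
    return out, coeffs


class TestDriftCorrector:
    def grid_xy(self, protocol):
        dx, dy, _ = protocol.voxel_size
        x = np.arange(GRID[0])[:, None, None] * dx
        y = np.arange(GRID[1])[None, :, None] * dy
        return x, y

    def make_drift(self, protocol, a=(0.02, 1e-3, -5e-4, 2e-3), n=20, start=0):
        x, y = self.grid_xy(protocol)
        return np.stack(
            [a[0] + a[1] * x + a[2] * y + a[3] * (start + k) * np.ones(GRID)
             for k in range(n)], axis=-1,
        )

    def test_model_matched_drift_removed_below_centidegree(self, protocol):
        drift = self.make_drift(protocol)
        corr = DriftCorrector(protocol, GRID)
        factor = prf_phase_factor(protocol)
        out, _ = run_drift_window(corr, drift, drift / factor,
                                  np.ones(GRID, bool))
        assert np.abs(out / factor).max() < 0.01

    def test_no_drift_leaves_data_untouched(self, protocol):
        zeros = np.zeros(GRID + (20,))
        corr = DriftCorrector(protocol, GRID)
        out, _ = run_drift_window(corr, zeros, zeros, np.ones(GRID, bool))
        assert np.abs(out).max() < 1e-6 * abs(prf_phase_factor(protocol))

    def test_hotspot_outside_gate_cannot_bias_fit(self, protocol):
        # a 10 °C hotspot sits in the field; with the ±5 °C gate it is
        # excluded from the fit, without the gate it corrupts the estimate
        factor = prf_phase_factor(protocol)
        drift = self.make_drift(protocol)
        hot = np.zeros(GRID)
        hot[4:8, 4:8, :] = 10.0
        phases = drift + (hot * factor)[..., None]
        temps = phases / factor
        gated = DriftCorrector(protocol, GRID)
        out_gated, _ = run_drift_window(gated, phases, temps,
                                        np.ones(GRID, bool))
        ungated = DriftCorrector(protocol, GRID, gate=(-1e9, 1e9))
        out_raw, _ = run_drift_window(ungated, phases, temps,
                                      np.ones(GRID, bool))
        cold = hot == 0.0
        bias_gated = np.abs(out_gated / factor - hot)[cold].max()
        bias_raw = np.abs(out_raw / factor - hot)[cold].max()
        assert bias_gated < 0.01
        assert bias_raw > 10 * bias_gated

    def test_idempotent_on_corrected_data(self, protocol):
        drift = self.make_drift(protocol)
        factor = prf_phase_factor(protocol)
        first = DriftCorrector(protocol, GRID)
        mask = np.ones(GRID, bool)
        corrected = []
        for k in range(20):
            out, _ = first.update(k, drift[..., k], drift[..., k] / factor, mask)
            corrected.append(out)
        second = DriftCorrector(protocol, GRID)
        # feed the last corrected frame repeatedly: the refit must be a no-op
        final = corrected[-1]
        for k in range(20):
            out2, _ = second.update(k, final, final / factor, mask)
        assert np.abs(out2 - final).max() < 1e-9

    def test_too_few_voxels_keeps_previous_coefficients(self, protocol):
        corr = DriftCorrector(protocol, GRID)
        mask = np.zeros(GRID, bool)
        mask[:2, :2, :] = True  # 4 voxels per slice < 50
        with pytest.warns(UserWarning, match="eligible voxels"):
            _, coeffs = corr.update(0, np.ones(GRID), np.zeros(GRID), mask)
        np.testing.assert_array_equal(coeffs, np.zeros((GRID[2], 4)))


def scalar_kalman(measurements, dt, q, r, x0, p0):
    """Straightforward textbook 2-state filter, written independently."""
    F = np.array([[1.0, dt], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    Q = q * np.eye(2)
    x = np.array([x0, 0.0])
    P = p0.copy()
    out = []
    for z in measurements:
        x = F @ x
        P = F @ P @ F.T + Q
        S = (H @ P @ H.T)[0, 0] + r
        K = (P @ H.T)[:, 0] / S
        x = x + K * (z - x[0])
        P = (np.eye(2) - np.outer(K, H[0])) @ P
        out.append(x[0])
    return np.array(out)


class TestKalman:
    def test_constant_baseline_variance_floored(self):
        baseline = np.full((4, 4, 2, 20), 1.5)
        state = init_kalman(baseline, KalmanConfig())
        np.testing.assert_allclose(state.measurement_variance, 1e-4)
        np.testing.assert_allclose(state.temperature, 1.5)

    def test_noise_variance_estimated_from_baseline(self):
        rng = np.random.default_rng(1)
        baseline = 0.5 * rng.standard_normal((40, 25, 1, 20))
        state = init_kalman(baseline, KalmanConfig())
        assert state.measurement_variance.mean() == pytest.approx(0.25, abs=0.05)

    def test_default_process_noise_matches_pipeline_setting(self):
        assert KalmanConfig().process_noise_variance == 0.001

    def test_white_acceleration_process_model(self):
        q = KalmanConfig(process_model="white_acceleration",
                         transition_dt=2.0).process_covariance()
        np.testing.assert_allclose(q, 0.001 * np.array([[4.0, 4.0],
                                                        [4.0, 4.0]]))
        with pytest.raises(ValueError):
            KalmanConfig(process_model="nope")

    def test_matches_scalar_oracle_on_noisy_ramp(self):
        rng = np.random.default_rng(9)
        n = 200
        truth = 0.1 * np.arange(n)
        meas = truth + 0.4 * rng.standard_normal(n)
        cfg = KalmanConfig(process_noise_variance=0.001, transition_dt=1.0)
        r = 0.16
        baseline = np.zeros((1, 1, 1, 20))
        state = init_kalman(baseline, cfg)
        state.measurement_variance[:] = r
        state.p11[:] = r
        state.p22[:] = r
        state.temperature[:] = 0.0
        expected = scalar_kalman(meas, 1.0, 0.001, r, 0.0,
                                 np.diag([r, r]))
        got = []
        for z in meas:
            kalman_update(state, np.full((1, 1, 1), z), cfg)
            got.append(state.temperature[0, 0, 0])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_tiny_measurement_noise_tracks_measurement(self):
        cfg = KalmanConfig()
        state = init_kalman(np.zeros((2, 2, 1, 20)), cfg)
        # floored variance 1e-4 °C² → the filter locks onto the data within
        # a few frames
        for _ in range(5):
            kalman_update(state, np.full((2, 2, 1), 7.0), cfg)
        np.testing.assert_allclose(state.temperature, 7.0, atol=0.01)

    def test_huge_measurement_noise_keeps_prediction(self):
        cfg = KalmanConfig()
        state = init_kalman(np.zeros((2, 2, 1, 20)), cfg)
        state.measurement_variance[:] = 1e9
        kalman_update(state, np.full((2, 2, 1), 7.0), cfg)
        np.testing.assert_allclose(state.temperature, 0.0, atol=1e-4)

    def test_nonfinite_measurement_predicts_and_flags(self):
        cfg = KalmanConfig()
        state = init_kalman(np.zeros((2, 1, 1, 20)), cfg)
        state.temperature[:] = 1.0
        state.rate[:] = 0.5
        z = np.array([[[np.nan]], [[1.4]]])
        kalman_update(state, z, cfg)
        assert state.skipped[0, 0, 0] and not state.skipped[1, 0, 0]
        assert state.temperature[0, 0, 0] == pytest.approx(1.5)

    def test_filter_reduces_stationary_noise(self):
        rng = np.random.default_rng(2)
        n = 500
        meas = 0.3 * rng.standard_normal((8, 8, 1, n))
        cfg = KalmanConfig()
        state = init_kalman(meas[..., :20], cfg)
        outs = []
        for k in range(20, n):
            kalman_update(state, meas[..., k], cfg)
            outs.append(state.temperature.copy())
        outs = np.stack(outs, axis=-1)
        assert outs.var(axis=-1).mean() < 0.5 * meas.var(axis=-1).mean()

    def test_no_lag_on_clean_ramp(self):
        # 0.25 °C/s ramp: the filtered series must trail the truth by at most
        # one frame (peak cross-correlation of the differenced series)
        n = 120
        truth = 0.25 * np.arange(n)
        cfg = KalmanConfig()
        state = init_kalman(np.zeros((1, 1, 1, 20)), cfg)
        got = []
        for z in truth:
            kalman_update(state, np.full((1, 1, 1), z), cfg)
            got.append(state.temperature[0, 0, 0])
        got = np.array(got)
        # steady-state tracking deficit divided by the slope = group delay
        lag_frames = (truth[40:] - got[40:]).mean() / 0.25
        assert lag_frames <= 1.0
        assert np.abs(got[20:] - truth[20:]).max() < 0.3


class TestCem43:
    def test_threshold_exactly_at_43_degrees_for_240_minutes(self):
        dose = DoseMap.zeros((2, 2, 1))
        accumulate_cem43(dose, np.full((2, 2, 1), 43.0 - 37.0), 37.0,
                         240.0 * 60.0)
        np.testing.assert_allclose(dose.cem43, 240.0)
        assert dose.lethal_mask.all()

    def test_47_degrees_needs_15_minutes(self):
        dose = DoseMap.zeros((1, 1, 1))
        accumulate_cem43(dose, np.full((1, 1, 1), 10.0), 37.0, 15.0 * 60.0)
        np.testing.assert_allclose(dose.cem43, 2**4 * 15.0)

    def test_body_temperature_accumulates_almost_nothing(self):
        dose = DoseMap.zeros((1, 1, 1))
        minutes = 100.0
        accumulate_cem43(dose, np.zeros((1, 1, 1)), 37.0, minutes * 60.0)
        assert dose.cem43[0, 0, 0] < 0.02 * minutes

    def test_dose_is_additive_and_monotone(self):
        rng = np.random.default_rng(3)
        a = 5 * rng.random((4, 4, 2))
        b = 5 * rng.random((4, 4, 2))
        split = DoseMap.zeros((4, 4, 2))
        accumulate_cem43(split, a, 37.0, 30.0)
        partial = split.cem43.copy()
        accumulate_cem43(split, b, 37.0, 30.0)
        assert np.all(split.cem43 >= partial)
        joint = DoseMap.zeros((4, 4, 2))
        accumulate_cem43(joint, b, 37.0, 30.0)
        accumulate_cem43(joint, a, 37.0, 30.0)
        np.testing.assert_allclose(split.cem43, joint.cem43, rtol=1e-12)
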