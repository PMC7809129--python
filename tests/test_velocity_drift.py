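import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shankgait import (
    GaitSimConfig,
    Quaternion,
    integrate_velocity,
    ipm_update_velocity,
    reconstruct,
    remove_drift,
    simulate_walk,
    zupt_update_velocity,
)

finite = st.floats(min_value=-10.0, max_value=10.0)


class TestIntegrateVelocity:
    def test_constant_acceleration_exact(self):
        a = np.tile([0.0, 1.0, 0.0], (101, 1))  # 1 m/s² for 1 s at 100 Hz
        v = integrate_velocity(a, 0.01, np.zeros(3))
        np.testing.assert_allclose(v[-1], [0.0, 1.0, 0.0], atol=1e-12)

    def test_zero_acceleration_keeps_v0(self):
        v = integrate_velocity(np.zeros((50, 3)), 0.01, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(v, np.tile([1.0, 2.0, 3.0], (50, 1)), atol=1e-15)

    def test_linear_ramp_exact(self):
        # trapezoid is exact for linear integrands: ramp 0 -> 2 m/s² over 1 s
        t = np.linspace(0.0, 1.0, 101)
        a = np.column_stack([2.0 * t, np.zeros(101), np.zeros(101)])
        v = integrate_velocity(a, 0.01, np.zeros(3))
        assert v[-1, 0] == pytest.approx(1.0, abs=1e-12)


class TestIpmUpdateVelocity:
    def test_cross_product_case(self):
        # identity orientation, rate about z, lever along x -> tangential y
        q = Quaternion.identity()
        v = ipm_update_velocity(q, [0.0, 0.0, 2.0], [9.81, 0.0, 0.0], 0.05)
        np.testing.assert_allclose(v, [0.0, 0.1, 0.0], atol=1e-12)

    def test_zero_rate_reduces_to_zupt(self):
        q = Quaternion.from_axis_angle([0, 0, 1], 0.4)
        v = ipm_update_velocity(q, np.zeros(3), [9.0, 1.0, 0.0], 0.05)
        np.testing.assert_allclose(v, zupt_update_velocity(), atol=1e-15)

    def test_rejects_bad_r(self):
        with pytest.raises(ValueError):
            ipm_update_velocity(Quaternion.identity(), [0, 0, 1], [9.81, 0, 0], 0.0)

    def test_matches_simulator_midstance_velocity(self, noiseless_trial, noiseless_result):
        # oracle: the simulator's analytic IMU velocity at each mid-stance
        vel = noiseless_result.velocity
        truth_v = noiseless_trial.truth_v
        for i, m in enumerate(vel.ms_idx):
            np.testing.assert_allclose(vel.v_update[i], truth_v[m], atol=1e-4)


class TestZupt:
    def test_returns_zero(self):
        np.testing.assert_array_equal(zupt_update_velocity(), np.zeros(3))

    def test_zupt_bias_larger_with_moving_midstance(self):
        cfg = GaitSimConfig(n_strides=10, seed=5)
        trial = simulate_walk(cfg)
        biases = {}
        for method in ("ipm", "zupt"):
            res = reconstruct(trial.rec, r=cfg.r_m, method=method)
            errs = [
                s.stride_length_m - t.stride_length_m
                for s, t in zip(res.strides, trial.truth_params)
            ]
            biases[method] = np.mean(errs)
        assert abs(biases["ipm"]) < abs(biases["zupt"])

    def test_zupt_equals_ipm_when_still_at_midstance(self):
        cfg = GaitSimConfig(n_strides=5, still_at_midstance=True)
        trial = simulate_walk(cfg)
        a = reconstruct(trial.rec, r=cfg.r_m, method="ipm")
        b = reconstruct(trial.rec, r=cfg.r_m, method="zupt")
        for sa, sb in zip(a.strides, b.strides):
            assert sa.stride_length_m == pytest.approx(sb.stride_length_m, abs=1e-9)
            assert sa.velocity_mps == pytest.approx(sb.velocity_mps, abs=1e-9)
            assert sa.vertical_disp_m == pytest.approx(sb.vertical_disp_m, abs=1e-9)


class TestRemoveDrift:
    def test_pure_linear_drift_cancels(self):
        k = np.arange(11)[:, None]
        v_raw = 0.01 * k * np.array([1.0, 1.0, 1.0])
        corrected, model = remove_drift(v_raw, np.zeros(3), np.zeros(3), (0, 10))
        np.testing.assert_allclose(model.alpha, 0.01, atol=1e-15)
        np.testing.assert_allclose(model.beta, 0.0, atol=1e-15)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-12)

    def test_driftfree_input_unchanged(self):
        v = np.tile([0.5, -0.2, 0.1], (20, 1))
        corrected, model = remove_drift(v, v[0], v[-1], (0, 19))
        np.testing.assert_allclose(model.alpha, 0.0, atol=1e-15)
        np.testing.assert_allclose(model.beta, 0.0, atol=1e-15)
        np.testing.assert_allclose(corrected, v, atol=1e-15)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            remove_drift(np.zeros((1, 3)), np.zeros(3), np.zeros(3), (0, 0))

    @given(
        st.lists(finite, min_size=3, max_size=3),
        st.lists(finite, min_size=3, max_size=3),
        st.lists(finite, min_size=3, max_size=3),
        st.integers(min_value=2, max_value=200),
    )
    @settings(max_examples=100)
    def test_arbitrary_linear_drift_removed_exactly(self, alpha, beta, v_true, m):
        # property: if raw = truth + alpha*k + beta and the update velocities
        # equal the true endpoint velocities, correction recovers truth
        alpha = np.asarray(alpha)
        beta = np.asarray(beta)
        v_true = np.tile(v_true, (m + 1, 1))
        k = np.arange(m + 1)[:, None]
        v_raw = v_true + alpha * k + beta
        corrected, _ = remove_drift(v_raw, v_true[0], v_true[-1], (0, m))
        np.testing.assert_allclose(corrected, v_true, atol=1e-9)

    def test_endpoint_exactness_on_every_segment(self, noiseless_result):
        vel = noiseless_result.velocity
        for i, m in enumerate(vel.ms_idx):
            np.testing.assert_allclose(
                vel.v_corr[m], vel.v_update[i], atol=1e-12
            )

    def test_model_reproduces_endpoint_mismatch(self, noiseless_trial, noiseless_result):
        # recompute each segment's raw integral (the assembled track
        # overwrites shared boundary samples with the next segment's values)
        vel = noiseless_result.velocity
        orient = noiseless_result.orientation
        dt = noiseless_trial.rec.dt
        for i, model in enumerate(vel.models):
            a, b = model.seg
            v_seg = integrate_velocity(orient.a_lin[a : b + 1], dt, vel.v_update[i])
            np.testing.assert_allclose(
                model.beta, v_seg[0] - vel.v_update[i], atol=1e-15
            )
            e_end = model.alpha * (b - a) + model.beta
            np.testing.assert_allclose(
                e_end, v_seg[-1] - vel.v_update[i + 1], atol=1e-12
            )

    def test_accelerometer_bias_drift_mostly_removed(self):
        # constant accel bias integrates to near-linear velocity drift — the
        # model's exact target; gentle gait + 200 Hz keeps the noiseless
        # baseline error small enough to see a >= 10x reduction
        cfg = GaitSimConfig(
            n_strides=10,
            shank_tilt_amplitude_rad=0.25,
            stride_duration_s=1.3,
            fs_hz=200.0,
            accel_bias=(0.1, 0.0, 0.0),
        )
        trial = simulate_walk(cfg)
        res = reconstruct(trial.rec, r=cfg.r_m)
        vel = res.velocity
        sl = slice(int(vel.ms_idx[0]), int(vel.ms_idx[-1]) + 1)
        rms = lambda e: np.sqrt(np.mean(np.sum(e**2, axis=1)))
        err_raw = rms(vel.v_raw[sl] - trial.truth_v[sl])
        err_corr = rms(vel.v_corr[sl] - trial.truth_v[sl])
        assert err_raw / err_corr >= 10.0
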