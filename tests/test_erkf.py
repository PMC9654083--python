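"""Error-state Kalman filter core: process model, measurement models,
batch update, and the strapdown-equivalence conservation property."""

import numpy as np
import pytest

from gaitkf import so3
from gaitkf.erkf import (
    CorrectionToggles,
    FilterDivergence,
    NoiseConfig,
    NominalState,
    batch_update,
    initial_covariance,
    make_joint_axis,
    make_joint_center,
    make_tilt,
    make_zupt,
    predict_covariance,
    predict_state,
    process_jacobian,
    process_noise,
    run_filter,
)

from conftest import random_unit_quaternion

DT = 1.0 / 128.0


def random_state(rng, n=1):
    return NominalState(
        rng.normal(size=(n, 3)),
        rng.normal(size=(n, 3)),
        random_unit_quaternion(rng, n),
    )


def boxplus(x, dx):
    """Inject an error-state vector into a nominal state (local attitude)."""
    out = x.copy()
    for j in range(x.n_imus):
        b = 9 * j
        out.p[j] += dx[b : b + 3]
        out.v[j] += dx[b + 3 : b + 6]
        out.q[j] = so3.quat_multiply(x.q[j], so3.rotvec_to_quat(dx[b + 6 : b + 9]))
    return out


def boxminus(x2, x1):
    """Error-state difference x2 ⊖ x1 under the local attitude convention."""
    out = np.empty(9 * x1.n_imus)
    for j in range(x1.n_imus):
        b = 9 * j
        out[b : b + 3] = x2.p[j] - x1.p[j]
        out[b + 3 : b + 6] = x2.v[j] - x1.v[j]
        out[b + 6 : b + 9] = so3.quat_to_rotvec(
            so3.quat_multiply(so3.quat_conjugate(x1.q[j]), x2.q[j])
        )
    return out


def fd_process_jacobian(x, acc, gyr, dt, eps=1e-6):
    n = 9 * x.n_imus
    J = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = eps
        xp = predict_state(boxplus(x, e), acc, gyr, dt)
        xm = predict_state(boxplus(x, -e), acc, gyr, dt)
        base = predict_state(x, acc, gyr, dt)
        J[:, i] = (boxminus(xp, base) - boxminus(xm, base)) / (2 * eps)
    return J


def fd_measurement_jacobian(event, x, eps=1e-6):
    n = 9 * x.n_imus
    J = np.empty((3, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = eps
        J[:, i] = (event.expected(boxplus(x, e)) - event.expected(boxplus(x, -e))) / (2 * eps)
    return J


# --------------------------------------------------------------------------
# process model
# --------------------------------------------------------------------------


class TestPredictState:
    def test_gravity_cancellation_keeps_stationary(self):
        x = NominalState(np.zeros((1, 3)), np.zeros((1, 3)), [[1, 0, 0, 0]])
        out = predict_state(x, [[0, 0, 9.81]], [[0, 0, 0]], DT)
        np.testing.assert_allclose(out.p, 0.0, atol=1e-15)
        np.testing.assert_allclose(out.v, 0.0, atol=1e-15)
        np.testing.assert_allclose(out.q, x.q)

    def test_constant_velocity_advance(self):
        x = NominalState(np.zeros((1, 3)), [[1.0, 0, 0]], [[1, 0, 0, 0]])
        out = predict_state(x, [[0, 0, 9.81]], [[0, 0, 0]], DT)
        np.testing.assert_allclose(out.p, [[DT, 0, 0]], atol=1e-15)

    def test_constant_rate_heading_advance(self):
        """1 s of constant ω about z advances heading by ‖ω‖ (closed form)."""
        omega = 0.7
        x = NominalState(np.zeros((1, 3)), np.zeros((1, 3)), [[1, 0, 0, 0]])
        for _ in range(128):
            x = predict_state(x, [[0, 0, 9.81]], [[0, 0, omega]], DT)
        yaw = so3.quat_to_rotvec(x.q[0])
        np.testing.assert_allclose(yaw, [0, 0, omega], atol=1e-6)

    def test_rejects_non_finite_sample_with_index(self):
        x = NominalState(np.zeros((2, 3)), np.zeros((2, 3)), [[1, 0, 0, 0], [1, 0, 0, 0]])
        with pytest.raises(ValueError, match="IMU index 1"):
            predict_state(x, [[0, 0, 9.81], [np.nan, 0, 0]], np.zeros((2, 3)), DT)


class TestProcessJacobian:
    def test_zero_input_block(self):
        x = NominalState(np.zeros((1, 3)), np.zeros((1, 3)), [[1, 0, 0, 0]])
        F = process_jacobian(x, np.zeros((1, 3)), np.zeros((1, 3)), DT)
        expect = np.eye(9)
        expect[0:3, 3:6] = DT * np.eye(3)
        np.testing.assert_allclose(F, expect)

    def test_matches_finite_differences(self, rng):
        for _ in range(10):
            x = random_state(rng)
            acc, gyr = rng.normal(size=(1, 3)) * 5, rng.normal(size=(1, 3)) * 2
            F = process_jacobian(x, acc, gyr, DT)
            F_fd = fd_process_jacobian(x, acc, gyr, DT)
            assert np.linalg.norm(F - F_fd) / np.linalg.norm(F_fd) < 1e-5

    def test_seven_imu_block_structure(self, rng):
        x = random_state(rng, n=7)
        F = process_jacobian(x, rng.normal(size=(7, 3)), rng.normal(size=(7, 3)), DT)
        assert F.shape == (63, 63)
        for i in range(7):
            for j in range(7):
                block = F[9 * i : 9 * i + 9, 9 * j : 9 * j + 9]
                if i == j:
                    assert np.abs(block).max() > 0
                else:
                    np.testing.assert_array_equal(block, 0.0)


class TestPredictCovariance:
    def test_zero_p_identity_f_gives_q(self):
        noise = NoiseConfig()
        P = predict_covariance(np.zeros((9, 9)), np.eye(9), noise, DT)
        np.testing.assert_allclose(P, process_noise(noise, DT, 1))

    def test_position_noise_block_is_zero(self):
        Q = process_noise(NoiseConfig(), DT, 2)
        for j in range(2):
            np.testing.assert_array_equal(Q[9 * j : 9 * j + 3, 9 * j : 9 * j + 3], 0.0)

    def test_trace_non_decreasing_under_identity_transition(self, rng):
        A = rng.normal(size=(9, 9))
        P = A @ A.T
        P2 = predict_covariance(P, np.eye(9), NoiseConfig(), DT)
        assert np.trace(P2) >= np.trace(P)

    def test_non_psd_input_warns_and_clamps(self):
        P = -1e-6 * np.eye(9)
        with pytest.warns(RuntimeWarning, match="clamping"):
            out = predict_covariance(P, np.eye(9), NoiseConfig(), DT)
        assert np.linalg.eigvalsh(out).min() >= -1e-12


# --------------------------------------------------------------------------
# measurement models
# --------------------------------------------------------------------------


class TestZupt:
    def test_innovation_is_minus_velocity(self):
        x = NominalState(np.zeros((1, 3)), [[0.3, 0, 0]], [[1, 0, 0, 0]])
        ev = make_zupt(0, NoiseConfig())
        np.testing.assert_allclose(ev.innovation(x), [-0.3, 0, 0])

    def test_tiny_noise_update_zeroes_velocity(self):
        """Scalar-Kalman closed form: K = p/(p+c) → v ← v(1 − K) ≈ 0."""
        noise = NoiseConfig(sigma_zupt=1e-6)
        x = NominalState(np.zeros((1, 3)), [[0.3, -0.1, 0.05]], [[1, 0, 0, 0]])
        P = initial_covariance(noise, 1)
        ev = make_zupt(0, noise)
        x2, _, _ = batch_update(x, P, [ev])
        assert np.linalg.norm(x2.v[0]) < 1e-3

    def test_rejects_non_foot_imu(self):
        with pytest.raises(ValueError, match="non-foot"):
            make_zupt(0, NoiseConfig(), foot_imus=[5, 6])

    def test_jacobian_matches_fd(self, rng):
        x = random_state(rng, n=2)
        ev = make_zupt(1, NoiseConfig())
        np.testing.assert_allclose(ev.jacobian(x), fd_measurement_jacobian(ev, x), atol=1e-6)


class TestTilt:
    def test_aligned_zero_innovation(self):
        x = NominalState(np.zeros((1, 3)), np.zeros((1, 3)), [[1, 0, 0, 0]])
        ev = make_tilt(0, [0, 0, 9.81], NoiseConfig())
        np.testing.assert_allclose(ev.innovation(x), 0.0, atol=1e-12)

    def test_magnitude_gate_suppresses(self):
        assert make_tilt(0, [0, 0, 5.0], NoiseConfig()) is None
        assert make_tilt(0, [0, 0, 14.0], NoiseConfig()) is None
        assert make_tilt(0, [0, 0, 9.0], NoiseConfig()) is not None

    def test_repeated_stills_reduce_tilt_error(self):
        """A 10° roll error shrinks monotonically under repeated tilt
        updates with the true gravity reaction as the measurement."""
        noise = NoiseConfig()
        q_true = so3.quat_identity()
        q_est = so3.rotvec_to_quat([np.deg2rad(10.0), 0.0, 0.0])
        x = NominalState(np.zeros((1, 3)), np.zeros((1, 3)), [q_est])
        P = initial_covariance(NoiseConfig(sigma_th0=np.deg2rad(15.0)), 1)
        a_meas = so3.quat_to_matrix(q_true).T @ np.array([0, 0, 9.81])
        errs = []
        for _ in range(6):
            ev = make_tilt(0, a_meas, noise)
            x, P, _ = batch_update(x, P, [ev])
            errs.append(np.linalg.norm(so3.quat_to_rotvec(x.q[0])))
        assert all(b < a for a, b in zip(errs, errs[1:]))
        assert errs[-1] < np.deg2rad(1.0)

    def test_jacobian_matches_fd(self, rng):
        x = random_state(rng)
        ev = make_tilt(0, so3.quat_to_matrix(x.q[0]).T @ np.array([0, 0, 9.81]), NoiseConfig())
        np.testing.assert_allclose(ev.jacobian(x), fd_measurement_jacobian(ev, x), atol=1e-6)


class TestJointCenter:
    def _consistent_pair(self, rng):
        x = random_state(rng, n=2)
        r1 = rng.normal(size=3) * 0.2
        joint_world = x.p[0] + so3.quat_to_matrix(x.q[0]) @ r1
        r2 = so3.quat_to_matrix(x.q[1]).T @ (joint_world - x.p[1])
        return x, r1, r2

    def test_consistent_poses_zero_innovation(self, rng):
        x, r1, r2 = self._consistent_pair(rng)
        ev = make_joint_center(0, 1, r1, r2, NoiseConfig())
        np.testing.assert_allclose(ev.innovation(x), 0.0, atol=1e-12)

    def test_translation_offset_appears_in_innovation(self, rng):
        x, r1, r2 = self._consistent_pair(rng)
        x.p[1] += [0.0, 0.0, 0.01]
        ev = make_joint_center(0, 1, r1, r2, NoiseConfig())
        np.testing.assert_allclose(ev.innovation(x), [0, 0, 0.01], atol=1e-12)

    def test_rejects_same_imu(self):
        with pytest.raises(ValueError):
            make_joint_center(1, 1, np.zeros(3), np.zeros(3), NoiseConfig())

    def test_jacobian_matches_fd(self, rng):
        for _ in range(5):
            x, r1, r2 = self._consistent_pair(rng)
            ev = make_joint_center(0, 1, r1, r2, NoiseConfig())
            np.testing.assert_allclose(
                ev.jacobian(x), fd_measurement_jacobian(ev, x), atol=1e-6
            )


class TestJointAxis:
    def test_aligned_zero_innovation(self, rng):
        x = random_state(rng, n=2)
        e_world = np.array([0.0, 0.0, 1.0])
        e1 = so3.quat_to_matrix(x.q[0]).T @ e_world
        e2 = so3.quat_to_matrix(x.q[1]).T @ e_world
        ev = make_joint_axis(0, 1, e1, e2, 0.02)
        np.testing.assert_allclose(ev.innovation(x), 0.0, atol=1e-12)

    def test_five_degree_misalignment_chord_length(self, rng):
        """Relative 5° rotation about an axis ⊥ e gives ‖ν‖ = 2 sin 2.5°."""
        x = NominalState(np.zeros((2, 3)), np.zeros((2, 3)), [[1, 0, 0, 0], [1, 0, 0, 0]])
        e1 = np.array([0.0, 0.0, 1.0])
        e2 = so3.rodrigues([np.deg2rad(5.0), 0, 0]).T @ e1
        ev = make_joint_axis(0, 1, e1, e2, 0.02)
        np.testing.assert_allclose(
            np.linalg.norm(ev.innovation(x)), 2 * np.sin(np.deg2rad(2.5)), atol=1e-9
        )

    def test_requires_unit_axes(self):
        with pytest.raises(ValueError, match="unit"):
            make_joint_axis(0, 1, [0, 0, 2.0], [0, 0, 1.0], 0.02)

    def test_jacobian_matches_fd(self, rng):
        x = random_state(rng, n=2)
        e1 = rng.normal(size=3)
        e1 /= np.linalg.norm(e1)
        e2 = rng.normal(size=3)
        e2 /= np.linalg.norm(e2)
        ev = make_joint_axis(0, 1, e1, e2, 0.02)
        np.testing.assert_allclose(ev.jacobian(x), fd_measurement_jacobian(ev, x), atol=1e-6)


# --------------------------------------------------------------------------
# batch update and full loop
# --------------------------------------------------------------------------


class TestBatchUpdate:
    def test_single_zupt_matches_hand_kalman(self):
        """Diagonal-P single-axis case reduces to the scalar Kalman form
        K = p/(p + c), computed by hand."""
        noise = NoiseConfig(sigma_p0=0.02, sigma_v0=0.05, sigma_th0=0.01)
        x = NominalState([[1.0, 2.0, 3.0]], [[0.4, -0.2, 0.1]], [[1, 0, 0, 0]])
        P = initial_covariance(noise, 1)
        ev = make_zupt(0, noise)
        x2, P2, _ = batch_update(x, P, [ev])
        p, c = noise.sigma_v0**2, noise.sigma_zupt**2
        k = p / (p + c)
        np.testing.assert_allclose(x2.v[0], x.v[0] * (1 - k), atol=1e-8)
        np.testing.assert_allclose(x2.p, x.p)  # no position/velocity coupling in P0
        np.testing.assert_allclose(
            P2[3, 3], (1 - k) * p, atol=1e-12
        )

    def test_empty_event_list_is_an_error(self, rng):
        x = random_state(rng)
        with pytest.raises(ValueError, match="pass-through"):
            batch_update(x, np.eye(9), [])

    def test_covariance_stays_symmetric_psd(self, rng):
        noise = NoiseConfig()
        x = random_state(rng, n=2)
        P = initial_covariance(noise, 2)
        for _ in range(200):
            acc, gyr = rng.normal(size=(2, 3)) * 3, rng.normal(size=(2, 3))
            F = process_jacobian(x, acc, gyr, DT)
            P = predict_covariance(P, F, noise, DT)
            x = predict_state(x, acc, gyr, DT)
            events = [make_zupt(0, noise)]
            if rng.random() < 0.5:
                e = rng.normal(size=3)
                events.append(make_joint_axis(0, 1, e / np.linalg.norm(e), [0, 0, 1.0], 0.02))
            x, P, _ = batch_update(x, P, events)
            np.testing.assert_allclose(P, P.T, atol=1e-9)
        assert np.linalg.eigvalsh(P).min() >= -1e-10


class TestRunFilter:
    def test_prediction_only_equals_strapdown_bitwise(self, truth10, imu10):
        """With all corrections disabled the loop IS strapdown integration."""
        acc, gyr = imu10
        n = 200
        res = run_filter(
            acc[:n], gyr[:n], DT, truth10.initial_state(), None, NoiseConfig(),
            toggles=CorrectionToggles.none(),
        )
        x = truth10.initial_state()
        for k in range(1, n):
            x = predict_state(x, acc[k - 1], gyr[k - 1], DT)
        np.testing.assert_array_equal(res.p[-1], x.p)
        np.testing.assert_array_equal(res.v[-1], x.v)
        np.testing.assert_array_equal(res.q[-1], x.q)

    def test_nan_input_raises_divergence_with_step(self, truth10, imu10):
        acc, gyr = imu10
        acc = acc[:100].copy()
        acc[50, 2] = np.nan
        with pytest.raises((FilterDivergence, ValueError)):
            run_filter(
                acc, gyr[:100], DT, truth10.initial_state(), None, NoiseConfig(),
                toggles=CorrectionToggles.none(),
            )
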