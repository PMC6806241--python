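"""Gradient-descent MARG filter: analytic oracles, convergence, drift."""

import numpy as np
import pytest

from quathar.attitude import (
    FilterState,
    ReferenceFields,
    estimate_attitude,
    fuse_step,
    gd_correction,
    gd_objective,
    gyro_propagate,
    triad_attitude,
)
from quathar.attitude import _mag_reference
from quathar.quaternion import (
    euler_to_quat,
    quat_angle,
    quat_from_axis_angle,
    quat_identity,
    quat_multiply,
    quat_normalize,
    quat_to_euler,
    rotate_inverse,
)
from quathar.synthetic import default_profiles, make_orientation_trajectory

from .conftest import random_unit_quaternions


def classic_elementwise_gradient(q, acc, mag):
    """Independent oracle: the published element-wise update equations of
    the gradient-descent MARG filter, transcribed term by term."""
    q0, q1, q2, q3 = q
    ax, ay, az = acc / np.linalg.norm(acc)
    mx, my, mz = mag / np.linalg.norm(mag)
    hx = (mx * q0 * q0 - 2 * q0 * my * q3 + 2 * q0 * mz * q2 + mx * q1 * q1
          + 2 * q1 * my * q2 + 2 * q1 * mz * q3 - mx * q2 * q2 - mx * q3 * q3)
    hy = (2 * q0 * mx * q3 + my * q0 * q0 - 2 * q0 * mz * q1 + 2 * q1 * mx * q2
          - my * q1 * q1 + my * q2 * q2 + 2 * q2 * mz * q3 - my * q3 * q3)
    bx = np.sqrt(hx * hx + hy * hy)
    bz = (2 * mx * (q1 * q3 - q0 * q2) + 2 * my * (q2 * q3 + q0 * q1)
          + mz * (q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3))
    f = np.array([
        2 * (q1 * q3 - q0 * q2) - ax,
        2 * (q0 * q1 + q2 * q3) - ay,
        2 * (0.5 - q1 * q1 - q2 * q2) - az,
        2 * bx * (0.5 - q2 * q2 - q3 * q3) + 2 * bz * (q1 * q3 - q0 * q2) - mx,
        2 * bx * (q1 * q2 - q0 * q3) + 2 * bz * (q0 * q1 + q2 * q3) - my,
        2 * bx * (q0 * q2 + q1 * q3) + 2 * bz * (0.5 - q1 * q1 - q2 * q2) - mz,
    ])
    jac = np.array([
        [-2 * q2, 2 * q3, -2 * q0, 2 * q1],
        [2 * q1, 2 * q0, 2 * q3, 2 * q2],
        [0.0, -4 * q1, -4 * q2, 0.0],
        [-2 * bz * q2, 2 * bz * q3, -4 * bx * q2 - 2 * bz * q0, -4 * bx * q3 + 2 * bz * q1],
        [-2 * bx * q3 + 2 * bz * q1, 2 * bx * q2 + 2 * bz * q0,
         2 * bx * q1 + 2 * bz * q3, -2 * bx * q0 + 2 * bz * q2],
        [2 * bx * q2, 2 * bx * q3 - 4 * bz * q1, 2 * bx * q0 - 4 * bz * q2, 2 * bx * q1],
    ])
    g = jac.T @ f
    return g / np.linalg.norm(g)


def static_sensors(q_true, fields):
    return rotate_inverse(q_true, fields.gravity_n), rotate_inverse(q_true, fields.mag_n)


class TestGyroPropagate:
    def test_zero_rate_leaves_state_unchanged(self, fields):
        st = FilterState(q=euler_to_quat(0.3, 0.2, -0.4), beta=0.0, fields=fields)
        q_before = st.q.copy()
        assert np.allclose(gyro_propagate(st, np.zeros(3)), q_before)

    def test_constant_rate_integrates_to_yaw(self, fields):
        omega, t, dt = 0.5, 4.0, 1e-3
        st = FilterState(q=quat_identity(), dt=dt, fields=fields)
        for _ in range(int(t / dt)):
            st.q = gyro_propagate(st, np.array([0.0, 0.0, omega]))
        yaw = quat_to_euler(st.q)[2]
        assert abs(yaw - omega * t) < 5 * dt

    def test_reconstructs_synthetic_trajectory(self):
        """Noise-free gyro integration tracks ground truth < 0.5° over 60 s."""
        prof = default_profiles()["walking"]
        q, om = make_orientation_trajectory(prof, 60.0, 50.0)
        st = FilterState(q=q[0], beta=0.0, dt=1.0 / 50.0)
        for i in range(1, len(q)):
            st.q = gyro_propagate(st, om[i - 1])
        assert np.degrees(quat_angle(st.q, q[-1])) < 0.5


class TestGradientCorrection:
    def test_zero_objective_and_correction_at_truth(self, rng, fields):
        q = quat_normalize(rng.normal(size=4))
        acc, mag = static_sensors(q, fields)
        assert np.abs(gd_objective(q, acc, mag, fields)).max() < 1e-12
        assert np.allclose(gd_correction(q, acc, mag, fields), 0.0)

    def test_level_attitude_with_pure_gravity_needs_no_correction(self, fields):
        out = gd_correction(quat_identity(), np.array([0.0, 0.0, 9.81]), None, fields)
        assert np.allclose(out, 0.0)

    def test_uninformative_sample_is_signalled(self, fields):
        assert gd_correction(quat_identity(), np.zeros(3), None, fields) is None

    def test_matches_central_difference_of_objective(self, rng, fields):
        """Analytic gradient vs numeric gradient of ½‖f‖², < 1e-6."""
        for _ in range(50):
            q = quat_normalize(rng.normal(size=4))
            q_true = quat_normalize(rng.normal(size=4))
            acc, mag = static_sensors(q_true, fields)
            bref = _mag_reference(q, mag / np.linalg.norm(mag))

            def phi(qq):
                f = gd_objective(qq, acc, mag, fields, mag_ref=bref)
                return 0.5 * float(f @ f)

            h = 1e-6
            num = np.array([
                (phi(q + h * np.eye(4)[k]) - phi(q - h * np.eye(4)[k])) / (2 * h)
                for k in range(4)
            ])
            grad = gd_correction(q, acc, mag, fields)
            assert np.linalg.norm(grad - num / np.linalg.norm(num)) < 1e-6

    def test_matches_published_elementwise_equations(self, rng, fields):
        for _ in range(100):
            q = quat_normalize(rng.normal(size=4))
            acc = rng.normal(size=3)
            mag = rng.normal(size=3)
            mine = gd_correction(q, acc, mag, fields)
            ref = classic_elementwise_gradient(q, acc, mag)
            assert np.linalg.norm(mine - ref) < 1e-12


class TestFuseStep:
    def test_zero_gain_reduces_to_gyro_integration(self, rng, fields):
        q0 = quat_normalize(rng.normal(size=4))
        gyr = rng.normal(size=3)
        acc, mag = rng.normal(size=3), rng.normal(size=3)
        st = FilterState(q=q0.copy(), beta=0.0, fields=fields)
        expected = gyro_propagate(FilterState(q=q0.copy(), fields=fields), gyr)
        fuse_step(st, acc, gyr, mag)
        assert min(np.linalg.norm(st.q - expected), np.linalg.norm(st.q + expected)) < 1e-12

    def test_static_convergence_within_capture_region(self, rng, fields):
        """From a 90° initial error, with the standard large-gain warmup
        second, the filter converges below 1° within 10 s at 50 Hz with
        operational β = 0.1."""
        q_true = quat_normalize(rng.normal(size=4))
        acc, mag = static_sensors(q_true, fields)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        q0 = quat_multiply(q_true, quat_from_axis_angle(axis, np.pi / 2))
        st = FilterState(q=q0, beta=0.1, fields=fields, beta_init=2.5)
        for _ in range(500):
            fuse_step(st, acc, np.zeros(3), mag)
        assert np.degrees(quat_angle(st.q, q_true)) < 1.0

    def test_correction_beats_pure_integration_under_gyro_bias(self, fields):
        """With a biased gyro on a dynamic noise-free stream, β > 0 ends
        closer to truth than β = 0."""
        prof = default_profiles()["walking"]
        q, om = make_orientation_trajectory(prof, 30.0, 50.0)
        bias = np.array([0.01, 0.01, 0.01])
        errs = {}
        for beta in (0.0, 0.1):
            st = FilterState(q=q[0], beta=beta, fields=fields)
            for i in range(len(q)):
                acc = rotate_inverse(q[i], fields.gravity_n)
                mag = rotate_inverse(q[i], fields.mag_n)
                fuse_step(st, acc, om[i] + bias, mag)
            errs[beta] = quat_angle(st.q, q[-1])
        assert errs[0.1] < errs[0.0]

    def test_roll_pitch_converge_without_magnetometer(self, rng, fields):
        """Accelerometer-only: yaw is unobservable but roll/pitch still
        converge below 1° — why full attitude needs the magnetometer."""
        q_true = quat_normalize(rng.normal(size=4))
        acc, _ = static_sensors(q_true, fields)
        st = FilterState(q=quat_identity(), beta=0.2, fields=fields, use_mag=False)
        for _ in range(1500):
            fuse_step(st, acc, np.zeros(3))
        e_true, e_est = quat_to_euler(q_true), quat_to_euler(st.q)
        assert np.degrees(np.abs(e_true[:2] - e_est[:2])).max() < 1.0


class TestEstimateAttitude:
    @pytest.fixture()
    def static_recording(self, fields):
        from quathar.synthetic import (
            ActivityProfile,
            SensorNoiseModel,
            ProtocolScript,
            generate_protocol_dataset,
        )

        script = ProtocolScript("static", (((("standing", 20.0),), 1),))
        return generate_protocol_dataset(
            script, 1, "LB", SensorNoiseModel.noiseless(), seed=0
        )[0]

    def test_output_aligns_with_input(self, static_recording):
        quats, eulers = estimate_attitude(static_recording)
        assert len(quats) == len(static_recording) == len(eulers)

    def test_every_quaternion_is_unit(self, static_recording):
        quats, _ = estimate_attitude(static_recording, q_init_mode="identity")
        assert np.abs(np.linalg.norm(quats, axis=1) - 1.0).max() < 1e-9

    def test_static_stream_settles_to_constant(self, static_recording):
        quats, _ = estimate_attitude(static_recording, q_init_mode="identity")
        tail = quats[-100:]
        assert np.degrees(quat_angle(tail, tail[-1])).max() < 1.0

    def test_agrees_with_elementwise_reference_filter(self, static_recording):
        """Full-stream agreement with an independently transcribed
        element-wise implementation of the same filter: < 0.5° after 5 s
        (in practice machine precision)."""
        beta, dt = 0.1, 1.0 / 50.0
        fields = ReferenceFields()
        quats, _ = estimate_attitude(static_recording, beta=beta, q_init_mode="triad")
        df = static_recording.data
        acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy()
        gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy()
        mag = df[["mag_x", "mag_y", "mag_z"]].to_numpy()
        q = triad_attitude(acc[0], mag[0], fields)
        ref = np.empty_like(quats)
        for i in range(len(acc)):
            grad = classic_elementwise_gradient(q, acc[i], mag[i])
            qdot = 0.5 * quat_multiply(q, np.array([0.0, *gyr[i]])) - beta * grad
            q = quat_normalize(q + qdot * dt)
            ref[i] = q
        err = np.degrees(quat_angle(quats[250:], ref[250:]))
        assert err.max() < 0.5

    def test_tracks_truth_after_convergence(self, static_recording):
        quats, _ = estimate_attitude(static_recording, q_init_mode="triad")
        truth = static_recording.data[["qw", "qx", "qy", "qz"]].to_numpy()
        err = np.degrees(quat_angle(quats[250:], truth[250:]))
        # the static profile's residual sway (~0.05 m/s²) bounds agreement
        assert err.max() < 1.5

    def test_empty_recording_is_rejected(self, static_recording):
        import pandas as pd

        from quathar.synthetic import LabeledRecording

        empty = LabeledRecording(
            1, "LB", static_recording.data.iloc[:0].copy(), 50.0
        )
        with pytest.raises(ValueError, match="empty"):
            estimate_attitude(empty)

    def test_unknown_init_mode_is_rejected(self, static_recording):
        with pytest.raises(ValueError, match="q_init_mode"):
            estimate_attitude(static_recording, q_init_mode="bogus")


class TestTriad:
    def test_exact_on_noise_free_pair(self, rng, fields):
        q = quat_normalize(rng.normal(size=4))
        acc, mag = static_sensors(q, fields)
        q_est = triad_attitude(acc, mag, fields)
        # quat_angle resolves no finer than ~2e-6 degrees (arccos floor)
        assert np.degrees(quat_angle(q_est, q)) < 1e-4
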