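"""Gradient-descent inertial/magnetic attitude estimation.

The estimator fuses two information sources each 50 Hz tick:

1. **Gyroscope integration** — the attitude kinematic equation
   ``q̇ = ½ q ⊗ (0, ω)`` propagated with one explicit-Euler step, accurate in
   the short term but subject to drift from integration error and gyro bias.
2. **Accelerometer/magnetometer correction** — the normalized gradient of
   the Wahba-style alignment objective between the measured field directions
   and the Earth-frame references (gravity and magnetic field), stepped with
   a single scalar gain ``beta`` (rad/s).

This is the classic gradient-descent MARG fusion scheme with magnetic
distortion compensation (the measured field is mapped to the Earth frame and
its horizontal components collapsed into a single-component reference
``(bx, 0, bz)``, so only the magnetic dip angle constrains the estimate) and
optional integral gyroscope-bias compensation with gain ``zeta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quaternion import (
    quat_canonical,
    quat_identity,
    quat_multiply,
    quat_normalize,
    quat_to_euler,
    quat_to_matrix,
    rotate,
)

__all__ = [
    "ReferenceFields",
    "FilterState",
    "gyro_propagate",
    "gd_objective",
    "gd_correction",
    "fuse_step",
    "estimate_attitude",
    "triad_attitude",
]

#: standard gravity, m/s²
G = 9.81


@dataclass(frozen=True)
class ReferenceFields:
    """Earth-frame reference directions seen by the sensors.

    ``gravity_n`` is the gravity vector in the NED Earth frame (down = +z);
    a static, level accelerometer therefore reads ``[0, 0, g]`` in the body
    frame.  ``mag_n`` is the unit Earth magnetic-field direction; any fixed
    unit vector that is not parallel to gravity makes yaw observable.  The
    default has a 60° dip angle, typical of mid-latitudes.
    """

    gravity_n: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, G])
    )
    mag_n: np.ndarray = field(
        default_factory=lambda: np.array([np.cos(np.pi / 3), 0.0, np.sin(np.pi / 3)])
    )

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_n, dtype=float)
        m = np.asarray(self.mag_n, dtype=float)
        if abs(np.linalg.norm(m) - 1.0) > 1e-9:
            raise ValueError("mag_n must be a unit vector")
        if g[2] <= 0:
            raise ValueError("gravity_n must point down (+z) under NED")
        object.__setattr__(self, "gravity_n", g)
        object.__setattr__(self, "mag_n", m)


@dataclass
class FilterState:
    """Mutable state of the fusion filter.

    Parameters
    ----------
    q : ndarray (4,)
        Current body-to-Earth attitude estimate (unit quaternion).
    beta : float
        Fusion gain, rad/s: the magnitude of the gyroscope measurement
        error represented as a quaternion-derivative correction.
    dt : float
        Sample period, s.
    fields : ReferenceFields
        Earth-frame gravity and magnetic references.
    zeta : float
        Integral gain for gyroscope bias drift compensation (default 0:
        disabled).
    use_mag : bool
        If False, run the IMU-only variant (gravity objective only); yaw is
        then unobservable and only roll/pitch converge.
    beta_init : float, optional
        Initialization gain.  The constant-gain filter slews toward truth
        at most ``2·beta`` rad/s, so a distant initial estimate cannot
        settle quickly at an operational gain; the standard remedy is a
        large gain during the first ``warmup`` seconds.  ``None`` (default)
        disables the schedule.
    warmup : float
        Duration of the initialization-gain phase, s.
    """

    q: np.ndarray = field(default_factory=quat_identity)
    beta: float = 0.1
    dt: float = 1.0 / 50.0
    fields: ReferenceFields = field(default_factory=ReferenceFields)
    zeta: float = 0.0
    use_mag: bool = True
    beta_init: float | None = None
    warmup: float = 1.0
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.q = quat_normalize(np.asarray(self.q, dtype=float))


def _dR_dq(q: np.ndarray) -> np.ndarray:
    """Partial derivatives ∂R/∂q_k of the body-to-Earth matrix, shape (4,3,3)."""
    q0, q1, q2, q3 = q
    return 2.0 * np.array(
        [
            [[0, -q3, q2], [q3, 0, -q1], [-q2, q1, 0]],
            [[0, q2, q3], [q2, -2 * q1, -q0], [q3, q0, -2 * q1]],
            [[-2 * q2, q1, q0], [q1, 0, q3], [-q0, q3, -2 * q2]],
            [[-2 * q3, -q0, q1], [q0, -2 * q3, q2], [q1, q2, 0]],
        ],
        dtype=float,
    )


def _mag_reference(q: np.ndarray, mag_unit: np.ndarray) -> np.ndarray:
    """Distortion-compensated Earth-frame magnetic reference (bx, 0, bz).

    The measured field is rotated into the Earth frame with the current
    estimate and its horizontal component collapsed onto the x axis, so
    static disturbances of the horizontal field cannot tilt the estimate.
    """
    h = rotate(q, mag_unit)
    return np.array([np.hypot(h[0], h[1]), 0.0, h[2]])


def gd_objective(
    q: np.ndarray,
    acc: np.ndarray,
    mag: np.ndarray | None,
    fields: ReferenceFields,
    mag_ref: np.ndarray | None = None,
) -> np.ndarray:
    """Alignment error vector f(q): predicted minus measured field directions.

    Returns a 3-vector (gravity only) or 6-vector (gravity + magnetic).
    ``mag_ref`` fixes the Earth-frame magnetic reference; by default it is
    recomputed from the measurement (distortion compensation).
    """
    rt = quat_to_matrix(q).T
    g_hat = fields.gravity_n / np.linalg.norm(fields.gravity_n)
    f = rt @ g_hat - acc / np.linalg.norm(acc)
    if mag is not None:
        m_unit = mag / np.linalg.norm(mag)
        if mag_ref is None:
            mag_ref = _mag_reference(q, m_unit)
        b_hat = mag_ref / np.linalg.norm(mag_ref)
        f = np.concatenate([f, rt @ b_hat - m_unit])
    return f


def gd_correction(
    q: np.ndarray,
    acc: np.ndarray,
    mag: np.ndarray | None,
    fields: ReferenceFields,
) -> np.ndarray | None:
    """Normalized gradient of the alignment objective ½‖f(q)‖².

    Returns a unit 4-vector giving the direction of the attitude error as a
    quaternion derivative, the zero vector when the objective is already at
    its minimum, or ``None`` for an uninformative sample (zero-norm
    accelerometer or magnetometer reading), in which case the caller skips
    the correction for that tick.
    """
    acc = np.asarray(acc, dtype=float)
    a_norm = np.linalg.norm(acc)
    if a_norm < 1e-12:
        return None
    m_unit = None
    mag_ref = None
    if mag is not None:
        mag = np.asarray(mag, dtype=float)
        m_norm = np.linalg.norm(mag)
        if m_norm < 1e-12:
            return None
        m_unit = mag / m_norm
        mag_ref = _mag_reference(q, m_unit)
        b_hat = mag_ref / np.linalg.norm(mag_ref)

    g_hat = fields.gravity_n / np.linalg.norm(fields.gravity_n)
    dr = _dR_dq(q)
    f = gd_objective(q, acc, mag, fields, mag_ref=mag_ref)
    # Jacobian rows: ∂(Rᵀ r)/∂q_k = (∂R/∂q_k)ᵀ r for each reference r
    jg = np.einsum("kji,j->ik", dr, g_hat)  # (3, 4)
    if mag is None:
        jac = jg
    else:
        jm = np.einsum("kji,j->ik", dr, b_hat)
        jac = np.vstack([jg, jm])  # (6, 4)
    grad = jac.T @ f
    n = np.linalg.norm(grad)
    if n < 1e-12:
        return np.zeros(4)
    return grad / n


def gyro_propagate(state: FilterState, gyr: np.ndarray) -> np.ndarray:
    """One explicit-Euler step of ``q̇ = ½ q ⊗ (0, ω)``; returns the new q."""
    gyr = np.asarray(gyr, dtype=float)
    qdot = 0.5 * quat_multiply(state.q, np.array([0.0, *gyr]))
    return quat_normalize(state.q + qdot * state.dt)


def fuse_step(state: FilterState, acc, gyr, mag=None) -> FilterState:
    """Advance the filter by one sample; mutates and returns ``state``.

    ``mag`` is ignored when ``state.use_mag`` is False.
    """
    gyr = np.asarray(gyr, dtype=float)
    mag_in = np.asarray(mag, dtype=float) if (state.use_mag and mag is not None) else None
    grad = gd_correction(state.q, np.asarray(acc, dtype=float), mag_in, state.fields)

    omega = gyr - state.gyro_bias
    if grad is not None and state.zeta > 0.0 and np.any(grad):
        # angular-rate error: 2 q* ⊗ ∇f̂, vector part; integrate into bias
        w_err = 2.0 * quat_multiply(
            np.array([state.q[0], -state.q[1], -state.q[2], -state.q[3]]), grad
        )[1:]
        state.gyro_bias = state.gyro_bias + state.zeta * w_err * state.dt
        omega = gyr - state.gyro_bias

    beta = state.beta
    if state.beta_init is not None and state.elapsed < state.warmup:
        beta = state.beta_init
    state.elapsed += state.dt
    qdot = 0.5 * quat_multiply(state.q, np.array([0.0, *omega]))
    if grad is not None:
        qdot = qdot - beta * grad
    q_new = quat_normalize(state.q + qdot * state.dt)
    if np.dot(q_new, state.q) < 0.0:  # hemisphere continuity
        q_new = -q_new
    state.q = q_new
    return state


def triad_attitude(acc, mag, fields: ReferenceFields) -> np.ndarray:
    """Algebraic single-sample attitude from one acc + mag pair (TRIAD).

    Builds orthonormal triads from the (gravity, magnetic) vector pair in
    both frames and composes the body-to-Earth rotation.  Used to
    initialize the filter without a convergence transient.
    """
    from scipy.spatial.transform import Rotation

    def triad(v1, v2):
        t1 = v1 / np.linalg.norm(v1)
        t2 = np.cross(t1, v2)
        n2 = np.linalg.norm(t2)
        if n2 < 1e-12:
            raise ValueError("reference vectors are parallel; attitude undefined")
        t2 = t2 / n2
        return np.column_stack([t1, t2, np.cross(t1, t2)])

    tn = triad(fields.gravity_n, fields.mag_n)
    tb = triad(np.asarray(acc, dtype=float), np.asarray(mag, dtype=float))
    r = tn @ tb.T  # body-to-Earth
    q = Rotation.from_matrix(r).as_quat(scalar_first=True)
    return quat_canonical(q)


def estimate_attitude(
    rec,
    beta: float = 0.1,
    q_init_mode: str = "triad",
    fields: ReferenceFields | None = None,
    zeta: float = 0.0,
    use_mag: bool = True,
):
    """Run the fusion filter over a labeled recording.

    Parameters
    ----------
    rec : LabeledRecording or pandas.DataFrame
        Must carry ``acc_*``, ``gyr_*``, ``mag_*`` columns and a strictly
        increasing ``time`` column at a fixed rate.
    beta : float
        Fusion gain, rad/s.
    q_init_mode : {"triad", "identity"}
        ``triad`` seeds the filter algebraically from the first
        accelerometer/magnetometer sample; ``identity`` starts at
        ``[1, 0, 0, 0]`` and converges over the first seconds.

    Returns
    -------
    (quats, eulers) : ndarray (N, 4), ndarray (N, 3)
        One attitude per input sample (canonical hemisphere) and the
        corresponding ``[roll, pitch, yaw]`` stream in radians.
    """
    df = getattr(rec, "data", rec)
    if len(df) == 0:
        raise ValueError("empty recording")
    fields = fields or ReferenceFields()
    time = df["time"].to_numpy()
    dt = float(time[1] - time[0]) if len(time) > 1 else 1.0 / 50.0
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy()
    gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy()
    mag = df[["mag_x", "mag_y", "mag_z"]].to_numpy()

    beta_init = None
    if q_init_mode == "identity":
        # identity start can be arbitrarily far from truth: use the
        # standard large-gain warmup to absorb the convergence transient
        q0 = quat_identity()
        beta_init = 2.5
    elif q_init_mode == "triad":
        q0 = triad_attitude(acc[0], mag[0], fields)
    else:
        raise ValueError(f"unknown q_init_mode {q_init_mode!r}")

    state = FilterState(
        q=q0, beta=beta, dt=dt, fields=fields, zeta=zeta, use_mag=use_mag,
        beta_init=beta_init,
    )
    out = np.empty((len(df), 4))
    for i in range(len(df)):
        fuse_step(state, acc[i], gyr[i], mag[i])
        out[i] = state.q
    out = quat_canonical(out)
    return out, quat_to_euler(quat_normalize(out))
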