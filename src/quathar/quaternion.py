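"""Quaternion algebra and Euler-angle conversions.

Conventions used throughout the package (stated once, here):

* Quaternions are scalar-first ``[q0, q1, q2, q3]`` Hamilton quaternions.
* A quaternion ``q`` stores the **body-to-Earth** rotation: for a vector
  ``v_b`` expressed in the sensor (body) frame, ``rotate(q, v_b)`` gives its
  Earth-frame coordinates.  The Earth frame follows the NED (north, east,
  down) convention, so gravity points along +z.
* Euler angles are intrinsic ZYX (yaw about z, then pitch about y, then roll
  about x), i.e. ``R(q) = Rz(yaw) @ Ry(pitch) @ Rx(roll)``.

All functions accept either a single quaternion of shape ``(4,)`` or a batch
of shape ``(N, 4)`` and broadcast accordingly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_multiply",
    "quat_conjugate",
    "quat_normalize",
    "quat_canonical",
    "quat_to_matrix",
    "quat_from_axis_angle",
    "rotate",
    "rotate_inverse",
    "quat_to_euler",
    "euler_to_quat",
    "quat_angle",
    "quat_identity",
]

#: Unit-norm tolerance used when validating quaternion inputs.
UNIT_TOL = 1e-6


def quat_identity() -> np.ndarray:
    """Return the identity quaternion ``[1, 0, 0, 0]``."""
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b``.

    The product composes rotations so that the result rotates by ``b``
    first, then by ``a`` (matrix convention ``R(a ⊗ b) = R(a) @ R(b)``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0, a1, a2, a3 = np.moveaxis(a, -1, 0)
    b0, b1, b2, b3 = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
            a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
            a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
            a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    """Conjugate (inverse for unit quaternions): negate the vector part."""
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] = -out[..., 1:]
    return out


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Scale to unit norm.  Raises on (near-)zero input."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-300):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Flip sign so the scalar part is non-negative (canonical hemisphere)."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sign


def quat_from_axis_angle(axis: np.ndarray, angle: float | np.ndarray) -> np.ndarray:
    """Unit quaternion rotating by ``angle`` (rad) about the unit ``axis``.

    ``angle`` may be an array; the axis is shared across the batch.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    angle = np.asarray(angle, dtype=float)
    half = angle / 2.0
    s = np.sin(half)
    return np.stack(
        [np.cos(half), s * axis[0], s * axis[1], s * axis[2]], axis=-1
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Body-to-Earth rotation matrix ``R(q)``, shape ``(..., 3, 3)``."""
    q = np.asarray(q, dtype=float)
    q0, q1, q2, q3 = np.moveaxis(q, -1, 0)
    r = np.empty(q.shape[:-1] + (3, 3))
    r[..., 0, 0] = 1.0 - 2.0 * (q2 * q2 + q3 * q3)
    r[..., 0, 1] = 2.0 * (q1 * q2 - q0 * q3)
    r[..., 0, 2] = 2.0 * (q1 * q3 + q0 * q2)
    r[..., 1, 0] = 2.0 * (q1 * q2 + q0 * q3)
    r[..., 1, 1] = 1.0 - 2.0 * (q1 * q1 + q3 * q3)
    r[..., 1, 2] = 2.0 * (q2 * q3 - q0 * q1)
    r[..., 2, 0] = 2.0 * (q1 * q3 - q0 * q2)
    r[..., 2, 1] = 2.0 * (q2 * q3 + q0 * q1)
    r[..., 2, 2] = 1.0 - 2.0 * (q1 * q1 + q2 * q2)
    return r


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate body-frame vector(s) ``v`` into the Earth frame: ``R(q) v``."""
    r = quat_to_matrix(q)
    v = np.asarray(v, dtype=float)
    return np.einsum("...ij,...j->...i", r, v)


def rotate_inverse(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate Earth-frame vector(s) ``v`` into the body frame: ``R(q)ᵀ v``."""
    r = quat_to_matrix(q)
    v = np.asarray(v, dtype=float)
    return np.einsum("...ji,...j->...i", r, v)


def _require_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > UNIT_TOL):
        raise ValueError(
            f"expected a unit quaternion (|norm - 1| <= {UNIT_TOL}); got norm {n}"
        )
    return q


def quat_to_euler(q: np.ndarray, *, gimbal_tol: float = 1e-9) -> np.ndarray:
    """Convert unit quaternion(s) to intrinsic-ZYX Euler angles.

    Returns ``[roll, pitch, yaw]`` in radians with roll, yaw in (−π, π] and
    pitch in [−π/2, π/2].

    At the pitch = ±π/2 singularity (gimbal lock) only the combination
    yaw ∓ roll is observable; the fallback fixes ``roll = 0`` and folds the
    remaining freedom into yaw, so the returned triple always reproduces the
    input rotation and is always finite.
    """
    q = _require_unit(q)
    q0, q1, q2, q3 = np.moveaxis(q, -1, 0)
    sinp = 2.0 * (q0 * q2 - q1 * q3)
    sinp_c = np.clip(sinp, -1.0, 1.0)

    roll = np.arctan2(2.0 * (q0 * q1 + q2 * q3), 1.0 - 2.0 * (q1 * q1 + q2 * q2))
    pitch = np.arcsin(sinp_c)
    yaw = np.arctan2(2.0 * (q0 * q3 + q1 * q2), 1.0 - 2.0 * (q2 * q2 + q3 * q3))

    locked = np.abs(sinp) >= 1.0 - gimbal_tol
    if np.any(locked):
        # pitch = +π/2: only yaw − roll observable → roll := 0, yaw = 2 atan2(q3, q0)
        # pitch = −π/2: only yaw + roll observable → roll := 0, yaw = 2 atan2(q1, q0)
        north = locked & (sinp > 0)
        south = locked & (sinp < 0)
        # 2·atan2 ranges over (−2π, 2π]: wrap back into (−π, π]
        yaw = np.where(north, _wrap_pi(2.0 * np.arctan2(q3, q0)), yaw)
        yaw = np.where(south, _wrap_pi(2.0 * np.arctan2(q1, q0)), yaw)
        roll = np.where(locked, 0.0, roll)
    out = np.stack([roll, pitch, yaw], axis=-1)
    # map the −π boundary to +π so the stated half-open ranges hold
    out[..., 0] = np.where(out[..., 0] <= -np.pi, np.pi, out[..., 0])
    out[..., 2] = np.where(out[..., 2] <= -np.pi, np.pi, out[..., 2])
    return out


def _wrap_pi(angle: np.ndarray) -> np.ndarray:
    """Wrap angle(s) into (−π, π]."""
    wrapped = np.mod(np.asarray(angle) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def euler_to_quat(
    roll: float | np.ndarray,
    pitch: float | np.ndarray,
    yaw: float | np.ndarray,
) -> np.ndarray:
    """Unit quaternion for intrinsic-ZYX Euler angles (radians)."""
    roll = np.asarray(roll, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    yaw = np.asarray(yaw, dtype=float)
    cr, sr = np.cos(roll / 2), np.sin(roll / 2)
    cp, sp = np.cos(pitch / 2), np.sin(pitch / 2)
    cy, sy = np.cos(yaw / 2), np.sin(yaw / 2)
    return np.stack(
        [
            cy * cp * cr + sy * sp * sr,
            cy * cp * sr - sy * sp * cr,
            cy * sp * cr + sy * cp * sr,
            sy * cp * cr - cy * sp * sr,
        ],
        axis=-1,
    )


def quat_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation angle (rad, in [0, π]) between two unit quaternions.

    This is the geodesic attitude error: the angle of the relative rotation
    ``a⁻¹ ⊗ b``, insensitive to the sign ambiguity of either operand.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = np.abs(np.sum(a * b, axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))
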