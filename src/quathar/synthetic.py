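"""Synthetic 9-axis inertial/magnetic recordings for scripted activity
protocols.

No public dataset exists for the scripted posture/activity protocols this
package analyses, so training and evaluation data are simulated.  The
generator produces, per subject and body location, the three streams a
wearable inertial/magnetic unit records at 50 Hz — specific force, angular
velocity and magnetic field, all in the sensor (body) frame — together with
per-sample activity labels and the ground-truth orientation used only for
testing.

The signal model is deliberately simple: each activity is a *profile* with a
characteristic base orientation of the worn sensor plus sinusoidal
orientation oscillation and sinusoidal body-frame linear acceleration.
Angular velocity is derived **analytically** from the orientation
trajectory (``ω = 2·vec(q* ⊗ q̇)``), so the gyroscope stream is exactly
consistent with the ground-truth quaternion path; sensor noise is i.i.d.
white Gaussian per axis and the gyroscope carries a constant per-recording
bias.

Two structural properties of the defaults matter for the downstream
experiments:

* stair ascent and descent share identical oscillation/acceleration
  parameters and differ only in the sign of the mean pitch, so their
  acceleration-norm statistics overlap while their attitudes separate —
  the structure that makes quaternion features informative;
* static postures differ in base orientation only, so per-axis
  accelerometer readings separate them while gyroscope readings add
  almost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .attitude import ReferenceFields
from .quaternion import (
    euler_to_quat,
    quat_canonical,
    quat_conjugate,
    quat_multiply,
    quat_normalize,
    rotate_inverse,
)

__all__ = [
    "SensorNoiseModel",
    "ActivityProfile",
    "ProtocolScript",
    "Segment",
    "LabeledRecording",
    "TARGET_CLASSES",
    "LOCATIONS",
    "DEFAULT_PROFILES",
    "default_profiles",
    "protocol_1",
    "protocol_2",
    "protocol_3",
    "protocol_postures_extra",
    "default_protocols",
    "make_orientation_trajectory",
    "synthesize_imu",
    "generate_protocol_dataset",
    "generate_dataset",
    "strip_marker_segments",
]

#: The seven classes the recognition task targets.
TARGET_CLASSES = (
    "standing",
    "sitting",
    "laying",
    "leaning",
    "walking",
    "downstairs",
    "upstairs",
)

#: Recording CSV column order.
RECORDING_COLUMNS = [
    "time",
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
    "label", "marker",
    "qw", "qx", "qy", "qz",
]


@dataclass(frozen=True)
class SensorNoiseModel:
    """White Gaussian sensor noise and gyro bias.

    Units: accelerometer m/s², gyroscope rad/s, magnetometer in units of
    the (normalized) reference field.  ``gyr_bias`` is constant over a
    recording, emulating the slowly varying rate offset of MEMS gyros.
    """

    acc_noise_std: float = 1.5
    gyr_noise_std: float = 0.15
    mag_noise_std: float = 0.02
    gyr_bias: np.ndarray = field(default_factory=lambda: np.full(3, 0.01))
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        if min(self.acc_noise_std, self.gyr_noise_std, self.mag_noise_std) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        object.__setattr__(
            self, "gyr_bias", np.broadcast_to(np.asarray(self.gyr_bias, float), (3,)).copy()
        )

    @classmethod
    def noiseless(cls, sample_rate: float = 50.0) -> "SensorNoiseModel":
        return cls(0.0, 0.0, 0.0, np.zeros(3), sample_rate)


def _deg(x: float) -> float:
    return np.radians(x)


@dataclass(frozen=True)
class ActivityProfile:
    """Signal signature of one activity at one worn location.

    ``osc_amp``/``osc_freq`` give per-axis (x, y, z) sinusoidal orientation
    oscillation about the base orientation (rad, Hz); ``accel_amp``/
    ``accel_freq``/``accel_phase`` give sinusoidal body-frame linear
    acceleration (m/s², Hz, rad).  Static postures carry zero orientation
    oscillation by construction.
    """

    name: str
    base_orientation: np.ndarray
    osc_amp: np.ndarray = field(default_factory=lambda: np.zeros(3))
    osc_freq: np.ndarray = field(default_factory=lambda: np.zeros(3))
    osc_phase: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_amp: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_freq: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_phase: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("osc_amp", "osc_freq", "osc_phase",
                     "accel_amp", "accel_freq", "accel_phase"):
            object.__setattr__(
                self, name, np.broadcast_to(np.asarray(getattr(self, name), float), (3,)).copy()
            )
        q = np.asarray(self.base_orientation, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError(f"base_orientation of {self.name!r} must be a unit quaternion")
        object.__setattr__(self, "base_orientation", q)

    @property
    def is_static(self) -> bool:
        return bool(np.all(self.osc_freq == 0.0))


def default_profiles() -> dict[str, ActivityProfile]:
    """Activity profiles for a lower-back-worn sensor.

    Base orientations give each static posture a distinct gravity
    projection; dynamic activities add oscillation at gait-like rates.
    Stair ascent/descent are identical except for the pitch sign (±15°).
    """
    e = euler_to_quat

    def p(name, base, **kw):
        return ActivityProfile(name, base, **kw)

    # gait oscillation axes are phase shifted (pelvic list peaks at heel
    # strike, axial rotation mid-swing), so the orientation orbit of a
    # dynamic activity never collapses onto its base orientation
    gait_phase = (0.0, np.pi / 2, np.pi / 4)
    # dynamic-activity accelerations reach ~0.8 g at the lower back, so the
    # instantaneous per-axis readings of walking and both stair classes
    # overlap heavily: the ±15° gravity-tilt component (±2.5 m/s²) is
    # swamped by the gait cycle, which is what defeats raw per-sample
    # features on stairs while leaving attitude features informative
    stair_dyn = dict(
        osc_amp=(0.06, 0.08, 0.05),
        osc_freq=(0.7, 1.4, 0.7),
        osc_phase=gait_phase,
        accel_amp=(8.0, 2.0, 6.0),
        accel_freq=(1.4, 0.7, 2.8),
        accel_phase=(0.0, np.pi / 2, np.pi / 4),
    )
    static_accel = dict(
        accel_amp=(0.05, 0.05, 0.05), accel_freq=(0.3, 0.4, 0.5)
    )
    return {
        "standing": p("standing", e(0.0, 0.0, 0.0), **static_accel),
        "sitting": p("sitting", e(0.0, _deg(-50), 0.0), **static_accel),
        "laying": p("laying", e(_deg(-85), 0.0, 0.0), **static_accel),
        "leaning": p("leaning", e(0.0, _deg(30), 0.0), **static_accel),
        "wait": p("wait", e(0.0, 0.0, 0.0), **static_accel),
        "walking": p(
            "walking", e(0.0, _deg(3), 0.0),
            osc_amp=(0.14, 0.06, 0.14), osc_freq=(0.9, 1.8, 0.9),
            osc_phase=gait_phase,
            accel_amp=(8.0, 2.0, 6.0), accel_freq=(1.8, 0.9, 3.6),
            accel_phase=(0.0, np.pi / 2, np.pi / 4),
        ),
        "upstairs": p("upstairs", e(0.0, _deg(18), 0.0), **stair_dyn),
        "downstairs": p("downstairs", e(0.0, _deg(-18), 0.0), **stair_dyn),
        "run": p(
            "run", e(0.0, _deg(5), 0.0),
            osc_amp=(0.10, 0.15, 0.06), osc_freq=(1.3, 2.6, 1.3),
            osc_phase=gait_phase,
            accel_amp=(5.0, 1.5, 8.0), accel_freq=(2.6, 1.3, 5.2),
            accel_phase=(0.0, np.pi / 2, np.pi / 4),
        ),
        "jump": p(
            "jump", e(0.0, 0.0, 0.0),
            osc_amp=(0.05, 0.20, 0.0), osc_freq=(2.0, 2.0, 0.0),
            accel_amp=(1.0, 1.0, 12.0), accel_freq=(2.0, 2.0, 2.0),
        ),
        "jumping jacks": p(
            "jumping jacks", e(0.0, 0.0, 0.0),
            osc_amp=(0.30, 0.05, 0.0), osc_freq=(2.0, 2.0, 0.0),
            accel_amp=(4.0, 1.0, 10.0), accel_freq=(2.0, 2.0, 2.0),
        ),
        "turn": p(
            "turn", e(0.0, 0.0, 0.0),
            osc_amp=(0.0, 0.0, 1.5), osc_freq=(0.0, 0.0, 0.25),
            accel_amp=(0.5, 0.5, 0.5), accel_freq=(1.0, 1.0, 1.0),
        ),
    }


DEFAULT_PROFILES = default_profiles()

#: Worn locations: lower back, left thigh, left foot.  Each maps to a fixed
#: mounting-offset rotation applied to every base orientation and a dynamics
#: scale applied to oscillation/acceleration amplitudes (distal segments
#: move more).
LOCATIONS = {
    "LB": (euler_to_quat(0.0, 0.0, 0.0), 1.0),
    "LT": (euler_to_quat(_deg(5), _deg(10), 0.0), 1.3),
    "LF": (euler_to_quat(_deg(10), _deg(20), 0.0), 1.6),
}


@dataclass(frozen=True)
class Segment:
    """One expanded protocol segment."""

    activity: str
    duration: float
    marker: bool

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment durations must be > 0")


@dataclass(frozen=True)
class ProtocolScript:
    """A scripted sequence of activities: blocks of (activity, duration)
    entries, each block repeated a fixed number of times.

    Activities outside the seven target classes (jumping jacks, wait, turn,
    run, jump) are *marker* segments: they exist for labeling/segmentation
    and are stripped before classification.
    """

    name: str
    blocks: tuple[tuple[tuple[tuple[str, float], ...], int], ...]

    def expand(self, time_scale: float = 1.0) -> list[Segment]:
        """Flatten blocks × repeats into an ordered segment list."""
        if time_scale <= 0:
            raise ValueError("time_scale must be > 0")
        out: list[Segment] = []
        for entries, repeats in self.blocks:
            for _ in range(repeats):
                for activity, duration in entries:
                    out.append(
                        Segment(activity, duration * time_scale, activity not in TARGET_CLASSES)
                    )
        return out

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.expand())


def protocol_1() -> ProtocolScript:
    """Postures protocol: sitting/standing then laying/standing loops,
    bracketed by jumping-jack markers and waits."""
    loop_a = (
        ("jumping jacks", 4.0), ("sitting", 60.0),
        ("jumping jacks", 4.0), ("standing", 60.0),
        ("jumping jacks", 4.0), ("wait", 30.0),
    )
    loop_b = (
        ("jumping jacks", 4.0), ("laying", 60.0),
        ("jumping jacks", 4.0), ("standing", 60.0),
        ("jumping jacks", 4.0), ("wait", 30.0),
    )
    return ProtocolScript("protocol-1", ((loop_a, 5), (loop_b, 5)))


def protocol_2() -> ProtocolScript:
    """Gait protocol: walk / run / jump separated by waits."""
    loop = (
        ("wait", 30.0), ("walking", 60.0),
        ("wait", 30.0), ("run", 60.0),
        ("wait", 30.0), ("jump", 10.0),
    )
    return ProtocolScript("protocol-2", ((loop, 5),))


def protocol_3() -> ProtocolScript:
    """Stairs protocol: 11 steps up (≈8 s), turn and wait, 11 steps down."""
    loop = (
        ("wait", 30.0), ("upstairs", 8.0),
        ("turn", 2.0), ("wait", 28.0),
        ("downstairs", 8.0), ("turn", 2.0),
    )
    return ProtocolScript("protocol-3", ((loop, 5),))


def protocol_postures_extra() -> ProtocolScript:
    """Leaning segments (the seventh class is not covered by the three main
    scripts, so it gets its own short protocol)."""
    loop = (
        ("jumping jacks", 4.0), ("leaning", 60.0),
        ("jumping jacks", 4.0), ("wait", 30.0),
    )
    return ProtocolScript("protocol-leaning", ((loop, 5),))


def default_protocols() -> list[ProtocolScript]:
    return [protocol_1(), protocol_2(), protocol_3(), protocol_postures_extra()]


@dataclass
class LabeledRecording:
    """One subject × location sensor stream with per-sample labels.

    ``data`` follows :data:`RECORDING_COLUMNS`: time (s), body-frame acc
    (m/s²) / gyr (rad/s) / mag (normalized field), activity ``label``,
    boolean ``marker`` flag and the ground-truth quaternion (testing only).
    """

    subject: int
    location: str
    data: pd.DataFrame
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        missing = [c for c in RECORDING_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"recording missing column {missing[0]!r}")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# orientation trajectories
# ---------------------------------------------------------------------------

_AXES = np.eye(3)


def _factor(axis: np.ndarray, alpha: np.ndarray, alpha_dot: np.ndarray):
    """Fixed-axis rotation factor exp(α n̂ / 2) and its time derivative."""
    half = alpha / 2.0
    c, s = np.cos(half), np.sin(half)
    f = np.stack([c, s * axis[0], s * axis[1], s * axis[2]], axis=-1)
    fdot = (alpha_dot / 2.0)[:, None] * np.stack(
        [-s, c * axis[0], c * axis[1], c * axis[2]], axis=-1
    )
    return f, fdot


def _chain(factors):
    """Compose factor quaternions and apply the product rule for q̇."""
    q = factors[0][0]
    for f, _ in factors[1:]:
        q = quat_multiply(q, f)
    qdot = np.zeros_like(q)
    n = len(factors)
    for i in range(n):
        term = factors[0][1] if i == 0 else factors[0][0]
        for j in range(1, n):
            term = quat_multiply(term, factors[j][1] if j == i else factors[j][0])
        qdot = qdot + term
    return q, qdot


def _profile_factors(profile: ActivityProfile, t: np.ndarray, envelope=None):
    """Oscillation factors about the body x, y, z axes, angle a·sin(2πft+φ).

    ``envelope`` is an optional ``(s, sdot)`` amplitude ramp (used at
    segment entry so oscillation with a nonzero phase offset still starts
    from the incoming orientation); both parts enter the analytic angle
    rate via the product rule.
    """
    out = []
    for k in range(3):
        a, f, ph = profile.osc_amp[k], profile.osc_freq[k], profile.osc_phase[k]
        w = 2.0 * np.pi * f
        sin, cos = np.sin(w * t + ph), np.cos(w * t + ph)
        if envelope is None:
            alpha = a * sin
            alpha_dot = a * w * cos
        else:
            s, sdot = envelope
            alpha = a * sin * s
            alpha_dot = a * (w * cos * s + sin * sdot)
        out.append(_factor(_AXES[k], alpha, alpha_dot))
    return out


def make_orientation_trajectory(
    profile: ActivityProfile,
    duration: float,
    rate: float = 50.0,
    seed: int | None = None,
):
    """Ground-truth orientation path and its exact body-frame angular rate.

    The path is ``q(t) = q_base ⊗ Rx(αx(t)) ⊗ Ry(αy(t)) ⊗ Rz(αz(t))`` with
    ``αk(t) = amp_k·sin(2π f_k t)``; the returned angular velocity is the
    analytic ``ω(t) = 2·vec(q*(t) ⊗ q̇(t))``, so integrating ω reconstructs
    the quaternion path.  ``seed`` is accepted for interface symmetry; the
    trajectory itself is deterministic (randomness enters via per-subject
    profile jitter and sensor noise, not here).

    Returns ``(quats, omega)`` with shapes (N, 4) and (N, 3),
    N = round(duration·rate).
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be > 0")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    base = np.asarray(profile.base_orientation, dtype=float)
    if abs(np.linalg.norm(base) - 1.0) > 1e-6:
        raise ValueError("base_orientation must be a unit quaternion")
    const = np.broadcast_to(base, (n, 4))
    factors = [(const, np.zeros((n, 4)))] + _profile_factors(profile, t)
    q, qdot = _chain(factors)
    omega = 2.0 * quat_multiply(quat_conjugate(q), qdot)[:, 1:]
    return quat_normalize(q), omega


def _segment_trajectory(
    profile: ActivityProfile,
    q_start: np.ndarray,
    n: int,
    rate: float,
    transition: float,
):
    """Trajectory for one protocol segment, entered smoothly from ``q_start``.

    A fixed-axis rotation from ``q_start`` to the segment's base orientation
    is ramped with a smoothstep over ``transition`` seconds (zero angular
    rate at both ends), while the profile oscillation runs on top; both
    parts contribute analytically to ω, so the gyro stream stays consistent
    with the quaternion path across segment boundaries.
    """
    t = np.arange(n) / rate
    base = profile.base_orientation
    tau = max(min(transition, n / rate), 2.0 / rate)
    u = np.clip(t / tau, 0.0, 1.0)
    s = u * u * (3.0 - 2.0 * u)  # smoothstep: s'(0) = s'(1) = 0
    sdot = np.where(u < 1.0, 6.0 * u * (1.0 - u) / tau, 0.0)
    d = quat_multiply(quat_conjugate(q_start), base)
    if d[0] < 0:
        d = -d
    theta = 2.0 * np.arccos(np.clip(d[0], -1.0, 1.0))
    if theta < 1e-12:
        const = np.broadcast_to(base, (n, 4))
        trans = (const.copy(), np.zeros((n, 4)))
    else:
        axis = d[1:] / np.linalg.norm(d[1:])
        f, fdot = _factor(axis, theta * s, theta * sdot)
        qs = np.broadcast_to(q_start, (n, 4))
        trans = (quat_multiply(qs, f), quat_multiply(qs, fdot))
    factors = [trans] + _profile_factors(profile, t, envelope=(s, sdot))
    q, qdot = _chain(factors)
    omega = 2.0 * quat_multiply(quat_conjugate(q), qdot)[:, 1:]
    return quat_normalize(q), omega


def _linear_accel(profile: ActivityProfile, t: np.ndarray) -> np.ndarray:
    w = 2.0 * np.pi * profile.accel_freq
    return profile.accel_amp * np.sin(w * t[:, None] + profile.accel_phase)


# ---------------------------------------------------------------------------
# sensor synthesis
# ---------------------------------------------------------------------------

def synthesize_imu(
    quats: np.ndarray,
    omega: np.ndarray,
    fields: ReferenceFields,
    noise: SensorNoiseModel,
    linear_accel: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
):
    """Project reference fields into the body frame and add sensor errors.

    ``acc[t] = R(q_t)ᵀ·gravity_n + linear_accel[t] + δ_a``;
    ``gyr[t] = ω[t] + gyr_bias + δ_g``;
    ``mag[t] = R(q_t)ᵀ·mag_n + δ_m`` — each δ i.i.d. zero-mean Gaussian.
    """
    quats = np.asarray(quats, dtype=float)
    omega = np.asarray(omega, dtype=float)
    n = len(quats)
    if linear_accel is None:
        linear_accel = np.zeros((n, 3))
    linear_accel = np.asarray(linear_accel, dtype=float)
    if len(linear_accel) != n or len(omega) != n:
        raise ValueError("trajectory, omega and linear_accel must have equal length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    acc = rotate_inverse(quats, fields.gravity_n) + linear_accel
    gyr = omega + noise.gyr_bias
    mag = rotate_inverse(quats, fields.mag_n)
    if noise.acc_noise_std > 0:
        acc = acc + rng.normal(0.0, noise.acc_noise_std, (n, 3))
    if noise.gyr_noise_std > 0:
        gyr = gyr + rng.normal(0.0, noise.gyr_noise_std, (n, 3))
    if noise.mag_noise_std > 0:
        mag = mag + rng.normal(0.0, noise.mag_noise_std, (n, 3))
    return acc, gyr, mag


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

#: multiplicative jitter on amplitudes/frequencies per subject
SUBJECT_JITTER_REL = 0.10
#: additive jitter on base-orientation Euler angles per subject, rad
SUBJECT_JITTER_ANGLE = _deg(5)

#: activities whose *dynamics* jitter is drawn jointly per subject (a
#: subject climbs and descends stairs with the same gait tempo, which also
#: preserves the up/down acceleration-norm overlap under jitter)
_JITTER_GROUPS = {"upstairs": "stairs", "downstairs": "stairs"}


def _jitter_profile(
    profile: ActivityProfile, rng_dyn: np.random.Generator, rng_base: np.random.Generator
) -> ActivityProfile:
    scale = 1.0 + rng_dyn.uniform(-SUBJECT_JITTER_REL, SUBJECT_JITTER_REL, 4)
    d_euler = rng_base.uniform(-SUBJECT_JITTER_ANGLE, SUBJECT_JITTER_ANGLE, 3)
    base = quat_multiply(profile.base_orientation, euler_to_quat(*d_euler))
    return replace(
        profile,
        base_orientation=quat_normalize(base),
        osc_amp=profile.osc_amp * scale[0],
        osc_freq=profile.osc_freq * scale[1],
        accel_amp=profile.accel_amp * scale[2],
        accel_freq=profile.accel_freq * scale[3],
    )


def _locate_profile(profile: ActivityProfile, location: str) -> ActivityProfile:
    offset, dyn_scale = LOCATIONS[location]
    return replace(
        profile,
        base_orientation=quat_normalize(quat_multiply(offset, profile.base_orientation)),
        osc_amp=profile.osc_amp * dyn_scale,
        accel_amp=profile.accel_amp * dyn_scale,
    )


def subject_profiles(
    profiles: dict[str, ActivityProfile],
    location: str,
    root_seed: int,
    subject: int,
) -> dict[str, ActivityProfile]:
    """Location-adjusted profiles with per-subject seeded jitter."""
    if location not in LOCATIONS:
        raise ValueError(f"unknown location {location!r}; expected one of {sorted(LOCATIONS)}")
    out = {}
    for name, prof in profiles.items():
        group = _JITTER_GROUPS.get(name, name)
        rng_dyn = substream(root_seed, "subject", subject, "dyn", group)
        rng_base = substream(root_seed, "subject", subject, "base", name)
        out[name] = _jitter_profile(_locate_profile(prof, location), rng_dyn, rng_base)
    return out


def generate_protocol_dataset(
    protocol: ProtocolScript,
    subjects: int,
    location: str = "LB",
    noise: SensorNoiseModel | None = None,
    seed: int = 0,
    time_scale: float = 1.0,
    profiles: dict[str, ActivityProfile] | None = None,
    fields: ReferenceFields | None = None,
    transition: float = 0.5,
) -> list[LabeledRecording]:
    """Simulate one recording per subject for a scripted protocol.

    Each subject gets seeded multiplicative jitter (±10%) on profile
    amplitudes/frequencies and additive jitter (±5° per Euler axis) on base
    orientations, so leave-one-subject-out validation is non-trivial.
    ``time_scale`` shortens every segment proportionally for desk-scale
    experiments.
    """
    if subjects < 1:
        raise ValueError("subjects must be >= 1")
    noise = noise or SensorNoiseModel()
    fields = fields or ReferenceFields()
    profiles = profiles or DEFAULT_PROFILES
    rate = noise.sample_rate
    # transitions are part of the scripted timeline, so they compress with it
    transition = transition * time_scale
    segments = protocol.expand(time_scale)
    recordings = []
    for subject in range(1, subjects + 1):
        profs = subject_profiles(profiles, location, seed, subject)
        qs, oms, lins, labels, markers = [], [], [], [], []
        q_prev = None
        t_off = 0.0
        for seg in segments:
            prof = profs.get(seg.activity)
            if prof is None:
                raise KeyError(f"no activity profile named {seg.activity!r}")
            n = int(round(seg.duration * rate))
            if n == 0:
                continue
            start = prof.base_orientation if q_prev is None else q_prev
            q, om = _segment_trajectory(prof, start, n, rate, transition)
            t_local = np.arange(n) / rate
            qs.append(q)
            oms.append(om)
            lins.append(_linear_accel(prof, t_local))
            labels.extend([seg.activity] * n)
            markers.extend([seg.marker] * n)
            q_prev = q[-1]
            t_off += seg.duration
        quats = np.concatenate(qs)
        omega = np.concatenate(oms)
        lin = np.concatenate(lins)
        noise_rng = substream(seed, "subject", subject, "noise", protocol.name)
        acc, gyr, mag = synthesize_imu(quats, omega, fields, noise, lin, noise_rng)
        time = np.arange(len(quats)) / rate
        qc = quat_canonical(quats)
        df = pd.DataFrame(
            {
                "time": time,
                "acc_x": acc[:, 0], "acc_y": acc[:, 1], "acc_z": acc[:, 2],
                "gyr_x": gyr[:, 0], "gyr_y": gyr[:, 1], "gyr_z": gyr[:, 2],
                "mag_x": mag[:, 0], "mag_y": mag[:, 1], "mag_z": mag[:, 2],
                "label": labels,
                "marker": np.asarray(markers, dtype=bool),
                "qw": qc[:, 0], "qx": qc[:, 1], "qy": qc[:, 2], "qz": qc[:, 3],
            }
        )
        recordings.append(LabeledRecording(subject, location, df, rate))
    return recordings


def generate_dataset(
    subjects: int = 8,
    location: str = "LB",
    protocols: list[ProtocolScript] | None = None,
    noise: SensorNoiseModel | None = None,
    seed: int = 0,
    time_scale: float = 1.0,
    **kw,
) -> list[LabeledRecording]:
    """All protocols concatenated into one recording per subject."""
    protocols = protocols or default_protocols()
    per_protocol = [
        generate_protocol_dataset(
            p, subjects, location, noise, seed, time_scale, **kw
        )
        for p in protocols
    ]
    out = []
    rate = (noise or SensorNoiseModel()).sample_rate
    for s in range(subjects):
        parts = []
        t_off = 0.0
        for recs in per_protocol:
            df = recs[s].data.copy()
            df["time"] = df["time"] + t_off
            t_off = df["time"].iloc[-1] + 1.0 / rate
            parts.append(df)
        data = pd.concat(parts, ignore_index=True)
        out.append(LabeledRecording(s + 1, location, data, rate))
    return out


def strip_marker_segments(rec: LabeledRecording) -> LabeledRecording:
    """Drop marker samples (transition/synchronization activities).

    The returned recording keeps original sample order and labels; only the
    seven target classes remain.
    """
    if "marker" not in rec.data.columns:
        raise ValueError("recording has no 'marker' column")
    data = rec.data.loc[~rec.data["marker"].astype(bool)].reset_index(drop=True)
    leftover = set(data["label"].unique()) - set(TARGET_CLASSES)
    if leftover:
        raise ValueError(f"non-target labels remain after stripping: {sorted(leftover)}")
    return LabeledRecording(rec.subject, rec.location, data, rec.sample_rate)
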