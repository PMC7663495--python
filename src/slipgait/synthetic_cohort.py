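"""Synthetic multi-subject treadmill cohort.

The experimental dataset this pipeline targets (sacral IMU + force
plates + motion capture on a split-belt treadmill) is not publicly
available, so every downstream stage is exercised on a virtual cohort
with the same statistical structure: subjects drawn from the reported
anthropometric distributions, walking bouts generated by the 3D SLIP
model at 0.7/1.0/1.3/1.6 m/s, sacral-IMU acceleration with sensor
noise, a small constant mounting tilt and a heel-strike transient, and
ground-truth per-leg GRF, CoP and quasi-static joint torques.

The joint-torque ground truth is deliberately a *stand-in*: real
inverse dynamics needs marker-based segment kinematics.  Here the leg
is a massless geometric chain (hip offset from the CoM, knee from a
two-link inverse-kinematics construction, ankle above the foot anchor)
and the torque at each joint is the moment of the GRF about that joint
projected on the laboratory axes.  It preserves the torque-GRF-CoP
geometry a network must learn, not the inertial content of real
inverse dynamics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import slip3d
from .slip3d import (
    ComTrajectory,
    PeriodicGait,
    SimulationFailure,
    SlipParameters,
    find_periodic_gait,
    simulate_stride,
)

__all__ = [
    "SubjectAnthropometrics",
    "CohortConfig",
    "SyntheticTrial",
    "Cohort",
    "sample_subject",
    "subject_slip_parameters",
    "imu_from_com",
    "build_leg_chain",
    "quasi_static_torques",
    "generate_trial",
    "generate_cohort",
    "TRUTH_RATE",
]

logger = logging.getLogger(__name__)

TRUTH_RATE = 100.0  # Hz of the stored ground-truth series
_SIM_RATE = 500.0  # Hz of the internal simulation sampling

# cohort statistics of the emulated participant pool
_HEIGHT_MEAN, _HEIGHT_SD = 1.667, 0.078  # m
_MASS_MEAN, _MASS_SD = 60.1, 8.9  # kg
_FOOT_RATIO = 0.152  # foot length / height
_LEG_RATIO = 0.53  # leg length / height


@dataclass(frozen=True)
class SubjectAnthropometrics:
    """Anthropometrics of one virtual subject."""

    subject_id: str
    height: float  # m
    mass: float  # kg
    foot_length: float  # m
    leg_length: float  # m

    def __post_init__(self) -> None:
        for name in ("height", "mass", "foot_length", "leg_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ratio = self.foot_length / self.height
        if not (0.8 * _FOOT_RATIO <= ratio <= 1.2 * _FOOT_RATIO):
            raise ValueError("foot length outside the human range for this height")

    @property
    def body_weight(self) -> float:
        return self.mass * 9.81


@dataclass(frozen=True)
class CohortConfig:
    """The stated world of the virtual treadmill experiment."""

    n_subjects: int = 8
    speeds: tuple = (0.7, 1.0, 1.3, 1.6)  # m/s
    strides_per_speed: int = 10  # stance phases kept per trial
    imu_rate: float = 148.0  # Hz
    noise_sd: float = 0.08  # m/s^2 white noise, horizontal channels
    noise_sd_vertical: float = 0.35  # m/s^2 white noise, vertical channel
    frame_tilt_sd: float = 0.01  # rad, per-trial roll misalignment (leaks g into ML)
    frame_pitch_sd: float = 0.04  # rad, per-trial sagittal misalignment (leaks g into AP)
    hs_transient_amp: float = 2.5  # m/s^2 heel-strike shock at the sacrum
    hs_transient_width: float = 0.04  # s
    hs_transient_dropout: float = 0.55  # probability a shod step absorbs the shock
    hs_transient_latency: float = -0.03  # s, mean shock lead vs force-defined HS
    hs_transient_jitter: float = 0.045  # s, per-step SD of the shock timing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 5:
            raise ValueError("need at least 5 subjects for a meaningful LOO")
        if self.strides_per_speed < 3:
            raise ValueError("need at least 3 strides per speed")

    def noise_free(self, **overrides) -> "CohortConfig":
        """Copy of this configuration with every disturbance disabled."""
        import dataclasses

        clean = dict(
            noise_sd=0.0,
            noise_sd_vertical=0.0,
            frame_tilt_sd=0.0,
            frame_pitch_sd=0.0,
            hs_transient_dropout=0.0,
            hs_transient_latency=0.0,
            hs_transient_jitter=0.0,
        )
        clean.update(overrides)
        return dataclasses.replace(self, **clean)


@dataclass
class SyntheticTrial:
    """One subject x speed walking bout with ground truth."""

    subject: SubjectAnthropometrics
    nominal_speed: float
    true_speed: float
    params: SlipParameters
    imu_time: np.ndarray  # (n,) s
    imu_acc: np.ndarray  # (n, 3) m/s^2, ML/AP/vertical, gravity-compensated
    truth_time: np.ndarray  # (m,) s at TRUTH_RATE
    com_position: np.ndarray  # (m, 3)
    com_velocity: np.ndarray
    com_acceleration: np.ndarray
    grf: dict = field(default_factory=dict)  # side -> (m, 3)
    cop: dict = field(default_factory=dict)  # side -> (m, 2)
    torques: dict = field(default_factory=dict)  # side -> (m, 7)
    events: list = field(default_factory=list)  # (t, "HS"|"TO", side)
    stance_truth: list = field(default_factory=list)  # (hs, to, side) kept stances

    def event_times(self, kind: str) -> np.ndarray:
        return np.array([t for t, k, _ in self.events if k == kind])

    def truth_curves(self, side: str, t_grid: np.ndarray) -> dict:
        """Ground-truth kinetics of one leg interpolated on ``t_grid``.

        CoP is returned as the excursion from its value at the first
        grid point (the detected heel strike), matching how per-stance
        CoP trajectories are expressed downstream.
        """
        grf = np.column_stack(
            [np.interp(t_grid, self.truth_time, self.grf[side][:, j]) for j in range(3)]
        )
        cop = np.column_stack(
            [np.interp(t_grid, self.truth_time, self.cop[side][:, j]) for j in range(2)]
        )
        cop = cop - cop[0]
        tor = np.column_stack(
            [
                np.interp(t_grid, self.truth_time, self.torques[side][:, j])
                for j in range(7)
            ]
        )
        return {"grf": grf, "cop": cop, "torques": tor}


@dataclass
class Cohort:
    """A generated virtual cohort."""

    config: CohortConfig
    subjects: list
    trials: list
    skipped: list = field(default_factory=list)  # (subject_id, speed, reason)

    def by_subject(self, subject_id: str):
        return [t for t in self.trials if t.subject.subject_id == subject_id]


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------


def sample_subject(
    rng: np.random.Generator, subject_id: str = "S00"
) -> SubjectAnthropometrics:
    """Draw one subject from the cohort's anthropometric distributions.

    Out-of-range draws (beyond 2.5 SD or outside human segment ratios)
    are resampled rather than clipped, so the cohort means match the
    nominal distributions.
    """
    while True:
        h = rng.normal(_HEIGHT_MEAN, _HEIGHT_SD)
        m = rng.normal(_MASS_MEAN, _MASS_SD)
        if abs(h - _HEIGHT_MEAN) > 2.5 * _HEIGHT_SD:
            continue
        if abs(m - _MASS_MEAN) > 2.5 * _MASS_SD:
            continue
        foot = _FOOT_RATIO * h * (1.0 + rng.normal(0.0, 0.05))
        # leg length: resample only the segment-ratio noise until the leg
        # stays inside the walking branch's feasible speed range (0.7 and
        # 1.6 m/s must both admit a periodic gait); the height draw is
        # kept so the cohort height statistics are unbiased
        for _ in range(100):
            leg = _LEG_RATIO * h * (1.0 + rng.normal(0.0, 0.03))
            if 0.77 <= leg <= 0.945:
                break
        else:
            continue
        try:
            return SubjectAnthropometrics(
                subject_id=subject_id,
                height=h,
                mass=m,
                foot_length=foot,
                leg_length=leg,
            )
        except ValueError:
            continue


def subject_slip_parameters(
    subject: SubjectAnthropometrics, speed: float
) -> SlipParameters:
    """SLIP parameters of a subject at one nominal speed."""
    return slip3d.default_parameters(
        mass=subject.mass,
        leg_length=subject.leg_length,
        foot_length=subject.foot_length,
        speed=speed,
    )


# ---------------------------------------------------------------------------
# IMU synthesis
# ---------------------------------------------------------------------------


def _tilt_matrix(tilt_x: float, tilt_y: float) -> np.ndarray:
    """Small constant sensor mounting tilt about the ML and AP axes."""
    cx, sx = math.cos(tilt_x), math.sin(tilt_x)
    cy, sy = math.cos(tilt_y), math.sin(tilt_y)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return Rx @ Ry


def imu_from_com(
    trajectory: ComTrajectory,
    imu_rate: float,
    noise_sd=0.0,
    frame_tilt: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    hs_transient_amp: float = 0.0,
    hs_transient_width: float = 0.04,
    hs_transient_dropout: float = 0.0,
    hs_transient_latency: float = 0.0,
    hs_transient_jitter: float = 0.0,
    gravity_included: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise sacral-IMU acceleration from a CoM trajectory.

    The CoM acceleration is resampled to ``imu_rate``; a heel-strike
    shock transient (a half-sine bump on the vertical channel -- a real
    and documented feature of sacrum-mounted accelerometers, and the
    signature the 20 Hz event-detection channel relies on) is added at
    every HS; the result is rotated by a small constant mounting tilt
    (the local sensor frame) and white noise is added.  With all extras
    at zero the output is exactly the resampled CoM acceleration.

    Returns ``(time, acc)`` with ``acc`` of shape (n, 3).
    """
    if max(abs(frame_tilt[0]), abs(frame_tilt[1])) > math.radians(15):
        import warnings

        warnings.warn(
            "frame tilt beyond 15 degrees violates the small-tilt assumption",
            stacklevel=2,
        )
    t_imu = np.arange(trajectory.time[0], trajectory.time[-1] + 1e-12, 1.0 / imu_rate)
    acc = np.column_stack(
        [
            np.interp(t_imu, trajectory.time, trajectory.acceleration[:, j])
            for j in range(3)
        ]
    )
    if hs_transient_amp != 0.0:
        # biphasic shock (a dip followed by an impact peak), the
        # signature the 20 Hz heel-strike detector keys on; its size
        # scales with the vertical touchdown speed, as impact severity
        # does in real gait
        # impact severity grows superlinearly with walking speed; below
        # ~1 m/s the shock floor is set by the leg drop itself
        v_walk = float(np.mean(trajectory.velocity[:, 1]))
        amp = hs_transient_amp * min(max(v_walk * v_walk, 1.0), 4.0)
        stochastic = hs_transient_dropout > 0.0 or hs_transient_jitter > 0.0
        if stochastic and rng is None:
            raise ValueError("rng required for transient dropout/jitter")
        for t_hs, kind, _ in trajectory.events:
            if kind != "HS":
                continue
            amp_step = amp
            # footwear sometimes absorbs the shock almost entirely, the
            # reason heel strikes are harder to pin down than toe-offs
            if hs_transient_dropout > 0.0 and rng.uniform() < hs_transient_dropout:
                amp_step = 0.0
            # the shock arrives early and with step-to-step timing
            # scatter relative to the force-defined heel strike
            t0b = t_hs + hs_transient_latency
            if hs_transient_jitter > 0.0:
                t0b += rng.normal(0.0, hs_transient_jitter)
            in_bump = (t_imu >= t0b) & (t_imu <= t0b + 2.0 * hs_transient_width)
            acc[in_bump, 2] += -amp_step * np.sin(
                math.pi * (t_imu[in_bump] - t0b) / hs_transient_width
            )
    # a tilted sensor measures the rotated specific force (a + g); the
    # gravity-compensated mode subtracts the *nominal* gravity vector,
    # so a small mounting tilt leaks a constant fraction of g into the
    # horizontal channels -- the dominant local-vs-global-frame error
    g = trajectory.params.gravity
    acc[:, 2] += g
    R = _tilt_matrix(*frame_tilt)
    acc = acc @ R.T
    if not gravity_included:
        acc[:, 2] -= g
    noise = np.broadcast_to(np.asarray(noise_sd, dtype=float), (3,))
    if np.any(noise > 0.0):
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        acc = acc + rng.normal(0.0, 1.0, acc.shape) * noise
    return t_imu, acc


# ---------------------------------------------------------------------------
# Quasi-static joint torques
# ---------------------------------------------------------------------------


@dataclass
class LegChain:
    """Joint centres of one massless stance leg (laboratory frame)."""

    hip: np.ndarray  # (n, 3)
    knee: np.ndarray
    ankle: np.ndarray


def build_leg_chain(
    com: np.ndarray,
    anchor: np.ndarray,
    side_sign: float,
    subject: SubjectAnthropometrics,
) -> LegChain:
    """Geometric joint centres from the CoM and the foot anchor.

    The ankle sits a fixed fraction of the foot length ahead of the
    anchor at anatomical ankle height; the hip lies along the
    ankle-to-pelvis direction at the anatomical thigh+shank length
    scaled by the model's spring-compression ratio; the knee comes from
    the two-link inverse kinematics between them, displaced toward the
    walking direction, so knee flexion follows the spring compression
    at human-like magnitude.
    """
    com = np.atleast_2d(np.asarray(com, dtype=float))
    anchor = np.atleast_2d(np.asarray(anchor, dtype=float))
    n = len(com)
    ankle = np.column_stack(
        [
            anchor[:, 0],
            anchor[:, 1] + 0.25 * subject.foot_length,
            np.full(n, 0.08),
        ]
    )
    thigh = 0.245 * subject.height
    shank = 0.246 * subject.height
    # hip: along the ankle->pelvis direction at the anatomical chain
    # length scaled by the model's spring-compression ratio, so knee
    # flexion tracks the spring compression at human-like magnitude
    l0 = 0.85 * subject.leg_length
    pelvis = com + np.array([0.09 * side_sign, 0.0, 0.0])
    anchor3 = np.column_stack([anchor[:, 0], anchor[:, 1], np.zeros(n)])
    l_ratio = np.linalg.norm(com - anchor3, axis=1) / l0
    l_ratio = np.clip(l_ratio, 0.85, 0.995)
    u_leg = pelvis - ankle
    u_norm = np.linalg.norm(u_leg, axis=1, keepdims=True)
    if np.any(u_norm < 1e-9):
        raise ValueError("degenerate leg geometry: pelvis and ankle coincide")
    u_leg = u_leg / u_norm
    hip = ankle + (l_ratio * (thigh + shank))[:, None] * u_leg
    d_vec = ankle - hip
    d_raw = np.linalg.norm(d_vec, axis=1)
    if np.any(d_raw < 1e-9):
        raise ValueError("degenerate leg geometry: hip and ankle coincide")
    d = np.minimum(d_raw, 0.999 * (thigh + shank))
    axis = d_vec / d_raw[:, None]
    along = (thigh**2 - shank**2 + d**2) / (2.0 * d)
    perp = np.sqrt(np.maximum(thigh**2 - along**2, 0.0))
    fwd = np.array([0.0, 1.0, 0.0])
    f_ortho = fwd - (axis @ fwd)[:, None] * axis
    norm = np.linalg.norm(f_ortho, axis=1, keepdims=True)
    norm[norm < 1e-9] = 1.0
    knee = hip + along[:, None] * axis + perp[:, None] * (f_ortho / norm)
    return LegChain(hip=hip, knee=knee, ankle=ankle)


_TORQUE_AXES = (
    ("hip", 1),  # hip Ab/Ad: moment about the AP axis
    ("hip", 0),  # hip E/F: moment about the ML axis
    ("hip", 2),  # hip ER/IR: moment about the vertical axis
    ("knee", 1),  # knee Ab/Ad
    ("knee", 0),  # knee F/E
    ("knee", 2),  # knee ER/IR
    ("ankle", 0),  # ankle PF/DF
)


def quasi_static_torques(
    grf: np.ndarray,
    cop: np.ndarray,
    chain: LegChain,
) -> np.ndarray:
    """Seven joint-torque channels from the GRF moment about each joint.

    ``torque_j = (p_CoP - p_joint) x F`` projected on the laboratory
    axes, channel order (hip Ab/Ad, hip E/F, hip ER/IR, knee Ab/Ad,
    knee F/E, knee ER/IR, ankle PF/DF).  Massless segments: this is the
    external GRF moment; internal (muscle) moments are its negative.
    Linear in the GRF, and zero at a joint that lies on the force's
    line of action.
    """
    grf = np.atleast_2d(np.asarray(grf, dtype=float))
    cop = np.atleast_2d(np.asarray(cop, dtype=float))
    n = len(grf)
    cop3 = np.column_stack([cop, np.zeros(n)])
    out = np.empty((n, 7))
    joints = {"hip": chain.hip, "knee": chain.knee, "ankle": chain.ankle}
    for ch, (joint, axis) in enumerate(_TORQUE_AXES):
        tau = np.cross(cop3 - joints[joint], grf)
        out[:, ch] = tau[:, axis]
    return out


# ---------------------------------------------------------------------------
# Trials and cohorts
# ---------------------------------------------------------------------------


def _leg_torque_series(
    traj: ComTrajectory,
    side: str,
    subject: SubjectAnthropometrics,
) -> np.ndarray:
    """Quasi-static torque series of one leg on the trajectory grid."""
    grf = traj.grf_left if side == "left" else traj.grf_right
    cop = traj.cop_left if side == "left" else traj.cop_right
    out = np.zeros((len(traj.time), 7))
    side_sign = 1.0 if side == "right" else -1.0
    for t_hs, t_to, _ in traj.stance_windows(side=side):
        sel = (traj.time >= t_hs - 1e-9) & (traj.time <= t_to + 1e-9)
        if not sel.any():
            continue
        cop_sel = cop[sel]
        # anchor: the CoP at the start of the stance (the heel)
        anchor = np.broadcast_to(cop_sel[0], cop_sel.shape)
        chain = build_leg_chain(traj.position[sel], anchor, side_sign, subject)
        out[sel] = quasi_static_torques(grf[sel], cop_sel, chain)
    return out


def _fill_swing_nans(t: np.ndarray, arr: np.ndarray) -> np.ndarray:
    """Replace swing-phase NaNs in a per-leg CoP series by edge-holding."""
    out = arr.copy()
    for j in range(arr.shape[1]):
        col = out[:, j]
        mask = np.isfinite(col)
        if mask.any():
            out[:, j] = np.interp(t, t[mask], col[mask])
    return out


def generate_trial(
    subject: SubjectAnthropometrics,
    speed: float,
    config: CohortConfig,
    rng: np.random.Generator,
    gait: PeriodicGait | None = None,
) -> SyntheticTrial:
    """Generate one subject x speed bout with IMU signal and ground truth.

    Simulates enough strides that ``strides_per_speed`` complete stance
    phases fall inside the bout plus a lead-in and lead-out step for
    the event detector.
    """
    params = subject_slip_parameters(subject, speed)
    if gait is None:
        gait = find_periodic_gait(params, speed)
    n_stances = config.strides_per_speed
    n_strides = n_stances // 2 + 3  # both sides contribute stances + margin
    traj = simulate_stride(gait.params, gait, n_strides=n_strides, sample_rate=_SIM_RATE)

    pitch = rng.normal(0.0, config.frame_pitch_sd)
    roll = rng.normal(0.0, config.frame_tilt_sd)
    t_imu, acc_imu = imu_from_com(
        traj,
        config.imu_rate,
        noise_sd=(config.noise_sd, config.noise_sd, config.noise_sd_vertical),
        frame_tilt=(float(pitch), float(roll)),
        rng=rng,
        hs_transient_amp=config.hs_transient_amp,
        hs_transient_width=config.hs_transient_width,
        hs_transient_dropout=config.hs_transient_dropout,
        hs_transient_latency=config.hs_transient_latency,
        hs_transient_jitter=config.hs_transient_jitter,
    )

    # ground truth on the 100 Hz grid
    t_truth = np.arange(traj.time[0], traj.time[-1] + 1e-12, 1.0 / TRUTH_RATE)

    def interp_cols(arr):
        return np.column_stack(
            [np.interp(t_truth, traj.time, arr[:, j]) for j in range(arr.shape[1])]
        )

    grf = {"left": interp_cols(traj.grf_left), "right": interp_cols(traj.grf_right)}
    cop = {
        "left": interp_cols(_fill_swing_nans(traj.time, traj.cop_left)),
        "right": interp_cols(_fill_swing_nans(traj.time, traj.cop_right)),
    }
    torques = {
        side: interp_cols(_leg_torque_series(traj, side, subject))
        for side in ("left", "right")
    }

    windows = traj.stance_windows()
    kept = windows[1 : 1 + n_stances]  # skip the lead-in stance
    return SyntheticTrial(
        subject=subject,
        nominal_speed=speed,
        true_speed=gait.speed,
        params=gait.params,
        imu_time=t_imu,
        imu_acc=acc_imu,
        truth_time=t_truth,
        com_position=interp_cols(traj.position),
        com_velocity=interp_cols(traj.velocity),
        com_acceleration=interp_cols(traj.acceleration),
        grf=grf,
        cop=cop,
        torques=torques,
        events=list(traj.events),
        stance_truth=kept,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full virtual cohort, reproducibly from the seed.

    A subject x speed combination for which the periodic-gait search
    fails is skipped with a logged reason, never silently.  Warm starts
    are shared across subjects per speed to keep the search fast.
    """
    rng = np.random.default_rng(config.seed)
    subjects = [
        sample_subject(rng, subject_id=f"S{i:02d}") for i in range(config.n_subjects)
    ]
    trials = []
    skipped = []
    warm: dict[float, np.ndarray] = {}
    for subject in subjects:
        for speed in config.speeds:
            params = subject_slip_parameters(subject, speed)
            gait = None
            for guess in (warm.get(speed), None):
                try:
                    gait = find_periodic_gait(params, speed, initial_guess=guess)
                    break
                except SimulationFailure as exc:
                    reason = str(exc)
            if gait is None:
                logger.warning(
                    "skipping %s at %.1f m/s: %s", subject.subject_id, speed, reason
                )
                skipped.append((subject.subject_id, speed, reason))
                continue
            warm[speed] = np.concatenate(
                [gait.section_unknowns, [gait.params.touchdown_polar]]
            )
            trials.append(generate_trial(subject, speed, config, rng, gait=gait))
    return Cohort(config=config, subjects=subjects, trials=trials, skipped=skipped)
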