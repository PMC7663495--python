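"""Three-dimensional compliant (SLIP) walking model.

A point mass on massless spring legs walks with alternating single and
double support.  The model serves two purposes: it is a nonlinear gait
simulator (periodic-gait search, per-leg ground reaction forces, moving
centre of pressure), and it carries the small-angle affine maps that
express the stance kinetics as a weighted sum of the centre-of-mass
position -- the relationship that motivates using a single sacral sensor
and a shallow network downstream.

Coordinate convention: ``x`` mediolateral, ``y`` anteroposterior
(direction of progression), ``z`` vertical; right-handed.  The leg state
is described in spherical coordinates with the ``y`` axis as zenith:
``l`` is the spring length, ``theta`` the polar angle from the ``y``
axis, and ``phi`` the azimuth of the projected leg in the ``z``-``x``
plane measured from the ``z`` axis.  ``theta_perp = theta - pi/2`` is
the deviation of the leg from vertical in the sagittal plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "SlipParameters",
    "LegState",
    "AugmentedState",
    "LinearMaps",
    "ComTrajectory",
    "PeriodicGait",
    "SimulationFailure",
    "com_from_leg",
    "leg_from_com",
    "spring_grf",
    "grf_linear",
    "cop_linear",
    "kinetics_from_com",
    "cop_progression",
    "maps_from_heelstrike",
    "simulate_stride",
    "find_periodic_gait",
    "default_parameters",
]

_DEG = math.pi / 180.0


class SimulationFailure(RuntimeError):
    """Raised when the model falls or the integrator cannot proceed."""


@dataclass(frozen=True)
class SlipParameters:
    """Constants of the 3D SLIP walker.

    Parameters
    ----------
    mass : float
        Point mass in kg.
    stiffness : float
        Leg spring stiffness ``k`` in N/m.
    rest_length : float
        Spring rest length ``l0`` in m.
    touchdown_polar : float
        Polar touchdown angle ``theta_td`` (rad, from the +y axis); a
        value above ``pi/2`` places the foot ahead of the mass.
    touchdown_azimuth : float
        Magnitude of the azimuthal touchdown angle ``phi_td`` (rad);
        its sign alternates with the stance side.
    cop_amplitude : float
        Total anteroposterior centre-of-pressure excursion ``c_f`` (m)
        of the logistic progression under each foot.
    cop_center : float
        Time ``a`` (s) after heel strike at which the CoP progression
        reaches half its excursion.
    cop_rate : float
        Logistic rate (1/s) of the CoP progression.
    gravity : float
        Gravitational acceleration (m/s^2).
    """

    mass: float
    stiffness: float
    rest_length: float
    touchdown_polar: float
    touchdown_azimuth: float
    cop_amplitude: float
    cop_center: float
    cop_rate: float
    gravity: float = 9.81

    def __post_init__(self) -> None:
        for name in ("mass", "stiffness", "rest_length", "gravity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (68 * _DEG <= self.touchdown_polar <= 112 * _DEG):
            warnings.warn(
                "touchdown_polar outside the 68-112 degree band of known "
                "walking solutions",
                stacklevel=2,
            )
        if abs(self.touchdown_azimuth) > 17 * _DEG:
            warnings.warn(
                "touchdown_azimuth beyond 17 degrees; outside the reported "
                "solution region",
                stacklevel=2,
            )

    @property
    def touchdown_height(self) -> float:
        """CoM height at which a leg at the touchdown angles reaches the ground."""
        return (
            self.rest_length
            * math.sin(self.touchdown_polar)
            * math.cos(self.touchdown_azimuth)
        )


@dataclass
class LegState:
    """Instantaneous geometry of one stance leg."""

    length: float
    polar: float
    azimuth: float
    foot_anchor: tuple[float, float] = (0.0, 0.0)
    cop_excursion: tuple[float, float] = (0.0, 0.0)
    stance_side: str = "right"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("leg length must be positive")
        xf, yf = self.cop_excursion
        if abs(xf) > abs(yf) + 1e-12 and abs(xf) > 1e-9:
            warnings.warn("ML CoP excursion exceeds AP excursion", stacklevel=2)

    @property
    def perpendicular(self) -> float:
        """Sagittal leg angle from vertical, ``theta - pi/2``."""
        return self.polar - math.pi / 2.0


@dataclass
class AugmentedState:
    """Augmented stance state ``r = [l, theta_perp, phi, l*theta_perp, l*phi]``."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape[-1] != 5:
            raise ValueError("augmented state must have 5 components")

    def check_consistency(self, atol: float = 1e-8) -> bool:
        r = self.r
        return bool(
            np.allclose(r[..., 3], r[..., 0] * r[..., 1], atol=atol)
            and np.allclose(r[..., 4], r[..., 0] * r[..., 2], atol=atol)
        )


def com_from_leg(leg: LegState) -> np.ndarray:
    """CoM position implied by a stance-leg state (exact nonlinear geometry)."""
    l, th, ph = leg.length, leg.polar, leg.azimuth
    xf, yf = leg.cop_excursion
    xa, ya = leg.foot_anchor
    return np.array(
        [
            l * math.sin(th) * math.sin(ph) + xf + xa,
            l * math.cos(th) + yf + ya,
            l * math.sin(th) * math.cos(ph),
        ]
    )


@dataclass(frozen=True)
class LinearMaps:
    """Small-angle affine maps from CoM position to stance state and kinetics.

    All maps act on the augmented input ``q_t = [x_m, y_m, z_m,
    f_sigmoid(t - a)]``.  Constants are evaluated at the heel-strike
    (onset-of-stance) configuration: ``z_hs`` is the CoM height at heel
    strike, ``anchor`` the foot anchor ``(x_hs, y_hs)`` (the constant
    part of the foot position, with the small ML CoP excursion folded
    in), and ``d`` the coefficient that scales the unit logistic to the
    AP CoP excursion (the excursion amplitude ``c_f``).

    The spring force is taken positive under compression (the ground
    pushes the mass up), which makes the CoP map consistent with the
    force map; see the methods note for the sign discussion.
    """

    stiffness: float
    rest_length: float
    z_hs: float
    d: float
    anchor: tuple[float, float]

    def __post_init__(self) -> None:
        if self.z_hs == 0:
            raise ZeroDivisionError("z_hs = 0 makes the state map singular")
        if abs(self.z_hs - self.rest_length) < 1e-12:
            raise ZeroDivisionError(
                "z_hs equal to the rest length makes the CoP map singular"
            )

    # -- state map: r = W_r q_t + b_r -------------------------------------
    @property
    def W_r(self) -> np.ndarray:
        z, d = self.z_hs, self.d
        return np.array(
            [
                [0.0, 0.0, 1.0, 0.0],
                [0.0, -1.0 / z, 0.0, d / z],
                [1.0 / z, 0.0, 0.0, 0.0],
                [0.0, -1.0, 0.0, d],
                [1.0, 0.0, 0.0, 0.0],
            ]
        )

    @property
    def b_r(self) -> np.ndarray:
        x_hs, y_hs = self.anchor
        z = self.z_hs
        return np.array([0.0, y_hs / z, -x_hs / z, y_hs, -x_hs])

    # -- force map: F = W_F r + b_F ---------------------------------------
    @property
    def W_F(self) -> np.ndarray:
        k, l0 = self.stiffness, self.rest_length
        return np.array(
            [
                [0.0, 0.0, k * l0, 0.0, -k],
                [0.0, -k * l0, 0.0, k, 0.0],
                [-k, 0.0, 0.0, 0.0, 0.0],
            ]
        )

    @property
    def b_F(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.stiffness * self.rest_length])

    # -- CoP map: q_f = W_f q_t + W_fF F + b_f ----------------------------
    @property
    def W_f(self) -> np.ndarray:
        return np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])

    @property
    def W_fF(self) -> np.ndarray:
        c = self.z_hs / (self.stiffness * (self.z_hs - self.rest_length))
        return np.array([[c, 0.0, 0.0], [0.0, c, 0.0]])

    @property
    def b_f(self) -> np.ndarray:
        x_hs, y_hs = self.anchor
        return np.array([-x_hs, -y_hs])

    # -- combined map: [F; q_f] = W_c q_t + b_c ---------------------------
    @property
    def W_c(self) -> np.ndarray:
        WFWr = self.W_F @ self.W_r
        return np.vstack([WFWr, self.W_fF @ WFWr + self.W_f])

    @property
    def b_c(self) -> np.ndarray:
        top = self.W_F @ self.b_r + self.b_F
        return np.concatenate([top, self.W_fF @ top + self.b_f])


def leg_from_com(q_t: np.ndarray, maps: LinearMaps) -> AugmentedState:
    """Linearized augmented stance state from the augmented CoM input.

    ``q_t`` is ``[x_m, y_m, z_m, f_sigmoid(t - a)]`` (a 4-vector or an
    (n, 4) stack).
    """
    q_t = np.asarray(q_t, dtype=float)
    if q_t.shape[-1] != 4:
        raise ValueError("q_t must have 4 components [x, y, z, f_sigmoid]")
    return AugmentedState(q_t @ maps.W_r.T + maps.b_r)


def spring_grf(leg: LegState, params: SlipParameters) -> np.ndarray:
    """Ground reaction force of one spring leg (exact nonlinear form).

    Positive under compression: ``F = k (l0 - l) * u_leg`` with the unit
    leg vector pointing from the foot toward the mass, so a compressed
    vertical leg pushes the mass upward.
    """
    k, l0 = params.stiffness, params.rest_length
    mag = k * (l0 - leg.length)
    if mag < -1e-9:
        warnings.warn(
            "spring in tension (l > l0); force pulls the mass down", stacklevel=2
        )
    tp, ph = leg.perpendicular, leg.azimuth
    return mag * np.array(
        [
            math.cos(tp) * math.sin(ph),
            -math.sin(tp),
            math.cos(tp) * math.cos(ph),
        ]
    )


def grf_linear(r: AugmentedState | np.ndarray, maps: LinearMaps) -> np.ndarray:
    """Small-angle affine force map ``F = W_F r + b_F``."""
    r = r.r if isinstance(r, AugmentedState) else np.asarray(r, dtype=float)
    return r @ maps.W_F.T + maps.b_F


def cop_linear(q_t: np.ndarray, F: np.ndarray, maps: LinearMaps) -> np.ndarray:
    """Affine CoP map ``q_f = W_f q_t + W_fF F + b_f`` (excursion from anchor)."""
    q_t = np.asarray(q_t, dtype=float)
    F = np.asarray(F, dtype=float)
    return q_t @ maps.W_f.T + F @ maps.W_fF.T + maps.b_f


def kinetics_from_com(q_t: np.ndarray, maps: LinearMaps) -> np.ndarray:
    """Stacked ``[F_x, F_y, F_z, x_f, y_f]`` from the single combined affine map."""
    q_t = np.asarray(q_t, dtype=float)
    return q_t @ maps.W_c.T + maps.b_c


def _sigmoid0(params: SlipParameters) -> float:
    """Value of the unit logistic at heel strike (t = 0)."""
    z = -params.cop_rate * params.cop_center
    return 0.5 * (1.0 + math.tanh(0.5 * z))


def cop_progression(params: SlipParameters, t_since_hs):
    """AP CoP excursion under one foot, zero at heel strike.

    ``y_f(t) = c_f * (sigmoid(rate*(t-a)) - sigmoid(-rate*a))``; the
    small logistic tail at t = 0 is subtracted so the foot-contact
    geometry is exact at touchdown (the constant is absorbed into the
    anchor term of the affine maps).  The ML excursion is identically
    zero: it is small compared with the AP progression and the model
    keeps only the latter.
    """
    t = np.asarray(t_since_hs, dtype=float)
    z = params.cop_rate * (t - params.cop_center)
    return params.cop_amplitude * (
        0.5 * (1.0 + np.tanh(0.5 * z)) - _sigmoid0(params)
    )


def maps_from_heelstrike(
    params: SlipParameters, z_hs: float, anchor: tuple[float, float]
) -> LinearMaps:
    """Build the affine maps with constants from a heel-strike configuration.

    ``anchor`` is the foot position at heel strike; the constant tail of
    the logistic CoP progression is folded into the AP anchor term so
    that ``y_foot(t) = y_hs + d * f_sigmoid(t - a)`` holds exactly.
    """
    return LinearMaps(
        stiffness=params.stiffness,
        rest_length=params.rest_length,
        z_hs=float(z_hs),
        d=params.cop_amplitude,
        anchor=(
            float(anchor[0]),
            float(anchor[1]) - params.cop_amplitude * _sigmoid0(params),
        ),
    )


# ---------------------------------------------------------------------------
# Nonlinear dynamics
# ---------------------------------------------------------------------------


@dataclass
class _Leg:
    """Bookkeeping for one stance episode during integration (local frame)."""

    side: str  # "right" for the leg touching down at the section
    phi_sign: float
    anchor: np.ndarray  # (x, y) foot anchor at heel strike
    t_hs: float

    def foot(self, params: SlipParameters, t) -> np.ndarray:
        """Foot (CoP) position at time(s) ``t``; shape (3,) or (n, 3)."""
        yf = cop_progression(params, np.asarray(t) - self.t_hs)
        x = np.broadcast_to(self.anchor[0], np.shape(yf))
        z = np.zeros_like(np.asarray(yf, dtype=float))
        return np.stack([x, self.anchor[1] + yf, z], axis=-1)

    def force(self, params: SlipParameters, t, q: np.ndarray) -> np.ndarray:
        """Spring force on the mass; ``q`` shape (3,) or (n, 3)."""
        d = np.asarray(q) - self.foot(params, t)
        l = np.linalg.norm(d, axis=-1, keepdims=True)
        return params.stiffness * (params.rest_length - l) / l * d

    def length(self, params: SlipParameters, t, q: np.ndarray) -> float:
        return float(np.linalg.norm(np.asarray(q) - self.foot(params, t)))


def _rhs(params: SlipParameters, legs: Sequence[_Leg]) -> Callable:
    m, g = params.mass, params.gravity

    def f(t, y):
        q = y[:3]
        a = np.array([0.0, 0.0, -g])
        for leg in legs:
            a = a + leg.force(params, t, q) / m
        return np.concatenate([y[3:], a])

    return f


def _touchdown_anchor(
    params: SlipParameters, q: np.ndarray, phi_sign: float
) -> np.ndarray:
    th, ph = params.touchdown_polar, phi_sign * params.touchdown_azimuth
    l0 = params.rest_length
    return np.array(
        [q[0] - l0 * math.sin(th) * math.sin(ph), q[1] - l0 * math.cos(th)]
    )


@dataclass
class _StepResult:
    t_takeoff: float
    t_end: float
    y_end: np.ndarray
    sol_ds: object  # solve_ivp results with dense output
    sol_ss: object
    new_leg: _Leg  # leg of this step (touched down at t=0)
    old_leg: _Leg


def _simulate_step(
    params: SlipParameters,
    state: np.ndarray,
    new_leg: _Leg,
    old_leg: _Leg,
    rtol: float = 1e-10,
    max_step_time: float = 2.5,
) -> _StepResult:
    """Integrate one step: touchdown of ``new_leg`` to touchdown of its successor.

    ``state`` is ``[x, y, z, vx, vy, vz]`` at the touchdown instant
    (t = 0 of the step).  Raises :class:`SimulationFailure` on a fall or
    a missing event.
    """
    z_floor = 0.35 * params.rest_length

    def fall(t, y):
        return y[2] - z_floor

    fall.terminal = True
    fall.direction = -1

    # --- double support: until the old leg unloads (l back to l0) -------
    def takeoff(t, y):
        return old_leg.length(params, t, y[:3]) - params.rest_length

    takeoff.terminal = True
    takeoff.direction = 1

    sol1 = solve_ivp(
        _rhs(params, (new_leg, old_leg)),
        (0.0, max_step_time),
        state,
        events=(takeoff, fall),
        rtol=rtol,
        atol=rtol * 1e-2,
        dense_output=True,
        max_step=0.05,
    )
    if not sol1.success:
        raise SimulationFailure(f"integration failed in double support: {sol1.message}")
    if sol1.t_events[1].size:
        raise SimulationFailure("model fell during double support")
    if not sol1.t_events[0].size:
        raise SimulationFailure("trailing leg never unloaded (no takeoff)")
    t_to = float(sol1.t_events[0][0])
    y_to = sol1.y_events[0][0]

    # --- single support: until the CoM descends to the touchdown height -
    z_td = params.touchdown_height

    def touchdown(t, y):
        return y[2] - z_td

    touchdown.terminal = True
    touchdown.direction = -1

    sol2 = solve_ivp(
        _rhs(params, (new_leg,)),
        (t_to, t_to + max_step_time),
        y_to,
        events=(touchdown, fall),
        rtol=rtol,
        atol=rtol * 1e-2,
        dense_output=True,
        max_step=0.05,
    )
    if not sol2.success:
        raise SimulationFailure(f"integration failed in single support: {sol2.message}")
    if sol2.t_events[1].size:
        raise SimulationFailure("model fell during single support")
    if not sol2.t_events[0].size:
        raise SimulationFailure("no touchdown reached within the step budget")
    t_end = float(sol2.t_events[0][0])
    y_end = sol2.y_events[0][0]

    return _StepResult(
        t_takeoff=t_to,
        t_end=t_end,
        y_end=np.asarray(y_end, dtype=float),
        sol_ds=sol1,
        sol_ss=sol2,
        new_leg=new_leg,
        old_leg=old_leg,
    )


# ---------------------------------------------------------------------------
# Periodic-gait search
# ---------------------------------------------------------------------------


@dataclass
class PeriodicGait:
    """A periodic step of the 3D SLIP walker found by the shooting search.

    The Poincare section is the touchdown instant of a new stance leg
    (in the canonical frame the foot lands at positive x).
    ``section_state`` is ``[vx, vy, vz]`` of the CoM at the section (the
    position is ``(0, 0, touchdown_height)``); ``old_leg_rel`` is the
    trailing-leg anchor relative to the CoM and ``old_leg_age`` the time
    since that leg's own touchdown.
    """

    params: SlipParameters
    section_state: np.ndarray
    old_leg_rel: np.ndarray
    old_leg_age: float
    step_time: float
    step_length: float
    residual: float
    speed: float

    @property
    def stride_time(self) -> float:
        return 2.0 * self.step_time

    @property
    def section_unknowns(self) -> np.ndarray:
        return np.concatenate(
            [self.section_state, self.old_leg_rel, [self.old_leg_age]]
        )


def _section_setup(params: SlipParameters, u: np.ndarray):
    """Initial condition of one canonical step from unknowns ``u``.

    ``u = [vx, vy, vz, dax, day, age]``; the new leg lands at positive x
    (azimuth sign -1 under the spherical convention used here).
    """
    z0 = params.touchdown_height
    q0 = np.array([0.0, 0.0, z0])
    state = np.concatenate([q0, u[:3]])
    new_leg = _Leg(
        side="new",
        phi_sign=-1.0,
        anchor=_touchdown_anchor(params, q0, -1.0),
        t_hs=0.0,
    )
    old_leg = _Leg(
        side="old",
        phi_sign=1.0,
        anchor=np.array([u[3], u[4]]),
        t_hs=-u[5],
    )
    return state, new_leg, old_leg


def _mirror_section(res: _StepResult) -> np.ndarray:
    """Unknown vector of the next section in the canonical (mirrored) frame."""
    y_end = res.y_end
    v = y_end[3:]
    th = res.new_leg  # the leg that touched down at t=0 is the next old leg
    rel = np.array([th.anchor[0] - y_end[0], th.anchor[1] - y_end[1]])
    return np.array([-v[0], v[1], v[2], -rel[0], rel[1], res.t_end])


def _step_map_residual(
    params: SlipParameters, u: np.ndarray, target_speed: float, rtol: float
) -> np.ndarray:
    state, new_leg, old_leg = _section_setup(params, u)
    res = _simulate_step(params, state, new_leg, old_leg, rtol=rtol)
    u_next = _mirror_section(res)
    speed = res.y_end[1] / res.t_end
    return np.concatenate([u_next - u, [speed - target_speed]])


def find_periodic_gait(
    params: SlipParameters,
    target_speed: float,
    initial_guess: np.ndarray | None = None,
    rtol: float = 1e-10,
    residual_tol: float = 1e-8,
    max_nfev: int = 300,
) -> PeriodicGait:
    """Shooting search for a symmetric periodic walking step at a target speed.

    The unknowns are the section velocity, the trailing-leg anchor and
    age, and the polar touchdown angle; the residual enforces closure of
    the mirrored step-to-step map and the average speed to match
    ``target_speed``.  Raises :class:`SimulationFailure` when no
    solution with residual below ``residual_tol`` is found within the
    iteration budget.
    """
    if initial_guess is None:
        u0 = _default_guess(params, target_speed)
    else:
        u0 = np.asarray(initial_guess, dtype=float).copy()

    def fun(v):
        p = replace(params, touchdown_polar=float(v[6]))
        try:
            return _step_map_residual(p, v[:6], target_speed, rtol)
        except SimulationFailure:
            return np.full(7, 10.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(
            fun,
            u0,
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=max_nfev,
            diff_step=1e-6,  # finite differences above the ODE noise floor
        )
    resid = float(np.linalg.norm(sol.fun))
    if not np.isfinite(resid) or resid > residual_tol:
        raise SimulationFailure(
            f"periodic-gait search did not converge (best residual {resid:.3e})"
        )
    u = sol.x
    p = replace(params, touchdown_polar=float(u[6]))
    res = _simulate_step(p, *_section_setup(p, u[:6]), rtol=rtol)
    speed = float(res.y_end[1] / res.t_end)
    return PeriodicGait(
        params=p,
        section_state=u[:3].copy(),
        old_leg_rel=u[3:5].copy(),
        old_leg_age=float(u[5]),
        step_time=float(res.t_end),
        step_length=float(res.y_end[1]),
        residual=resid,
        speed=speed,
    )


# Dimensionless warm starts [vx, vy, vz, dax, day, age, theta_td] per
# dimensionless speed v/sqrt(g*l0) (velocities in sqrt(g*l0), lengths in
# l0, times in sqrt(l0/g)); solved once for the nominal 60 kg /
# l0 = 0.792 m walker on the shallow (double-humped GRF) branch and
# reused, rescaled, for every subject.
_REFERENCE_GUESSES: dict[float, list[float]] = {
    0.247544: [0.0400822239, 0.2733812841, -0.0894678343, -0.0623209005, -0.2508156011, 2.2065350203, 1.8706688183],
    0.249338: [0.0403682297, 0.2758300053, -0.0846264825, -0.0622113307, -0.2543172865, 2.2077962405, 1.8714757826],
    0.251131: [0.0400341014, 0.2763477155, -0.0908758532, -0.0624032797, -0.2601890095, 2.2068672592, 1.8692311374],
    0.287007: [0.0442549907, 0.3208211468, -0.0183925686, -0.0609383619, -0.3336029068, 2.2255526942, 1.8808889975],
    0.322883: [0.0413187787, 0.3482516755, -0.0346529265, -0.0614175541, -0.3753767932, 2.1086188680, 1.8812186077],
    0.358759: [0.0372927733, 0.3760125789, -0.0307219619, -0.0637794450, -0.3555883540, 1.8161887790, 1.8712837945],
    0.412573: [0.0335111320, 0.4253851657, -0.0281160516, -0.0667933125, -0.3450278093, 1.5498093521, 1.8696047082],
    0.466387: [0.0347172655, 0.4899593696, -0.0646250130, -0.0665947621, -0.3975682785, 1.6029865485, 1.9284138694],
    0.520201: [0.0323749575, 0.5440816872, -0.0891954074, -0.0675890795, -0.4267785623, 1.5231315407, 1.9450258509],
    0.574015: [0.0280292566, 0.5939847093, -0.1238088687, -0.0688150886, -0.4459548542, 1.4252052478, 1.9521030615],
    0.595540: [0.0248973647, 0.6119218161, -0.1459568019, -0.0697072131, -0.4450483329, 1.3684695078, 1.9497301141],
    0.617066: [0.0211721958, 0.6293438920, -0.1714081523, -0.0709192649, -0.4437978142, 1.3081873302, 1.9427536627],
    0.638591: [0.0195076061, 0.6516543020, -0.2005839555, -0.0710332481, -0.4612758358, 1.3110281190, 1.9562020636],
}


def _interp_table(vn: float, table: dict[float, np.ndarray]) -> np.ndarray:
    keys = sorted(table)
    vn = min(max(vn, keys[0]), keys[-1])
    lo = max(s for s in keys if s <= vn)
    hi = min(s for s in keys if s >= vn)
    w = 0.0 if hi == lo else (vn - lo) / (hi - lo)
    return (1 - w) * np.asarray(table[lo]) + w * np.asarray(table[hi])


def _default_guess(params: SlipParameters, speed: float) -> np.ndarray:
    """Nominal shooting unknowns, scaled from a solved reference gait."""
    l0 = params.rest_length
    tau = math.sqrt(l0 / params.gravity)
    vscale = math.sqrt(params.gravity * l0)
    if not _REFERENCE_GUESSES:
        t_step = 0.55
        return np.array(
            [0.1, speed, -0.25, 0.12, speed * t_step * 0.55, t_step, 100 * _DEG]
        )
    g = _interp_table(
        speed / vscale, {k: np.asarray(v) for k, v in _REFERENCE_GUESSES.items()}
    )
    u = np.empty(7)
    u[:3] = g[:3] * vscale
    u[3:5] = g[3:5] * l0
    u[5] = g[5] * tau
    u[6] = g[6]
    return u


# ---------------------------------------------------------------------------
# Stride simulation
# ---------------------------------------------------------------------------


@dataclass
class ComTrajectory:
    """Densely sampled CoM trajectory with per-leg kinetics and events."""

    time: np.ndarray
    position: np.ndarray  # (n, 3)
    velocity: np.ndarray  # (n, 3)
    acceleration: np.ndarray  # (n, 3)
    grf_left: np.ndarray  # (n, 3), zero while the leg swings
    grf_right: np.ndarray
    cop_left: np.ndarray  # (n, 2), NaN while the leg swings
    cop_right: np.ndarray
    events: list  # (time, "HS"|"TO", side) tuples, time-sorted
    params: SlipParameters

    @property
    def grf_total(self) -> np.ndarray:
        return self.grf_left + self.grf_right

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def stance_windows(self, side: str | None = None):
        """(hs, to, side) for every stance with both events in the record."""
        hs = [(t, s) for t, kind, s in self.events if kind == "HS"]
        to = [(t, s) for t, kind, s in self.events if kind == "TO"]
        out = []
        for t_hs, s in hs:
            if side is not None and s != side:
                continue
            later = [t for t, s2 in to if s2 == s and t > t_hs + 1e-9]
            if later:
                out.append((t_hs, min(later), s))
        return sorted(out)


def _sample_step(
    params: SlipParameters,
    res: _StepResult,
    t_grid: np.ndarray,
):
    """Evaluate state, acceleration, per-leg force and CoP on local times."""
    n = t_grid.size
    y = np.empty((6, n))
    in_ds = t_grid <= res.t_takeoff
    if in_ds.any():
        y[:, in_ds] = res.sol_ds.sol(t_grid[in_ds])
    if (~in_ds).any():
        y[:, ~in_ds] = res.sol_ss.sol(t_grid[~in_ds])
    q = y[:3].T
    v = y[3:].T
    f_new = res.new_leg.force(params, t_grid, q)
    cop_new = res.new_leg.foot(params, t_grid)[:, :2]
    f_old = np.zeros((n, 3))
    cop_old = np.full((n, 2), np.nan)
    if in_ds.any():
        f_old[in_ds] = res.old_leg.force(params, t_grid[in_ds], q[in_ds])
        cop_old[in_ds] = res.old_leg.foot(params, t_grid[in_ds])[:, :2]
    acc = (f_new + f_old) / params.mass
    acc[:, 2] -= params.gravity
    return q, v, acc, f_new, f_old, cop_new, cop_old


def simulate_stride(
    params: SlipParameters,
    gait: PeriodicGait | None = None,
    n_strides: int = 1,
    sample_rate: float = 1000.0,
    rtol: float = 1e-10,
    reinitialize: bool = True,
    target_speed: float | None = None,
    first_side: str = "right",
) -> ComTrajectory:
    """Simulate ``n_strides`` strides of a periodic gait.

    If ``gait`` is omitted it is first found with
    :func:`find_periodic_gait` at ``target_speed``.  With
    ``reinitialize=True`` (the default) every step restarts from the
    converged fixed point, mirrored and translated, so the bout is
    periodic by construction and the open-loop lateral instability of
    the walker cannot accumulate; with ``reinitialize=False`` the
    dynamics run free from the fixed point.
    """
    if gait is None:
        if target_speed is None:
            raise ValueError("either a PeriodicGait or a target_speed is required")
        gait = find_periodic_gait(params, target_speed, rtol=rtol)
    p = gait.params

    n_steps = 2 * n_strides
    dt = 1.0 / sample_rate

    u_fixed = gait.section_unknowns
    u_cur = u_fixed.copy()
    t_abs = 0.0
    offset = np.zeros(2)  # x/y translation of the local frame
    mirror = 1.0 if first_side == "right" else -1.0

    times, pos, vel, acc = [], [], [], []
    grf = {"left": [], "right": []}
    cop = {"left": [], "right": []}
    events = []
    next_idx = 0

    for _ in range(n_steps):
        state0, new_leg, old_leg = _section_setup(p, u_cur)
        res = _simulate_step(p, state0, new_leg, old_leg, rtol=rtol)

        new_side = "right" if mirror > 0 else "left"
        old_side = "left" if mirror > 0 else "right"
        events.append((t_abs, "HS", new_side))
        events.append((t_abs + res.t_takeoff, "TO", old_side))

        n0 = max(int(math.ceil(t_abs / dt - 1e-9)), next_idx)
        n1 = int(math.floor((t_abs + res.t_end) / dt + 1e-9))
        next_idx = n1 + 1
        t_local = np.clip(np.arange(n0, n1 + 1) * dt - t_abs, 0.0, res.t_end)
        q, v, a, f_new, f_old, cop_new, cop_old = _sample_step(p, res, t_local)

        sgn = np.array([mirror, 1.0, 1.0])
        times.append(t_abs + t_local)
        pos.append(q * sgn + np.array([offset[0], offset[1], 0.0]))
        vel.append(v * sgn)
        acc.append(a * sgn)
        grf[new_side].append(f_new * sgn)
        grf[old_side].append(f_old * sgn)
        cop[new_side].append(cop_new * sgn[:2] + offset)
        cop[old_side].append(cop_old * sgn[:2] + offset)

        shift = res.y_end[:2].copy()
        shift[0] *= mirror
        offset = offset + shift
        t_abs += res.t_end
        mirror = -mirror
        u_cur = u_fixed.copy() if reinitialize else _mirror_section(res)

    return ComTrajectory(
        time=np.concatenate(times),
        position=np.concatenate(pos),
        velocity=np.concatenate(vel),
        acceleration=np.concatenate(acc),
        grf_left=np.concatenate(grf["left"]),
        grf_right=np.concatenate(grf["right"]),
        cop_left=np.concatenate(cop["left"]),
        cop_right=np.concatenate(cop["right"]),
        events=sorted(events),
        params=p,
    )


# Per-speed gait-family schedule, dimensionless in v/sqrt(g*l0).
# Columns: dimensionless stiffness k*l0/(m*g); CoP excursion / l0;
# CoP half-way time / sqrt(l0/g); CoP logistic rate * sqrt(l0/g);
# touchdown polar angle (rad).  The values trace the shallow walking
# branch (double-humped vertical GRF, small vertical touchdown
# velocity) found by numerical continuation; see docs/methods.md.
_SCHEDULE: dict[float, np.ndarray] = {
    0.247544: np.array([27.000000, 0.094697, 1.339846, 2.686885, 1.87066882]),
    0.249338: np.array([27.000000, 0.098485, 1.339846, 2.686885, 1.87147578]),
    0.251131: np.array([27.000000, 0.107323, 1.339846, 2.686885, 1.86923114]),
    0.287007: np.array([26.000000, 0.189394, 1.339846, 2.686885, 1.88088900]),
    0.322883: np.array([24.000000, 0.252525, 1.290222, 2.790227, 1.88121861]),
    0.358759: np.array([24.000000, 0.252525, 1.141350, 3.154170, 1.87128379]),
    0.412573: np.array([24.000000, 0.252525, 0.992478, 3.627295, 1.86960471]),
    0.466387: np.array([22.000000, 0.252525, 0.992478, 3.627295, 1.92841387]),
    0.520201: np.array([22.000000, 0.277778, 0.942854, 3.818206, 1.94502585]),
    0.574015: np.array([22.000000, 0.309343, 0.893230, 4.030328, 1.95210306]),
    0.595540: np.array([22.000000, 0.321970, 0.868419, 4.145480, 1.94973011]),
    0.617066: np.array([22.000000, 0.340909, 0.843607, 4.267406, 1.94275366]),
    0.638591: np.array([22.000000, 0.353535, 0.843607, 4.267406, 1.95620206]),
}


def default_parameters(
    mass: float = 60.0,
    leg_length: float = 0.88,
    foot_length: float = 0.25,
    speed: float = 1.3,
    phi_td_deg: float = 5.0,
) -> SlipParameters:
    """Nominal SLIP parameters for a subject at a given walking speed.

    The rest length is 0.85 of the anatomical leg length (the
    effective CoM pendulum is shorter than the leg, and this places
    the whole protocol speed range inside the model's walking
    branch for the full anthropometric spread).  Stiffness,
    CoP-progression amplitude and timing, and the touchdown angle are
    interpolated from a dimensionless per-speed schedule along the
    shallow walking branch of the model, then rescaled to the subject's
    size; two subjects therefore walk with dynamically similar gaits.
    ``foot_length`` is accepted for interface symmetry; the CoP
    excursion is a gait-family parameter scaled by leg length, not by
    the foot.
    """
    g = 9.81
    l0 = 0.85 * leg_length
    tau = math.sqrt(l0 / g)
    vscale = math.sqrt(g * l0)
    if _SCHEDULE:
        kappa, c_hat, a_hat, r_hat, theta = _interp_table(speed / vscale, _SCHEDULE)
    else:  # bootstrap fallback (exploration only)
        t_stance = max(0.76 - 0.2 * (speed - 0.7) / 0.9, 0.35)
        kappa, c_hat, a_hat, r_hat, theta = (
            18.0,
            0.8 * foot_length / l0,
            0.45 * t_stance / tau,
            8.0 * tau / t_stance,
            100.0 * _DEG,
        )
    return SlipParameters(
        mass=mass,
        stiffness=kappa * mass * g / l0,
        rest_length=l0,
        touchdown_polar=float(theta),
        touchdown_azimuth=phi_td_deg * _DEG,
        cop_amplitude=float(c_hat * l0),
        cop_center=float(a_hat * tau),
        cop_rate=float(r_hat / tau),
    )
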