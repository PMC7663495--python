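"""Sacral-accelerometer processing chain.

Turns raw tri-axial sacral acceleration into stance-phase network
inputs: zero-phase low-pass filtering, mid-stance/heel-strike/toe-off
detection, stride-wise integration with linear drift removal, walking
speed estimation from cadence and acceleration amplitude, mediolateral
side unification, and 201-point stance resampling.

The chain assumes the sensor's local frame is approximately aligned
with the global frame (small mounting tilt) and that walking is steady
state, so that over one stride the mean vertical and mediolateral
velocities vanish and the mean anteroposterior velocity equals the
walking speed.  Channel order throughout: ML, AP, vertical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "AccelSeries",
    "GaitEvents",
    "StrideKinematics",
    "WalkingSpeedModel",
    "StancePhase",
    "lowpass",
    "local_minima",
    "detect_midstances",
    "detect_events",
    "remove_drift",
    "integrate_stride",
    "estimate_speed",
    "fit_speed_model",
    "unify_ml_side",
    "resample_stance",
    "process_trial",
    "PROCESS_RATE",
]

PROCESS_RATE = 100.0  # Hz; all series are brought to this rate first
STANCE_SAMPLES = 201
_MIN_STRIDE = 0.3  # s, sanity bounds on stride duration
_MAX_STRIDE = 2.0


@dataclass
class AccelSeries:
    """Uniformly sampled tri-axial acceleration (columns ML, AP, vertical)."""

    data: np.ndarray  # (n, 3) m/s^2
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != 3:
            raise ValueError("acceleration must have 3 channels (ML, AP, vertical)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("acceleration contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.data)) / self.sample_rate

    def resampled(self, rate: float) -> "AccelSeries":
        """Polyphase resampling to ``rate`` (anti-aliased)."""
        if abs(rate - self.sample_rate) < 1e-9:
            return self
        from fractions import Fraction

        frac = Fraction(rate / self.sample_rate).limit_denominator(1000)
        out = signal.resample_poly(self.data, frac.numerator, frac.denominator, axis=0)
        return AccelSeries(out, rate, self.t0)


@dataclass
class GaitEvents:
    """Detected gait events; times in the series' time base (seconds)."""

    midstance: np.ndarray
    hs: np.ndarray
    to: np.ndarray
    invalid_steps: int = 0

    def __post_init__(self) -> None:
        self.midstance = np.asarray(self.midstance, dtype=float)
        self.hs = np.asarray(self.hs, dtype=float)
        self.to = np.asarray(self.to, dtype=float)


@dataclass
class StrideKinematics:
    """Drift-corrected kinematics over one stride (HS to ipsilateral HS)."""

    time: np.ndarray  # absolute seconds
    acceleration: np.ndarray  # (n, 3)
    velocity: np.ndarray  # (n, 3)
    displacement: np.ndarray  # (n, 3)
    duration: float
    speed: float  # AP mean velocity fixed during integration


@dataclass
class WalkingSpeedModel:
    """Walking speed from cadence and acceleration amplitude.

    ``v0 = (a1 * f + a2 * A + a3) * h * g`` with ``f`` the stride
    frequency (strides/s), ``A`` the mean acceleration magnitude
    (m/s^2), ``h`` the subject height (m) and ``g`` gravity.  The
    coefficients are dimensionless by construction only up to the
    scaling of ``f`` and ``A``; they are always refit on training
    subjects.
    """

    a1: float | None = None
    a2: float | None = None
    a3: float | None = None
    gravity: float = 9.81

    @property
    def fitted(self) -> bool:
        return self.a1 is not None


@dataclass
class StancePhase:
    """One stance resampled to 201 points: the 10-channel network input."""

    time: np.ndarray  # (201,) seconds since HS
    position: np.ndarray  # (201, 3)
    velocity: np.ndarray  # (201, 3)
    acceleration: np.ndarray  # (201, 3)
    hs_time: float
    to_time: float
    side: str = "unknown"
    ml_flipped: bool = False
    speed_label: float = float("nan")

    def input_matrix(self) -> np.ndarray:
        """(201, 10) matrix ``[t, x, y, z, vx, vy, vz, ax, ay, az]``."""
        return np.column_stack(
            [self.time, self.position, self.velocity, self.acceleration]
        )


# ---------------------------------------------------------------------------
# Filtering and event detection
# ---------------------------------------------------------------------------


def lowpass(series: AccelSeries | np.ndarray, cutoff: float, sample_rate: float | None = None):
    """Fifth-order zero-phase (forward-backward) Butterworth low-pass.

    The forward-backward application doubles the effective order and
    cancels the group delay, so event timing is not biased by the
    filter.
    """
    if isinstance(series, AccelSeries):
        fs = series.sample_rate
        x = series.data
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for a bare array")
        fs = sample_rate
        x = np.asarray(series, dtype=float)
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({fs / 2} Hz)")
    sos = signal.butter(5, cutoff, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=0)
    if isinstance(series, AccelSeries):
        return AccelSeries(y, fs, series.t0)
    return y


def local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima; plateaus contribute their midpoint.

    Endpoints are excluded: a minimum must be bracketed by larger values
    on both sides.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    idx, _ = signal.find_peaks(-x, plateau_size=1)
    return idx


def detect_midstances(ap_5hz: np.ndarray, sample_rate: float, t0: float = 0.0) -> np.ndarray:
    """Mid-stance marks from the 5 Hz-filtered AP acceleration.

    Each mark lies one-third of the way between consecutive local minima
    of the filtered AP signal, which places the subsequent bipedal
    support phase at the centre of the step window it starts.
    """
    mins = local_minima(ap_5hz)
    if len(mins) < 2:
        raise ValueError("need at least two AP local minima to mark mid-stances")
    t_min = t0 + mins / sample_rate
    return t_min[:-1] + np.diff(t_min) / 3.0


def detect_events(acc: AccelSeries) -> GaitEvents:
    """Heel-strike and toe-off times from sacral acceleration.

    The AP channel filtered at 5 Hz provides mid-stance marks and the
    toe-off (the minimum of each step window); the vertical channel
    filtered at 20 Hz provides the heel strike (the last local minimum
    before the maximum of the step window).  When the heel strike is
    found after the toe-off it is moved to the previous local minimum
    until it precedes the toe-off; a step with no such minimum is
    dropped and counted in ``invalid_steps``.
    """
    ap5 = lowpass(acc.data[:, 1], 5.0, acc.sample_rate)
    v20 = lowpass(acc.data[:, 2], 20.0, acc.sample_rate)
    fs = acc.sample_rate
    mids_t = detect_midstances(ap5, fs, acc.t0)
    mids = np.round((mids_t - acc.t0) * fs).astype(int)

    v20_minima = local_minima(v20)
    hs_list, to_list = [], []
    invalid = 0
    for i0, i1 in zip(mids[:-1], mids[1:]):
        seg_ap = ap5[i0:i1]
        seg_v = v20[i0:i1]
        if len(seg_ap) < 3:
            invalid += 1
            continue
        i_to = i0 + int(np.argmin(seg_ap))
        i_max = i0 + int(np.argmax(seg_v))
        cand = [i for i in v20_minima if i0 <= i < i_max]
        if not cand:
            invalid += 1
            continue
        i_hs = cand[-1]
        # iterative correction: HS must precede TO
        while i_hs >= i_to:
            cand = cand[:-1]
            if not cand:
                i_hs = -1
                break
            i_hs = cand[-1]
        if i_hs < 0:
            invalid += 1
            continue
        hs_list.append(acc.t0 + i_hs / fs)
        to_list.append(acc.t0 + i_to / fs)
    return GaitEvents(
        midstance=mids_t,
        hs=np.asarray(hs_list),
        to=np.asarray(to_list),
        invalid_steps=invalid,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def remove_drift(v: np.ndarray, T: float, t: np.ndarray | None = None) -> np.ndarray:
    """Remove the linear drift implied by the end-to-start mismatch.

    ``v_hat(t) = v(t) - (v(T) - v(0)) * t / T``; afterwards
    ``v_hat(0) == v_hat(T)``.  Idempotent, and exact for purely linear
    drift.  Works on (n,) or (n, k) arrays.
    """
    if T <= 0:
        raise ValueError("stride duration must be positive")
    v = np.asarray(v, dtype=float)
    if t is None:
        t = np.linspace(0.0, T, len(v))
    ramp = (t / T)[:, None] if v.ndim == 2 else t / T
    return v - (v[-1] - v[0]) * ramp


def integrate_stride(
    acc: np.ndarray,
    sample_rate: float,
    v0: float,
    t0: float = 0.0,
) -> StrideKinematics:
    """Integrate one stride of acceleration into velocity and displacement.

    Cumulative-trapezoid integration with linear drift removal at both
    levels.  Integration constants follow the steady-state assumption:
    mean ML and vertical velocity are zero over the stride, the mean AP
    velocity equals the walking speed ``v0``; mean ML and vertical
    displacement are zero and the AP displacement advances by ``v0``
    per second (the net AP advance over the stride is preserved as
    ``v0 * T`` while the within-stride drift is removed).
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    n = len(acc)
    T = (n - 1) / sample_rate
    if not (_MIN_STRIDE <= T <= _MAX_STRIDE):
        raise ValueError(f"stride duration {T:.3f} s outside [{_MIN_STRIDE}, {_MAX_STRIDE}] s")
    t = np.arange(n) / sample_rate

    vel = cumulative_trapezoid(acc, t, axis=0, initial=0.0)
    vel = remove_drift(vel, T, t)
    vel = vel - vel.mean(axis=0)
    vel[:, 1] += v0

    disp = cumulative_trapezoid(vel, t, axis=0, initial=0.0)
    # AP: remove only the drift in excess of the expected v0*T advance
    expected = np.array([0.0, v0 * T, 0.0])
    disp = disp - np.outer(t / T, (disp[-1] - disp[0]) - expected)
    disp[:, [0, 2]] -= disp[:, [0, 2]].mean(axis=0)
    disp[:, 1] -= disp[0, 1]

    return StrideKinematics(
        time=t0 + t,
        acceleration=acc,
        velocity=vel,
        displacement=disp,
        duration=T,
        speed=v0,
    )


# ---------------------------------------------------------------------------
# Walking-speed model
# ---------------------------------------------------------------------------


def stride_features(acc: AccelSeries, hs: np.ndarray) -> tuple[float, float]:
    """Stride frequency (strides/s) and mean acceleration magnitude (m/s^2).

    ``hs`` are ipsilateral-equivalent heel strikes (every other one is
    one stride apart); the frequency uses the mean interval between
    alternate heel strikes.
    """
    hs = np.sort(np.asarray(hs, dtype=float))
    if len(hs) < 3:
        raise ValueError("need at least three heel strikes for a stride frequency")
    stride_T = np.mean(hs[2:] - hs[:-2])
    f = 1.0 / stride_T
    A = float(np.mean(np.linalg.norm(acc.data, axis=1)))
    return f, A


def estimate_speed(f: float, A: float, h: float, model: WalkingSpeedModel) -> float:
    """Walking speed ``v0 = (a1 f + a2 A + a3) h g`` from a fitted model."""
    if not model.fitted:
        raise ValueError("walking-speed model has not been fitted")
    return (model.a1 * f + model.a2 * A + model.a3) * h * model.gravity


def fit_speed_model(
    features,
    gravity: float = 9.81,
) -> WalkingSpeedModel:
    """Least-squares fit of the speed coefficients on training trials.

    ``features`` is an iterable of ``(f, A, h, v_true)`` tuples.  The
    design must span at least two distinct speeds and be full rank.
    """
    rows = list(features)
    if len(rows) < 3:
        raise ValueError("need at least three trials to fit the speed model")
    X = np.array([[f * h * gravity, A * h * gravity, h * gravity] for f, A, h, _ in rows])
    y = np.array([v for *_, v in rows])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design; speeds/features do not vary enough")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return WalkingSpeedModel(a1=float(coef[0]), a2=float(coef[1]), a3=float(coef[2]), gravity=gravity)


# ---------------------------------------------------------------------------
# Stance assembly
# ---------------------------------------------------------------------------


def unify_ml_side(
    time: np.ndarray,
    position: np.ndarray,
    velocity: np.ndarray,
    acceleration: np.ndarray,
    hs: float,
    to: float,
):
    """Flip the ML channel so every stance presents as the same side.

    The side is read from the sign of the ML displacement at the 50%
    point of the stance phase: a negative mid-stance ML displacement is
    flipped.  An exactly-zero displacement is left unflipped (tie-break
    toward no flip).  Returns (position, velocity, acceleration,
    flipped).
    """
    t_mid = 0.5 * (hs + to)
    d_mid = float(np.interp(t_mid, time, position[:, 0]))
    if d_mid < 0:
        flip = np.array([-1.0, 1.0, 1.0])
        return position * flip, velocity * flip, acceleration * flip, True
    return position, velocity, acceleration, False


def resample_stance(
    time: np.ndarray,
    channels: np.ndarray,
    hs: float,
    to: float,
    n_points: int = STANCE_SAMPLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of stance channels onto ``n_points`` samples.

    Returns ``(t_rel, resampled)`` with ``t_rel`` seconds since HS,
    first sample at HS and last at TO.  Requires at least 4 raw samples
    inside the stance window.
    """
    time = np.asarray(time, dtype=float)
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    if channels.shape[0] != time.shape[0]:
        channels = channels.T
    if to <= hs:
        raise ValueError("toe-off must come after heel strike")
    n_inside = int(np.sum((time >= hs) & (time <= to)))
    if n_inside < 4:
        raise ValueError("fewer than 4 raw samples in the stance window")
    t_new = np.linspace(hs, to, n_points)
    out = np.column_stack(
        [np.interp(t_new, time, channels[:, j]) for j in range(channels.shape[1])]
    )
    return t_new - hs, out


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def process_trial(
    acc: AccelSeries,
    height: float,
    speed_model: WalkingSpeedModel | None = None,
    known_speed: float | None = None,
    gravity_included: bool = False,
    lowpass_cutoff: float = 20.0,
) -> dict:
    """Run the full chain on one walking bout.

    Resamples to 100 Hz, filters, detects events, integrates every
    stride with drift removal, unifies the ML side and produces
    201-point stance phases.  The AP integration constant comes from
    ``known_speed`` when given (training-time truth), otherwise from the
    fitted ``speed_model``.

    Returns a dict with ``events``, ``stances`` (list of
    :class:`StancePhase`), ``estimated_speed``, ``stride_features`` and
    ``n_invalid`` counters.
    """
    acc100 = acc.resampled(PROCESS_RATE)
    data = acc100.data.copy()
    if gravity_included:
        # small-tilt assumption: no orientation correction, just remove
        # the nominal gravity offset from the vertical channel
        data[:, 2] -= 9.81
        acc100 = AccelSeries(data, acc100.sample_rate, acc100.t0)
    events = detect_events(acc100)
    acc_f = lowpass(acc100, lowpass_cutoff)

    f_A: tuple[float, float] | None = None
    est_speed = None
    try:
        f_A = stride_features(acc_f, events.hs)
    except ValueError:
        pass
    if known_speed is not None:
        v0 = known_speed
    elif speed_model is not None and f_A is not None:
        v0 = estimate_speed(f_A[0], f_A[1], height, speed_model)
        est_speed = v0
    else:
        raise ValueError("either known_speed or a fitted speed_model is required")
    if f_A is not None and speed_model is not None and known_speed is not None:
        est_speed = estimate_speed(f_A[0], f_A[1], height, speed_model)

    # pair HS_i with the first TO after it (the TO of the next step
    # window); stance duration sanity keeps mispaired events out
    hs, to = events.hs, events.to
    stances: list[StancePhase] = []
    n_invalid = 0
    t = acc_f.time
    for i, t_hs in enumerate(hs[:-2]):
        t_hs_next = hs[i + 2]
        # the stance's TO is the last TO before the next ipsilateral HS
        cand = to[(to > t_hs + 0.15) & (to < t_hs_next)]
        if cand.size == 0:
            n_invalid += 1
            continue
        t_to = float(cand[-1])
        # integrate the full stride for integration constants
        i0 = int(np.round((t_hs - acc_f.t0) * PROCESS_RATE))
        i1 = int(np.round((t_hs_next - acc_f.t0) * PROCESS_RATE))
        try:
            stride = integrate_stride(
                acc_f.data[i0 : i1 + 1], PROCESS_RATE, v0, t0=t[i0]
            )
        except ValueError:
            n_invalid += 1
            continue
        pos, vel, a_s, flipped = unify_ml_side(
            stride.time,
            stride.displacement,
            stride.velocity,
            stride.acceleration,
            t_hs,
            t_to,
        )
        try:
            t_rel, chans = resample_stance(
                stride.time,
                np.hstack([pos, vel, a_s]),
                t_hs,
                t_to,
            )
        except ValueError:
            n_invalid += 1
            continue
        stances.append(
            StancePhase(
                time=t_rel,
                position=chans[:, 0:3],
                velocity=chans[:, 3:6],
                acceleration=chans[:, 6:9],
                hs_time=t_hs,
                to_time=t_to,
                side="flipped" if flipped else "reference",
                ml_flipped=flipped,
            )
        )
    return {
        "events": events,
        "stances": stances,
        "estimated_speed": est_speed,
        "stride_features": f_A,
        "n_invalid": n_invalid + events.invalid_steps,
    }
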