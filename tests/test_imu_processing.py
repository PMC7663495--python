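"""Filtering, event detection, integration and stance assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slipgait import imu_processing as imu
from slipgait.imu_processing import (
    AccelSeries,
    WalkingSpeedModel,
    detect_events,
    detect_midstances,
    estimate_speed,
    fit_speed_model,
    integrate_stride,
    lowpass,
    remove_drift,
    resample_stance,
    unify_ml_side,
)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def test_lowpass_passes_dc():
    x = np.full(500, 3.7)
    y = lowpass(x, 10.0, sample_rate=100.0)
    assert np.allclose(y, 3.7, atol=1e-9)


def test_lowpass_attenuates_tone_above_cutoff():
    fs, f_c = 100.0, 10.0
    t = np.arange(2000) / fs
    x = np.sin(2 * np.pi * 2 * f_c * t)
    y = lowpass(x, f_c, sample_rate=fs)
    mid = slice(300, -300)
    # zero-phase doubling of a 5th-order Butterworth: >= 60 dB at 2x cutoff
    assert np.max(np.abs(y[mid])) < 1e-3 * np.max(np.abs(x))


def test_lowpass_commutes_with_time_reversal(rng):
    x = rng.normal(size=800)
    fs = 100.0
    y1 = lowpass(x[::-1], 12.0, sample_rate=fs)
    y2 = lowpass(x, 12.0, sample_rate=fs)[::-1]
    # edge padding differs in the first/last few samples; the body of
    # the record is reversal-symmetric
    assert np.allclose(y1[60:-60], y2[60:-60], atol=1e-5)


def test_lowpass_rejects_cutoff_at_nyquist():
    with pytest.raises(ValueError):
        lowpass(np.zeros(100), 50.0, sample_rate=100.0)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


def test_midstance_one_third_rule():
    fs = 100.0
    t = np.arange(0, 3.2, 1 / fs)
    # cosine dips put AP minima at exactly t = 1.0 and t = 2.2
    x = -np.exp(-((t - 1.0) ** 2) / 0.01) - np.exp(-((t - 2.2) ** 2) / 0.01)
    mids = detect_midstances(x, fs)
    assert len(mids) == 1
    assert abs(mids[0] - 1.4) < 1.5 / fs


def test_midstance_requires_two_minima():
    with pytest.raises(ValueError):
        detect_midstances(np.zeros(300), 100.0)


def test_event_detection_shift_invariance(one_subject):
    """Shifting the input in time shifts all detected events equally."""
    from slipgait.synthetic_cohort import CohortConfig, generate_trial

    cfg = CohortConfig(seed=1, strides_per_speed=4).noise_free()
    tr = generate_trial(one_subject, 1.3, cfg, np.random.default_rng(2))
    rate = (len(tr.imu_time) - 1) / (tr.imu_time[-1] - tr.imu_time[0])
    a = AccelSeries(tr.imu_acc, rate)
    shift_samples = 37
    b = AccelSeries(tr.imu_acc[shift_samples:], rate)
    ev_a = detect_events(a.resampled(100.0))
    ev_b = detect_events(b.resampled(100.0))
    dt = shift_samples / rate
    # compare events present in both (edges differ)
    for t_b in ev_b.hs:
        if ev_a.hs.size and np.min(np.abs(ev_a.hs - (t_b + dt))) < 0.02:
            continue
    shifted = ev_b.hs + dt
    common = [
        (x, ev_a.hs[np.argmin(np.abs(ev_a.hs - x))])
        for x in shifted
        if np.min(np.abs(ev_a.hs - x)) < 0.05
    ]
    assert len(common) >= 3
    for x, y in common:
        assert abs(x - y) <= 0.011  # one resampled sample


def test_detect_events_hs_before_to(one_subject):
    from slipgait.synthetic_cohort import CohortConfig, generate_trial

    cfg = CohortConfig(seed=1, strides_per_speed=6).noise_free()
    tr = generate_trial(one_subject, 1.0, cfg, np.random.default_rng(3))
    rate = (len(tr.imu_time) - 1) / (tr.imu_time[-1] - tr.imu_time[0])
    ev = detect_events(AccelSeries(tr.imu_acc, rate).resampled(100.0))
    n = min(len(ev.hs), len(ev.to))
    assert n >= 4
    assert np.all(ev.hs[:n] < ev.to[:n])


def test_hs_correction_moves_to_prior_minimum():
    """A crafted vertical trace whose naive HS lands after the TO."""
    fs = 100.0
    t = np.arange(0, 6.0, 1 / fs)
    # AP: minima every 1 s -> mid-stances, TO at the dip centres
    ap = -np.cos(2 * np.pi * t)
    # vertical: one deep minimum early in each cycle and a decoy local
    # minimum after the AP dip, just before the maximum
    vert = np.sin(2 * np.pi * t + 0.5)
    vert += -0.3 * np.exp(-(((t % 1.0) - 0.55) ** 2) / 0.0004)
    acc = np.column_stack([np.zeros_like(t), ap, vert])
    ev = detect_events(AccelSeries(acc, fs))
    n = min(len(ev.hs), len(ev.to))
    assert n >= 2
    assert np.all(ev.hs[:n] < ev.to[:n])


# ---------------------------------------------------------------------------
# drift removal and integration
# ---------------------------------------------------------------------------


def test_remove_drift_annihilates_linear_ramp():
    t = np.linspace(0, 1, 101)
    v = t.copy()
    v_hat = remove_drift(v, 1.0, t)
    assert np.max(np.abs(v_hat)) < 1e-12


def test_remove_drift_leaves_periodic_unchanged():
    t = np.linspace(0, 1, 101)
    v = np.sin(2 * np.pi * t)
    assert np.allclose(remove_drift(v, 1.0, t), v, atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_remove_drift_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(80, 3))
    once = remove_drift(v, 0.79)
    twice = remove_drift(once, 0.79)
    assert np.allclose(once, twice, atol=1e-12)


def test_remove_drift_rejects_bad_duration():
    with pytest.raises(ValueError):
        remove_drift(np.zeros(10), 0.0)


def test_constant_accel_bias_cancels_after_drift_removal(rng):
    """A constant accelerometer bias maps to a linear velocity drift that
    the stride-wise correction removes exactly."""
    fs = 100.0
    n = 120
    t = np.arange(n) / fs
    a_true = np.column_stack(
        [0.3 * np.sin(2 * np.pi * 2 * t), np.cos(2 * np.pi * 2 * t), np.sin(4 * np.pi * t)]
    )
    bias = np.array([0.2, -0.4, 0.1])
    k_clean = integrate_stride(a_true, fs, v0=1.0)
    k_biased = integrate_stride(a_true + bias, fs, v0=1.0)
    assert np.allclose(k_clean.velocity, k_biased.velocity, atol=1e-9)
    # displacement drift is quadratic in time, removed only to first
    # order; the residual is bounded by bias * T^2 / 8 per axis
    T = (n - 1) / fs
    bound = np.abs(bias) * T**2 / 8 + 1e-9
    assert np.all(
        np.max(np.abs(k_clean.displacement - k_biased.displacement), axis=0) <= bound
    )


def test_integrate_stride_zero_acceleration():
    k = integrate_stride(np.zeros((80, 3)), 100.0, v0=0.0)
    assert np.allclose(k.velocity, 0.0, atol=1e-12)
    assert np.allclose(k.displacement, 0.0, atol=1e-12)


def test_integrate_stride_recovers_sinusoid():
    fs = 200.0
    f = 2.0
    n = int(fs) + 1  # exactly one second, whole number of periods
    t = np.arange(n) / fs
    w = 2 * np.pi * f
    a = np.column_stack([np.zeros(n), np.zeros(n), -w**2 * np.sin(w * t)])
    k = integrate_stride(a, fs, v0=0.0)
    expected = np.sin(w * t)
    expected -= expected.mean()
    assert np.max(np.abs(k.displacement[:, 2] - expected)) < 5e-3


def test_integrate_stride_sets_ap_speed():
    rng = np.random.default_rng(0)
    a = rng.normal(scale=0.5, size=(100, 3))
    k = integrate_stride(a, 100.0, v0=1.25)
    assert abs(k.velocity[:, 1].mean() - 1.25) < 1e-9
    assert abs(k.velocity[:, 0].mean()) < 1e-9
    assert abs(k.velocity[:, 2].mean()) < 1e-9


def test_integrate_stride_duration_bounds():
    with pytest.raises(ValueError):
        integrate_stride(np.zeros((10, 3)), 100.0, v0=0.0)  # 0.09 s stride


# ---------------------------------------------------------------------------
# walking speed
# ---------------------------------------------------------------------------


def test_estimate_speed_constant_model():
    m = WalkingSpeedModel(a1=0.0, a2=0.0, a3=0.02)
    v = estimate_speed(2.0, 3.0, 1.7, m)
    assert np.isclose(v, 0.02 * 1.7 * 9.81)


def test_estimate_speed_monotone_in_cadence():
    m = WalkingSpeedModel(a1=0.05, a2=0.0, a3=0.0)
    assert estimate_speed(1.2, 3.0, 1.7, m) > estimate_speed(0.9, 3.0, 1.7, m)


def test_estimate_speed_requires_fit():
    with pytest.raises(ValueError):
        estimate_speed(1.0, 3.0, 1.7, WalkingSpeedModel())


def test_fit_speed_model_exact_recovery():
    a1, a2, a3 = 0.03, 0.005, -0.01
    rows = []
    rng = np.random.default_rng(1)
    for _ in range(12):
        f, A, h = rng.uniform(0.7, 1.2), rng.uniform(2, 5), rng.uniform(1.5, 1.9)
        v = (a1 * f + a2 * A + a3) * h * 9.81
        rows.append((f, A, h, v))
    m = fit_speed_model(rows)
    assert np.allclose([m.a1, m.a2, m.a3], [a1, a2, a3], atol=1e-12)


def test_fit_speed_model_rank_deficient():
    rows = [(1.0, 3.0, 1.7, 1.2)] * 6  # duplicated design rows
    with pytest.raises(ValueError):
        fit_speed_model(rows)


def test_fit_speed_model_se_shrinks_with_n(rng):
    """Coefficient scatter shrinks as 1/sqrt(n) under output noise."""
    a = np.array([0.03, 0.005, -0.01])

    def fitted_a1(n, seed):
        r = np.random.default_rng(seed)
        rows = []
        for _ in range(n):
            f, A, h = r.uniform(0.7, 1.2), r.uniform(2, 5), r.uniform(1.5, 1.9)
            v = (a[0] * f + a[1] * A + a[2]) * h * 9.81 + r.normal(0, 0.05)
            rows.append((f, A, h, v))
        return fit_speed_model(rows).a1

    small = np.std([fitted_a1(20, s) for s in range(40)])
    large = np.std([fitted_a1(320, s + 1000) for s in range(40)])
    ratio = small / large
    assert 2.0 < ratio < 8.0  # expect ~4 = sqrt(16)


# ---------------------------------------------------------------------------
# side unification and resampling
# ---------------------------------------------------------------------------


def _stance_arrays(sign=1.0):
    t = np.linspace(0.0, 0.6, 61)
    pos = np.column_stack([sign * np.sin(np.pi * t / 0.6), t, 0.02 * np.cos(t)])
    vel = np.gradient(pos, t, axis=0)
    acc = np.gradient(vel, t, axis=0)
    return t, pos, vel, acc


def test_unify_ml_side_is_involution():
    t, pos, vel, acc = _stance_arrays(sign=-1.0)
    p1, v1, a1, flipped = unify_ml_side(t, pos, vel, acc, 0.0, 0.6)
    assert flipped
    p2, v2, a2, flipped2 = unify_ml_side(t, p1, v1, a1, 0.0, 0.6)
    assert not flipped2
    assert np.allclose(p1, p2) and np.allclose(v1, v2)


def test_unify_ml_side_mirrored_strides_agree():
    t, pos, vel, acc = _stance_arrays(sign=1.0)
    t2, pos2, vel2, acc2 = _stance_arrays(sign=-1.0)
    pA, vA, aA, _ = unify_ml_side(t, pos, vel, acc, 0.0, 0.6)
    pB, vB, aB, _ = unify_ml_side(t2, pos2, vel2, acc2, 0.0, 0.6)
    assert np.allclose(pA, pB) and np.allclose(aA, aB)


def test_unify_ml_side_zero_tie_unflipped():
    t = np.linspace(0, 0.6, 61)
    z = np.zeros((61, 3))
    _, _, _, flipped = unify_ml_side(t, z, z, z, 0.0, 0.6)
    assert not flipped


def test_resample_stance_linear_exactness():
    t = np.linspace(0, 1, 50)
    ramp = np.column_stack([2 * t + 1, -t])
    t_rel, out = resample_stance(t, ramp, 0.1, 0.9)
    assert len(t_rel) == 201
    assert t_rel[0] == 0.0
    assert np.isclose(t_rel[-1], 0.8)
    assert np.allclose(out[:, 0], 2 * (t_rel + 0.1) + 1, atol=1e-12)


def test_resample_stance_endpoints_match_raw():
    t = np.arange(0, 1.0, 0.01)
    x = np.sin(t * 7)[:, None]
    t_rel, out = resample_stance(t, x, 0.2, 0.8)
    assert np.isclose(out[0, 0], np.interp(0.2, t, x[:, 0]))
    assert np.isclose(out[-1, 0], np.interp(0.8, t, x[:, 0]))


def test_resample_stance_requires_samples():
    t = np.linspace(0, 1, 6)
    with pytest.raises(ValueError):
        resample_stance(t, np.zeros((6, 1)), 0.4, 0.45)
    with pytest.raises(ValueError):
        resample_stance(t, np.zeros((6, 1)), 0.6, 0.4)


def test_resample_round_trip_error_bounded_by_curvature():
    t = np.linspace(0, 1, 201)
    x = np.sin(2 * np.pi * t)[:, None]
    t_dn, dn = resample_stance(t, x, 0.0, 1.0, n_points=41)
    _, up = resample_stance(t_dn, dn, 0.0, 1.0, n_points=201)
    h = 1.0 / 40
    curvature_bound = (2 * np.pi) ** 2 * h**2 / 8
    assert np.max(np.abs(up[:, 0] - x[:, 0])) < curvature_bound
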