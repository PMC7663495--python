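"""Geometry, affine maps and dynamics of the 3D compliant walker."""

import math

import numpy as np
import pytest

from slipgait import slip3d
from slipgait.slip3d import (
    AugmentedState,
    LegState,
    LinearMaps,
    SimulationFailure,
    SlipParameters,
    com_from_leg,
    cop_linear,
    cop_progression,
    find_periodic_gait,
    grf_linear,
    kinetics_from_com,
    leg_from_com,
    maps_from_heelstrike,
    spring_grf,
)


def make_maps(k=13000.0, l0=0.792, z_hs=0.76, d=0.2, anchor=(0.0, 0.2)):
    return LinearMaps(stiffness=k, rest_length=l0, z_hs=z_hs, d=d, anchor=anchor)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "leg, expected",
    [
        (LegState(length=1.0, polar=math.pi / 2, azimuth=0.0), (0.0, 0.0, 1.0)),
        (LegState(length=1.0, polar=math.pi / 2, azimuth=math.pi / 2), (1.0, 0.0, 0.0)),
    ],
)
def test_com_from_leg_axis_cases(leg, expected):
    assert np.allclose(com_from_leg(leg), expected, atol=1e-12)


def test_leg_length_must_be_positive():
    with pytest.raises(ValueError):
        LegState(length=-0.1, polar=math.pi / 2, azimuth=0.0)


def test_com_leg_round_trip_near_vertical():
    """Linear state map inverts the nonlinear geometry near vertical."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        l = 0.75 + 0.05 * rng.uniform(-1, 1)
        tp = 0.02 * rng.uniform(-1, 1)
        ph = 0.02 * rng.uniform(-1, 1)
        leg = LegState(length=l, polar=math.pi / 2 + tp, azimuth=ph)
        com = com_from_leg(leg)
        maps = make_maps(z_hs=com[2], d=0.2, anchor=(0.0, 0.0))
        r = leg_from_com(np.array([com[0], com[1], com[2], 0.0]), maps).r
        assert abs(r[0] - l) < 4e-4  # l recovered to O(angle^2)
        assert abs(r[1] - tp) < 2e-3
        assert abs(r[2] - ph) < 2e-3


def test_leg_from_com_heelstrike_configuration(nominal_params):
    """At heel strike the linear map reproduces the touchdown angles."""
    p = nominal_params
    th, ph = p.touchdown_polar, -p.touchdown_azimuth
    leg = LegState(length=p.rest_length, polar=th, azimuth=ph, foot_anchor=(0.1, 0.3))
    com = com_from_leg(leg)
    maps = maps_from_heelstrike(p, z_hs=com[2], anchor=leg.foot_anchor)
    q_t = np.array([com[0], com[1], com[2], slip3d._sigmoid0(p)])
    r = leg_from_com(q_t, maps).r
    # linearization error is O(angle^2); the touchdown angles are ~20 deg
    tp = th - math.pi / 2
    assert abs(r[1] - tp) < abs(tp) ** 3 / 3 + 5e-3
    assert abs(r[2] - ph) < 5e-3
    assert abs(r[0] - p.rest_length) < p.rest_length * (1 - math.sin(th) * math.cos(ph)) + 1e-3


def test_leg_from_com_linearity():
    maps = make_maps(anchor=(0.0, 0.0))
    # with zero anchor the y_f,hs-free bias entries vanish for zero input
    r0 = leg_from_com(np.zeros(4), maps).r
    assert np.allclose(r0, 0.0)
    q = np.array([0.1, -0.2, 0.7, 0.5])
    assert np.allclose(
        leg_from_com(2 * q, maps).r, 2 * leg_from_com(q, maps).r, atol=1e-12
    )


def test_augmented_state_consistency_check():
    ok = AugmentedState(np.array([0.7, 0.1, 0.05, 0.07, 0.035]))
    assert ok.check_consistency()
    bad = AugmentedState(np.array([0.7, 0.1, 0.05, 0.2, 0.035]))
    assert not bad.check_consistency()


def test_leg_from_com_rejects_bad_shape():
    with pytest.raises(ValueError):
        leg_from_com(np.zeros(3), make_maps())


def test_singular_map_constants():
    with pytest.raises(ZeroDivisionError):
        make_maps(z_hs=0.0)
    with pytest.raises(ZeroDivisionError):
        make_maps(z_hs=0.792)


# ---------------------------------------------------------------------------
# forces and CoP
# ---------------------------------------------------------------------------


def test_spring_grf_rest_length_gives_zero(nominal_params):
    leg = LegState(
        length=nominal_params.rest_length, polar=math.pi / 2 + 0.1, azimuth=0.05
    )
    assert np.allclose(spring_grf(leg, nominal_params), 0.0, atol=1e-9)


def test_spring_grf_pure_vertical_compression(nominal_params):
    delta = 0.01
    leg = LegState(
        length=nominal_params.rest_length - delta, polar=math.pi / 2, azimuth=0.0
    )
    F = spring_grf(leg, nominal_params)
    assert np.allclose(F, [0.0, 0.0, nominal_params.stiffness * delta], atol=1e-9)


def test_spring_grf_warns_in_tension(nominal_params):
    leg = LegState(
        length=nominal_params.rest_length + 0.01, polar=math.pi / 2, azimuth=0.0
    )
    with pytest.warns(UserWarning, match="tension"):
        spring_grf(leg, nominal_params)


def test_linear_force_map_matches_nonlinear_to_first_order(nominal_params):
    """W_F r + b_F equals the exact spring force up to O(angle^2)."""
    p = nominal_params
    rng = np.random.default_rng(7)
    for _ in range(30):
        s = 0.02
        tp, ph = s * rng.uniform(-1, 1), s * rng.uniform(-1, 1)
        l = p.rest_length * (1 - 0.03 * rng.uniform(0, 1))
        leg = LegState(length=l, polar=math.pi / 2 + tp, azimuth=ph)
        F_exact = spring_grf(leg, p)
        r = np.array([l, tp, ph, l * tp, l * ph])
        maps = make_maps(k=p.stiffness, l0=p.rest_length, z_hs=l)
        F_lin = grf_linear(r, maps)
        assert np.max(np.abs(F_lin - F_exact)) < 5e-3 * p.stiffness * 0.03


def test_cop_linear_anchor_case():
    maps = make_maps(anchor=(0.05, 0.3))
    q_t = np.array([0.05, 0.3, 0.76, 0.0])
    q_f = cop_linear(q_t, np.zeros(3), maps)
    assert np.allclose(q_f, 0.0, atol=1e-12)


def test_cop_progression_is_monotone_sigmoid(nominal_params):
    t = np.linspace(0.0, 1.0, 400)
    y = cop_progression(nominal_params, t)
    assert np.all(np.diff(y) > 0)
    assert abs(y[0]) < 1e-9  # zero excursion at heel strike
    assert y[-1] < nominal_params.cop_amplitude
    # inflection near the half-way time
    i_inf = np.argmax(np.diff(y))
    assert abs(t[i_inf] - nominal_params.cop_center) < 0.05


def test_combined_map_equals_composition():
    maps = make_maps()
    rng = np.random.default_rng(0)
    q = rng.normal(size=(200, 4))
    direct = kinetics_from_com(q, maps)
    r = leg_from_com(q, maps).r
    F = grf_linear(r, maps)
    q_f = cop_linear(q, F, maps)
    assert np.allclose(direct, np.column_stack([F, q_f]), rtol=0, atol=1e-10)


def test_kinetics_from_com_zero_bias_zero_input():
    maps = make_maps(anchor=(0.0, 0.0))
    out = kinetics_from_com(np.zeros(4), maps)
    # biases from the spring rest force remain (F_z row), the CoP rows
    # compose them; verify exact equality with the assembled constants
    assert np.allclose(out, maps.b_c, atol=1e-12)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def test_periodic_gait_speed_targets():
    """The shooting search hits each protocol speed within 2 percent."""
    for v in (0.7, 1.0, 1.3, 1.6):
        p = slip3d.default_parameters(speed=v)
        g = find_periodic_gait(p, v)
        assert abs(g.speed - v) / v < 0.02
        assert g.residual < 1e-8


def test_periodic_gait_infeasible_stiffness():
    p = slip3d.default_parameters(speed=1.3)
    from dataclasses import replace

    soft = replace(p, stiffness=50.0)  # far below the walking regime
    with pytest.raises(SimulationFailure):
        find_periodic_gait(soft, 1.3, max_nfev=60)


def test_stride_mean_vertical_grf_balances_weight(nominal_params, nominal_trajectory):
    traj = nominal_trajectory
    T = traj.time[-1] - traj.time[0]
    mean_fz = np.trapezoid(traj.grf_total[:, 2], traj.time) / T
    assert abs(mean_fz / (nominal_params.mass * nominal_params.gravity) - 1) < 0.01


def test_vertical_grf_double_humped(nominal_trajectory):
    """Per-leg vertical GRF shows the two-peaked stance profile."""
    from scipy.signal import find_peaks

    traj = nominal_trajectory
    bw = traj.params.mass * traj.params.gravity
    for hs, to, _ in traj.stance_windows(side="right")[:2]:
        sel = (traj.time >= hs) & (traj.time <= to)
        peaks, _ = find_peaks(traj.grf_right[sel, 2], prominence=0.02 * bw)
        assert len(peaks) == 2


def test_left_right_mirror_symmetry(nominal_trajectory):
    """Left-stance GRF mirrors right-stance GRF through the sagittal plane."""
    traj = nominal_trajectory
    wr = traj.stance_windows(side="right")[0]
    wl = traj.stance_windows(side="left")[0]
    # trim one sample at each end: the 1 kHz sampling grid does not hit
    # the event times exactly
    tg_r = np.linspace(wr[0] + 2e-3, wr[1] - 2e-3, 250)
    tg_l = np.linspace(wl[0] + 2e-3, wl[1] - 2e-3, 250)
    Fr = np.column_stack(
        [np.interp(tg_r, traj.time, traj.grf_right[:, j]) for j in range(3)]
    )
    Fl = np.column_stack(
        [np.interp(tg_l, traj.time, traj.grf_left[:, j]) for j in range(3)]
    )
    mirrored = Fl * np.array([-1.0, 1.0, 1.0])
    bw = traj.params.mass * traj.params.gravity
    assert np.max(np.abs(Fr - mirrored)) < 1e-3 * bw  # grid-interpolation limited


def test_free_run_apex_drift(nominal_params, nominal_gait):
    """Re-simulated free-running gait drifts less than 1e-6 per stride."""
    traj = slip3d.simulate_stride(
        nominal_params, nominal_gait, n_strides=5, sample_rate=500.0,
        reinitialize=False,
    )
    T = nominal_gait.stride_time
    apex = []
    for k in range(5):
        sel = (traj.time >= k * T) & (traj.time <= (k + 1) * T)
        apex.append(traj.position[sel, 2].max())
    drift = np.max(np.abs(np.diff(apex)))
    assert drift < 1e-6


def test_trajectory_vertical_grf_nonnegative(nominal_trajectory):
    assert nominal_trajectory.grf_total[:, 2].min() > -1e-9


def test_parameter_validation():
    with pytest.raises(ValueError):
        SlipParameters(
            mass=-1, stiffness=1e4, rest_length=0.8, touchdown_polar=1.9,
            touchdown_azimuth=0.09, cop_amplitude=0.2, cop_center=0.3, cop_rate=10.0,
        )
    with pytest.warns(UserWarning, match="touchdown_polar"):
        SlipParameters(
            mass=60, stiffness=1e4, rest_length=0.8, touchdown_polar=2.2,
            touchdown_azimuth=0.09, cop_amplitude=0.2, cop_center=0.3, cop_rate=10.0,
        )
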