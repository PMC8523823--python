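"""Hill-type MTU dynamics: forces, equilibrium solve, stiffness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anklemech.mtu import (MuscleParams, fiber_force, fiber_stiffness,
                           mtu_stiffness, rigid_fiber_length, series_stiffness,
                           solve_equilibrium, tendon_force, tendon_stiffness)

SOL = MuscleParams("SOL", fmax=3549.0, lm0=0.050, lst=0.250,
                   phi0=math.radians(25.0), group="plantarflexor")


# ---------------------------------------------------------------------------
# tendon model

@pytest.mark.parametrize("strain, expected", [
    (-0.01, 0.0),
    (0.0, 0.0),
    (0.0127, 0.23875),       # linear branch at the transition
    (0.02, 0.5125),          # 37.5*0.02 - 0.2375
    (0.01, 1480.3e-4),       # toe branch 1480.3 * 0.01^2
])
def test_tendon_force_piecewise_values(strain, expected):
    assert tendon_force(strain, 1.0) == pytest.approx(expected, abs=1e-12)


def test_tendon_force_continuity_at_breakpoints():
    for eps in (0.0, 0.0127):
        below = tendon_force(eps - 1e-9, 1.0)
        above = tendon_force(eps + 1e-9, 1.0)
        assert abs(above - below) < 1e-3


@settings(max_examples=50, deadline=None, derandomize=True)
@given(e1=st.floats(-0.05, 0.08), e2=st.floats(-0.05, 0.08))
def test_tendon_force_monotone_nondecreasing(e1, e2):
    lo, hi = sorted((e1, e2))
    assert tendon_force(hi, 1000.0) >= tendon_force(lo, 1000.0)
    assert np.all(tendon_stiffness(np.array([lo, hi]), 1000.0, 0.25) >= 0.0)


def test_tendon_stiffness_linear_branch_value():
    # 37.5 * 1000 / 0.25
    assert tendon_stiffness(0.02, 1000.0, 0.25) == pytest.approx(150000.0)


# ---------------------------------------------------------------------------
# fiber model

def test_fiber_force_normalization_points():
    assert fiber_force(1.0, 1.0, 0.0, 500.0) == pytest.approx(500.0)
    assert fiber_force(0.0, 1.0, 0.0, 500.0) == pytest.approx(0.0)
    assert fiber_force(1.0, 1.0, -1.0, 500.0) == pytest.approx(0.0)  # at vmax


def test_fiber_stiffness_matches_finite_difference():
    """Analytic dFm/dlm (frozen a, v) vs central difference, h = 1e-7 m."""
    p = SOL
    h = 1e-7
    for lnorm, a, v in [(1.10, 0.7, -0.2), (0.95, 0.4, 0.1), (1.25, 0.9, 0.0)]:
        lm = lnorm * p.lm0
        fd = (fiber_force(a, (lm + h) / p.lm0, v, p.fmax)
              - fiber_force(a, (lm - h) / p.lm0, v, p.fmax)) / (2 * h)
        analytic = fiber_stiffness(a, lnorm, v, p.fmax, p.lm0)
        assert analytic == pytest.approx(fd, rel=1e-3)


def test_tendon_stiffness_matches_finite_difference():
    p = SOL
    h = 1e-7
    for eps in (0.005, 0.02):
        lt = p.lst * (1 + eps)
        fd = (tendon_force((lt + h - p.lst) / p.lst, p.fmax)
              - tendon_force((lt - h - p.lst) / p.lst, p.fmax)) / (2 * h)
        assert tendon_stiffness(eps, p.fmax, p.lst) == pytest.approx(fd, rel=1e-3)


# ---------------------------------------------------------------------------
# series combination

def test_series_stiffness_cases():
    assert series_stiffness(2.0, 2.0) == pytest.approx(1.0)
    assert series_stiffness(5.0, np.inf) == pytest.approx(5.0)  # rigid tendon
    assert series_stiffness(0.0, 100.0) == 0.0
    assert series_stiffness(100.0, 0.0) == 0.0


# ---------------------------------------------------------------------------
# equilibrium solve

def test_slack_configuration_gives_negligible_forces():
    n = 30
    lmt = np.full(n, SOL.lst + SOL.lm0 * math.cos(SOL.phi0))
    traj = solve_equilibrium(np.zeros(n), lmt, SOL, 100.0)
    # the solver's small activation floor leaves a whisker of tension
    assert np.all(np.abs(traj.strain) < 5e-3)
    assert np.all(traj.ft < 0.01 * SOL.fmax)


def test_rigid_tendon_closed_form_geometry():
    n = 20
    lmt = np.linspace(0.295, 0.305, n)
    traj = solve_equilibrium(np.full(n, 0.5), lmt, SOL, 100.0, rigid_tendon=True)
    assert np.allclose(traj.lm, rigid_fiber_length(lmt, SOL), atol=1e-15)
    assert np.allclose(traj.lt, SOL.lst)
    km, kt, kmt = mtu_stiffness(traj)
    assert np.all(np.isinf(kt))
    assert np.allclose(kmt, km)


def test_steady_state_independent_of_rate_and_step_count():
    lmt_val = SOL.lst * 1.01 + SOL.lm0 * math.cos(SOL.phi0)
    a = 0.5
    states = []
    for rate, n in [(100.0, 60), (1000.0, 600)]:
        traj = solve_equilibrium(np.full(n, a), np.full(n, lmt_val), SOL, rate)
        states.append((traj.lm[-1], traj.ft[-1]))
    assert states[0][0] == pytest.approx(states[1][0], abs=1e-9)
    assert states[0][1] == pytest.approx(states[1][1], abs=1e-6)


def test_equilibrium_invariants_on_gait_trial(forward0):
    for name, traj in forward0.trajectories.items():
        # geometric closure and force balance at every accepted step
        closure = traj.lm * np.cos(traj.phi) + traj.lt - traj.lmt
        assert np.max(np.abs(closure)) < 1e-9, name
        assert np.max(np.abs(traj.residual)) < 1e-6, name
        balance = traj.ft - traj.fm * np.cos(traj.phi)
        assert np.max(np.abs(balance)) < 1e-6, name


def test_series_stiffness_bounded_by_components(forward0):
    for traj in forward0.trajectories.values():
        pos = (traj.km > 0) & (traj.kt > 0)
        assert np.all(traj.kmt[pos] <= np.minimum(traj.km, traj.kt)[pos] + 1e-9)


def test_vnorm_override_reproduces_unconstrained_solution(forward0, truth0):
    traj = forward0.trajectories["SOL"]
    p = truth0.model.effective_muscles()["SOL"]
    again = solve_equilibrium(traj.activation, traj.lmt, p, traj.rate,
                              vnorm_override=traj.vnorm)
    assert np.allclose(again.lm, traj.lm, atol=1e-10)
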