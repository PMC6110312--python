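"""Closed-form steady-state math and the free-Ago fixed point."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirkinet.kinetic_core import (
    CellState,
    DegenerateTargetError,
    InvalidParameterError,
    TargetParams,
    bound_fraction,
    critical_free_ago,
    integrate_ode,
    km_constant,
    read_params_tsv,
    solve_free_ago,
    target_steady_state,
    write_params_tsv,
)


@pytest.mark.parametrize(
    "k_off,k_cat,k_on,expected",
    [
        (0.1, 0.1, 0.2, 1.0),
        (0.0, 0.2, 0.2, 1.0),
        # at k_on = 0.2, a high-affinity constant K_M = 0.02 pins the total
        # unbinding+decay rate at exactly 0.004
        (0.002, 0.002, 0.2, 0.02),
    ],
)
def test_km_constant_examples(k_off, k_cat, k_on, expected):
    assert km_constant(k_off, k_cat, k_on) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [(0.1, 0.1, 0.0), (0.1, 0.1, -1.0), (-0.1, 0.1, 1.0), (0.0, 0.0, 1.0)])
def test_km_constant_rejects_bad_rates(bad):
    with pytest.raises(InvalidParameterError):
        km_constant(*bad)


@pytest.mark.parametrize(
    "km,a_free,expected",
    [(1.0, 1.0, 0.5), (1.0, 0.0, 0.0), (1.0, 3.0, 0.75)],
)
def test_bound_fraction_examples(km, a_free, expected):
    assert bound_fraction(km, a_free) == pytest.approx(expected)


def test_bound_fraction_monotone_and_bounded():
    a = np.logspace(-6, 6, 200)
    f = bound_fraction(2.5, a)
    assert np.all(np.diff(f) > 0)
    assert f.min() >= 0 and f.max() < 1
    with pytest.raises(InvalidParameterError):
        bound_fraction(1.0, -0.5)
    with pytest.raises(InvalidParameterError):
        bound_fraction(0.0, 1.0)


@pytest.mark.parametrize(
    "t0,tinf,f,expected",
    [
        (100.0, 25.0, 0.0, 100.0),
        (100.0, 25.0, 0.2, 62.5),  # f = 1/(T0/Tinf + 1): the halfway point
        (100.0, 25.0, 2.0 / 3.0, 100.0 / 3.0),
    ],
)
def test_target_steady_state_examples(t0, tinf, f, expected):
    assert target_steady_state(t0, tinf, f) == pytest.approx(expected, rel=1e-12)


def test_target_steady_state_limits_and_errors():
    # f -> 1 approaches the saturated level
    assert target_steady_state(100.0, 25.0, 1 - 1e-12) == pytest.approx(25.0, rel=1e-9)
    with pytest.raises(InvalidParameterError):
        target_steady_state(100.0, 25.0, 1.0)
    with pytest.raises(InvalidParameterError):
        target_steady_state(100.0, 25.0, -0.1)


def _halfway_bisection(km, t0, tinf):
    """Independent oracle: solve T*(f(A)) = (T0+Tinf)/2 by bisection."""
    target = (t0 + tinf) / 2.0
    lo, hi = 0.0, km * 1e8
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if target_steady_state(t0, tinf, bound_fraction(km, mid)) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.mark.parametrize("km,t0,tinf,expected", [(1.0, 100.0, 25.0, 0.25), (2.0, 200.0, 100.0, 1.0)])
def test_critical_free_ago_matches_bisection(km, t0, tinf, expected):
    afc = critical_free_ago(km, t0, tinf)
    assert afc == pytest.approx(expected, rel=1e-12)
    assert afc == pytest.approx(_halfway_bisection(km, t0, tinf), rel=1e-6)


def test_critical_free_ago_degenerate():
    with pytest.raises(DegenerateTargetError):
        critical_free_ago(1.0, 100.0, 100.0)


@settings(max_examples=100, derandomize=True)
@given(
    km=st.floats(1e-3, 1e3),
    t0=st.floats(1.0, 1e4),
    ratio=st.floats(1.01, 100.0),
)
def test_halfway_identity(km, t0, ratio):
    """Evaluating the steady state at A_F^C lands exactly midway."""
    tinf = t0 / ratio
    afc = critical_free_ago(km, t0, tinf)
    value = target_steady_state(t0, tinf, bound_fraction(km, afc))
    assert value == pytest.approx((t0 + tinf) / 2.0, rel=1e-12)


def _free_ago_bisection(params, a_total, iters=200):
    """Independent oracle for the conservation fixed point."""
    arr_km = np.array([p.km for p in params])
    arr_t0 = np.array([p.t0 for p in params])
    arr_tinf = np.array([p.tinf for p in params])

    def excess(a):
        f = a / (a + arr_km)
        t = arr_t0 / (1 + f * (arr_t0 / arr_tinf - 1))
        return a + float(np.sum(f * t)) - a_total

    lo, hi = 0.0, a_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if excess(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_solve_free_ago_no_mirna(four_targets):
    state = solve_free_ago(four_targets, 0.0)
    assert state.a_free == 0.0
    np.testing.assert_allclose(state.m, [p.t0 for p in four_targets])
    assert state.am.sum() == 0.0


def test_solve_free_ago_single_target_oracle():
    p = TargetParams(alpha=10.0, delta=0.1, k_on=0.2, k_off=0.1, k_cat=0.4, id="s")
    assert (p.t0, p.tinf, p.km) == (100.0, 25.0, 2.5)
    for a_total in (1.0, 10.0, 50.0, 500.0):
        state = solve_free_ago([p], a_total)
        assert state.a_free == pytest.approx(_free_ago_bisection([p], a_total), abs=1e-8)


def test_solve_free_ago_random_systems_match_bisection():
    rng = np.random.default_rng(42)
    for _ in range(100):
        m = rng.integers(1, 6)
        params = [
            TargetParams(
                alpha=float(rng.uniform(1, 50)),
                delta=float(rng.uniform(0.05, 0.5)),
                k_on=float(rng.uniform(0.01, 2.0)),
                k_off=float(rng.uniform(0.0, 1.0)),
                k_cat=float(rng.uniform(0.05, 2.0)),
                id=f"r{_}",
            )
            for _ in range(m)
        ]
        a_total = float(rng.uniform(0.1, 2000))
        state = solve_free_ago(params, a_total)
        oracle = _free_ago_bisection(params, a_total)
        assert state.a_free == pytest.approx(oracle, rel=1e-8, abs=1e-8)
        # conservation
        assert state.a_free + state.am.sum() == pytest.approx(a_total, rel=1e-10)


def test_solve_free_ago_saturation_limit(four_targets):
    tinf_sum = sum(p.tinf for p in four_targets)
    a_total = 1e6
    state = solve_free_ago(four_targets, a_total)
    assert state.a_free == pytest.approx(a_total - tinf_sum, rel=1e-3)


def test_integrate_ode_birth_death_relaxation():
    p = TargetParams(alpha=10.0, delta=0.1, k_on=0.2, k_off=0.1, k_cat=0.4, id="s")
    traj = integrate_ode([p], 0.0, None, np.linspace(0, 200, 21))
    assert traj[-1].m[0] == pytest.approx(p.t0, rel=1e-6)
    assert traj[-1].am[0] == pytest.approx(0.0, abs=1e-9)


def test_integrate_ode_endpoint_and_conservation(four_targets):
    a_total = 200.0
    t_grid = np.linspace(0, 500, 101)
    traj = integrate_ode(four_targets, a_total, None, t_grid)
    fixed = solve_free_ago(four_targets, a_total)
    np.testing.assert_allclose(traj[-1].total, fixed.total, rtol=1e-6)
    assert traj[-1].a_free == pytest.approx(fixed.a_free, rel=1e-5)
    drift = max(abs(a_total - s.a_free - s.am.sum()) for s in traj)
    assert drift < 1e-8 * a_total


def test_integrate_ode_rejects_bad_grid(four_targets):
    with pytest.raises(InvalidParameterError):
        integrate_ode(four_targets, 10.0, None, [0.0, 0.0, 1.0])


def test_target_params_validation_and_derived():
    p = TargetParams(alpha=10.0, delta=0.1, k_on=0.2, k_off=0.1, k_cat=0.4)
    assert (p.t0, p.tinf) == (100.0, 25.0)
    assert p.is_downregulated
    assert p.a_f_c == pytest.approx(2.5 * 25 / 100)
    with pytest.raises(InvalidParameterError):
        TargetParams(alpha=0.0, delta=0.1, k_on=0.2, k_off=0.1, k_cat=0.4)
    with pytest.raises(InvalidParameterError):
        TargetParams(alpha=1.0, delta=0.1, k_on=0.2, k_off=-0.1, k_cat=0.4)


def test_params_tsv_roundtrip(tmp_path, four_targets):
    path = tmp_path / "params.tsv"
    write_params_tsv(four_targets, path)
    back = read_params_tsv(path)
    assert back == four_targets


def test_cell_state_bound_fraction_consistency():
    state = CellState(10.0, 4.0, m=np.array([3.0, 0.0]), am=np.array([6.0, 0.0]))
    np.testing.assert_allclose(state.f, [6.0 / 9.0, 0.0])
    np.testing.assert_allclose(state.total, [9.0, 0.0])
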