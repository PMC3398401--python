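"""Circuit equations: regulation function, lattices, division, integration."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from gapcircuit.basins import integrate_omega_batch
from gapcircuit.core_model import (
    CircuitParameters,
    MitosisSchedule,
    StateMatrix,
    apply_nuclear_division,
    build_lattice,
    integrate_full_circuit,
    integrate_shorted_nucleus,
    regulation_g,
    regulation_g_prime,
    rhs_full,
    rhs_shorted,
    total_input,
)


# ---------------------------------------------------------------------------
# regulation function
# ---------------------------------------------------------------------------


def test_regulation_g_values():
    assert regulation_g(0.0) == pytest.approx(0.5)
    assert regulation_g(1.0) == pytest.approx(0.5 * (1.0 / np.sqrt(2.0) + 1.0))
    assert regulation_g(1e8) == pytest.approx(1.0, abs=1e-8)
    assert regulation_g(-1e8) == pytest.approx(0.0, abs=1e-8)


def test_regulation_g_rejects_nonfinite():
    with pytest.raises(ValueError):
        regulation_g(np.inf)


@settings(derandomize=True, max_examples=200)
@given(st.floats(-1e6, 1e6, allow_nan=False))
def test_regulation_g_symmetry_and_range(u):
    g = regulation_g(u)
    assert 0.0 < g < 1.0
    assert g + regulation_g(-u) == pytest.approx(1.0, abs=1e-12)


def test_regulation_g_monotone_and_derivative():
    u = np.linspace(-50, 50, 1001)
    g = regulation_g(u)
    assert np.all(np.diff(g) > 0)
    # derivative consistent with central differences
    du = 1e-6
    num = (regulation_g(u + du) - regulation_g(u - du)) / (2 * du)
    assert np.allclose(regulation_g_prime(u), num, atol=1e-7)


# ---------------------------------------------------------------------------
# total input
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def arbitrary_params():
    rng = np.random.default_rng(7)
    return CircuitParameters(
        R=rng.uniform(5, 30, 4),
        T=rng.normal(0, 0.03, (4, 4)),
        bcd_weight=rng.normal(0, 0.05, 4),
        ext_weight=rng.normal(0, 0.02, (4, 2)),
        h=rng.normal(-2, 1, 4),
        lambda_=rng.uniform(0.05, 0.2, 4),
        D=np.abs(rng.normal(0, 0.2, 4)),
    )


def test_total_input_threshold_only():
    params = CircuitParameters(
        np.ones(4), np.zeros((4, 4)), np.zeros(4), np.zeros((4, 2)),
        np.array([-2.5, 0, 0, 0]), np.ones(4), np.zeros(4),
    )
    assert total_input(0, np.array([5.0, 1, 2, 3]), 9.0, (4.0, 2.0), params) == -2.5


def test_total_input_matches_naive_sum(arbitrary_params):
    """Vectorised input must agree with an explicit term-by-term loop."""
    rng = np.random.default_rng(11)
    state = rng.uniform(0, 200, 4)
    bcd, ext = 12.3, (45.0, 6.0)
    for a in range(4):
        expected = arbitrary_params.h[a]
        for b in range(4):
            expected += arbitrary_params.T[a, b] * state[b]
        expected += arbitrary_params.bcd_weight[a] * bcd
        for e in range(2):
            expected += arbitrary_params.ext_weight[a, e] * ext[e]
        assert total_input(a, state, bcd, ext, arbitrary_params) == pytest.approx(expected)


def test_total_input_rejects_mismatched_lengths(arbitrary_params):
    with pytest.raises(ValueError):
        total_input(0, np.zeros(3), 0.0, (0.0, 0.0), arbitrary_params)


# ---------------------------------------------------------------------------
# shorted RHS
# ---------------------------------------------------------------------------


def test_rhs_shorted_pure_decay(schedule, arbitrary_params):
    params = replace(arbitrary_params, R=np.zeros(4))
    v = np.array([10.0, 20.0, 30.0, 40.0])
    dv = rhs_shorted(v, 5.0, 10.0, 3.0, params, schedule)
    assert np.allclose(dv, -params.lambda_ * v)


def test_rhs_shorted_mitosis_gates_synthesis(schedule, arbitrary_params):
    v = np.array([10.0, 20.0, 30.0, 40.0])
    t_mitosis = 0.5 * (schedule.interphase13_end + schedule.mitosis13_end)
    dv = rhs_shorted(v, t_mitosis, 10.0, 3.0, arbitrary_params, schedule)
    assert np.allclose(dv, -arbitrary_params.lambda_ * v)


def test_rhs_shorted_cad_frozen_after_t6(schedule, arbitrary_params, cad_table):
    cad = cad_table.series_at(47.0)
    v = np.array([10.0, 20.0, 30.0, 40.0])
    dv_late = rhs_shorted(v, schedule.t_T6 + 7.0, 10.0, cad, arbitrary_params, schedule)
    dv_t6 = rhs_shorted(v, schedule.t_T6, 10.0, cad(schedule.t_T6), arbitrary_params, schedule)
    assert np.allclose(dv_late, dv_t6)


# ---------------------------------------------------------------------------
# lattices and division
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "domain,cycle,count",
    [
        ((35, 92), 13, 30),
        ((35, 92), 14, 58),
        ((37, 57), 13, 11),
        ((37, 57), 14, 22),
    ],
)
def test_lattice_nucleus_counts(domain, cycle, count):
    """The lattice convention reproduces the four printed nucleus counts."""
    assert len(build_lattice(domain, cycle)) == count


def test_lattice_positions_parity():
    lat13 = build_lattice((35, 92), 13)
    assert np.all(lat13.positions % 2 == 1)
    lat14 = build_lattice((35, 92), 14)
    assert np.all(np.diff(lat14.positions) == 1)
    assert lat14.positions[-1] == 92


def test_lattice_rejects_inverted_domain():
    with pytest.raises(ValueError):
        build_lattice((57, 37), 13)


def test_division_copies_parent_states():
    lat13 = build_lattice((37, 57), 13)
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 255, (4, len(lat13)))
    state14, lat14 = apply_nuclear_division(StateMatrix(21.1, vals), lat13)
    assert len(lat14) == 22
    for j, x in enumerate(lat14.positions):
        parent = x if x % 2 == 1 else x - 1
        i = int(np.where(lat13.positions == parent)[0][0])
        assert np.array_equal(state14.values[:, j], vals[:, i])


def test_division_clips_at_full_domain():
    lat13 = build_lattice((35, 92), 13)
    vals = np.zeros((4, len(lat13)))
    state14, lat14 = apply_nuclear_division(StateMatrix(21.1, vals), lat13)
    assert len(lat14) == 58


def test_division_requires_cycle13():
    lat14 = build_lattice((37, 57), 14)
    with pytest.raises(ValueError):
        apply_nuclear_division(StateMatrix(0.0, np.zeros((4, 22))), lat14)


# ---------------------------------------------------------------------------
# shorted integration
# ---------------------------------------------------------------------------


def test_integrate_shorted_pure_decay_closed_form(schedule, arbitrary_params):
    params = replace(arbitrary_params, R=np.zeros(4))
    ic = np.array([100.0, 50.0, 20.0, 5.0])
    traj = integrate_shorted_nucleus(10.0, 3.0, ic, params, schedule, t_span=(0.0, 30.0))
    for t in (5.0, 17.0, 30.0):
        expected = ic * np.exp(-params.lambda_ * t)
        assert np.allclose(traj(t), expected, rtol=1e-6)


def test_integrate_shorted_single_gene_steady_state(schedule):
    # constant input u = h (no coupling): steady state R g(h) / lambda
    params = CircuitParameters(
        np.array([20.0, 0, 0, 0]), np.zeros((4, 4)), np.zeros(4), np.zeros((4, 2)),
        np.array([1.3, 0, 0, 0]), np.full(4, 0.1), np.zeros(4),
    )
    traj = integrate_shorted_nucleus(0.0, 0.0, np.zeros(4), params, schedule, t_span=(0.0, 400.0))
    expected = 20.0 * regulation_g(1.3) / 0.1
    assert traj.endpoint[0] == pytest.approx(expected, rel=1e-6)
    assert np.allclose(traj.endpoint[1:], 0.0, atol=1e-9)


def _rk4_shorted(bcd, cad, ic, params, schedule, t_end, dt):
    """Independent fixed-step RK4 integrator, restarted at RHS breakpoints."""
    cuts = [0.0] + [float(b) for b in schedule.breakpoints() if b < t_end] + [t_end]
    y = np.asarray(ic, dtype=float)
    for a, b in zip(cuts[:-1], cuts[1:]):
        n = max(1, int(np.ceil((b - a) / dt)))
        h = (b - a) / n
        t = a
        for _ in range(n):
            # evaluate chi just inside the segment to avoid edge ambiguity
            def f(tt, yy):
                return rhs_shorted(yy, min(max(tt, a + 1e-12), b - 1e-12), bcd, cad, params, schedule)

            k1 = f(t, y)
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
    return y


def test_integrate_shorted_matches_fixed_step_rk4(schedule, bistable_params, cad_table):
    """Adaptive endpoint agrees with an independent fine fixed-step RK4 run."""
    cad = cad_table.series_at(47.0)
    ic = np.array([60.0, 0.0, 0.0, 0.0])
    t_end = 30.0
    traj = integrate_shorted_nucleus(
        8.7, cad, ic, bistable_params, schedule, t_span=(0.0, t_end), rtol=1e-10, atol=1e-12
    )
    oracle = _rk4_shorted(8.7, cad, ic, bistable_params, schedule, t_end, dt=0.002)
    assert np.allclose(traj(t_end), oracle, rtol=1e-8, atol=1e-8)


def test_trajectory_nonnegative_and_bounded(schedule, bistable_params, cad_table):
    cad = cad_table.series_at(45.0)
    bound = np.maximum(255.0, bistable_params.R / bistable_params.lambda_)
    for hb_init in (0.0, 100.0, 255.0):
        ic = np.array([hb_init, 0.0, 0.0, 0.0])
        traj = integrate_shorted_nucleus(10.0, cad, ic, bistable_params, schedule)
        for t in np.linspace(0, schedule.tau, 30):
            v = traj(t)
            assert np.all(v >= -1e-6)
            assert np.all(v <= bound + 1e-6)


def test_mitosis_window_is_exact_exponential_decay(schedule, bistable_params, cad_table):
    """During mitosis (chi = 0) each gene decays exactly at its own rate."""
    cad = cad_table.series_at(47.0)
    traj = integrate_shorted_nucleus(
        8.7, cad, np.array([80.0, 0.0, 0.0, 0.0]), bistable_params, schedule
    )
    t1, t2 = schedule.interphase13_end + 0.5, schedule.mitosis13_end - 0.5
    v1, v2 = traj(t1), traj(t2)
    expected = v1 * np.exp(-bistable_params.lambda_ * (t2 - t1))
    assert np.allclose(v2, expected, rtol=1e-6, atol=1e-9)


def test_integrate_shorted_rejects_bad_ic(schedule, bistable_params):
    with pytest.raises(ValueError):
        integrate_shorted_nucleus(5.0, 0.0, np.array([-5.0, 0, 0, 0]), bistable_params, schedule)


# ---------------------------------------------------------------------------
# full-circuit RHS and integration
# ---------------------------------------------------------------------------


def test_rhs_full_uniform_state_no_diffusion_flux(schedule, bistable_params, cad_table, tll_table):
    lat = build_lattice((37, 57), 13)
    state = np.tile(np.array([50.0, 20.0, 10.0, 5.0])[:, None], (1, len(lat)))
    bcd = np.full(len(lat), 8.0)
    dv = rhs_full(state, 5.0, bcd, cad_table, tll_table, bistable_params, schedule, lat)
    p0 = replace(bistable_params, D=np.zeros((2, 4)))
    dv0 = rhs_full(state, 5.0, bcd, cad_table, tll_table, p0, schedule, lat)
    assert np.allclose(dv, dv0)


def test_rhs_full_three_nucleus_laplacian_by_hand(schedule, cad_table, tll_table):
    """Diffusion term checked against hand-computed finite differences."""
    params = CircuitParameters(
        np.zeros(4), np.zeros((4, 4)), np.zeros(4), np.zeros((4, 2)),
        np.zeros(4), np.full(4, 1e-9), np.full(4, 0.25),
    )
    lat = build_lattice((45, 49), 13)  # nuclei at 45, 47, 49
    assert len(lat) == 3
    hb = np.array([10.0, 40.0, 20.0])
    state = np.zeros((4, 3))
    state[0] = hb
    dv = rhs_full(state, 5.0, np.zeros(3), cad_table, tll_table, params, schedule, lat)
    # boundary nuclei have a single neighbour; centre has two
    assert dv[0, 0] == pytest.approx(0.25 * (40.0 - 10.0), rel=1e-7)
    assert dv[0, 1] == pytest.approx(0.25 * ((10.0 - 40.0) + (20.0 - 40.0)), rel=1e-7)
    assert dv[0, 2] == pytest.approx(0.25 * (40.0 - 20.0), rel=1e-7)


def test_full_circuit_decouples_at_d0(schedule, bistable_params, cad_table, tll_table,
                                      hb0, median_profile):
    """With D = 0 (and Tll off) each nucleus follows the shorted equations."""
    ew = bistable_params.ext_weight.copy()
    ew[:, 1] = 0.0
    p0 = replace(bistable_params, D=np.zeros((2, 4)), ext_weight=ew)
    lat13 = build_lattice((37, 57), 13)
    sol = integrate_full_circuit(
        hb0, median_profile, cad_table, tll_table, p0, schedule, lat13,
        rtol=1e-10, atol=1e-11,
    )
    for k in (2, 5, 8):
        t = float(schedule.time_class_edges[k])
        full_state = sol.at_time(t)
        lattice = sol.lattice_at(t)
        for j, x in enumerate(lattice.positions):
            if x % 2 == 0:
                continue  # daughters at even %EL inherit the parent's IC
            short = integrate_omega_batch(
                [float(hb0(x))], float(median_profile(x)), cad_table.series_at(float(x)),
                p0, schedule, t_final=t, rtol=1e-10, atol=1e-11,
            )[0]
            denom = np.abs(full_state.values[:, j]) + 1e-6
            assert np.all(np.abs(short - full_state.values[:, j]) / denom < 1e-6)


def test_full_circuit_pure_decay_through_division(schedule, cad_table, tll_table):
    params = CircuitParameters(
        np.zeros(4), np.zeros((4, 4)), np.zeros(4), np.zeros((4, 2)),
        np.zeros(4), np.full(4, 0.1), np.zeros(4),
    )
    lat13 = build_lattice((37, 57), 13)
    hb_init = lambda x: 100.0 * np.ones_like(np.asarray(x, dtype=float))
    bcd = lambda x: np.zeros_like(np.asarray(x, dtype=float))
    sol = integrate_full_circuit(hb_init, bcd, cad_table, tll_table, params, schedule, lat13)
    st = sol.at_time(schedule.tau)
    expected = 100.0 * np.exp(-0.1 * schedule.tau)
    assert np.allclose(st.values[0], expected, rtol=1e-6)
    assert st.values.shape[1] == 22


def test_full_circuit_step_halving_convergence(schedule, bistable_params, cad_table,
                                               tll_table, hb0, median_profile):
    lat13 = build_lattice((37, 57), 13)
    sols = [
        integrate_full_circuit(
            hb0, median_profile, cad_table, tll_table, bistable_params, schedule, lat13,
            rtol=rt, atol=rt * 1e-2,
        )
        for rt in (1e-8, 1e-10)
    ]
    a = sols[0].at_time(schedule.tau).values
    b = sols[1].at_time(schedule.tau).values
    assert np.allclose(a, b, rtol=1e-5, atol=1e-5)
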