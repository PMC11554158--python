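"""Reaction network: rate matrix, exact propagation, steady states, density."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from hipposim.hippo_reaction import (
    PropagatorCache,
    critical_density,
    packing_fraction,
    packing_fractions,
    propagate,
    propagator,
    rate_matrix,
    reaction_rhs,
    steady_state,
)
from hipposim.model_core import MechanicsParams, ReactionParams

from .conftest import make_population


def rk_oracle(X0, rho, dt, p, rtol=1e-12):
    """Independent adaptive Runge-Kutta reference for the reaction ODEs."""
    sol = solve_ivp(
        lambda t, x: reaction_rhs(x, rho, p), (0.0, dt), np.asarray(X0, float),
        method="DOP853", rtol=rtol, atol=1e-14,
    )
    return sol.y[:, -1]


class TestRhsAndMatrix:
    def test_table_values_hand_evaluation(self, reaction_params):
        rhs = reaction_rhs((0.05, 0.2, 0.0), 1.0, reaction_params)
        np.testing.assert_allclose(rhs, [-9.9e-3, 2.4e-3, 7.5e-3], rtol=1e-12)

    @given(
        x=st.tuples(*[st.floats(0, 1)] * 3),
        rho=st.floats(0, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_components_sum_to_zero(self, x, rho):
        p = ReactionParams()
        assert abs(reaction_rhs(x, rho, p).sum()) < 1e-15

    def test_matrix_matches_rhs(self, reaction_params):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 1, 3)
            rho = rng.uniform(0, 2)
            A = rate_matrix(rho, reaction_params).A
            np.testing.assert_allclose(A @ x, reaction_rhs(x, rho, reaction_params),
                                       rtol=1e-12, atol=1e-18)

    def test_matrix_structure(self, reaction_params):
        A0 = rate_matrix(0.0, reaction_params).A
        assert A0[2, 0] == 0.0  # no phosphorylation flux without crowding
        A1 = rate_matrix(1.0, reaction_params).A
        assert math.isclose(A1[0, 0], -0.2, rel_tol=1e-12)
        for rho in (0.0, 0.3, 1.0, 2.5):
            A = rate_matrix(rho, reaction_params).A
            np.testing.assert_allclose(A.sum(axis=0), 0.0, atol=1e-16)
            off = A[~np.eye(3, dtype=bool)]
            assert np.all(off >= 0)  # Metzler structure

    def test_negative_density_rejected(self, reaction_params):
        with pytest.raises(ValueError, match="negative"):
            reaction_rhs((0.1, 0.1, 0.1), -0.5, reaction_params)
        with pytest.raises(ValueError, match="negative"):
            rate_matrix(-1e-9, reaction_params)


class TestPropagate:
    def test_dt_zero_is_identity(self, reaction_params):
        x = np.array([0.05, 0.2, 0.0])
        np.testing.assert_array_equal(propagate(x, 1.0, 0.0, reaction_params), x)

    def test_matches_rk_oracle_on_random_triples(self, reaction_params):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.uniform(0, 0.5, 3)
            rho = rng.uniform(0, 2.0)
            dt = rng.uniform(0.1, 100.0)
            got = propagate(x, rho, dt, reaction_params)
            want = rk_oracle(x, rho, dt, reaction_params)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-14)

    def test_long_time_limit_is_steady_state(self, reaction_params):
        x = np.array([0.05, 0.2, 0.0])
        for rho in (0.0, 0.5, 1.0):
            limit = propagate(x, rho, 1e7, reaction_params)
            ss = steady_state(rho, float(x.sum()), reaction_params)
            np.testing.assert_allclose(limit, [ss.X1, ss.X2, ss.X3],
                                       rtol=1e-9, atol=1e-12)

    def test_steady_state_is_fixed_point_of_rhs(self, reaction_params):
        ss = steady_state(0.8, 0.25, reaction_params)
        rhs = reaction_rhs((ss.X1, ss.X2, ss.X3), 0.8, reaction_params)
        np.testing.assert_allclose(rhs, 0.0, atol=1e-12)

    def test_conservation_over_many_steps(self, reaction_params):
        rng = np.random.default_rng(7)
        x = np.array([0.05, 0.2, 0.0])
        total0 = x.sum()
        for _ in range(10_000):
            x = propagate(x, float(rng.uniform(0, 2)), 3.75, reaction_params)
        assert abs(x.sum() - total0) / total0 <= 1e-12

    @given(st.floats(0, 2), st.floats(0.5, 500))
    @settings(max_examples=30, deadline=None)
    def test_nonnegativity_preserved(self, rho, dt):
        p = ReactionParams()
        x = propagate((0.0, 0.001, 0.3), rho, dt, p)
        assert np.all(x >= 0)

    def test_non_finite_input_rejected(self, reaction_params):
        with pytest.raises(ValueError, match="non-finite"):
            propagate((np.nan, 0.1, 0.1), 1.0, 3.75, reaction_params)

    def test_expm_fallback_agrees_with_eigen_path(self, reaction_params):
        # force the scaling-and-squaring branch and compare on a normal case
        import hipposim.hippo_reaction as hr
        P_eig = propagator(1.0, 3.75, reaction_params)
        old = hr._EIG_COND_LIMIT
        hr._EIG_COND_LIMIT = 0.0
        try:
            P_expm = propagator(1.0, 3.75, reaction_params)
        finally:
            hr._EIG_COND_LIMIT = old
        np.testing.assert_allclose(P_eig, P_expm, rtol=1e-12, atol=1e-15)


class TestSteadyState:
    def test_closed_form_normal_rho1(self, reaction_params):
        ss = steady_state(1.0, 0.25, reaction_params)
        assert math.isclose(ss.X2, 25.0 / 1601.0, rel_tol=1e-12)

    def test_closed_form_rho0(self, reaction_params):
        ss = steady_state(0.0, 0.25, reaction_params)
        assert ss.X3 == 0.0
        assert math.isclose(ss.X2, 0.25 * 100 / 101, rel_tol=1e-12)

    @given(st.floats(0, 5), st.floats(0.01, 2))
    @settings(max_examples=50, deadline=None)
    def test_normalisation(self, rho, total):
        ss = steady_state(rho, total, ReactionParams())
        assert math.isclose(ss.X1 + ss.X2 + ss.X3, total, rel_tol=1e-12)

    def test_monotone_in_density(self, reaction_params):
        rhos = np.linspace(0, 3, 50)
        x2 = [steady_state(r, 0.25, reaction_params).X2 for r in rhos]
        x3 = [steady_state(r, 0.25, reaction_params).X3 for r in rhos]
        assert np.all(np.diff(x2) < 0)  # nuclear pool depleted by crowding
        assert np.all(np.diff(x3) > 0)

    def test_nonpositive_total_rejected(self, reaction_params):
        with pytest.raises(ValueError):
            steady_state(1.0, 0.0, reaction_params)


class TestCriticalDensity:
    def test_closed_form_values(self, reaction_params):
        assert math.isclose(critical_density(0.25, reaction_params),
                            1.3215555555555556, rel_tol=1e-9)
        assert math.isclose(critical_density(0.5, reaction_params),
                            2.7104444444444447, rel_tol=1e-9)

    def test_is_inverse_of_steady_state(self, reaction_params):
        for total in (0.25, 0.5, 1.0):
            rho_star = critical_density(total, reaction_params)
            ss = steady_state(rho_star, total, reaction_params)
            assert math.isclose(ss.X2, reaction_params.X_th, rel_tol=1e-12)

    def test_monotone_in_total(self, reaction_params):
        totals = np.linspace(0.05, 2.0, 40)
        stars = [critical_density(t, reaction_params) for t in totals]
        assert np.all(np.diff(stars) > 0)

    def test_infeasible_total_rejected(self, reaction_params):
        with pytest.raises(ValueError, match="too low"):
            critical_density(0.012, reaction_params)


def fcc_contact_shell(radius):
    """Twelve nearest-neighbour directions of an FCC lattice, scaled so each
    neighbour touches a central cell of the same radius (distance 2*radius)."""
    dirs = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for si in (-1, 1):
            for sj in (-1, 1):
                v = np.zeros(3)
                v[i], v[j] = si, sj
                dirs.append(v / np.sqrt(2))
    return np.array(dirs) * 2 * radius


class TestPackingFraction:
    def test_isolated_cell_zero(self):
        pop = make_population([[0.0, 0.0, 0.0]])
        assert packing_fraction(pop, 0) == 0.0

    def test_twelve_fcc_contact_neighbours_give_one(self, mech):
        radius = mech.sigma0_prime
        shell = fcc_contact_shell(radius)
        pop = make_population(np.vstack([[0, 0, 0], shell]))
        assert math.isclose(packing_fraction(pop, 0), 1.0, rel_tol=1e-12)

    def test_six_contact_neighbours_give_half(self, mech):
        radius = mech.sigma0_prime
        shell = fcc_contact_shell(radius)[:6]
        pop = make_population(np.vstack([[0, 0, 0], shell]))
        assert math.isclose(packing_fraction(pop, 0), 0.5, rel_tol=1e-12)

    def test_decreases_as_neighbour_recedes(self):
        vals = []
        for d in (8.0, 10.0, 12.0, 14.0):
            pop = make_population([[0, 0, 0], [d, 0, 0]])
            vals.append(packing_fraction(pop, 0))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_coincident_centers_finite(self, mech):
        pop = make_population([[0, 0, 0], [0, 0, 0]])
        got = packing_fraction(pop, 0, delta_rho=0.25)
        assert math.isclose(got, math.exp(1 / 0.25) / 12.0, rel_tol=1e-12)

    def test_truncated_at_mechanical_cutoff(self, mech):
        # neighbour just beyond s = r_cut_factor contributes nothing
        far = 2 * mech.sigma0_prime * 2.5 * 1.001
        pop = make_population([[0, 0, 0], [far, 0, 0]])
        assert packing_fraction(pop, 0) == 0.0

    def test_interior_exceeds_surface_in_packed_cluster(self, mech):
        # 3x3x3 cubic cluster at contact spacing: center sees more neighbours
        radius = mech.sigma0_prime
        grid = np.array([[i, j, k] for i in range(3) for j in range(3)
                         for k in range(3)], dtype=float) * 2 * radius
        pop = make_population(grid)
        rho = packing_fractions(pop)
        center = 13  # (1,1,1)
        surface = [i for i in range(27) if i != center]
        assert all(rho[center] > rho[s] for s in surface)

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(5)
        pop = make_population(rng.uniform(-15, 15, size=(20, 3)))
        vec = packing_fractions(pop)
        for i in range(20):
            assert math.isclose(vec[i], packing_fraction(pop, i), rel_tol=1e-12)


class TestPropagatorCache:
    def test_cached_propagation_matches_direct(self, reaction_params):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 0.5, size=(30, 3))
        rho = rng.uniform(0, 2, size=30)
        quantum = 1e-3
        cache = PropagatorCache(reaction_params, 3.75, quantum=quantum)
        got = cache.propagate_population(X.copy(), rho)
        for i in range(30):
            rq = np.rint(rho[i] / quantum) * quantum
            want = propagate(X[i], float(rq), 3.75, reaction_params)
            np.testing.assert_allclose(got[i], want, rtol=1e-12, atol=1e-18)

    def test_unquantised_mode_is_exact(self, reaction_params):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 0.5, size=(10, 3))
        rho = rng.uniform(0, 2, size=10)
        cache = PropagatorCache(reaction_params, 3.75, quantise=False)
        got = cache.propagate_population(X.copy(), rho)
        for i in range(10):
            np.testing.assert_allclose(
                got[i], propagate(X[i], float(rho[i]), 3.75, reaction_params),
                rtol=1e-12)

    def test_cache_reused_across_calls(self, reaction_params):
        cache = PropagatorCache(reaction_params, 3.75)
        rho = np.array([0.5, 0.5, 1.0])
        X = np.tile([0.05, 0.2, 0.0], (3, 1))
        cache.propagate_population(X, rho)
        n_entries = len(cache._index)
        cache.propagate_population(X, rho)
        assert len(cache._index) == n_entries == 2
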