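"""Replicator flow, closed form, and the heteroclinic vertex spectrum."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import saddlescape as ss
from saddlescape.dynamics import as_fractions


def random_simplex_point(rng, k):
    x = rng.dirichlet(np.ones(k))
    return x


class TestMeanFitnessAndRhs:
    def test_pure_state_mean_is_vertex_fitness(self, three_type):
        for i, t in enumerate(three_type.type_ids):
            e = np.zeros(3)
            e[i] = 1.0
            assert ss.mean_fitness(e, three_type) == pytest.approx(
                three_type.fitness[i]
            )

    def test_two_type_mixture(self, two_type):
        assert ss.mean_fitness([0.5, 0.5], two_type) == pytest.approx(1.5)
        b = ss.replicator_rhs([0.5, 0.5], two_type)
        assert b == pytest.approx([-0.25, 0.25])

    def test_vertices_are_critical_points(self, four_type_complete):
        for i in range(4):
            e = np.zeros(4)
            e[i] = 1.0
            assert np.allclose(ss.replicator_rhs(e, four_type_complete), 0.0)

    @given(seed=st.integers(0, 10_000))
    def test_rhs_conserves_simplex_and_mean_bounds(self, seed):
        g = ss.random_landscape(5, seed=17)
        x = random_simplex_point(np.random.default_rng(seed), 5)
        assert abs(ss.replicator_rhs(x, g).sum()) < 1e-12
        fbar = ss.mean_fitness(x, g)
        assert g.fitness.min() - 1e-12 <= fbar <= g.fitness.max() + 1e-12


class TestClosedForm:
    def test_identity_at_t_zero(self, three_type, rng):
        x0 = random_simplex_point(rng, 3)
        assert np.allclose(ss.closed_form_solution(x0, three_type, 0.0), x0)

    def test_two_type_logistic_hand_value(self, two_type):
        # x_b(t) = e^t/(1+e^t) from x0=(1/2,1/2), f=(1,2); at t=ln3, x_b=3/4
        x = ss.closed_form_solution([0.5, 0.5], two_type, math.log(3.0))
        assert x[1] == pytest.approx(0.75, abs=1e-12)

    def test_converges_to_fittest_vertex(self, four_type_complete):
        x = ss.closed_form_solution(np.full(4, 0.25), four_type_complete, 60.0)
        assert x[3] == pytest.approx(1.0, abs=1e-10)

    def test_fitness_shift_invariance_and_overflow_guard(self, rng):
        ids = ["a", "b", "c"]
        f1 = {"a": 1.0, "b": 1.5, "c": 2.0}
        f2 = {k: v + 500.0 for k, v in f1.items()}  # would overflow naively
        g1 = ss.build_landscape(ids, f1)
        g2 = ss.build_landscape(ids, f2)
        x0 = random_simplex_point(rng, 3)
        t = 300.0
        assert np.allclose(
            ss.closed_form_solution(x0, g1, t),
            ss.closed_form_solution(x0, g2, t),
            atol=1e-12,
        )

    def test_zero_fraction_types_stay_absent(self, three_type):
        x = ss.closed_form_solution([0.4, 0.0, 0.6], three_type, 2.0)
        assert x[1] == 0.0 and x.sum() == pytest.approx(1.0)

    @given(seed=st.integers(0, 10_000), t=st.floats(-5, 5), u=st.floats(0, 5))
    def test_semigroup_property(self, seed, t, u):
        g = ss.random_landscape(4, seed=29)
        x0 = random_simplex_point(np.random.default_rng(seed), 4)
        direct = ss.closed_form_solution(x0, g, t + u)
        stepped = ss.closed_form_solution(
            ss.closed_form_solution(x0, g, t), g, u
        )
        assert np.abs(direct - stepped).sum() < 1e-10

    def test_fittest_fraction_monotone(self, four_type_complete, rng):
        x0 = random_simplex_point(rng, 4)
        traj = ss.closed_form_solution(x0, four_type_complete, np.linspace(0, 30, 200))
        assert np.all(np.diff(traj[:, 3]) >= -1e-12)
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-9)


class TestNumericalIntegration:
    def test_single_type_constant(self):
        g = ss.build_landscape(["a"], {"a": 1.3})
        y = ss.integrate_replicator([1.0], g, np.linspace(0, 5, 11))
        assert np.allclose(y, 1.0)

    def test_phase_portrait_terminal_state(self, four_type_complete):
        # mixed start must end within 1e-6 of the attracting vertex e(4)
        t = np.linspace(0.0, 40.0, 81)
        y = ss.integrate_replicator(np.full(4, 0.25), four_type_complete, t)
        assert np.abs(y[-1] - np.array([0, 0, 0, 1.0])).sum() < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_closed_form_on_random_instances(self, seed):
        g = ss.random_landscape(5, seed=seed)
        rng = np.random.default_rng(100 + seed)
        x0 = random_simplex_point(rng, 5)
        t = np.linspace(0, 20, 50)
        y = ss.integrate_replicator(x0, g, t, tolerance=1e-10)
        exact = ss.closed_form_solution(x0, g, t)
        assert np.abs(y - exact).sum(axis=1).max() < 1e-8


class TestSelectionCoefficient:
    def test_basic_gaps(self, two_type):
        assert ss.selection_coefficient(two_type) == pytest.approx(1.0)
        g = ss.build_landscape(["a", "b", "c"], {"a": 1.0, "b": 1.05, "c": 1.1})
        assert ss.selection_coefficient(g) == pytest.approx(0.05)

    def test_invariant_to_adding_weaker_types(self, three_type):
        s_all = ss.selection_coefficient(three_type)
        s_top = ss.selection_coefficient(three_type, active_set=["b", "c"])
        assert s_all == pytest.approx(s_top)

    def test_singleton_errors(self, three_type):
        with pytest.raises(ValueError):
            ss.selection_coefficient(three_type, active_set=["a"])


class TestVertexAnalysis:
    def test_eigenvalues_are_fitness_gaps(self, four_type_complete):
        va = ss.vertex_analysis(four_type_complete, "2")
        f = dict(zip(four_type_complete.type_ids, four_type_complete.fitness))
        assert va.eigenvalues == {
            i: pytest.approx(f[i] - f["2"]) for i in ["1", "3", "4"]
        }
        assert va.saddle_index == 1
        assert not va.is_sink_in_I

    def test_sink_and_source(self, four_type_complete):
        top = ss.vertex_analysis(four_type_complete, "4")
        assert top.is_sink_in_I and all(v < 0 for v in top.eigenvalues.values())
        bottom = ss.vertex_analysis(four_type_complete, "1")
        assert bottom.saddle_index == 0
        assert all(v > 0 for v in bottom.eigenvalues.values())

    @pytest.mark.parametrize("seed", [3, 11])
    def test_spectrum_matches_finite_difference_jacobian(self, seed):
        g = ss.random_landscape(6, seed=seed)
        h = 1e-6
        for k, tid in enumerate(g.type_ids):
            e = np.zeros(6)
            e[k] = 1.0

            def rhs(x):
                return x * (g.fitness - np.dot(g.fitness, x))

            J = np.empty((6, 6))
            for j in range(6):
                dp, dm = e.copy(), e.copy()
                dp[j] += h
                dm[j] -= h
                J[:, j] = (rhs(dp) - rhs(dm)) / (2 * h)
            numeric = np.sort(np.linalg.eigvals(J).real)
            analytic = np.sort(
                [g.fitness[i] - g.fitness[k] for i in range(6) if i != k]
                + [-g.fitness[k]]  # transversal eigenvalue along e(k)
            )
            assert np.abs(numeric - analytic).max() < 1e-6


class TestLogisticEdge:
    def test_absorbing_endpoints_and_midpoint(self):
        assert ss.logistic_edge_solution(0.0, 2.0, 1.0, 5.0) == 0.0
        assert ss.logistic_edge_solution(1.0, 2.0, 1.0, 5.0) == 1.0
        assert ss.logistic_edge_solution(0.5, 2.0, 1.0, 0.0) == pytest.approx(0.5)

    @given(
        xi0=st.floats(0.01, 0.99),
        fi=st.floats(1.1, 3.0),
        fk=st.floats(0.1, 1.0),
        t=st.floats(-3, 3),
    )
    def test_matches_two_type_closed_form(self, xi0, fi, fk, t):
        g = ss.build_landscape(["k", "i"], {"k": fk, "i": fi})
        full = ss.closed_form_solution([1 - xi0, xi0], g, t)[1]
        edge = ss.logistic_edge_solution(xi0, fi, fk, t)
        assert abs(full - edge) < 1e-12


class TestSweepTime:
    def test_values_and_scaling(self):
        assert ss.sweep_time(math.e**2, 1.0) == pytest.approx(2.0)
        assert ss.sweep_time(1000, 0.2) == pytest.approx(2 * ss.sweep_time(1000, 0.4))

    def test_logistic_traversal_is_two_sweep_times(self):
        # time from x=1/N to x=1-1/N under dx/dt = s x(1-x) is 2 ln(N-1)/s
        N, s = 10_000.0, 0.37
        t_traverse = (math.log((1 - 1 / N) / (1 / N)) - math.log((1 / N) / (1 - 1 / N))) / s
        assert t_traverse == pytest.approx(2 * math.log(N - 1) / s)
        assert t_traverse / ss.sweep_time(N, s) == pytest.approx(2.0, rel=1e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            ss.sweep_time(1, 0.1)
        with pytest.raises(ValueError):
            ss.sweep_time(100, 0.0)


class TestFractionsCoercion:
    def test_dict_and_array_agree(self, three_type):
        assert np.allclose(
            as_fractions(three_type, {"a": 0.2, "b": 0.3, "c": 0.5}),
            [0.2, 0.3, 0.5],
        )

    def test_rejects_off_simplex(self, three_type):
        with pytest.raises(ValueError):
            as_fractions(three_type, [0.5, 0.5, 0.5])
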