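"""Exact Moran jump-process simulation: rates, conservation, fixation laws,
and agreement between the fast kernel and the reference engine."""

import math

import numpy as np
import pytest

import saddlescape as ss
from saddlescape.moran import as_counts, child_seeds, run_to_fixation, simulate


class TestRateTable:
    def test_monomorphic_without_mutation_is_absorbing(self, two_type):
        rates = ss.total_rates(np.array([100, 0]), two_type, 0.0)
        assert rates.total == 0.0 and not rates.reproduction

    def test_two_individual_example(self, two_type):
        # N=2, one of each, f=(1,2): replacement rates 0.5 and 1.0
        rates = ss.total_rates(np.array([1, 1]), two_type, 0.0)
        assert rates.reproduction[("a", "b")] == pytest.approx(0.5)
        assert rates.reproduction[("b", "a")] == pytest.approx(1.0)
        assert rates.total == pytest.approx(1.5)

    def test_mutation_adds_lambda_N_xi_per_edge(self, three_type):
        lam = 0.01
        counts = np.array([50, 50, 0])
        r0 = ss.total_rates(counts, three_type, 0.0)
        r1 = ss.total_rates(counts, three_type, lam)
        # each present type has 2 incident edges and x_i = 1/2
        assert r1.total - r0.total == pytest.approx(4 * 100 * lam * 0.5)
        assert r1.mutation[("a", "b")] == pytest.approx(100 * lam * 0.5)


class TestSimulateBasics:
    def test_single_type_no_events(self):
        g = ss.build_landscape(["a"], {"a": 1.0})
        traj = simulate(g, 50, 0.0, ("monomorphic", "a"), 10.0, seed=1)
        assert traj.n_events == 0 and traj.stop_reason == "absorbed"
        assert np.array_equal(traj.final_counts, traj.initial_counts)

    def test_two_type_always_absorbs(self, two_type):
        for seed in range(5):
            traj = simulate(
                g := two_type, 40, 0.0, {"a": 20, "b": 20}, math.inf, seed,
                recording="none", stop_when_monomorphic=True,
            )
            assert traj.stop_reason == "monomorphic"
            assert set(np.unique(traj.final_counts)) <= {0, 40}

    def test_population_conserved_on_grid(self, three_type):
        traj = simulate(three_type, 200, 0.005, "uniform", 30.0, seed=3,
                        recording="grid", grid_dt=0.5)
        assert np.all(traj.counts.sum(axis=1) == 200)

    def test_support_never_grows_without_mutation(self, four_type_complete):
        traj = simulate(four_type_complete, 100, 0.0, "uniform", 50.0, seed=9,
                        recording="grid", grid_dt=0.5)
        supports = traj.counts > 0
        for k in range(1, len(supports)):
            assert np.all(supports[k] <= supports[k - 1])

    def test_invalid_inputs(self, two_type):
        with pytest.raises(ValueError):
            simulate(two_type, 10, 0.0, {"a": 5, "b": 4}, 1.0, seed=1)
        with pytest.raises(ValueError):
            simulate(two_type, 10, 0.0, "uniform", -1.0, seed=1)
        with pytest.raises(ValueError):
            as_counts(two_type, {"a": -1, "b": 11}, 10)

    def test_determinism_same_seed_same_trajectory(self, three_type):
        run = lambda: simulate(
            three_type, 150, 0.001, "uniform", 40.0, seed=77, recording="grid",
            grid_dt=1.0,
        )
        a, b = run(), run()
        assert np.array_equal(a.counts, b.counts)
        assert a.t_end == b.t_end and a.n_events == b.n_events


class TestEventRecordsAndReplay:
    def test_replay_reproduces_final_state(self, three_type):
        traj = simulate(three_type, 60, 0.01, "uniform", 20.0, seed=5,
                        recording="events")
        assert traj.events, "expected at least one event"
        times = [e.time for e in traj.events]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))
        replayed = ss.replay_events(three_type, traj.initial_counts, traj.events)
        assert np.array_equal(replayed, traj.final_counts)

    def test_mutations_only_along_edges(self):
        g = ss.staircase_landscape(4, 1.0, 0.2)
        traj = simulate(g, 40, 0.05, ("monomorphic", "0"), 30.0, seed=8,
                        recording="events")
        muts = [e for e in traj.events if e.kind == "mutation"]
        assert muts, "expected mutation events at this rate"
        for e in muts:
            assert e.target in g.neighbors(e.source)

    def test_null_event_equivalence(self, two_type):
        """Including rate-N f_i x_i^2 self-replacement events (which do not
        change the state) must leave the law unchanged: fixation-probability
        estimates agree within 3 combined SE."""
        N, reps = 30, 400

        def fix_freq(include_null, seed):
            seeds = child_seeds(seed, reps)
            fixed = 0
            for r in range(reps):
                traj = simulate(
                    two_type, N, 0.0, {"a": N - 1, "b": 1}, math.inf,
                    int(seeds[r]), recording="events", engine="reference",
                    stop_on_type="b", include_self_replacement=include_null,
                )
                fixed += traj.stop_reason == "type_fixed"
            return fixed / reps

        p_plain = fix_freq(False, 101)
        p_null = fix_freq(True, 202)
        se = math.sqrt(2 * 0.25 / reps)
        assert abs(p_plain - p_null) < 3 * se


class TestFixationLaw:
    def test_certain_fixation_from_full_population(self, two_type):
        p, se = ss.estimate_fixation_probability(two_type, 50, "b", 50, 10, seed=1)
        assert p == 1.0

    def test_smallest_chain_matches_exact_birth_death(self, two_type):
        # N=2 from one copy each: exact fixation probability of the fitter
        # type is (1-rho)/(1-rho^2) = 2/3
        reps = 2000
        seeds = child_seeds(99, reps)
        wins = 0
        for r in range(reps):
            w, _ = run_to_fixation(two_type, 2, {"a": 1, "b": 1}, int(seeds[r]))
            wins += w == "b"
        exact = ss.rw_fixation_probability(2.0, 1.0, 2, 1)
        assert exact == pytest.approx(2 / 3)
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(wins / reps - exact) < 3 * se

    def test_engines_agree_on_fixation_probability(self, two_type):
        """Differential test: numba kernel vs full-recompute reference."""
        N, reps = 30, 300
        exact = ss.rw_fixation_probability(2.0, 1.0, N, 1)
        p_fast, se_fast = ss.estimate_fixation_probability(
            two_type, N, "b", 1, reps, seed=7
        )
        seeds = child_seeds(8, reps)
        fixed = 0
        for r in range(reps):
            traj = simulate(
                two_type, N, 0.0, {"a": N - 1, "b": 1}, math.inf, int(seeds[r]),
                recording="events", engine="reference", stop_on_type="b",
            )
            fixed += traj.stop_reason == "type_fixed"
        p_ref = fixed / reps
        se = math.sqrt(2 * exact * (1 - exact) / reps)
        assert abs(p_fast - p_ref) < 3 * se
        assert abs(p_fast - exact) < 3 * math.sqrt(exact * (1 - exact) / reps)

    def test_single_mutant_fixation_does_not_decay_with_N(self, two_type):
        # the N-free lower bound: estimates at N=100 and N=1000 are comparable
        p_100, _ = ss.estimate_fixation_probability(two_type, 100, "b", 1, 600, seed=3)
        p_1000, _ = ss.estimate_fixation_probability(two_type, 1000, "b", 1, 600, seed=4)
        assert p_1000 >= p_100 / 2
        assert p_100 > 0.3  # 1 - rho = 0.5 at this fitness ratio

    def test_near_fixation_start_fixes_fittest(self, two_type):
        N = 200
        seeds = child_seeds(55, 50)
        wins = sum(
            run_to_fixation(two_type, N, {"a": 1, "b": N - 1}, int(s))[0] == "b"
            for s in seeds
        )
        assert wins >= 49  # extinction from 1-1/N is vanishingly unlikely

    def test_conditional_fixation_time_scales_like_logN(self, two_type):
        # mean time to fixation of the fitter type from an even split grows
        # like ln(N)/s; the log-linear slope must sit within 30% of 1/s = 1
        means = []
        Ns = (100, 1000, 10000)
        for N in Ns:
            seeds = child_seeds(500 + N, 40)
            ts = [
                t
                for w, t in (
                    run_to_fixation(two_type, N, {"a": N // 2, "b": N - N // 2}, int(s))
                    for s in seeds
                )
                if w == "b"
            ]
            means.append(np.mean(ts))
        slope = np.polyfit(np.log(Ns), means, 1)[0]
        assert abs(slope - 1.0) < 0.3


class TestEmbeddedChain:
    def test_jump_chain_is_asymmetric_walk(self, two_type):
        """For two types the jump chain steps up with probability
        p = f*/(f*+f**) independently of the state; realized frequencies
        over >= 1e5 jumps must match within 3 SE."""
        N = 100
        p_expect = 2.0 / 3.0
        up = total = 0
        seeds = child_seeds(123, 4000)
        i = 0
        while total < 100_000:
            traj = simulate(
                two_type, N, 0.0, {"a": N // 2, "b": N // 2}, math.inf,
                int(seeds[i]), recording="none", stop_when_monomorphic=True,
            )
            i += 1
            up += int(traj.gain_counts[1])
            total += int(traj.n_events)
        se = math.sqrt(p_expect * (1 - p_expect) / total)
        assert abs(up / total - p_expect) < 3 * se
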