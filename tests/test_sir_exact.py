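"""Exact outbreak-size solver: transition rule, closed forms, oracles."""

from fractions import Fraction

import numpy as np
import pytest

from sirpredict.graphspace import Graph, enumerate_connected_graphs, node_orbits
from sirpredict.sir_exact import (
    DEFAULT_BETAS,
    SIRParameters,
    expected_outbreak_size,
    gillespie_estimate,
    markov_oracle,
    outbreak_table,
    successor_distribution,
)

S, I, R = 0, 1, 2


class TestParameters:
    def test_default_grid_is_dyadic_sixteenths(self):
        assert DEFAULT_BETAS[0] == 1 / 16 and DEFAULT_BETAS[-1] == 16
        assert len(DEFAULT_BETAS) == 9
        assert all(b2 == 2 * b1 for b1, b2 in zip(DEFAULT_BETAS, DEFAULT_BETAS[1:]))

    @pytest.mark.parametrize("betas", [(), (0.0, 1.0), (-1.0,), (1.0, 1.0), (2.0, 1.0)])
    def test_invalid_grids_rejected(self, betas):
        with pytest.raises(ValueError):
            SIRParameters(betas)


class TestSuccessorDistribution:
    def test_triangle_seed_splits_two_thirds_infection(self, triangle):
        succ = successor_distribution((I, S, S), triangle, beta=1.0)
        p_inf = sum(p for st, p in succ if st.count(I) == 2)
        p_rec = sum(p for st, p in succ if st.count(R) == 1)
        assert p_inf == pytest.approx(2 / 3)
        assert p_rec == pytest.approx(1 / 3)

    def test_edge_beta3_races_three_to_one(self, single_edge):
        succ = dict(successor_distribution((I, S), single_edge, beta=3.0))
        assert succ[(I, I)] == pytest.approx(3 / 4)
        assert succ[(R, S)] == pytest.approx(1 / 4)

    def test_no_si_edges_pure_recovery(self, path3):
        # infected ends, recovered middle: two recoveries at 1/2 each
        succ = successor_distribution((I, R, I), path3, beta=5.0)
        assert len(succ) == 2
        assert all(p == pytest.approx(0.5) for _, p in succ)

    def test_probabilities_sum_to_one(self, ensemble6):
        rng = np.random.default_rng(0)
        g = ensemble6[17]
        state = tuple(rng.integers(0, 3) for _ in range(6))
        if I not in state:
            state = (I,) + state[1:]
        total = sum(p for _, p in successor_distribution(state, g, beta=0.7))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_absorbing_state_has_no_successors(self, triangle):
        with pytest.raises(ValueError, match="absorbing"):
            successor_distribution((S, R, R), triangle, beta=1.0)


class TestClosedForms:
    def test_single_edge_matches_closed_form_all_betas(self, single_edge, params):
        omega = expected_outbreak_size(single_edge, 0, params)
        for beta in params.betas:
            assert omega[beta] == pytest.approx(1 + beta / (beta + 1), abs=1e-12)

    def test_triangle_beta_one_is_thirteen_sixths(self, triangle):
        omega = expected_outbreak_size(triangle, 0, SIRParameters((1.0,)))
        assert omega[1.0] == pytest.approx(13 / 6, abs=1e-12)

    def test_exact_rational_mode_triangle(self, triangle):
        omega = expected_outbreak_size(triangle, 0, SIRParameters((1.0,)), exact=True)
        assert omega[1.0] == Fraction(13, 6)

    def test_exact_rational_mode_single_edge(self, single_edge):
        omega = expected_outbreak_size(single_edge, 0, SIRParameters((0.0625,)), exact=True)
        assert omega[0.0625] == 1 + Fraction(1, 16) / (Fraction(1, 16) + 1)

    def test_tiny_beta_outbreak_dies_at_seed(self, ensemble6):
        omega = expected_outbreak_size(ensemble6[40], 0, SIRParameters((1e-9,)))
        assert omega[1e-9] == pytest.approx(1.0, abs=1e-6)


class TestMarkovOracle:
    def test_single_edge(self, single_edge):
        assert markov_oracle(single_edge, 0, 1.0) == pytest.approx(1.5, abs=1e-12)

    def test_triangle(self, triangle):
        assert markov_oracle(triangle, 0, 1.0) == pytest.approx(13 / 6, abs=1e-12)

    def test_path_end_high_beta_infects_everyone(self, path3):
        assert markov_oracle(path3, 0, 1e6) == pytest.approx(3.0, abs=1e-4)

    def test_rejects_large_graphs(self):
        g = Graph.from_edges(7, [(i, i + 1) for i in range(6)])
        with pytest.raises(ValueError):
            markov_oracle(g, 0, 1.0)

    def test_agrees_with_solver_on_sampled_graphs(self, params):
        rng = np.random.default_rng(5)
        graphs = enumerate_connected_graphs(5)
        for idx in rng.choice(len(graphs), 6, replace=False):
            g = graphs[idx]
            omega = expected_outbreak_size(g, 0, params)
            for beta in params.betas:
                assert omega[beta] == pytest.approx(markov_oracle(g, 0, beta), abs=1e-10)


class TestSolverInvariants:
    def test_omega_within_bounds_and_increasing_in_beta(self, ensemble6, params):
        rng = np.random.default_rng(11)
        for idx in rng.choice(len(ensemble6), 10, replace=False):
            g = ensemble6[idx]
            omega = expected_outbreak_size(g, 0, params)
            vals = [omega[b] for b in params.betas]
            assert all(1 <= v <= 6 + 1e-12 for v in vals)
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_orbit_equivalent_seeds_computed_independently_agree(self, ensemble6, params):
        rng = np.random.default_rng(3)
        checked = 0
        for idx in rng.permutation(len(ensemble6)):
            g = ensemble6[idx]
            orbit = next((o for o in node_orbits(g).orbits if len(o) > 1), None)
            if orbit is None:
                continue
            a = expected_outbreak_size(g, orbit[0], params)
            b = expected_outbreak_size(g, orbit[1], params)
            for beta in params.betas:
                assert a[beta] == pytest.approx(b[beta], abs=1e-12)
            checked += 1
            if checked == 5:
                break
        assert checked == 5


class TestOutbreakTable:
    def test_triangle_rows_identical_across_seeds(self, triangle, params):
        table = outbreak_table(triangle, params)
        assert len(table) == 3 * 9
        for beta in params.betas:
            vals = table[table.beta == beta].omega.unique()
            assert len(vals) == 1

    def test_star_center_dominates_leaves(self, star4, params):
        table = outbreak_table(star4, params)
        for beta in params.betas:
            sub = table[table.beta == beta].set_index("seed").omega
            assert sub[0] > sub[1]
            assert sub[1] == sub[2] == sub[3]

    def test_complete_graph_single_orbit(self, params):
        k4 = Graph.from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        table = outbreak_table(k4, params)
        assert len(table) == 4 * 9
        assert table.groupby("beta").omega.nunique().max() == 1

    def test_rejects_foreign_orbit_partition(self, triangle, path3, params):
        with pytest.raises(ValueError, match="different graph"):
            outbreak_table(triangle, params, orbits=node_orbits(path3))


class TestGillespie:
    def test_zero_beta_always_one(self, triangle):
        r = gillespie_estimate(triangle, 0, 0.0, n_runs=200, rng_seed=1)
        assert r.mean == 1.0 and r.stderr == 0.0

    def test_single_edge_within_three_stderr(self, single_edge):
        r = gillespie_estimate(single_edge, 0, 1.0, n_runs=100_000, rng_seed=2)
        assert abs(r.mean - 1.5) < 3 * r.stderr

    def test_triangle_within_three_stderr(self, triangle):
        r = gillespie_estimate(triangle, 0, 1.0, n_runs=100_000, rng_seed=3)
        assert abs(r.mean - 13 / 6) < 3 * r.stderr

    def test_exact_solver_within_three_stderr_on_random_triples(self, params):
        # 20 random (graph, seed, beta) triples from the N=4..6 ensembles
        rng = np.random.default_rng(9)
        pool = [g for n in (4, 5, 6) for g in enumerate_connected_graphs(n)]
        misses = 0
        for _ in range(20):
            g = pool[rng.integers(len(pool))]
            seed = int(rng.integers(g.n_nodes))
            beta = float(params.betas[rng.integers(len(params.betas))])
            exact = expected_outbreak_size(g, seed, SIRParameters((beta,)))[beta]
            est = gillespie_estimate(g, seed, beta, n_runs=100_000, rng_seed=int(rng.integers(2**31)))
            if abs(est.mean - exact) >= 3 * max(est.stderr, 1e-12):
                misses += 1
        # one 3-sigma excursion in twenty draws is within expectation
        assert misses <= 1

    def test_run_count_validated(self, triangle):
        with pytest.raises(ValueError):
            gillespie_estimate(triangle, 0, 1.0, n_runs=0, rng_seed=0)
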