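"""Branch-and-bound search: bounds, oracle equivalence, dominance."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pema import PEMAConfig, ValidationError, branch_and_bound_fit, greedy_fit
from pema.bnb import node_upper_bound, plateau_index, score_sequence, score_set
from tests.conftest import make_random_problem


def brute_force_best(problem, k):
    """Independent reference: enumerate all k-subsets, score each by
    repeatedly deflating its best member (plain loops, no search code)."""
    best = (-np.inf, ())
    tss = float(np.sum(problem.V**2))
    for subset in combinations(sorted(problem.kept_mode_ids), k):
        remaining = list(subset)
        V = problem.V.copy()
        captured = 0.0
        order = []
        while remaining:
            gains = {}
            for mid in remaining:
                e = problem.E_norm[:, problem.mode_index(mid)]
                p = np.maximum(e @ V, 0.0)
                gains[mid] = float(p @ p)
            pick = max(sorted(remaining), key=lambda mid: gains[mid])
            e = problem.E_norm[:, problem.mode_index(pick)]
            p = np.maximum(e @ V, 0.0)
            V = V - np.outer(e, p)
            captured += gains[pick]
            order.append(pick)
            remaining.remove(pick)
        theta = captured / tss
        if theta > best[0]:
            best = (theta, tuple(order))
    return best


class TestScoreSequence:
    def test_order_dependence_of_fixed_set(self):
        from pema import EMSet, FluxData, build_problem

        r2 = 1 / np.sqrt(2)
        ems = EMSet(np.array([[1.0, r2], [0.0, r2]]), ("f1", "f2"), ("a", "c"))
        flux = FluxData(np.array([[3.0], [1.0]]), ("f1", "f2"), ("x1",))
        prob = build_problem(flux, ems, PEMAConfig(n_fac=2, scaling_mode="none"))
        theta_ac, _, _ = score_sequence(prob, ("a", "c"))
        theta_ca, _, _ = score_sequence(prob, ("c", "a"))
        assert theta_ac == pytest.approx(0.95, abs=1e-12)
        assert theta_ca == pytest.approx(0.90, abs=1e-12)

    def test_empty_sequence_explains_nothing(self, greedy_trap_problem):
        theta, weights, residual = score_sequence(greedy_trap_problem, ())
        assert theta == 0.0
        np.testing.assert_allclose(residual, greedy_trap_problem.V)

    def test_duplicate_id_rejected(self, greedy_trap_problem):
        with pytest.raises(ValidationError, match="duplicate"):
            score_sequence(greedy_trap_problem, ("a", "a"))

    def test_score_set_uses_greedy_order_within_set(self, greedy_trap_problem):
        theta, order = score_set(greedy_trap_problem, ("c", "a"))
        # within {a, c}: c has the larger root gain on this data
        assert order[0] == "c"


class TestUpperBound:
    def test_zero_residual_bound_equals_theta(self, greedy_trap_problem):
        prob = greedy_trap_problem
        bound = node_upper_bound(0.7, np.zeros_like(prob.V), prob.E_norm, 2, prob.total_ss)
        assert bound == pytest.approx(0.7)

    def test_no_slots_bound_equals_theta(self, greedy_trap_problem):
        prob = greedy_trap_problem
        assert node_upper_bound(0.5, prob.V, prob.E_norm, 0, prob.total_ss) == 0.5

    def test_one_slot_bound_is_attainable(self, greedy_trap_problem):
        prob = greedy_trap_problem
        bound = node_upper_bound(0.0, prob.V, prob.E_norm, 1, prob.total_ss)
        best_single = max(score_sequence(prob, (m,))[0] for m in prob.kept_mode_ids)
        assert bound == pytest.approx(best_single, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bound_dominates_exhaustive_completion(self, seed):
        rng = np.random.default_rng(seed)
        prob, _, _ = make_random_problem(rng, n_mes=4, m=6, n_d=3)
        k = 3
        best_theta, _ = brute_force_best(prob, k)
        bound = node_upper_bound(0.0, prob.V, prob.E_norm, k, prob.total_ss)
        assert bound >= best_theta - 1e-12


class TestBranchAndBound:
    def test_greedy_trap_recovers_generating_pair(self, greedy_trap_problem):
        config = PEMAConfig(n_fac=2, scaling_mode="none")
        result = branch_and_bound_fit(greedy_trap_problem, config)
        final = result.factors[-1]
        assert set(final.selected_ids) == {"a", "b"}
        assert final.theta == pytest.approx(1.0, abs=1e-12)
        greedy_theta = result.greedy.theta_curve[-1]
        assert greedy_theta == pytest.approx(11.7125 / 18.02, abs=1e-12)
        assert final.stats.nodes_evaluated <= final.stats.n_comb_theoretical == 3

    def test_single_matching_candidate(self, rng):
        from pema import EMSet, FluxData, build_problem

        e = rng.uniform(0.1, 1, size=4)
        ems = EMSet(e[:, None], tuple("abcd"), ("only",))
        flux = FluxData(np.outer(e, [2.0, 3.0]), tuple("abcd"), ("x1", "x2"))
        prob = build_problem(flux, ems, PEMAConfig(n_fac=1, scaling_mode="none"))
        result = branch_and_bound_fit(prob, PEMAConfig(n_fac=1, scaling_mode="none"))
        assert result.factors[0].selected_ids == ("only",)
        assert result.factors[0].theta == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 3))
    def test_matches_exhaustive_enumeration(self, seed, k):
        rng = np.random.default_rng(seed)
        prob, _, _ = make_random_problem(rng, n_mes=5, m=8, n_d=3)
        config = PEMAConfig(n_fac=k, scaling_mode="none")
        result = branch_and_bound_fit(prob, config)
        best_theta, _ = brute_force_best(prob, k)
        assert result.factors[-1].theta == pytest.approx(best_theta, abs=1e-12)
        assert result.factors[-1].stats.nodes_evaluated <= comb(prob.m_prime, k)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pruning_never_changes_the_optimum(self, seed):
        rng = np.random.default_rng(seed)
        prob, _, _ = make_random_problem(rng, n_mes=4, m=7, n_d=3)
        config = PEMAConfig(n_fac=3, scaling_mode="none")
        pruned = branch_and_bound_fit(prob, config, prune=True)
        full = branch_and_bound_fit(prob, config, prune=False)
        for fp, ff in zip(pruned.factors, full.factors):
            assert fp.theta == pytest.approx(ff.theta, abs=1e-12)
        assert pruned.stats.nodes_evaluated <= full.stats.nodes_evaluated

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_dominates_greedy_and_monotone_in_k(self, seed):
        rng = np.random.default_rng(seed)
        prob, _, _ = make_random_problem(rng, n_mes=5, m=8, n_d=4)
        config = PEMAConfig(n_fac=4, scaling_mode="none")
        result = branch_and_bound_fit(prob, config)
        greedy = greedy_fit(prob, 4)
        for k, f in enumerate(result.factors, start=1):
            assert f.theta >= greedy.theta_curve[k - 1] - 1e-12
        curve = result.theta_curve
        assert all(curve[i + 1] >= curve[i] - 1e-12 for i in range(len(curve) - 1))

    def test_n_fac_capped_with_warning(self, rng, caplog):
        prob, _, _ = make_random_problem(rng, n_mes=3, m=6)
        with caplog.at_level("WARNING"):
            result = branch_and_bound_fit(prob, PEMAConfig(n_fac=10, scaling_mode="none"))
        assert len(result.factors) == 3
        assert "capped" in caplog.text

    def test_node_budget_flags_not_proven(self, rng):
        prob, _, _ = make_random_problem(rng, n_mes=5, m=9, n_d=4)
        config = PEMAConfig(n_fac=4, scaling_mode="none", max_evals=1)
        result = branch_and_bound_fit(prob, config)
        assert not result.factors[-1].stats.proven_optimal
        # budgeted result still dominates the greedy initialization
        greedy = greedy_fit(prob, 4)
        assert result.factors[-1].theta >= greedy.theta_curve[-1] - 1e-12

    def test_active_set_recovery_well_separated(self, rng):
        """Noise-free data from well-separated modes is recovered exactly."""
        from pema import EMSet, FluxData, build_problem
        from pema.synthetic import simulate_flux_data

        # orthogonal generating modes plus correlated decoys
        E = np.eye(4)
        decoys = rng.uniform(0.1, 1.0, size=(4, 4))
        ems = EMSet(
            np.hstack([E[:, :3], decoys]),
            tuple("abcd"),
            ("g1", "g2", "g3", "d1", "d2", "d3", "d4"),
        )
        flux, truth = simulate_flux_data(ems, ("g1", "g2", "g3"), n_experiments=5, seed=7)
        prob = build_problem(flux, ems, PEMAConfig(n_fac=3, scaling_mode="none"))
        result = branch_and_bound_fit(prob, PEMAConfig(n_fac=3, scaling_mode="none"))
        assert set(result.factors[-1].selected_ids) == {"g1", "g2", "g3"}
        assert result.factors[-1].theta == pytest.approx(1.0, abs=1e-10)


class TestPlateau:
    def test_flat_after_saturation(self):
        assert plateau_index([0.6, 1.0, 1.0, 1.0]) == 2

    def test_tiny_gain_at_the_end(self):
        curve = [0.2, 0.4, 0.6, 0.7, 0.8, 0.86, 0.9, 0.93, 0.95, 0.9501]
        assert plateau_index(curve) == 9

    def test_no_plateau_returns_curve_length(self):
        assert plateau_index([0.3, 0.6, 0.9]) == 3
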