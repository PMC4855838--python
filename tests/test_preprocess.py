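"""Pre-selection: scaling, direction filtering, ambiguity grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pema import EMSet, FluxData, PEMAConfig, ValidationError, build_problem, greedy_fit
from pema.preprocess import detect_ambiguous, filter_by_direction, mean_scale
from tests.conftest import make_random_problem


def _toy(V, E, flux_ids=None, mode_ids=None):
    V = np.asarray(V, float)
    E = np.asarray(E, float)
    n_mes, m = E.shape
    flux_ids = flux_ids or tuple(f"r{i}" for i in range(n_mes))
    mode_ids = mode_ids or tuple(f"m{j}" for j in range(m))
    return (
        FluxData(np.asarray(V, float), flux_ids, tuple(f"x{k}" for k in range(np.shape(V)[1]))),
        EMSet(np.asarray(E, float), flux_ids, mode_ids),
    )


class TestMeanScale:
    def test_abs_mean_divides_by_mean_magnitude(self):
        flux, ems = _toy([[2.0, 4.0]], [[1.0]])
        V, E, factors, kept = mean_scale(flux, ems, "abs_mean")
        assert factors["r0"] == pytest.approx(3.0)
        np.testing.assert_allclose(V, [[2 / 3, 4 / 3]])
        np.testing.assert_allclose(E, [[1 / 3]])

    def test_signed_mean_zero_drops_row_with_warning(self, caplog):
        flux, ems = _toy([[-2.0, 2.0], [1.0, 1.0]], [[1.0], [1.0]])
        with caplog.at_level("WARNING"):
            V, E, factors, kept = mean_scale(flux, ems, "signed_mean")
        assert kept == ("r1",)
        assert "r0" in caplog.text
        assert V.shape == (1, 2)

    def test_none_mode_returns_unit_factors(self):
        flux, ems = _toy([[5.0, -1.0]], [[2.0]])
        V, E, factors, _ = mean_scale(flux, ems, "none")
        assert factors["r0"] == 1.0
        np.testing.assert_allclose(V, flux.values)


class TestDirectionFilter:
    def test_opposing_mode_removed_for_consistent_flux(self):
        # oxygen uptake positive in all experiments; a mode consuming it
        # in reverse violates non-cancellation
        V = np.array([[1.0, 2.0, 0.5]])
        E = np.array([[-0.3, 0.8]])
        _, kept, removed = filter_by_direction(E, V, ("bad", "good"), flux_ids=("vO2",))
        assert removed == ("bad",)
        assert kept == ("good",)

    def test_mixed_sign_flux_imposes_no_constraint(self):
        V = np.array([[1.0, -1.0]])
        E = np.array([[-0.3, 0.8]])
        _, kept, removed = filter_by_direction(E, V, ("a", "b"), flux_ids=("v1",))
        assert removed == ()

    def test_zero_entry_is_kept(self):
        V = np.array([[1.0, 2.0]])
        E = np.array([[0.0]])
        _, kept, removed = filter_by_direction(E, V, ("a",), flux_ids=("v1",))
        assert kept == ("a",)

    def test_off_mode_disables_filtering(self):
        V = np.array([[1.0, 2.0]])
        E = np.array([[-1.0]])
        _, kept, removed = filter_by_direction(E, V, ("a",), mode="off")
        assert kept == ("a",)


class TestAmbiguity:
    def test_positively_proportional_restrictions_group(self):
        E = np.array([[1.0, 2.0], [0.0, 0.0]])
        _, kept, report, removed_zero = detect_ambiguous(E, ("a", "b"))
        assert kept == ("a",)  # lowest id is the representative
        assert report.groups == (("a", "b"),)

    def test_zero_restriction_removed(self):
        E = np.array([[1.0, 0.0], [0.0, 0.0]])
        _, kept, report, removed_zero = detect_ambiguous(E, ("a", "b"))
        assert removed_zero == ("b",)
        assert kept == ("a",)

    def test_opposite_directions_not_grouped(self):
        E = np.array([[1.0, -1.0], [0.0, 0.0]])
        _, kept, report, _ = detect_ambiguous(E, ("a", "b"))
        assert kept == ("a", "b")
        assert report.groups == ()

    def test_opposite_modes_differ_under_nonnegative_weights(self):
        # on data [[1],[0]] the mode [1,0] explains everything, [-1,0]
        # nothing: opposite restrictions are genuinely different modes
        flux, ems = _toy([[1.0], [0.0]], [[1.0, -1.0], [0.0, 0.0]], mode_ids=("pos", "neg"))
        prob = build_problem(flux, ems, PEMAConfig(n_fac=1, scaling_mode="none",
                                                   direction_filter_mode="off"))
        thetas = {}
        for mid in ("pos", "neg"):
            from pema.bnb import score_sequence

            thetas[mid], _, _ = score_sequence(prob, (mid,))
        assert thetas["pos"] == pytest.approx(1.0)
        assert thetas["neg"] == pytest.approx(0.0)


class TestBuildProblem:
    def test_identity_toy_norms_and_kept(self):
        flux, ems = _toy(
            [[1.0, 2.0], [2.0, 1.0]],
            [[1.0, 0.0, 3.0], [0.0, 1.0, 4.0]],
            mode_ids=("a", "b", "c"),
        )
        prob = build_problem(flux, ems, PEMAConfig(n_fac=2, scaling_mode="none"))
        assert prob.kept_mode_ids == ("a", "b", "c")
        np.testing.assert_allclose(prob.column_norms, [1.0, 1.0, 5.0])
        np.testing.assert_allclose(np.linalg.norm(prob.E_norm, axis=0), 1.0, atol=1e-12)

    def test_duplicate_restriction_reduces_m(self):
        flux, ems = _toy(
            [[1.0, 2.0]],
            [[1.0, 2.0, 3.0]],
            mode_ids=("a", "b", "c"),
        )
        prob = build_problem(flux, ems, PEMAConfig(n_fac=1, scaling_mode="none"))
        assert prob.m_prime == 1

    def test_no_surviving_modes_raises(self):
        flux, ems = _toy([[1.0, 2.0]], [[-1.0]])
        with pytest.raises(ValidationError, match="no feasible"):
            build_problem(flux, ems, PEMAConfig(n_fac=1, scaling_mode="none"))

    def test_partition_property_on_random_problems(self, rng):
        for _ in range(20):
            n_mes, m = 4, 10
            E = rng.normal(size=(n_mes, m))
            E[:, rng.integers(m)] = 0.0
            E[:, E.any(axis=0).argmin()] += 1e-16  # keep EMSet validation happy
            E[np.abs(E) < 0.2] = 0.0
            for j in range(m):
                if not E[:, j].any():
                    E[0, j] = 1.0
            V = rng.uniform(0.1, 1, size=(n_mes, 3))
            flux, ems = _toy(V, E)
            prob = build_problem(flux, ems, PEMAConfig(n_fac=1))
            n_grouped_away = sum(len(g) - 1 for g in prob.ambiguity.groups)
            assert (
                prob.m_prime
                + len(prob.removed_by_direction)
                + len(prob.removed_zero_measured)
                + n_grouped_away
            ) == m

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_mode_scale_invariance(self, seed, scale):
        """Unit normalization makes results invariant to column rescaling."""
        rng = np.random.default_rng(seed)
        prob1, ems, flux = make_random_problem(rng, m=6)
        E2 = ems.modes.copy()
        E2[:, 2] *= scale
        ems2 = EMSet(E2, ems.reaction_ids, ems.mode_ids)
        prob2 = build_problem(flux, ems2, PEMAConfig(n_fac=3, scaling_mode="none"))
        t1 = greedy_fit(prob1, 3)
        t2 = greedy_fit(prob2, 3)
        assert t1.selected_ids == t2.selected_ids
        np.testing.assert_allclose(t1.theta_curve, t2.theta_curve, atol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mode_order_invariance(self, seed):
        """Selection does not depend on the column order of the input file."""
        rng = np.random.default_rng(seed)
        prob1, ems, flux = make_random_problem(rng, m=6)
        perm = rng.permutation(ems.m)
        ems2 = EMSet(ems.modes[:, perm], ems.reaction_ids, tuple(ems.mode_ids[j] for j in perm))
        prob2 = build_problem(flux, ems2, PEMAConfig(n_fac=3, scaling_mode="none"))
        t1 = greedy_fit(prob1, 3)
        t2 = greedy_fit(prob2, 3)
        assert t1.selected_ids == t2.selected_ids
        np.testing.assert_allclose(t1.theta_curve, t2.theta_curve, atol=1e-10)

    def test_flux_row_rescaling_cancels_out(self, rng):
        """Pre-multiplying a flux row of both inputs by a positive constant
        is undone by mean scaling, leaving the solution unchanged."""
        prob1, ems, flux = make_random_problem(rng, m=6, scaling="abs_mean")
        c = 7.3
        V2 = flux.values.copy()
        V2[1] *= c
        E2 = ems.modes.copy()
        E2[1] *= c
        flux2 = FluxData(V2, flux.flux_ids, flux.experiment_ids)
        ems2 = EMSet(E2, ems.reaction_ids, ems.mode_ids)
        prob2 = build_problem(flux2, ems2, PEMAConfig(n_fac=3, scaling_mode="abs_mean"))
        t1 = greedy_fit(prob1, 3)
        t2 = greedy_fit(prob2, 3)
        assert t1.selected_ids == t2.selected_ids
        np.testing.assert_allclose(t1.theta_curve, t2.theta_curve, atol=1e-10)
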