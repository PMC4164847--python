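"""The FAHP calculus: aggregation, transforms, and priority vectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fahp
from fahp.errors import ConvergenceError, DegenerateMatrixError, ValidationError

from conftest import all_3x3_judgments

SCORE = st.sampled_from([0.0, 0.5, 1.0])


def panel_from_votes(votes):
    """A two-child panel with the given vote list for the single pair."""
    return fahp.ExpertPanel("n", ("a", "b"), {("a", "b"): tuple(votes)})


class TestAggregateScores:
    def test_plurality_wins(self):
        # seven experts: three give 0, two 0.5, two 1 -> 0 wins
        f = fahp.aggregate_scores(
            panel_from_votes([0, 0, 0.5, 1, 0.5, 0, 1])).f
        assert f[0, 1] == 0.0 and f[1, 0] == 1.0

    def test_single_expert(self):
        f = fahp.aggregate_scores(panel_from_votes([1.0])).f
        assert f[0, 1] == 1.0 and f[1, 0] == 0.0 and f[0, 0] == 0.5

    @pytest.mark.parametrize("votes", [
        (0.0, 1.0),                    # extremes tie
        (0.0, 0.5),                    # middle ties one extreme
        (0.0, 0.0, 1.0, 1.0, 0.5),     # extremes tie above the middle
    ])
    def test_ties_resolve_to_equal_importance(self, votes):
        f = fahp.aggregate_scores(panel_from_votes(votes)).f
        assert f[0, 1] == 0.5

    @settings(max_examples=200, deadline=None)
    @given(st.lists(SCORE, min_size=1, max_size=9))
    def test_aggregation_is_symmetric(self, votes):
        """Aggregating the complementary panel must complement the result."""
        direct = fahp.aggregate_scores(panel_from_votes(votes)).f
        flipped = fahp.aggregate_scores(
            panel_from_votes([1.0 - v for v in votes])).f
        assert direct[0, 1] == pytest.approx(1.0 - flipped[0, 1])


class TestToConsistent:
    def test_three_by_three_worked_example(self, goal_consistent):
        expected = np.array([
            [0.5, 2 / 3, 5 / 6],
            [1 / 3, 0.5, 2 / 3],
            [1 / 6, 1 / 3, 0.5],
        ])
        np.testing.assert_allclose(goal_consistent.r, expected, atol=1e-12)
        # matches the published 3-d.p. rendering
        assert round(goal_consistent.r[0, 2], 3) == 0.833

    def test_indifferent_matrix_stays_indifferent(self):
        f = fahp.FuzzyJudgmentMatrix(np.full((4, 4), 0.5))
        r = fahp.to_consistent(f).r
        np.testing.assert_allclose(r, 0.5, atol=1e-15)

    def test_five_by_five_entry(self, case):
        r = fahp.to_consistent(
            fahp.aggregate_scores(case.panels["C11"])).r
        # row sums (0.5, 2.5, 4, 4, 1.5): r_31 = (4 - 0.5)/10 + 0.5
        assert r[2, 0] == pytest.approx(0.85, abs=1e-12)

    def test_additive_consistency_on_random_panels(self, random_panels):
        for panel in random_panels:
            r = fahp.to_consistent(fahp.aggregate_scores(panel)).r
            n = len(r)
            # r_ij = r_ik - r_jk + 0.5 for all triples
            lhs = np.broadcast_to(r[:, :, None], (n, n, n))
            rhs = r[:, None, :] - r[None, :, :] + 0.5
            assert np.abs(lhs - rhs).max() < 1e-12

    def test_complementarity_preserved(self, random_panels):
        for panel in random_panels[:50]:
            f = fahp.aggregate_scores(panel).f
            assert np.all(f + f.T == 1.0)


class TestDirectWeightMethods:
    def test_normalizing_worked_example(self, goal_consistent):
        w = fahp.weights_normalizing(goal_consistent).w
        np.testing.assert_allclose(
            np.round(w, 4), [0.4444, 0.3333, 0.2222])

    def test_sqrt_worked_example(self, goal_consistent):
        w = fahp.weights_sqrt(goal_consistent).w
        # published to 4 d.p. from 3-d.p. intermediates
        np.testing.assert_allclose(w, [0.4543, 0.3347, 0.2110], atol=2e-4)

    @pytest.mark.parametrize("method", [fahp.weights_normalizing,
                                        fahp.weights_sqrt])
    def test_uniform_matrix_gives_uniform_weights(self, method):
        r = fahp.to_consistent(fahp.FuzzyJudgmentMatrix(np.full((4, 4), 0.5)))
        np.testing.assert_allclose(method(r).w, 0.25, atol=1e-12)

    def test_normalizing_five_by_five(self, case):
        r = fahp.to_consistent(fahp.aggregate_scores(case.panels["C11"]))
        np.testing.assert_allclose(
            fahp.weights_normalizing(r).w, [0.12, 0.20, 0.26, 0.26, 0.16],
            atol=1e-12)

    def test_sqrt_two_by_two_closed_form(self):
        # r_12 = 0.75: w ~ (sqrt(0.5*0.75), sqrt(0.25*0.5)), normalized
        r = fahp.FuzzyConsistentMatrix(
            r=np.array([[0.5, 0.75], [0.25, 0.5]]), row_sums=np.array([2., 1.]))
        np.testing.assert_allclose(
            fahp.weights_sqrt(r).w, [0.634, 0.366], atol=1e-3)

    def test_sqrt_rejects_zero_entries(self):
        r = fahp.extreme_consistent_matrix(3)
        assert r.r.min() == 0.0
        with pytest.raises(DegenerateMatrixError):
            fahp.weights_sqrt(r)


class TestToReciprocal:
    def test_worked_example_entries(self, goal_consistent):
        e = fahp.to_reciprocal(goal_consistent).e
        # exact ratios; the published rendering (2.0030, 4.9880) comes from
        # 3-d.p. intermediates, so allow that rounding propagation
        assert e[0, 1] == pytest.approx(2.0, abs=1e-12)
        assert e[0, 2] == pytest.approx(5.0, abs=1e-12)
        assert e[0, 1] == pytest.approx(2.0030, abs=0.005)
        assert e[0, 2] == pytest.approx(4.9880, abs=0.015)

    def test_indifference_maps_to_ones(self):
        r = fahp.to_consistent(fahp.FuzzyJudgmentMatrix(np.full((3, 3), 0.5)))
        np.testing.assert_allclose(fahp.to_reciprocal(r).e, 1.0)

    def test_five_by_five_entry(self, case):
        r = fahp.to_consistent(fahp.aggregate_scores(case.panels["C11"]))
        e = fahp.to_reciprocal(r).e
        assert e[2, 4] == pytest.approx(3.0, abs=1e-12)

    def test_extreme_entries_rejected_with_pair(self):
        r = fahp.extreme_consistent_matrix(3)
        with pytest.raises(DegenerateMatrixError,
                           match=r"\(.*0.*1.*\)|\(.*1.*0.*\)"):
            fahp.to_reciprocal(r)

    def test_reciprocity_on_random_panels(self, random_panels):
        for panel in random_panels:
            r = fahp.to_consistent(fahp.aggregate_scores(panel))
            try:
                e = fahp.to_reciprocal(r).e
            except DegenerateMatrixError:
                continue
            assert np.abs(e * e.T - 1.0).max() < 1e-9


class TestPowerIterate:
    def test_worked_example(self, goal_consistent):
        e = fahp.to_reciprocal(goal_consistent)
        wv = fahp.power_iterate(e, fahp.weights_normalizing(goal_consistent))
        assert wv.lambda_max == pytest.approx(3.0061, abs=2e-3)
        np.testing.assert_allclose(
            wv.w, [0.5954, 0.2763, 0.1283], atol=2e-3)
        assert wv.iterations <= 6

    def test_consistent_indifference_converges_immediately(self):
        e = fahp.ReciprocalMatrix(np.ones((4, 4)))
        wv = fahp.power_iterate(e, np.full(4, 0.25))
        np.testing.assert_allclose(wv.w, 0.25, atol=1e-12)
        assert wv.lambda_max == pytest.approx(4.0, abs=1e-9)
        assert wv.iterations <= 2

    def test_matches_dense_eigendecomposition(self, random_panels):
        for panel in random_panels:
            r = fahp.to_consistent(fahp.aggregate_scores(panel))
            try:
                e = fahp.to_reciprocal(r)
            except DegenerateMatrixError:
                continue
            wv = fahp.power_iterate(e, fahp.weights_normalizing(r),
                                    tol=1e-10, max_iter=10_000)
            vals, vecs = np.linalg.eig(e.e)
            lead = np.argmax(vals.real)
            principal = np.abs(vecs[:, lead].real)
            principal /= principal.sum()
            np.testing.assert_allclose(wv.w, principal, atol=1e-6)
            # Perron bound for positive reciprocal matrices
            assert wv.lambda_max >= e.n - 1e-6

    def test_nonconvergence_raises(self, goal_consistent):
        e = fahp.to_reciprocal(goal_consistent)
        with pytest.raises(ConvergenceError):
            fahp.power_iterate(e, fahp.weights_normalizing(goal_consistent),
                               tol=1e-12, max_iter=1)

    def test_seed_must_match_and_be_positive(self, goal_consistent):
        e = fahp.to_reciprocal(goal_consistent)
        with pytest.raises(ValidationError):
            fahp.power_iterate(e, np.array([0.5, 0.5]))
        with pytest.raises(ValidationError):
            fahp.power_iterate(e, np.array([0.5, -0.1, 0.6]))


class TestNodeWeights:
    def test_goal_panel_iterative(self, case):
        wv = fahp.node_weights(case.panels["A"], method="iterative")
        np.testing.assert_allclose(wv.w, [0.5954, 0.2763, 0.1283], atol=2e-3)

    def test_criterion_panel_iterative(self, case):
        wv = fahp.node_weights(case.panels["C11"], method="iterative")
        np.testing.assert_allclose(
            wv.w, [0.0647, 0.1665, 0.3310, 0.3310, 0.1068], atol=2e-3)

    def test_unknown_method_rejected(self, case):
        with pytest.raises(ValidationError):
            fahp.node_weights(case.panels["A"], method="magic")

    @pytest.mark.parametrize("method", ["normalizing", "sqrt", "iterative"])
    def test_all_methods_preserve_row_sum_order_exhaustively(self, method):
        """Across every complementary 3x3 judgment matrix, each weight
        method ranks children exactly as the judgment row sums do."""
        for judgment in all_3x3_judgments():
            consistent = fahp.to_consistent(judgment)
            try:
                if method == "normalizing":
                    wv = fahp.weights_normalizing(consistent)
                elif method == "sqrt":
                    wv = fahp.weights_sqrt(consistent)
                else:
                    wv = fahp.power_iterate(
                        fahp.to_reciprocal(consistent),
                        fahp.weights_normalizing(consistent))
            except DegenerateMatrixError:
                continue  # unanimous extremes: sqrt/reciprocal undefined
            r_i = judgment.row_sums()
            for i in range(3):
                for j in range(3):
                    if r_i[i] > r_i[j]:
                        assert wv.w[i] > wv.w[j]
                    elif r_i[i] == r_i[j]:
                        assert wv.w[i] == pytest.approx(wv.w[j], abs=1e-9)

    def test_weights_sum_to_one(self, random_panels):
        for panel in random_panels[:50]:
            for method in ("normalizing", "sqrt", "iterative"):
                try:
                    wv = fahp.node_weights(panel, method=method)
                except DegenerateMatrixError:
                    continue
                assert abs(wv.w.sum() - 1.0) < 1e-9
                assert (wv.w > 0).all()
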