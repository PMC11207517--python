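"""AHP weights, entropy weighting and TOPSIS scoring."""

import numpy as np
import pandas as pd
import pytest

from tepqual.exceptions import InputError
from tepqual.mcdm import (
    ComprehensiveQualityScorer,
    JudgmentMatrix,
    WeightVector,
    ahp_weights,
    combined_weights,
    comprehensive_quality,
    entropy_weights,
    minmax_standardize,
    topsis_closeness,
)
from tepqual.quality import load_fixture_table, records_to_frame


class TestAhp:
    def test_all_ones_matrix(self):
        jm = JudgmentMatrix(("a", "b", "c"), np.ones((3, 3)))
        result = ahp_weights(jm)
        np.testing.assert_allclose(result.weights.weights, [1 / 3] * 3, atol=1e-10)
        assert result.consistency_ratio == pytest.approx(0.0, abs=1e-9)

    def test_two_by_two_closed_form(self):
        jm = JudgmentMatrix(("a", "b"), [[1.0, 3.0], [1 / 3, 1.0]])
        result = ahp_weights(jm)
        np.testing.assert_allclose(result.weights.weights, [0.75, 0.25], atol=1e-10)

    def test_consistent_ratio_matrix(self):
        w = np.array([4.0, 2.0, 1.0])
        jm = JudgmentMatrix(("a", "b", "c"), np.outer(w, 1.0 / w))
        result = ahp_weights(jm)
        np.testing.assert_allclose(result.weights.weights, w / w.sum(), atol=1e-10)
        assert result.consistent
        assert result.lambda_max == pytest.approx(3.0, abs=1e-9)

    def test_inconsistent_matrix_flagged(self):
        # a>b (3), b>c (3), but c>a (3): maximally cyclic, CR far above 0.1
        values = np.array([[1, 3, 1 / 3], [1 / 3, 1, 3], [3, 1 / 3, 1]])
        result = ahp_weights(JudgmentMatrix(("a", "b", "c"), values))
        assert not result.consistent

    def test_non_reciprocal_rejected(self):
        with pytest.raises(InputError):
            JudgmentMatrix(("a", "b"), [[1.0, 2.0], [1.0, 1.0]])

    def test_diagonal_must_be_one(self):
        with pytest.raises(InputError):
            JudgmentMatrix(("a", "b"), [[2.0, 1.0], [1.0, 1.0]])


class TestStandardize:
    def test_benefit_and_cost_columns(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        out = minmax_standardize(frame, directions={"y": "cost"})
        np.testing.assert_allclose(out["x"], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(out["y"], [1.0, 0.5, 0.0])

    def test_affine_invariance(self, rng):
        frame = pd.DataFrame({"x": rng.normal(size=8)})
        scaled = frame * 3.7 + 11.0
        np.testing.assert_allclose(
            minmax_standardize(frame)["x"], minmax_standardize(scaled)["x"], atol=1e-12
        )

    def test_every_column_attains_bounds(self, table5_frame):
        out = minmax_standardize(table5_frame.drop(columns="tep"))
        np.testing.assert_allclose(out.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=0), 1.0, atol=1e-12)

    def test_constant_column_rejected(self):
        frame = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(InputError):
            minmax_standardize(frame)


class TestEntropyWeights:
    def test_identity_matrix_symmetric(self):
        r = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], columns=["a", "b"])
        np.testing.assert_allclose(entropy_weights(r).weights, [0.5, 0.5])

    def test_identical_columns_share_weight(self):
        r = pd.DataFrame({"a": [0.1, 0.7, 1.0], "b": [0.1, 0.7, 1.0]})
        np.testing.assert_allclose(entropy_weights(r).weights, [0.5, 0.5])

    def test_uniform_column_gets_zero_weight(self):
        # a uniform column has maximal entropy (e=1) hence zero information
        r = pd.DataFrame({"flat": [0.5, 0.5, 0.5, 0.5], "sharp": [1.0, 0.0, 0.0, 0.0]})
        w = entropy_weights(r)
        assert w["flat"] == pytest.approx(0.0, abs=1e-12)
        assert w["sharp"] == pytest.approx(1.0)

    def test_permutation_equivariance(self, rng):
        r = pd.DataFrame(rng.uniform(0.01, 1.0, size=(9, 4)), columns=list("abcd"))
        base = entropy_weights(r).as_series()
        rows = entropy_weights(r.sample(frac=1.0, random_state=1)).as_series()
        cols = entropy_weights(r[["c", "a", "d", "b"]]).as_series()
        pd.testing.assert_series_equal(base, rows.reindex(base.index), atol=1e-12)
        pd.testing.assert_series_equal(base.sort_index(), cols.sort_index(), atol=1e-12)

    def test_all_zero_column_rejected(self):
        r = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 0.5]})
        with pytest.raises(InputError):
            entropy_weights(r)


class TestCombinedWeights:
    def test_identity_factor(self):
        sub = WeightVector(("x", "y"), [0.3, 0.7])
        combined = combined_weights(WeightVector(("f",), [1.0]), {"f": sub})
        np.testing.assert_allclose(combined.weights, [0.3, 0.7])

    def test_label_mismatch_rejected(self):
        with pytest.raises(InputError):
            combined_weights(
                WeightVector(("f", "g"), [0.5, 0.5]),
                {"f": WeightVector(("x",), [1.0])},
            )

    @pytest.mark.parametrize("name", ["table3", "table8"])
    def test_printed_weight_arithmetic(self, name):
        """Every printed combined weight is factor x sub-factor within +-0.001."""
        table = load_fixture_table(name)
        for factor in table["factors"].labels:
            fw = table["factors"][factor]
            sub = table["subfactors"][factor]
            for criterion in sub.labels:
                assert fw * sub[criterion] == pytest.approx(
                    table["combined"][criterion], abs=1e-3
                ), (name, criterion)

    def test_taste_block_reproduction(self):
        table = load_fixture_table("table8")
        taste = table["subfactors"]["taste"]
        expected = 0.680 * np.array([0.335, 0.374, 0.290])
        np.testing.assert_allclose(
            0.680 * taste.weights, expected, atol=1e-12
        )
        np.testing.assert_allclose(expected, [0.228, 0.254, 0.197], atol=1e-3)


class TestTopsis:
    def test_ideal_and_anti_ideal_rows(self):
        std = pd.DataFrame(
            [[1.0, 1.0], [0.0, 0.0], [0.5, 0.2]], index=["best", "worst", "mid"],
            columns=["a", "b"],
        )
        out = topsis_closeness(std, np.array([0.5, 0.5]))
        assert out.loc["best", "closeness"] == pytest.approx(1.0)
        assert out.loc["worst", "closeness"] == pytest.approx(0.0)
        assert 0.0 < out.loc["mid", "closeness"] < 1.0
        assert out.loc["best", "rank"] == 1

    def test_symmetric_two_option_matrix(self):
        std = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], columns=["a", "b"])
        out = topsis_closeness(std, np.array([0.5, 0.5]))
        np.testing.assert_allclose(out["closeness"], [0.5, 0.5])

    def test_degenerate_matrix_rejected(self):
        std = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], columns=["a", "b"])
        with pytest.raises(InputError):
            topsis_closeness(std, np.array([0.5, 0.5]))

    def test_nonextremal_duplicate_leaves_scores_unchanged(self, table5_frame, rng):
        # with the weights held fixed, duplicating an interior option moves
        # no column extreme, so every original closeness is unchanged
        std = minmax_standardize(table5_frame.drop(columns="tep"))
        weights = rng.dirichlet(np.ones(std.shape[1]))
        base = topsis_closeness(std, weights)
        dup = pd.concat([std, std.iloc[[10]].rename(index={std.index[10]: "dup"})])
        with_dup = topsis_closeness(dup, weights)
        np.testing.assert_allclose(
            base["closeness"], with_dup.loc[base.index, "closeness"], atol=1e-12
        )


class TestComprehensiveQuality:
    def test_red_ripe_t6_is_best_calibration_option(self, table5_records):
        scores = comprehensive_quality(table5_records)
        assert scores["closeness"].idxmax() == "T6-RR"
        assert scores.loc["T6-RR", "rank"] == 1

    def test_t6_ranks_first_among_batches(self, table2_records):
        scores = comprehensive_quality(table2_records)
        assert scores["closeness"].idxmax() == "T6-RR"

    def test_scores_track_tep(self, table5_frame):
        from scipy.stats import spearmanr

        scores = comprehensive_quality(table5_frame.drop(columns="tep"))
        rho = spearmanr(scores["closeness"], table5_frame["tep"]).statistic
        assert rho > 0.8

    def test_entropy_subweights_match_printed_table(self, table5_frame):
        """The within-factor entropy weights of the calibration matrix
        reproduce the printed sub-factor weights to +-0.001."""
        scorer = ComprehensiveQualityScorer().fit(table5_frame)
        printed = load_fixture_table("table8")["subfactors"]
        for factor, sub in printed.items():
            fitted = scorer.subfactor_weights_[factor]
            for criterion in sub.labels:
                assert fitted[criterion] == pytest.approx(sub[criterion], abs=1.5e-3), (
                    factor, criterion,
                )

    def test_single_option_rejected(self, table5_frame):
        with pytest.raises(InputError):
            comprehensive_quality(table5_frame.iloc[[0]])

    def test_scorer_transform_consistent_with_fit(self, table5_frame):
        scorer = ComprehensiveQualityScorer().fit(table5_frame)
        direct = scorer.transform(table5_frame)
        frame_scores = comprehensive_quality(table5_frame)
        np.testing.assert_allclose(direct, frame_scores["closeness"], atol=1e-12)

    def test_scorer_sklearn_params(self):
        scorer = ComprehensiveQualityScorer(factor_weights={"a": 1.0})
        assert scorer.get_params()["factor_weights"] == {"a": 1.0}

    def test_scores_in_unit_interval(self, table5_frame):
        scores = comprehensive_quality(table5_frame)
        assert scores["closeness"].between(0.0, 1.0).all()


def test_weight_vector_validation():
    with pytest.raises(InputError):
        WeightVector(("a", "b"), [0.7, 0.7])
    with pytest.raises(InputError):
        WeightVector(("a",), [-1.0])
    wv = WeightVector(("a", "b"), [0.25, 0.75])
    assert wv["b"] == 0.75
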