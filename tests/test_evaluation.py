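"""Split procedure, binarization, metric suites, feature importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ptml.data_model import ReactionRecord
from ptml.evaluation import (
    binarize_yield,
    classification_metrics,
    dataset_summary,
    feature_importance,
    rank_auc,
    regression_metrics,
    split_labels,
    stratified_split,
)


def _recs(yields, rtype="suzuki_miyaura"):
    return [ReactionRecord(f"r{i}", rtype, 0, y) for i, y in enumerate(yields)]


class TestStratifiedSplit:
    def test_every_fourth_rule_on_eight_records(self, worked):
        records, _, _, expected = worked
        labelled = stratified_split(records)
        assert [r.split_label for r in labelled] == expected["split_labels"]

    def test_fewer_than_four_records_all_train(self):
        labelled = stratified_split(_recs([90, 80, 70]))
        assert [r.split_label for r in labelled] == ["t", "t", "t"]

    def test_equal_yields_tiebreak_by_original_index(self):
        labelled = stratified_split(_recs([80.0] * 8))
        # sorted order == original order, so positions 4 and 8 go to "v"
        assert [r.split_label for r in labelled] == [
            "t", "t", "t", "v", "t", "t", "t", "v",
        ]
        again = stratified_split(_recs([80.0] * 8))
        assert [r.split_label for r in again] == [r.split_label for r in labelled]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["suzuki_miyaura", "kumada", "negishi"]),
                st.floats(0, 100),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_validation_count_and_per_type_share(self, rows):
        types = [t for t, _ in rows]
        yields = [y for _, y in rows]
        labels = split_labels(types, yields)
        assert (labels == "v").sum() == len(rows) // 4
        # within each type with >= 4 members the share is within one record
        # of 25%
        for t in set(types):
            mask = np.array(types) == t
            if mask.sum() >= 4:
                v = (labels[mask] == "v").sum()
                assert abs(v - mask.sum() / 4) < 1.0 + 1e-9


class TestBinarize:
    @pytest.mark.parametrize("y,expected", [(80.0, 1), (79.0, 0), (0.0, 0)])
    def test_published_boundary(self, y, expected):
        assert binarize_yield([y], threshold=79.0)[0] == expected

    def test_default_threshold_is_the_mean(self, worked):
        records, _, _, expected = worked
        yields = [r.yield_pct for r in records]
        assert np.mean(yields) == expected["mean_yield"]
        assert binarize_yield(yields).tolist() == expected["class_labels"]

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=50))
    def test_partitions_every_dataset(self, yields):
        labels = binarize_yield(yields, threshold=50.0)
        assert ((labels == 0) | (labels == 1)).all()
        assert (labels == 0).sum() + (labels == 1).sum() == len(yields)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        rep = regression_metrics([10, 50, 90], [10, 50, 90])
        assert rep.R == pytest.approx(1.0)
        assert rep.mae == 0.0 and rep.rmse == 0.0

    def test_anti_correlation(self):
        rep = regression_metrics([0, 100], [100, 0])
        assert rep.R == pytest.approx(-1.0)

    def test_hand_arithmetic(self):
        rep = regression_metrics([70, 90], [75, 85])
        assert rep.mae == pytest.approx(5.0)
        assert rep.rmse == pytest.approx(5.0)

    def test_zero_variance_reports_missing_r(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rep = regression_metrics([50, 50], [40, 60])
        assert rep.R is None

    def test_stratified_bands(self):
        rep = regression_metrics([70, 90], [75, 85], threshold=79.0)
        assert rep.stratified["low"]["mae"] == pytest.approx(5.0)
        assert rep.stratified["high"]["n"] == 1
        assert rep.mae <= rep.rmse


class TestClassificationMetrics:
    def test_perfect_probabilities(self):
        rep = classification_metrics([1, 1, 0, 0], [1.0, 1.0, 0.0, 0.0])
        assert rep.auc == 1.0 and rep.accuracy == 1.0
        assert rep.confusion == {"tp": 2, "tn": 2, "fp": 0, "fn": 0}

    def test_uninformative_probabilities_tie_average(self):
        rep = classification_metrics([1, 0, 1, 0], [0.5] * 4)
        assert rep.auc == pytest.approx(0.5)

    def test_derived_auc_example(self):
        rep = classification_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert rep.auc == pytest.approx(0.75)  # brute force over pos/neg pairs

    def test_confusion_counts_consistent(self):
        labels = [1, 0, 1, 0, 1, 1, 0]
        probs = [0.8, 0.3, 0.4, 0.6, 0.9, 0.7, 0.1]
        rep = classification_metrics(labels, probs)
        c = rep.confusion
        assert sum(c.values()) == len(labels)
        assert rep.tpr_pct == pytest.approx(100 * c["tp"] / (c["tp"] + c["fn"]))
        assert rep.tnr_pct == pytest.approx(100 * c["tn"] / (c["tn"] + c["fp"]))

    def test_single_class_flagged(self):
        with pytest.warns(UserWarning, match="single-class"):
            rep = classification_metrics([1, 1], [0.9, 0.8])
        assert rep.auc is None

    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=2, max_size=100
        ).filter(lambda rows: len({lab for lab, _ in rows}) == 2)
    )
    def test_rank_auc_matches_pairwise_oracle(self, rows):
        labels = np.array([l for l, _ in rows])
        scores = np.array([s for _, s in rows])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert rank_auc(labels, scores) == pytest.approx(
            wins / (len(pos) * len(neg)), rel=1e-12, abs=1e-12
        )


class TestFeatureImportance:
    class _LinearStub:
        def __init__(self, weights):
            self.w = np.asarray(weights)

        def predict(self, frame):
            return np.asarray(frame, dtype=float) @ self.w

    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        y = 5.0 * X["b"].to_numpy() + rng.normal(0, 0.1, 200)
        model = self._LinearStub([0.0, 5.0, 0.0])
        ranked = feature_importance(model, X, y, n_repeats=10, seed=1)
        assert ranked.iloc[0]["feature"] == "b"
        noise_rows = ranked[ranked["feature"] != "b"]
        assert (noise_rows["importance"].abs() < 0.1).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        y = X["a"].to_numpy()
        model = self._LinearStub([1.0, 0.0, 0.0])
        r1 = feature_importance(model, X, y, n_repeats=5, seed=7)
        r2 = feature_importance(model, X, y, n_repeats=5, seed=7)
        pd.testing.assert_frame_equal(r1, r2)


class TestDatasetSummary:
    def test_training_sizes_under_every_fourth_rule(self):
        records = _recs([80.0] * 1052) + _recs([70.0] * 82, rtype="double_carbonylation")
        summary = dataset_summary(records)
        assert summary["n_total"] == 1134
        assert summary["train_size_all"] == 851
        assert summary["train_size_excluding"] == 789
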