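"""Feature assembly, grouped CV, SMOTE and metric contracts."""

import numpy as np
import pandas as pd
import pytest

import dyncausal as dc
from dyncausal.gnn import CausalGraph, PredictedEdge
from dyncausal.preprocess import ColumnInfo, FeatureMatrix
from dyncausal.synthetic import COHORT_COUNTS


def toy_feature_matrix(n_vars=10, n_ind=30, lags=(1, 2), seed=0):
    rng = np.random.default_rng(seed)
    variables = [f"v{i}" for i in range(n_vars)]
    n_waves = 4
    frame = pd.DataFrame(
        {
            "id": np.repeat(np.arange(n_ind), n_waves),
            "wave": np.tile(np.arange(n_waves), n_ind),
        }
    )
    columns = {}
    for v in variables:
        frame[v] = rng.normal(size=len(frame))
        columns[v] = ColumnInfo("base", v)
        for l in lags:
            lagged = frame.groupby("id")[v].shift(l)
            frame[f"{v}_lag{l}"] = lagged
            frame[f"{v}_diff{l}"] = frame[v] - lagged
            columns[f"{v}_lag{l}"] = ColumnInfo("lag", v, l)
            columns[f"{v}_diff{l}"] = ColumnInfo("diff", v, l)
    frame["stroke"] = rng.integers(0, 2, size=len(frame)).astype(float)
    return FeatureMatrix(frame, columns), variables


def graph_over(variables, edges, d=8):
    preds = [PredictedEdge(s, t, 0.9, "both") for s, t in edges]
    emb = np.random.default_rng(0).standard_normal((len(variables), d))
    return CausalGraph(nodes=list(variables), edges=preds, granger_only=[], embeddings=emb)


class TestAssembleFeatures:
    def test_all_mode_uses_base_columns_only(self):
        fm, variables = toy_feature_matrix()
        design = dc.assemble_features(fm, None, mode="all")
        assert design.manifest == variables
        assert len(design.X) == len(fm.frame)

    def test_dynamic_causal_manifest_arithmetic(self):
        fm, variables = toy_feature_matrix()
        causal = variables[:7]
        edges = [(causal[i], causal[i + 1]) for i in range(0, 6, 2)] + [(causal[6], causal[0])]
        design = dc.assemble_features(fm, graph_over(variables, edges), mode="dynamic_causal")
        # 7 base + 14 lag + 14 diff + 7*8 embedding columns
        assert len(design.manifest) == 7 + 14 + 14 + 56

    def test_rows_without_lag_support_dropped(self):
        fm, variables = toy_feature_matrix()
        design = dc.assemble_features(fm, graph_over(variables, [("v0", "v1")]), mode="dynamic_causal")
        # max lag 2 of 4 waves -> 2 usable waves per individual
        assert len(design.X) == len(fm.frame) // 2

    def test_empty_graph_is_error(self):
        fm, variables = toy_feature_matrix()
        with pytest.raises(ValueError, match="no nodes"):
            dc.assemble_features(fm, graph_over(variables, []), mode="dynamic_causal")


class TestStratifiedGroupKFold:
    def test_published_split_sizes(self):
        n, n_pos = COHORT_COUNTS["stroke"][1], COHORT_COUNTS["stroke"][0]
        y = np.zeros(n)
        y[:n_pos] = 1
        groups = np.arange(n)
        plan = dc.stratified_group_kfold(y, groups, k=5, seed=0)
        test_sizes = sorted(len(test) for _, test in plan.folds)
        assert test_sizes == [2357, 2358, 2358, 2358, 2358]
        train_sizes = [len(train) for train, _ in plan.folds]
        assert max(set(train_sizes), key=train_sizes.count) == 9431
        # stratification: per-fold positive rate within 2 points of global
        for frac in plan.label_proportions(y):
            assert abs(frac - n_pos / n) < 0.02

    def test_whole_individual_stays_in_one_fold(self):
        y = np.tile([1, 0, 0, 0], 25)
        groups = np.repeat(np.arange(25), 4)
        plan = dc.stratified_group_kfold(y, groups, k=5, seed=1)
        for _, test in plan.folds:
            assert set(np.bincount(groups[test], minlength=25)) <= {0, 4}

    def test_all_negative_labels_fall_back_to_group_kfold(self):
        y = np.zeros(40)
        groups = np.arange(40)
        with pytest.warns(UserWarning, match="group K-fold"):
            plan = dc.stratified_group_kfold(y, groups, k=4, seed=0)
        plan.validate(y, groups)

    def test_overlapping_plan_rejected(self):
        y = np.array([0, 1, 0, 1])
        groups = np.array([0, 0, 1, 1])
        bad = dc.CvPlan(folds=[(np.array([0, 1]), np.array([1, 2, 3]))], seed=0)
        with pytest.raises(ValueError):
            bad.validate(y, groups)


class TestSmote:
    def test_balances_to_majority_count(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = np.r_[np.zeros(90), np.ones(10)]
        X2, y2 = dc.smote_oversample(X, y, seed=0)
        assert (y2 == 1).sum() == (y2 == 0).sum() == 90
        assert len(X2) == 180
        np.testing.assert_array_equal(X2[:100], X)  # originals verbatim

    def test_identical_minority_points_give_identical_synthetics(self):
        X = np.vstack([np.zeros((2, 2)) + 7.0, np.random.default_rng(1).normal(size=(10, 2))])
        y = np.r_[np.ones(2), np.zeros(10)]
        X2, y2 = dc.smote_oversample(X, y, seed=0)
        np.testing.assert_allclose(X2[12:], 7.0)

    def test_synthetic_rows_lie_on_parent_segments(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4))
        y = np.r_[np.zeros(45), np.ones(15)]
        sm = dc.SMOTEOversampler(k_neighbors=5, seed=2)
        X2, _ = sm.fit_resample(X, y)
        base, neigh, u = sm.parents_
        X_min = X[y == 1]
        expect = X_min[base] + u[:, None] * (X_min[neigh] - X_min[base])
        np.testing.assert_allclose(X2[60:], expect)
        assert ((u >= 0) & (u <= 1)).all()

    def test_small_minority_reduces_k_with_warning(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.r_[np.zeros(17), np.ones(3)]
        with pytest.warns(UserWarning, match="k="):
            X2, y2 = dc.smote_oversample(X, y, k_neighbors=5, seed=0)
        assert (y2 == 1).sum() == 17

    def test_single_minority_row_is_error(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.r_[np.zeros(9), np.ones(1)]
        with pytest.raises(ValueError, match="at least 2"):
            dc.smote_oversample(X, y)


class TestComputeMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = dc.compute_metrics(y, s)
        assert m["auc"] == 1.0 and m["mcc"] == 1.0 and m["f1"] == 1.0

    def test_hand_computed_confusion_algebra(self):
        # TP=5 FP=2 FN=3 TN=10
        y = np.r_[np.ones(5), np.zeros(2), np.ones(3), np.zeros(10)]
        s = np.r_[np.full(5, 0.9), np.full(2, 0.9), np.full(3, 0.1), np.full(10, 0.1)]
        m = dc.compute_metrics(y, s)
        assert m["precision"] == pytest.approx(0.7143, abs=1e-4)
        assert m["recall"] == pytest.approx(0.625, abs=1e-4)
        assert m["mcc"] == pytest.approx(44 / np.sqrt(7 * 8 * 12 * 13), abs=1e-6)

    def test_constant_scores_give_chance_auc(self):
        y = np.array([0, 1, 0, 1, 1])
        m = dc.compute_metrics(y, np.full(5, 0.3))
        assert m["auc"] == 0.5

    def test_single_class_auc_missing_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = dc.compute_metrics(np.zeros(5), np.linspace(0.1, 0.9, 5))
        assert np.isnan(m["auc"])

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.uniform(size=50)
        a = dc.compute_metrics(y, s)["auc"]
        b = dc.compute_metrics(y, s**3)["auc"]
        assert a == b

    def test_mcc_symmetric_under_class_swap(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        s = rng.uniform(0.01, 0.99, 60)
        m = dc.compute_metrics(y, s)["mcc"]
        m_swap = dc.compute_metrics(1 - y, 1 - s + 1e-9)["mcc"]
        assert m == pytest.approx(m_swap, abs=1e-9)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            dc.compute_metrics(np.array([0, 1]), np.array([0.5, 1.2]))


class TestTrainAndEvaluate:
    def _design(self, X, y, groups, feature_set="all"):
        return dc.DesignMatrix(
            X=pd.DataFrame(X), y=np.asarray(y), groups=np.asarray(groups), feature_set=feature_set
        )

    def test_separable_labels_reach_high_auc_for_all_families(self):
        rng = np.random.default_rng(0)
        n = 500
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 3))
        X[:, 0] = y * 4.0 + rng.normal(scale=0.1, size=n)  # one feature separates
        design = self._design(X, y, np.arange(n))
        plan = dc.stratified_group_kfold(design.y, design.groups, k=2, seed=0)
        report = dc.train_and_evaluate(design, plan, seed=0)
        means = report.mean_table()
        assert (means["auc"] >= 0.99).all(), means

    def test_pure_noise_features_sit_at_chance(self):
        rng = np.random.default_rng(1)
        n = 1000
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 5))
        design = self._design(X, y, np.arange(n))
        plan = dc.stratified_group_kfold(design.y, design.groups, k=5, seed=1)
        report = dc.train_and_evaluate(design, plan, models=["gradient_boosting"], seed=1)
        auc = report.mean_metric("gradient_boosting", "all", "auc")
        assert 0.45 <= auc <= 0.55

    def test_unknown_model_family_fails_at_setup(self):
        with pytest.raises(ValueError, match="unknown model"):
            dc.build_models(["perceptron_of_doom"])

    def test_report_table_layout(self):
        rng = np.random.default_rng(2)
        n = 120
        design = self._design(rng.normal(size=(n, 2)), rng.integers(0, 2, n), np.arange(n))
        plan = dc.stratified_group_kfold(design.y, design.groups, k=2, seed=0)
        report = dc.train_and_evaluate(design, plan, models=["knn", "logistic_regression"], seed=0)
        assert set(report.table.columns) == {
            "model", "feature_set", "fold", "auc", "accuracy", "precision", "recall", "f1", "mcc",
        }
        assert len(report.table) == 4  # 2 models x 2 folds
        means = report.mean_table()
        assert len(means) == 2
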