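"""ROC primitives, correlation filter, forest model/results."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from srsradiomics.forest import (
    ForestConfig,
    ProgressionForest,
    RocCurve,
    _DesignSpec,
    _tree_bootstrap_indices,
    correlation_filter,
    metrics_at_threshold,
    roc_from_scores,
    select_operating_point,
)

SMALL = ForestConfig(n_estimators_grid=(100,), max_features_grid=("sqrt",),
                     min_samples_leaf_grid=(3,))


def _pairwise_auc(scores, labels):
    """Concordance-count AUC oracle: ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_all_scores_equal_gives_half(self):
        roc = roc_from_scores([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_inversion_matches_pairwise_oracle(self):
        scores = [0.9, 0.2, 0.7, 0.6, 0.4, 0.3]
        labels = [1, 1, 1, 0, 0, 0]
        roc = roc_from_scores(scores, labels)
        assert roc.auc == pytest.approx(_pairwise_auc(scores, labels))

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.choice([0.1, 0.4, 0.4, 0.8], size=12)
            labels = rng.integers(0, 2, size=12)
            if labels.min() == labels.max():
                continue
            roc = roc_from_scores(scores, labels)
            assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
            assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
            assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        a0 = roc_from_scores(scores, labels).auc
        a1 = roc_from_scores(np.exp(5 * scores), labels).auc
        assert a0 == pytest.approx(a1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_from_scores([0.1, 0.2], [1, 1])


class TestOperatingPoint:
    def test_perfect_point_chosen(self):
        roc = roc_from_scores([0.9, 0.8, 0.1], [1, 1, 0])
        op = select_operating_point(roc)
        assert (op.fnr, op.fpr) == (0.0, 0.0)
        assert op.objective == 0.0

    def test_hand_evaluated_pair(self):
        # (FPR=0.1, TPR=0.6): 0.16+0.01=0.17; (FPR=0.3, TPR=0.9): 0.01+0.09=0.10
        roc = RocCurve(np.array([np.inf, 0.8, 0.4]),
                       np.array([0.0, 0.1, 0.3]),
                       np.array([0.0, 0.6, 0.9]), auc=0.8)
        op = select_operating_point(roc)
        assert (op.fpr, op.fnr) == (0.3, pytest.approx(0.1))

    def test_symmetric_tie_takes_lower_fpr(self):
        roc = RocCurve(np.array([np.inf, 0.7, 0.3]),
                       np.array([0.0, 0.1, 0.4]),
                       np.array([0.0, 0.6, 0.9]), auc=0.8)
        # objectives: (1,0); (0.4^2+0.1^2)=0.17; (0.1^2+0.4^2)=0.17 -> tie
        op = select_operating_point(roc)
        assert op.fpr == 0.1

    def test_argmin_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            scores = rng.random(15)
            labels = rng.integers(0, 2, 15)
            labels[:2] = [0, 1]
            roc = roc_from_scores(scores, labels)
            op = select_operating_point(roc)
            objs = (1 - roc.tpr) ** 2 + roc.fpr ** 2
            assert op.objective == pytest.approx(objs.min())


class TestMetricsAtThreshold:
    def test_perfect_scores(self):
        m = metrics_at_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert (m.auc, m.mcr, m.fnr, m.fpr) == (1.0, 0.0, 0.0, 0.0)

    def test_threshold_below_all_scores(self):
        m = metrics_at_threshold([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0], 0.0)
        assert (m.fpr, m.fnr) == (1.0, 0.0)

    def test_confusion_counts_match_enumeration(self):
        scores = [0.9, 0.8, 0.75, 0.6, 0.55, 0.5, 0.4, 0.3, 0.2, 0.1]
        labels = [1, 1, 0, 1, 0, 1, 0, 0, 1, 0]
        thr = 0.55
        m = metrics_at_threshold(scores, labels, thr)
        tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= thr and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 1)
        tn = sum(1 for s, l in zip(scores, labels) if s < thr and l == 0)
        assert m.mcr == pytest.approx((fp + fn) / 10)
        assert m.fnr == pytest.approx(fn / (fn + tp))
        assert m.fpr == pytest.approx(fp / (fp + tn))


class TestCorrelationFilter:
    def test_duplicated_column_keeps_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 1))
        res = correlation_filter(np.hstack([x, x]), ["f1", "f2"])
        assert res.kept == ["f1"]
        assert res.removed == {"f2": "f1"}

    def test_constructed_correlation_structure(self):
        rng = np.random.default_rng(4)
        n = 4000
        base1, base2 = rng.normal(size=n), rng.normal(size=n)
        x = np.column_stack([
            base1, base1 + 0.35 * rng.normal(size=n),       # rho ~ 0.94
            base2, base2 + 0.55 * rng.normal(size=n),       # rho ~ 0.88
        ])
        res = correlation_filter(x, ["a", "b", "c", "d"], threshold=0.8)
        assert res.kept == ["a", "c"]
        assert set(res.removed) == {"b", "d"}

    def test_orthogonal_features_all_kept(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(200, 6))
        assert len(correlation_filter(x, [f"f{i}" for i in range(6)]).kept) == 6

    def test_constant_feature_removed_with_reason(self):
        rng = np.random.default_rng(6)
        x = np.column_stack([np.ones(30), rng.normal(size=30)])
        res = correlation_filter(x, ["const", "ok"])
        assert res.removed["const"] == "constant"
        assert res.kept == ["ok"]

    def test_row_permutation_stability(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(60, 8))
        x[:, 3] = x[:, 1] * 0.97 + 0.05 * rng.normal(size=60)
        names = [f"f{i}" for i in range(8)]
        res1 = correlation_filter(x, names)
        res2 = correlation_filter(x[rng.permutation(60)], names)
        assert res1.kept == res2.kept


def _plain_model(X, y, config=SMALL):
    spec = _DesignSpec({}, [f"c{i}" for i in range(X.shape[1])], [])
    return ProgressionForest(np.asarray(X, float), np.asarray(y, int), spec,
                             config)


class TestProgressionForest:
    def test_separable_data_high_oob_auc(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += 3 * y
        res = _plain_model(X, y).fit(seed=0)
        assert res.oob_auc >= 0.95

    def test_permuted_labels_null_oob_auc(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 20))
            y = rng.permutation([1] * 24 + [0] * 96)
            aucs.append(_plain_model(X, np.array(y)).fit(seed=seed).oob_auc)
        assert min(aucs) >= 0.30 and max(aucs) <= 0.65
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_fixed_seed_reproduces_hyperparameters(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 6))
        y = (X[:, 0] + 0.7 * rng.normal(size=80) > 0).astype(int)
        cfg = ForestConfig(n_estimators_grid=(50, 100),
                           max_features_grid=("sqrt", "all"),
                           min_samples_leaf_grid=(1, 3))
        res1 = _plain_model(X, y, cfg).fit(seed=5)
        res2 = _plain_model(X, y, cfg).fit(seed=5)
        assert res1.params == res2.params
        np.testing.assert_array_equal(res1.oob_scores, res2.oob_scores)

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="single class"):
            _plain_model(rng.normal(size=(20, 3)), np.ones(20))

    def test_from_cohort_feature_sets(self, default_cohorts, small_grid):
        a, _ = default_cohorts
        clin = ProgressionForest.from_cohort(a, "clinical", small_grid)
        rad = ProgressionForest.from_cohort(a, "radiomic", small_grid)
        both = ProgressionForest.from_cohort(a, "all", small_grid)
        assert not clin.design.radiomic
        assert not rad.design.categorical and not rad.design.continuous
        assert len(both.design.columns) == len(clin.design.columns) + len(
            rad.design.columns)

    def test_summary_mentions_key_quantities(self, default_cohorts, small_grid):
        a, _ = default_cohorts
        res = ProgressionForest.from_cohort(a, "clinical", small_grid).fit(0)
        text = res.summary()
        assert "OOB AUC" in text and "Operating point" in text

    def test_bootstrap_indices_match_sklearn(self, default_cohorts, small_grid):
        from sklearn.ensemble._forest import _generate_sample_indices
        a, _ = default_cohorts
        res = ProgressionForest.from_cohort(a, "clinical", small_grid).fit(0)
        tree = res.estimator.estimators_[0]
        n = len(a.records)
        for sw in (None, res.sample_weight):
            expected = _generate_sample_indices(tree.random_state, n, n, sw)
            np.testing.assert_array_equal(
                _tree_bootstrap_indices(tree.random_state, n, sw), expected)

    def test_save_load_roundtrip(self, tmp_path, default_cohorts, small_grid):
        from srsradiomics.forest import ProgressionForestResults
        a, b = default_cohorts
        res = ProgressionForest.from_cohort(a, "all", small_grid).fit(0)
        res.save(tmp_path / "model")
        back = ProgressionForestResults.load(tmp_path / "model")
        assert back.params == res.params
        assert back.operating_point == res.operating_point
        np.testing.assert_array_equal(back.predict_scores(b),
                                      res.predict_scores(b))

    def test_oob_permutation_importance_finds_signal(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(150, 8))
        y = (X[:, 2] + 0.5 * rng.normal(size=150) > 0).astype(int)
        res = _plain_model(X, y).fit(seed=0)
        imp = res.feature_importances()
        assert imp.idxmax() == "c2"
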