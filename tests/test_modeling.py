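"""Thresholds, metrics, DeLong comparison, and model training."""

import numpy as np
import pandas as pd
import pytest

from glioradiomics import (
    delong_compare,
    evaluate,
    f1_from_precision_recall,
    roc_auc,
    train_model,
    youden_threshold,
)
from glioradiomics.modeling import confusion_metrics, delong_auc_variance


class TestYouden:
    def test_separable_returns_gap_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        t = youden_threshold(scores, labels)
        assert t == pytest.approx(0.5)

    def test_matches_exhaustive_scan(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 1, 0, 1])
        t = youden_threshold(scores, labels)
        # exhaustive scan over a fine grid
        best_j, best_t = -np.inf, None
        for cand in np.linspace(-0.1, 1.1, 2401):
            pred = scores >= cand
            sen = (pred & (labels == 1)).sum() / 2
            spe = (~pred & (labels == 0)).sum() / 2
            j = sen + spe - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, cand
        pred_at_t = scores >= t
        pred_at_best = scores >= best_t
        assert np.array_equal(pred_at_t, pred_at_best)

    def test_tie_broken_toward_sensitivity(self):
        # two thresholds achieve the same J; the lower one (higher SEN) wins
        scores = np.array([0.1, 0.5, 0.5, 0.9])
        labels = np.array([0, 1, 0, 1])
        t = youden_threshold(scores, labels)
        alt = [c for c in (0.3, 0.7)]
        js = []
        for c in alt:
            pred = scores >= c
            js.append(
                (pred & (labels == 1)).sum() / 2 + (~pred & (labels == 0)).sum() / 2 - 1
            )
        assert js[0] == js[1]
        assert t < 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.2], [1, 1])


class TestMetrics:
    @pytest.mark.parametrize(
        "precision,recall,expected",
        [(0.88, 0.70, 0.78), (0.89, 0.80, 0.84)],
    )
    def test_f1_identity_matches_published_rounding(self, precision, recall, expected):
        assert round(f1_from_precision_recall(precision, recall), 2) == expected

    def test_confusion_identities(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        m = confusion_metrics(scores, labels, 0.5)
        tp, tn, fp, fn = m["TP"], m["TN"], m["FP"], m["FN"]
        assert tp + tn + fp + fn == 200
        assert m["ACC"] == pytest.approx((tp + tn) / 200)
        assert m["SEN"] == pytest.approx(tp / (tp + fn))
        assert m["SPE"] == pytest.approx(tn / (tn + fp))
        assert m["PRE"] == pytest.approx(tp / (tp + fp))
        assert m["F1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestAUC:
    def test_perfect_ranking(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == 1.0
        t = youden_threshold(scores, labels)
        m = confusion_metrics(scores, labels, t)
        assert m["SEN"] == 1.0 and m["SPE"] == 1.0

    def test_constant_scores_auc_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(100)
        labels = (rng.random(100) < 0.4).astype(int)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) - 7, labels)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("seed", range(10))
    def test_placement_auc_equals_trapezoid(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = 60
        scores = np.round(rng.random(n), 2)  # ties on purpose
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestDeLong:
    def test_self_comparison_p_one(self, rng):
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        res = delong_compare(scores, scores, labels)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_variance_components_match_bruteforce(self):
        """Midrank placements equal the O(n^2) pairwise Heaviside sums."""
        rng = np.random.default_rng(4)
        pos = np.round(rng.random(6), 2)
        neg = np.round(rng.random(8), 2)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 6 + [0] * 8)
        auc, v10, v01 = delong_auc_variance(scores, labels)

        def psi(x, y):
            return 1.0 if x > y else (0.5 if x == y else 0.0)

        v10_brute = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
        v01_brute = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
        assert np.allclose(v10, v10_brute)
        assert np.allclose(v01, v01_brute)
        assert auc == pytest.approx(v10_brute.mean())

    def test_different_scores_give_valid_p(self, rng):
        labels = (rng.random(80) < 0.3).astype(int)
        labels[:2] = [0, 1]
        a = rng.random(80) + labels * 0.8
        b = rng.random(80)
        res = delong_compare(a, b, labels)
        assert 0.0 <= res.p_value <= 1.0
        assert res.variance >= 0.0
        assert res.auc_a > res.auc_b


class TestTrainEvaluate:
    def _table(self, rng, n=80, separable=False):
        y = (rng.random(n) < 0.4).astype(int)
        y[:2] = [0, 1]
        x1 = y * 2.0 + (0.0 if separable else rng.normal(0, 0.6, n))
        df = pd.DataFrame({"f1": x1, "f2": rng.normal(size=n)})
        df["idh1"] = y
        return df

    def test_separable_training_accuracy(self, rng):
        table = self._table(rng, separable=True)
        bundle = train_model(table, ["f1"], "toy", seed=1, n_trees=50)
        report = evaluate(bundle, table)
        assert report.metrics["ACC"] == 1.0

    def test_forest_has_300_trees_by_default(self, rng):
        table = self._table(rng)
        bundle = train_model(table, ["f1", "f2"], "toy", seed=1)
        assert len(bundle.forest.estimators_) == 300

    def test_deterministic_under_seed(self, rng):
        table = self._table(rng)
        a = train_model(table, ["f1", "f2"], "toy", seed=3)
        b = train_model(table, ["f1", "f2"], "toy", seed=3)
        assert np.array_equal(a.scores(table), b.scores(table))

    def test_empty_feature_set_errors(self, rng):
        with pytest.raises(ValueError, match="empty"):
            train_model(self._table(rng), [], "toy")

    def test_single_class_eval_warns_missing_auc(self, rng):
        table = self._table(rng)
        bundle = train_model(table, ["f1"], "toy", seed=1, n_trees=50)
        single = table[table["idh1"] == 0]
        with pytest.warns(UserWarning, match="AUC undefined"):
            report = evaluate(bundle, single)
        assert report.auc is None

    def test_roc_curve_endpoints(self, rng):
        table = self._table(rng)
        bundle = train_model(table, ["f1"], "toy", seed=1, n_trees=50)
        report = evaluate(bundle, table)
        assert report.roc_points[0] == (0.0, 0.0)
        assert report.roc_points[-1] == (1.0, 1.0)
        assert all(0 <= v <= 1 for pt in report.prc_points for v in pt)
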