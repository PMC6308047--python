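"""Random-forest modeling and the full evaluation suite.

Each of the nine model configurations (four single-region, tumor core, whole
tumor, all-region, clinical-only, and combined all-region + clinical) is a
300-tree Gini random forest fitted on the Boruta-confirmed features of the
balanced training table.  The probability score of a case is the forest's
mutated-class probability (mean of per-tree votes).  Evaluation reports
ACC/SEN/SPE/PRE, F1, trapezoidal ROC-AUC with midrank tie handling (so the
AUC equals the Mann-Whitney statistic and the DeLong placement AUC), the
precision-recall curve, and the Youden-index cutoff.  Paired AUCs are
compared with the fast midrank (placement-value) DeLong estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve, roc_curve

N_TREES = 300

MODEL_CONFIGS = (
    "enhance", "non_enhance", "necrosis", "edema",
    "tumor_core", "whole_tumor", "all_region", "clinical", "combined",
)


# ---------------------------------------------------------------------------
# thresholds and scalar metrics


def youden_threshold(scores, labels) -> float:
    """Cutoff maximizing the Youden index (SEN + SPE - 1).

    Candidate cut points are the midpoints between consecutive distinct
    scores plus sentinels below/above the score range; a case is called
    positive when its score is >= the threshold.  Ties in the Youden index
    are broken toward the lower threshold (higher sensitivity).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = scores >= t
        sen = (pred & (labels == 1)).sum() / n_pos
        spe = (~pred & (labels == 0)).sum() / n_neg
        j = sen + spe - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """ACC/SEN/SPE/PRE/F1 at a fixed threshold (positive iff score >= t)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sen = tp / (tp + fn) if tp + fn else np.nan
    spe = tn / (tn + fp) if tn + fp else np.nan
    pre = tp / (tp + fp) if tp + fp else 0.0
    return {
        "ACC": (tp + tn) / len(labels),
        "SEN": sen,
        "SPE": spe,
        "PRE": pre,
        "F1": f1_from_precision_recall(pre, sen) if tp + fn else np.nan,
        "TP": tp, "TN": tn, "FP": fp, "FN": fn,
    }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2 * precision * recall / (precision + recall); 0 if both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray):
    """Placement values and AUC for one score vector (DeLong components).

    Returns ``(auc, v10, v01)`` where ``v10`` are the structural components
    over positives and ``v01`` over negatives.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return float(auc), v10, v01


def roc_auc(scores, labels) -> float:
    """AUC with midrank tie handling (= Mann-Whitney statistic)."""
    auc, _, _ = delong_auc_variance(scores, labels)
    return auc


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    statistic: float  # z
    p_value: float
    variance: float


def delong_compare(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test for the difference of two paired AUCs.

    Identical score vectors (zero variance of the difference) return
    statistic 0 and p = 1 by convention.
    """
    labels = np.asarray(labels).astype(int)
    auc_a, v10_a, v01_a = delong_auc_variance(scores_a, labels)
    auc_b, v10_b, v01_b = delong_auc_variance(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return DeLongResult(auc_a, auc_b, 0.0, 1.0, max(var, 0.0))
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, float(z), float(min(p, 1.0)), float(var))


# ---------------------------------------------------------------------------
# model bundle and evaluation report


@dataclass
class ModelBundle:
    """Fitted model for one configuration."""

    name: str
    feature_names: list
    forest: RandomForestClassifier
    imputation_medians: pd.Series
    seed: int
    training_threshold: float | None = None

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Mutated-class probability per case."""
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"table lacks model features: {missing[:5]}")
        X = table[self.feature_names].copy()
        X = X.fillna(self.imputation_medians)
        proba = self.forest.predict_proba(X.to_numpy(dtype=np.float64))
        mutated_col = list(self.forest.classes_).index(1)
        return proba[:, mutated_col]


@dataclass
class EvaluationReport:
    model: str
    threshold: float
    metrics: dict  # ACC/SEN/SPE/PRE/F1 (+ confusion counts)
    auc: float | None
    roc_points: list = field(default_factory=list)  # (fpr, tpr)
    prc_points: list = field(default_factory=list)  # (recall, precision)

    def rounded(self, ndigits: int = 2) -> dict:
        out = {"model": self.model}
        for k in ("ACC", "SEN", "SPE", "PRE", "F1"):
            out[k] = round(self.metrics[k], ndigits)
        out["AUC"] = round(self.auc, ndigits) if self.auc is not None else None
        return out


def train_model(
    train_table: pd.DataFrame,
    feature_names,
    name: str,
    seed: int = 0,
    n_trees: int = N_TREES,
    label_column: str = "idh1",
) -> ModelBundle:
    """Fit a 300-tree Gini random forest on the confirmed features."""
    feature_names = list(feature_names)
    if not feature_names:
        raise ValueError(
            "empty confirmed feature set; rerun selection with tentative "
            "rough-fix resolution"
        )
    X = train_table[feature_names]
    medians = X.median()
    X = X.fillna(medians)
    y = train_table[label_column].to_numpy().astype(int)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X.to_numpy(dtype=np.float64), y)
    bundle = ModelBundle(
        name=name,
        feature_names=feature_names,
        forest=forest,
        imputation_medians=medians,
        seed=seed,
    )
    train_scores = bundle.scores(train_table)
    bundle.training_threshold = youden_threshold(train_scores, y)
    return bundle


def evaluate(
    bundle: ModelBundle,
    table: pd.DataFrame,
    label_column: str = "idh1",
    threshold: float | None = None,
    reoptimize_threshold: bool = False,
) -> EvaluationReport:
    """Evaluate a fitted bundle on a labeled table.

    The cutoff defaults to the Youden threshold fixed on the training cohort;
    ``reoptimize_threshold=True`` re-optimizes it on the evaluated scores.
    """
    labels = table[label_column].to_numpy().astype(int)
    scores = bundle.scores(table)
    single_class = len(np.unique(labels)) < 2
    if threshold is None:
        if reoptimize_threshold and not single_class:
            threshold = youden_threshold(scores, labels)
        else:
            threshold = bundle.training_threshold
    metrics = confusion_metrics(scores, labels, threshold)
    if single_class:
        import warnings

        warnings.warn("single-class table: AUC undefined", UserWarning, stacklevel=2)
        auc = None
        roc_pts: list = []
        prc_pts: list = []
    else:
        auc = roc_auc(scores, labels)
        fpr, tpr, _ = roc_curve(labels, scores)
        prec, rec, _ = precision_recall_curve(labels, scores)
        roc_pts = list(zip(fpr.tolist(), tpr.tolist()))
        prc_pts = list(zip(rec.tolist(), prec.tolist()))
    return EvaluationReport(
        model=bundle.name,
        threshold=float(threshold),
        metrics=metrics,
        auc=auc,
        roc_points=roc_pts,
        prc_points=prc_pts,
    )
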