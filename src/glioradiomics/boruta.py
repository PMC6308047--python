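"""Boruta all-relevant feature selection with random-forest importance.

Each iteration appends one shadow copy (an independently permuted column) of
every original feature — keeping the shadow pool at full strength for the
whole run, since a shrinking pool weakens the max-shadow null reference and
lets weakly chance-structured survivors through — fits a random forest on
real + shadow columns, and records a "hit" for every undecided feature whose
importance exceeds the maximum shadow importance.  Importance is the per-tree Gini (impurity
decrease) importance Z-scored across trees.  After every iteration a
two-sided binomial test against p = 0.5, Bonferroni-corrected across the
undecided features, confirms features with significantly more hits than
chance and rejects features with significantly fewer.  Features still
undecided at the iteration cap are resolved by the "rough fix": confirmed if
their median importance across iterations exceeds the median of the
max-shadow importance, else rejected.

Unlike minimal-optimal selectors, Boruta keeps *all* features carrying
information about the class, including duplicated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier


@dataclass(frozen=True)
class BorutaConfig:
    max_iterations: int = 100
    alpha: float = 0.05
    rf_trees_per_iter: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.max_iterations < 10:
            raise ValueError("max_iterations must be >= 10")
        if not (0.0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")


@dataclass
class SelectionResult:
    confirmed: list
    rejected: list
    tentative: list
    importance_history: pd.DataFrame  # iterations x features (NaN once decided)
    shadow_max_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        all_sets = [set(self.confirmed), set(self.rejected), set(self.tentative)]
        for i in range(3):
            for j in range(i + 1, 3):
                if all_sets[i] & all_sets[j]:
                    raise ValueError("confirmed/rejected/tentative must be disjoint")


class BorutaSelector:
    """All-relevant feature selector (sklearn-style fit / get_support).

    Attributes after ``fit``: ``confirmed_``, ``rejected_``, ``tentative_``
    (resolved by the rough fix into ``support_``), ``importance_history_``,
    ``shadow_max_history_``, ``n_iterations_``.
    """

    def __init__(self, max_iterations: int = 100, alpha: float = 0.05,
                 rf_trees_per_iter: int = 300, random_state: int = 0):
        self.max_iterations = max_iterations
        self.alpha = alpha
        self.rf_trees_per_iter = rf_trees_per_iter
        self.random_state = random_state

    def get_params(self, deep=True) -> dict:
        return {
            "max_iterations": self.max_iterations,
            "alpha": self.alpha,
            "rf_trees_per_iter": self.rf_trees_per_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "BorutaSelector":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _importance_z(self, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        forest = RandomForestClassifier(
            n_estimators=self.rf_trees_per_iter,
            criterion="gini",
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
        forest.fit(X, y)
        per_tree = np.stack([t.feature_importances_ for t in forest.estimators_])
        mean = per_tree.mean(axis=0)
        sd = per_tree.std(axis=0, ddof=1)
        sd[sd == 0] = 1e-12
        return mean / sd * np.sqrt(per_tree.shape[0])

    def fit(self, X, y) -> "BorutaSelector":
        BorutaConfig(self.max_iterations, self.alpha, self.rf_trees_per_iter,
                     self.random_state).validate()
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=np.float64)
        else:
            Xv = np.asarray(X, dtype=np.float64)
            names = [f"f{i}" for i in range(Xv.shape[1])]
        y = np.asarray(y)
        if Xv.shape[1] < 2:
            raise ValueError("need at least 2 candidate features")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")

        n_features = Xv.shape[1]
        ss = np.random.SeedSequence(self.random_state)
        perm_rng = np.random.default_rng(ss.spawn(1)[0])
        rf_seeds = np.random.default_rng(ss.spawn(1)[0]).integers(
            0, 2**31 - 1, size=self.max_iterations
        )

        undecided = np.ones(n_features, dtype=bool)
        confirmed = np.zeros(n_features, dtype=bool)
        rejected = np.zeros(n_features, dtype=bool)
        hits = np.zeros(n_features, dtype=int)
        history = np.full((self.max_iterations, n_features), np.nan)
        shadow_max_history = []

        it = 0
        for it in range(1, self.max_iterations + 1):
            active = undecided | confirmed  # keep confirmed in the model
            idx_active = np.flatnonzero(active)
            idx_und = np.flatnonzero(undecided)
            # one shadow per original feature, independent of decision state:
            # a shrinking shadow pool weakens the max-shadow null late in the
            # run and lets chance-structured survivors through
            shadows = Xv.copy()
            for c in range(shadows.shape[1]):
                shadows[:, c] = perm_rng.permutation(shadows[:, c])
            design = np.hstack([Xv[:, idx_active], shadows])
            z = self._importance_z(design, y, int(rf_seeds[it - 1]))
            z_real = z[: len(idx_active)]
            z_shadow = z[len(idx_active):]
            shadow_max = z_shadow.max() if len(z_shadow) else 0.0
            shadow_max_history.append(float(shadow_max))
            history[it - 1, idx_active] = z_real

            und_pos = {f: k for k, f in enumerate(idx_active)}
            for f in idx_und:
                if z_real[und_pos[f]] > shadow_max:
                    hits[f] += 1

            # two-sided binomial test, Bonferroni across undecided features
            m = undecided.sum()
            if m == 0:
                break
            thresh = self.alpha / m
            und_idx = np.flatnonzero(undecided)
            h = hits[und_idx]
            p_hi = stats.binom.sf(h - 1, it, 0.5)  # P(X >= h)
            p_lo = stats.binom.cdf(h, it, 0.5)  # P(X <= h)
            newly_conf = und_idx[p_hi < thresh]
            newly_rej = und_idx[(p_lo < thresh) & ~(p_hi < thresh)]
            confirmed[newly_conf] = True
            rejected[newly_rej] = True
            undecided[newly_conf] = False
            undecided[newly_rej] = False
            if not undecided.any():
                break

        history = history[:it]
        self.n_iterations_ = it
        self.hits_ = hits
        self.shadow_max_history_ = shadow_max_history
        self.importance_history_ = pd.DataFrame(history, columns=names)
        self.confirmed_ = [names[f] for f in np.flatnonzero(confirmed)]
        self.rejected_ = [names[f] for f in np.flatnonzero(rejected)]
        self.tentative_ = [names[f] for f in np.flatnonzero(undecided)]

        # rough fix for leftover tentative features
        support = confirmed.copy()
        shadow_median = float(np.median(shadow_max_history))
        for f in np.flatnonzero(undecided):
            med = np.nanmedian(history[:, f])
            if np.isfinite(med) and med > shadow_median:
                support[f] = True
        self.support_ = support
        self.feature_names_in_ = names
        return self

    def get_support(self, indices: bool = False):
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    @property
    def selected_features_(self) -> list:
        return [n for n, s in zip(self.feature_names_in_, self.support_) if s]

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features_]
        return np.asarray(X)[:, self.support_]

    def result_(self) -> SelectionResult:
        return SelectionResult(
            confirmed=list(self.confirmed_),
            rejected=list(self.rejected_),
            tentative=list(self.tentative_),
            importance_history=self.importance_history_,
            shadow_max_history=list(self.shadow_max_history_),
        )


def boruta_select(
    table: pd.DataFrame,
    config: BorutaConfig | None = None,
    label_column: str = "idh1",
) -> SelectionResult:
    """Run Boruta on a labeled feature table."""
    config = config or BorutaConfig()
    est = BorutaSelector(
        max_iterations=config.max_iterations,
        alpha=config.alpha,
        rf_trees_per_iter=config.rf_trees_per_iter,
        random_state=config.seed,
    )
    est.fit(table.drop(columns=[label_column]), table[label_column])
    return est.result_()
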