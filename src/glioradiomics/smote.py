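"""SMOTE oversampling of the minority class on the training table only.

Synthetic minority instances are generated along the segment joining a
minority instance and one of its k nearest minority neighbors:
``x_new = x + u * (x_nn - x)`` with ``u ~ U[0, 1)``.  The majority class is
left untouched and in its original order.  Neighbor search uses Euclidean
distance on z-scored feature columns (training statistics) so that mixed
feature scales do not distort the neighborhoods; ties are broken by lowest
row index.  Categorical / clinical columns of a synthetic row are copied from
its seed instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BalancingConfig:
    target_minority_count: int = 64
    k_neighbors: int = 5
    seed: int = 0


class SMOTEOversampler:
    """Minority-class oversampler (imblearn-style ``fit_resample``).

    Parameters
    ----------
    target_minority_count : int
        Minority class size after balancing (64 in the default protocol).
    k_neighbors : int
        Number of nearest minority neighbors a synthetic point may
        interpolate toward.
    random_state : int
        Seed for the neighbor choice and interpolation coefficient.
    """

    def __init__(self, target_minority_count: int = 64, k_neighbors: int = 5,
                 random_state: int = 0):
        self.target_minority_count = target_minority_count
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def get_params(self, deep=True) -> dict:
        return {
            "target_minority_count": self.target_minority_count,
            "k_neighbors": self.k_neighbors,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "SMOTEOversampler":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_resample(
        self,
        X: pd.DataFrame,
        y: pd.Series | np.ndarray,
        interpolate_columns=None,
    ) -> tuple[pd.DataFrame, pd.Series]:
        """Return the balanced table: original rows first, synthetic after.

        ``interpolate_columns`` restricts interpolation (and the neighbor
        metric) to those columns; the remaining columns of synthetic rows are
        copied verbatim from the seed instance.  Default: every column.
        """
        y = pd.Series(np.asarray(y), index=X.index, name="label")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("SMOTE needs both classes present")
        minority = classes[np.argmin(counts)]
        n_min = counts.min()
        if self.target_minority_count < n_min:
            raise ValueError(
                "target_minority_count must be >= current minority count"
            )
        if n_min <= self.k_neighbors:
            raise ValueError(
                f"minority count {n_min} <= k_neighbors {self.k_neighbors}; "
                f"lower k_neighbors"
            )
        n_syn = self.target_minority_count - n_min
        if n_syn == 0:
            return X.copy(), y.copy()

        cols = list(interpolate_columns) if interpolate_columns is not None else list(X.columns)
        min_mask = (y == minority).to_numpy()
        Xmin = X.loc[min_mask]
        V = Xmin[cols].to_numpy(dtype=np.float64)

        # z-score with training statistics for the neighbor metric
        mu = V.mean(axis=0)
        sd = V.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (V - mu) / sd
        d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        # stable argsort: ties broken by lowest row index
        neighbor_idx = np.argsort(d2, axis=1, kind="stable")[:, : self.k_neighbors]

        rng = np.random.default_rng(self.random_state)
        synthetic = []
        for j in range(n_syn):
            seed_row = j % len(Xmin)
            nn = int(neighbor_idx[seed_row, rng.integers(self.k_neighbors)])
            u = rng.random()
            new = Xmin.iloc[seed_row].copy()
            new[cols] = V[seed_row] + u * (V[nn] - V[seed_row])
            new.name = f"smote-{j:03d}"
            synthetic.append(new)

        X_out = pd.concat([X, pd.DataFrame(synthetic)], axis=0)
        y_out = pd.concat(
            [y, pd.Series([minority] * n_syn, index=[s.name for s in synthetic])]
        )
        return X_out, y_out


def smote_oversample(
    table: pd.DataFrame,
    config: BalancingConfig | None = None,
    label_column: str = "idh1",
    interpolate_columns=None,
) -> pd.DataFrame:
    """Balance a labeled feature table (label column preserved)."""
    config = config or BalancingConfig()
    X = table.drop(columns=[label_column])
    y = table[label_column]
    est = SMOTEOversampler(
        target_minority_count=config.target_minority_count,
        k_neighbors=config.k_neighbors,
        random_state=config.seed,
    )
    if interpolate_columns is None:
        # clinical and categorical columns are copied from the seed instance,
        # not interpolated
        categorical = {"age", "sex", "kps", "location_region", "location_side"}
        interpolate_columns = [c for c in X.columns if c not in categorical]
    X_out, y_out = est.fit_resample(X, y, interpolate_columns=interpolate_columns)
    out = X_out.copy()
    out[label_column] = y_out
    return out
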