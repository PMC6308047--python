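"""Lloyd-Max scalar quantization to a fixed number of gray levels.

Texture matrices need a small discrete alphabet; intensities inside the tumor
are quantized to 64 gray levels with a Lloyd-Max quantizer: alternating
centroid (level = mean of its cell) and boundary (threshold = midpoint of
adjacent levels) updates on the empirical intensity distribution, which is
exactly 1-D k-means / Lloyd's algorithm and minimizes mean-squared
quantization error locally.  Initialization is deterministic (equal-mass
quantiles), so the quantizer needs no seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class QuantizerCodebook:
    """Fitted codebook: ``levels`` representatives and ``boundaries`` thresholds."""

    n_levels: int
    boundaries: tuple  # len n_used - 1, strictly increasing
    levels: tuple  # len n_used, strictly increasing
    n_used: int
    mse: float


class LloydMaxQuantizer:
    """Deterministic Lloyd-Max quantizer (sklearn-style fit/transform).

    Parameters
    ----------
    n_levels : int
        Size of the gray-level alphabet (64 for the texture pipeline).
    tol : float
        Relative MSE improvement below which iteration stops.
    max_iter : int
        Hard iteration cap.

    Attributes
    ----------
    levels_ : ndarray
        Representative value per used level, strictly increasing.
    boundaries_ : ndarray
        Decision thresholds between adjacent used levels.
    mse_ : float
        Final mean-squared quantization error.
    n_used_ : int
        Number of levels actually used (< n_levels iff the input has fewer
        distinct values than levels, in which case each distinct value gets
        its own level and the MSE is 0).
    """

    def __init__(self, n_levels: int = 64, tol: float = 1e-7, max_iter: int = 500):
        if n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        self.n_levels = n_levels
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True) -> dict:
        return {"n_levels": self.n_levels, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "LloydMaxQuantizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, values) -> "LloydMaxQuantizer":
        values = np.asarray(values, dtype=np.float64).ravel()
        if values.size == 0:
            raise ValueError("cannot fit quantizer on empty input")
        srt = np.sort(values)
        uniq = np.unique(srt)
        self.mse_history_ = []
        if uniq.size <= self.n_levels:
            self.levels_ = uniq
            self.boundaries_ = (uniq[:-1] + uniq[1:]) / 2.0
            self.n_used_ = uniq.size
            self.mse_ = 0.0
            self.mse_history_.append(0.0)
            return self

        n = self.n_levels
        # Two deterministic initializations: equal-mass quantiles (good for
        # heavy tails) and equal-width midpoints (whose first Lloyd step IS
        # uniform binning, so the final MSE never exceeds it).  Keep the
        # lower-MSE run; Lloyd's updates are monotone within each run.
        q = (np.arange(n) + 0.5) / n
        inits = [
            np.quantile(srt, q),
            srt[0] + (np.arange(n) + 0.5) * (srt[-1] - srt[0]) / n,
        ]
        best = None
        for init in inits:
            levels = init.astype(np.float64)
            history = []
            prev_mse = np.inf
            for _ in range(self.max_iter):
                boundaries = (levels[:-1] + levels[1:]) / 2.0
                idx = np.searchsorted(boundaries, srt, side="right")
                # cell means via bincount on the sorted data
                counts = np.bincount(idx, minlength=n)
                sums = np.bincount(idx, weights=srt, minlength=n)
                nonempty = counts > 0
                levels = levels.copy()
                levels[nonempty] = sums[nonempty] / counts[nonempty]
                # an empty cell keeps its previous representative
                mse = np.mean((srt - levels[idx]) ** 2)
                history.append(float(mse))
                if prev_mse - mse < self.tol * max(prev_mse, 1e-300):
                    break
                prev_mse = mse
            if best is None or mse < best[0]:
                best = (mse, levels, history)
        mse, levels, self.mse_history_ = best
        order = np.argsort(levels, kind="stable")
        levels = levels[order]
        self.levels_ = levels
        self.boundaries_ = (levels[:-1] + levels[1:]) / 2.0
        self.n_used_ = n
        self.mse_ = float(mse)
        return self

    @property
    def codebook_(self) -> QuantizerCodebook:
        return QuantizerCodebook(
            n_levels=self.n_levels,
            boundaries=tuple(float(b) for b in self.boundaries_),
            levels=tuple(float(v) for v in self.levels_),
            n_used=self.n_used_,
            mse=self.mse_,
        )

    def transform(self, values) -> np.ndarray:
        """Return 1-based level indices (1..n_levels) for ``values``."""
        if not hasattr(self, "levels_"):
            raise ValueError("quantizer is not fitted")
        x = np.asarray(values, dtype=np.float64)
        return (np.searchsorted(self.boundaries_, x, side="right") + 1).astype(np.int16)

    def fit_transform(self, values) -> np.ndarray:
        return self.fit(values).transform(values)


def lloyd_max_quantize(values, n_levels: int = 64, tol: float = 1e-7, max_iter: int = 500):
    """Fit a Lloyd-Max quantizer and quantize ``values``.

    Returns ``(codebook, labels)`` with labels in 1..n_levels.
    """
    est = LloydMaxQuantizer(n_levels=n_levels, tol=tol, max_iter=max_iter)
    labels = est.fit_transform(values)
    return est.codebook_, labels
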