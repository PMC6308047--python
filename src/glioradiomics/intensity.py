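"""First-order intensity statistics over a region mask.

The 14 statistics are computed on the standardized intensities of the masked
voxels.  Entropy and Uniformity are histogram features; when the caller
supplies the 64-level quantized labels (the extraction pipeline does, so that
first-order and texture features share one gray-level alphabet) the histogram
is the level histogram, otherwise a 64-bin equal-width histogram over the
masked range is used.  Entropy is in bits.  Variance and standard deviation
are population (n) moments; Skewness is the standardized third moment and
Kurtosis the standardized fourth moment (Pearson, not excess); both are 0 by
convention for constant input.
"""

from __future__ import annotations

import numpy as np

N_BINS = 64


def intensity_features(values: np.ndarray, quantized: np.ndarray | None = None) -> dict:
    """The 14 first-order statistics of ``values`` (masked voxels, 1-D).

    Returns NaN for every feature when ``values`` is empty.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    names = (
        "MaxValue", "MedianValue", "MinValue", "MeanValue", "Range", "Energy",
        "Entropy", "Variance", "Kurtosis", "Uniformity", "RootMeanSquare",
        "Skewness", "StandardDeviation", "MeanAbsoluteDeviation",
    )
    if x.size == 0:
        return {name: np.nan for name in names}

    n = x.size
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    centered = x - mean
    if sd > 0:
        skew = np.mean(centered**3) / sd**3
        kurt = np.mean(centered**4) / var**2
    else:
        skew = 0.0
        kurt = 0.0

    if quantized is not None:
        q = np.asarray(quantized).ravel()
        counts = np.bincount(q)[1:]  # levels are 1-based
    else:
        counts, _ = np.histogram(x, bins=N_BINS)
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    return {
        "MaxValue": float(x.max()),
        "MedianValue": float(np.median(x)),
        "MinValue": float(x.min()),
        "MeanValue": float(mean),
        "Range": float(x.max() - x.min()),
        "Energy": float(np.sum(x**2)),
        "Entropy": entropy,
        "Variance": float(var),
        "Kurtosis": float(kurt),
        "Uniformity": uniformity,
        "RootMeanSquare": float(np.sqrt(np.sum(x**2) / n)),
        "Skewness": float(skew),
        "StandardDeviation": float(sd),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centered))),
    }
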