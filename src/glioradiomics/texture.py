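"""Gray-level texture matrices and their scalar features.

All four matrix families work on a 64-level quantized volume restricted to a
region mask, with 26-voxel connectivity expressed as 13 unique direction
offsets at distance 1:

* GLCM: voxel-pair co-occurrences accumulated (merged) over the 13 offsets,
  each ordered pair counted both ways so the matrix is symmetric, then
  normalized to probabilities.  Only pairs with both voxels in-mask count.
* GLRLM: one run-length matrix per direction over maximal in-mask collinear
  same-level runs; scalar features are averaged over the 13 directions.
* GLSZM: zones are maximal 26-connected same-level in-mask components;
  direction-free, computed once.
* NGTDM: per level, the summed absolute difference between each in-mask voxel
  and the mean of its in-mask 26-neighbors (voxels with no in-mask neighbor
  are excluded).

Feature formulas follow the standard Haralick / Galloway / Thibault /
Amadasun definitions, including both homogeneity variants and both
informational measures of correlation.  Degenerate denominators yield 0 for
variance-normalized features; NGTDM Coarseness is capped at 1e9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

N_LEVELS = 64
_EPS = 1e-9
_COARSENESS_CAP = 1e9

#: The 13 unique direction offsets of the 26-neighborhood (one per +/- pair).
DIRECTIONS = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def _shift(arr: np.ndarray, off, fill) -> np.ndarray:
    """Return ``out`` with ``out[i] = arr[i + off]``, ``fill`` outside."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, o in zip(arr.shape, off):
        if o >= 0:
            dst.append(slice(0, max(n - o, 0)))
            src.append(slice(o, n))
        else:
            dst.append(slice(-o, n))
            src.append(slice(0, n + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


@dataclass
class RunLengthMatrices:
    """Per-direction run-length count matrices, shape (n_levels, max_run)."""

    matrices: list
    n_voxels: int
    n_levels: int


@dataclass
class SizeZoneMatrix:
    """Zone counts in compressed form: parallel (level, size, count) arrays."""

    levels: np.ndarray
    sizes: np.ndarray
    counts: np.ndarray
    n_voxels: int
    n_levels: int

    def to_dense(self) -> np.ndarray:
        max_size = int(self.sizes.max()) if len(self.sizes) else 1
        dense = np.zeros((self.n_levels, max_size))
        for g, s, c in zip(self.levels, self.sizes, self.counts):
            dense[g - 1, s - 1] += c
        return dense


@dataclass
class NGTDMatrix:
    """Per-level occurrence counts n_i and summed neighborhood differences s_i."""

    n: np.ndarray
    s: np.ndarray
    n_voxels: int
    n_levels: int


@dataclass
class TextureMatrices:
    glcm: np.ndarray  # (n_levels, n_levels) probabilities, symmetric
    glrlm: RunLengthMatrices
    glszm: SizeZoneMatrix
    ngtdm: NGTDMatrix


def glcm_matrix(quantized: np.ndarray, mask: np.ndarray, n_levels: int = N_LEVELS) -> np.ndarray:
    """Direction-merged symmetric normalized co-occurrence matrix."""
    if not mask.any():
        raise ValueError("empty mask")
    lv = np.asarray(quantized, dtype=np.int64)
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in DIRECTIONS:
        m2 = _shift(mask, off, False)
        valid = mask & m2
        if not valid.any():
            continue
        lv2 = _shift(lv, off, 0)
        a = lv[valid] - 1
        b = lv2[valid] - 1
        flat = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
        counts += flat.reshape(n_levels, n_levels)
    counts = counts + counts.T  # each ordered pair both ways
    total = counts.sum()
    if total == 0:
        # no valid voxel pair (isolated voxels): fall back to the diagonal
        # level histogram so the matrix still normalizes
        hist = np.bincount(lv[mask] - 1, minlength=n_levels)
        counts[np.arange(n_levels), np.arange(n_levels)] = hist
        total = counts.sum()
    return counts / total


def glrlm_matrices(quantized: np.ndarray, mask: np.ndarray, n_levels: int = N_LEVELS) -> RunLengthMatrices:
    """Per-direction run-length matrices over maximal same-level runs.

    Uses the window-count identity: if c_k(g) is the number of in-mask
    uniform windows of length k at level g along the direction, the number of
    maximal runs of length exactly l is c_l - 2 c_{l+1} + c_{l+2}.
    """
    if not mask.any():
        raise ValueError("empty mask")
    lv = np.asarray(quantized, dtype=np.int64)
    n_vox = int(mask.sum())
    matrices = []
    for off in DIRECTIONS:
        same = mask & _shift(mask, off, False) & (lv == _shift(lv, off, -1))
        w = mask.copy()
        window_counts = []
        k = 1
        while w.any():
            window_counts.append(np.bincount(lv[w] - 1, minlength=n_levels))
            step = tuple(o * (k - 1) for o in off) if k > 1 else (0, 0, 0)
            w = w & _shift(same, step, False)
            k += 1
        c = np.asarray(window_counts, dtype=np.float64)  # (K, n_levels)
        K = c.shape[0]
        ext = np.zeros((K + 2, n_levels))
        ext[:K] = c
        runs = ext[:K] - 2.0 * ext[1 : K + 1] + ext[2 : K + 2]
        matrices.append(runs.T.copy())  # (n_levels, K)
    return RunLengthMatrices(matrices=matrices, n_voxels=n_vox, n_levels=n_levels)


def glszm_matrix(quantized: np.ndarray, mask: np.ndarray, n_levels: int = N_LEVELS) -> SizeZoneMatrix:
    """Size-zone counts over maximal 26-connected same-level components."""
    if not mask.any():
        raise ValueError("empty mask")
    lv = np.asarray(quantized, dtype=np.int64)
    levels_out, sizes_out, counts_out = [], [], []
    for g in np.unique(lv[mask]):
        comp, n_comp = ndimage.label((lv == g) & mask, structure=_STRUCTURE_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        for size, count in zip(*np.unique(sizes, return_counts=True)):
            levels_out.append(int(g))
            sizes_out.append(int(size))
            counts_out.append(int(count))
    return SizeZoneMatrix(
        levels=np.asarray(levels_out, dtype=np.int64),
        sizes=np.asarray(sizes_out, dtype=np.int64),
        counts=np.asarray(counts_out, dtype=np.float64),
        n_voxels=int(mask.sum()),
        n_levels=n_levels,
    )


def ngtdm_matrix(quantized: np.ndarray, mask: np.ndarray, n_levels: int = N_LEVELS) -> NGTDMatrix:
    """Neighborhood gray-tone difference totals per level."""
    if not mask.any():
        raise ValueError("empty mask")
    lv = np.asarray(quantized, dtype=np.float64)
    m = mask.astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_n = ndimage.convolve(m, kernel, mode="constant")
    neigh_sum = ndimage.convolve(lv * m, kernel, mode="constant")
    valid = mask & (neigh_n > 0)
    g = np.asarray(quantized, dtype=np.int64)[valid] - 1
    diffs = np.abs(lv[valid] - neigh_sum[valid] / neigh_n[valid])
    return NGTDMatrix(
        n=np.bincount(g, minlength=n_levels).astype(np.float64),
        s=np.bincount(g, weights=diffs, minlength=n_levels),
        n_voxels=int(valid.sum()),
        n_levels=n_levels,
    )


def compute_texture_matrices(quantized: np.ndarray, mask: np.ndarray, n_levels: int = N_LEVELS) -> TextureMatrices:
    """All four matrix families for one (region, channel)."""
    return TextureMatrices(
        glcm=glcm_matrix(quantized, mask, n_levels),
        glrlm=glrlm_matrices(quantized, mask, n_levels),
        glszm=glszm_matrix(quantized, mask, n_levels),
        ngtdm=ngtdm_matrix(quantized, mask, n_levels),
    )


# ---------------------------------------------------------------------------
# scalar features


def glcm_features(P: np.ndarray) -> dict:
    """The 21 GLCM features of a normalized symmetric co-occurrence matrix."""
    N = P.shape[0]
    i = np.arange(1, N + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)
    nz = P > 0

    # sum / difference distributions
    p_sum = np.zeros(2 * N + 1)  # index k = i + j, 2..2N
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(N)  # index k = |i - j|, 0..N-1
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    ks = np.arange(2 * N + 1)
    kd = np.arange(N)
    sum_avg = float((ks * p_sum).sum())
    diff_avg = float((kd * p_diff).sum())

    def _ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    entropy = _ent(P.ravel())
    hx = _ent(px)
    # symmetric matrix: py == px, HY == HX
    pxpy = np.outer(px, px)
    both = nz & (pxpy > 0)
    hxy1 = float(-(P[both] * np.log2(pxpy[both])).sum())
    pp = pxpy[pxpy > 0]
    hxy2 = float(-(pp * np.log2(pp)).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0  # HY == HX by symmetry
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    if sigma > 0:
        correlation = float((((ii - mu) * (jj - mu) * P).sum()) / sigma2)
    else:
        correlation = 0.0

    return {
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": correlation,
        "Autocorrelation": float((ii * jj * P).sum()),
        "Energy": float((P**2).sum()),
        "Variance": sigma2,
        "Dissimilarity": float((np.abs(ii - jj) * P).sum()),
        "Entropy": entropy,
        "SumAverage": sum_avg,
        "SumEntropy": _ent(p_sum),
        "SumVariance": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "DifferenceVariance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
        "DifferenceEntropy": _ent(p_diff),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * P).sum()),
        "MaximumProbability": float(P.max()),
        "Homogeneity1": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Homogeneity2": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "InformationalMeasureOfCorrelation1": float(imc1),
        "InformationalMeasureOfCorrelation2": imc2,
        "InverseDifferenceMomentNormalized": float((P / (1.0 + (ii - jj) ** 2 / N**2)).sum()),
        "InverseDifferenceNormalized": float((P / (1.0 + np.abs(ii - jj) / N)).sum()),
    }


def _run_zone_features(mat: np.ndarray, n_voxels: int, prefix: str) -> dict:
    """Shared Galloway/Thibault feature set for one run-length or size-zone
    count matrix ``mat`` of shape (n_levels, max_size)."""
    G, L = mat.shape
    g = np.arange(1, G + 1)[:, None].astype(np.float64)
    l = np.arange(1, L + 1)[None, :].astype(np.float64)
    Nr = mat.sum()
    if Nr == 0:
        return {name: 0.0 for name in _RZ_NAMES[prefix]}
    p = mat / Nr
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    mu_l = float((p * l).sum())
    mu_g = float((p * g).sum())
    short_name, long_name, sn, ln_ = _RZ_PREFIXES[prefix]
    return {
        f"{short_name}Emphasis": float((mat / l**2).sum() / Nr),
        f"{long_name}Emphasis": float((mat * l**2).sum() / Nr),
        "GrayLevelNonuniformity": float((row**2).sum() / Nr),
        f"{prefix}Nonuniformity": float((col**2).sum() / Nr),
        f"{sn}Percentage": float(Nr / n_voxels),
        f"LowGrayLevel{ln_}Emphasis": float((mat / g**2).sum() / Nr),
        f"HighGrayLevel{ln_}Emphasis": float((mat * g**2).sum() / Nr),
        f"{prefix}Variance": float((p * (l - mu_l) ** 2).sum()),
        f"{short_name}LowGrayLevelEmphasis": float((mat / (g**2 * l**2)).sum() / Nr),
        f"{short_name}HighGrayLevelEmphasis": float((mat * g**2 / l**2).sum() / Nr),
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        f"{long_name}LowGrayLevelEmphasis": float((mat * l**2 / g**2).sum() / Nr),
        f"{long_name}HighGrayLevelEmphasis": float((mat * l**2 * g**2).sum() / Nr),
    }


_RZ_PREFIXES = {
    # prefix -> (short, long, percentage prefix, run/zone word)
    "RunLength": ("ShortRun", "LongRun", "Run", "Run"),
    "ZoneSize": ("SmallZone", "LargeZone", "Zone", "Zone"),
}
_RZ_NAMES = {
    prefix: tuple(
        _run_zone_features(np.ones((2, 2)), 4, prefix).keys()
    )
    for prefix in ("RunLength", "ZoneSize")
}


def glrlm_features(rlm: RunLengthMatrices) -> dict:
    """The 13 GLRLM features, averaged over the 13 per-direction matrices."""
    acc: dict = {}
    for mat in rlm.matrices:
        feats = _run_zone_features(mat, rlm.n_voxels, "RunLength")
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    n = len(rlm.matrices)
    return {k: v / n for k, v in acc.items()}


def glszm_features(szm: SizeZoneMatrix) -> dict:
    """The 13 GLSZM features (direction-free, computed once)."""
    max_size = int(szm.sizes.max()) if len(szm.sizes) else 1
    mat = np.zeros((szm.n_levels, max_size))
    if len(szm.sizes):
        np.add.at(mat, (szm.levels - 1, szm.sizes - 1), szm.counts)
    return _run_zone_features(mat, szm.n_voxels, "ZoneSize")


def ngtdm_features(m: NGTDMatrix) -> dict:
    """The 5 NGTDM features (Amadasun & King)."""
    N = m.n_voxels
    if N == 0:
        return {k: 0.0 for k in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p = m.n / N
    s = m.s
    present = p > 0
    i = np.arange(1, m.n_levels + 1, dtype=np.float64)
    pi, si, gi = p[present], s[present], i[present]
    n_gp = int(present.sum())

    ps = float((pi * si).sum())
    coarseness = min(1.0 / max(ps, _EPS), _COARSENESS_CAP)

    if n_gp > 1:
        di = gi[:, None] - gi[None, :]
        pij = pi[:, None] * pi[None, :]
        contrast = float((pij * di**2).sum() / (n_gp * (n_gp - 1)) * (s.sum() / N))
        denom_busy = float(np.abs(gi[:, None] * pi[:, None] - gi[None, :] * pi[None, :]).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        psi = pi * si
        complexity = float(
            (np.abs(di) * (psi[:, None] + psi[None, :]) / (pi[:, None] + pi[None, :])).sum() / N
        )
        s_total = float(s.sum())
        strength = (
            float(((pi[:, None] + pi[None, :]) * di**2).sum()) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(matrices: TextureMatrices) -> dict:
    """All 52 texture features of one (region, channel), keyed family_name."""
    out = {}
    for name, value in glcm_features(matrices.glcm).items():
        out[f"GLCM_{name}"] = value
    for name, value in glrlm_features(matrices.glrlm).items():
        out[f"GLRLM_{name}"] = value
    for name, value in glszm_features(matrices.glszm).items():
        out[f"GLSZM_{name}"] = value
    for name, value in ngtdm_features(matrices.ngtdm).items():
        out[f"NGTDM_{name}"] = value
    return out
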