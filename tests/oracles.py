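"""Independent brute-force oracles used by the test suite.

Everything here is written for clarity at tiny problem sizes (explicit voxel
loops, flood fills, exhaustive pair enumeration) and is deliberately separate
from the vectorized implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def ellipsoid_members(shape, spacing, center, radii):
    """Voxel-by-voxel ellipsoid membership test."""
    members = set()
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                pz = z * spacing[0] - center[0]
                py = y * spacing[1] - center[1]
                px = x * spacing[2] - center[2]
                if (pz / radii[0]) ** 2 + (py / radii[1]) ** 2 + (px / radii[2]) ** 2 <= 1.0:
                    members.add((z, y, x))
    return members


def percentile_sorted(values, q):
    """Linear-interpolation percentile computed from an explicit sort."""
    srt = sorted(float(v) for v in values)
    n = len(srt)
    pos = (n - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return srt[lo] * (1 - frac) + srt[hi] * frac


def uniform_binning_mse(values, n_levels):
    """MSE of equal-width binning with per-bin mean representatives."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, n_levels + 1)
    idx = np.clip(np.digitize(values, edges[1:-1]), 0, n_levels - 1)
    err = 0.0
    for b in range(n_levels):
        sel = values[idx == b]
        if len(sel):
            err += ((sel - sel.mean()) ** 2).sum()
    return err / len(values)


# ---------------------------------------------------------------------------
# texture matrix oracles (explicit enumeration)


def _in(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def glcm_oracle(levels, mask, n_levels):
    """Pair loop over the 13 offsets, each ordered pair counted both ways."""
    shape = mask.shape
    counts = np.zeros((n_levels, n_levels))
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                for d in DIRECTIONS_13:
                    w = (z + d[0], y + d[1], x + d[2])
                    if _in(shape, w) and mask[w]:
                        a = levels[z, y, x] - 1
                        b = levels[w] - 1
                        counts[a, b] += 1
                        counts[b, a] += 1
    total = counts.sum()
    if total == 0:
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if mask[z, y, x]:
                        g = levels[z, y, x] - 1
                        counts[g, g] += 1
        total = counts.sum()
    return counts / total


def glrlm_oracle(levels, mask, n_levels):
    """Run scan: per direction, list maximal collinear same-level runs."""
    shape = mask.shape
    out = []
    for d in DIRECTIONS_13:
        runs = {}  # (level, length) -> count
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    v = (z, y, x)
                    if not mask[v]:
                        continue
                    prev = (z - d[0], y - d[1], x - d[2])
                    if _in(shape, prev) and mask[prev] and levels[prev] == levels[v]:
                        continue  # not a run start
                    length = 1
                    cur = v
                    while True:
                        nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                        if _in(shape, nxt) and mask[nxt] and levels[nxt] == levels[v]:
                            length += 1
                            cur = nxt
                        else:
                            break
                    key = (int(levels[v]), length)
                    runs[key] = runs.get(key, 0) + 1
        max_len = max((l for (_, l) in runs), default=1)
        mat = np.zeros((n_levels, max_len))
        for (g, l), c in runs.items():
            mat[g - 1, l - 1] = c
        out.append(mat)
    return out


def glszm_oracle(levels, mask, n_levels):
    """Flood fill of maximal 26-connected same-level zones.

    Returns dict (level, size) -> count.
    """
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    zones = {}
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                v = (z, y, x)
                if not mask[v] or seen[v]:
                    continue
                g = levels[v]
                stack = [v]
                seen[v] = True
                size = 0
                while stack:
                    cur = stack.pop()
                    size += 1
                    for d in NEIGHBORS_26:
                        w = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                        if (
                            _in(shape, w) and mask[w] and not seen[w]
                            and levels[w] == g
                        ):
                            seen[w] = True
                            stack.append(w)
                key = (int(g), size)
                zones[key] = zones.get(key, 0) + 1
    return zones


def ngtdm_oracle(levels, mask, n_levels):
    """Neighbor loop: per-level counts and summed |value - neighborhood mean|."""
    shape = mask.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    total = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                v = (z, y, x)
                if not mask[v]:
                    continue
                neigh = [
                    levels[v[0] + d[0], v[1] + d[1], v[2] + d[2]]
                    for d in NEIGHBORS_26
                    if _in(shape, (v[0] + d[0], v[1] + d[1], v[2] + d[2]))
                    and mask[v[0] + d[0], v[1] + d[1], v[2] + d[2]]
                ]
                if not neigh:
                    continue
                g = int(levels[v])
                n_i[g - 1] += 1
                s_i[g - 1] += abs(float(levels[v]) - sum(neigh) / len(neigh))
                total += 1
    return n_i, s_i, total


# ---------------------------------------------------------------------------
# direct-formula feature oracles (explicit double loops)


def glcm_features_oracle(P):
    N = P.shape[0]
    mu = sum((i + 1) * P[i, :].sum() for i in range(N))
    sigma2 = sum((i + 1 - mu) ** 2 * P[i, :].sum() for i in range(N))
    feats = {}
    contrast = corr = autoc = energy = dissim = ent = 0.0
    hom1 = hom2 = idmn = idn = shade = prom = 0.0
    p_sum = np.zeros(2 * N + 1)
    p_diff = np.zeros(N)
    for i in range(N):
        for j in range(N):
            p = P[i, j]
            a, b = i + 1, j + 1
            contrast += (a - b) ** 2 * p
            autoc += a * b * p
            energy += p * p
            dissim += abs(a - b) * p
            if p > 0:
                ent -= p * math.log2(p)
            hom1 += p / (1 + abs(a - b))
            hom2 += p / (1 + (a - b) ** 2)
            idmn += p / (1 + (a - b) ** 2 / N**2)
            idn += p / (1 + abs(a - b) / N)
            shade += (a + b - 2 * mu) ** 3 * p
            prom += (a + b - 2 * mu) ** 4 * p
            p_sum[a + b] += p
            p_diff[abs(a - b)] += p
            if sigma2 > 0:
                corr += (a - mu) * (b - mu) * p / sigma2
    sum_avg = sum(k * p_sum[k] for k in range(len(p_sum)))
    sum_ent = -sum(p * math.log2(p) for p in p_sum if p > 0)
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(len(p_sum)))
    diff_avg = sum(k * p_diff[k] for k in range(N))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(N))
    diff_ent = -sum(p * math.log2(p) for p in p_diff if p > 0)
    px = [P[i, :].sum() for i in range(N)]
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hxy1 = 0.0
    hxy2 = 0.0
    for i in range(N):
        for j in range(N):
            q = px[i] * px[j]
            if q > 0:
                hxy2 -= q * math.log2(q)
                if P[i, j] > 0:
                    hxy1 -= P[i, j] * math.log2(q)
    imc1 = (ent - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - ent))))
    feats.update({
        "Contrast": contrast, "Correlation": corr, "Autocorrelation": autoc,
        "Energy": energy, "Variance": sigma2, "Dissimilarity": dissim,
        "Entropy": ent, "SumAverage": sum_avg, "SumEntropy": sum_ent,
        "SumVariance": sum_var, "DifferenceVariance": diff_var,
        "DifferenceEntropy": diff_ent, "ClusterProminence": prom,
        "ClusterShade": shade, "MaximumProbability": float(P.max()),
        "Homogeneity1": hom1, "Homogeneity2": hom2,
        "InformationalMeasureOfCorrelation1": imc1,
        "InformationalMeasureOfCorrelation2": imc2,
        "InverseDifferenceMomentNormalized": idmn,
        "InverseDifferenceNormalized": idn,
    })
    return feats


def _rz_features_oracle(mat, n_voxels, kind):
    G, L = mat.shape
    Nr = mat.sum()
    sre = lre = gln = rln = lgl = hgl = srl = srh = lrl = lrh = 0.0
    mu_l = mu_g = 0.0
    for g in range(1, G + 1):
        for l in range(1, L + 1):
            r = mat[g - 1, l - 1]
            sre += r / l**2
            lre += r * l**2
            lgl += r / g**2
            hgl += r * g**2
            srl += r / (g**2 * l**2)
            srh += r * g**2 / l**2
            lrl += r * l**2 / g**2
            lrh += r * l**2 * g**2
            mu_l += r * l / Nr
            mu_g += r * g / Nr
    rlv = glv = 0.0
    for g in range(1, G + 1):
        for l in range(1, L + 1):
            p = mat[g - 1, l - 1] / Nr
            rlv += p * (l - mu_l) ** 2
            glv += p * (g - mu_g) ** 2
    for g in range(G):
        gln += mat[g, :].sum() ** 2
    for l in range(L):
        rln += mat[:, l].sum() ** 2
    if kind == "run":
        names = (
            "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonuniformity",
            "RunLengthNonuniformity", "RunPercentage", "LowGrayLevelRunEmphasis",
            "HighGrayLevelRunEmphasis", "RunLengthVariance",
            "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
            "GrayLevelVariance", "LongRunLowGrayLevelEmphasis",
            "LongRunHighGrayLevelEmphasis",
        )
    else:
        names = (
            "SmallZoneEmphasis", "LargeZoneEmphasis", "GrayLevelNonuniformity",
            "ZoneSizeNonuniformity", "ZonePercentage", "LowGrayLevelZoneEmphasis",
            "HighGrayLevelZoneEmphasis", "ZoneSizeVariance",
            "SmallZoneLowGrayLevelEmphasis", "SmallZoneHighGrayLevelEmphasis",
            "GrayLevelVariance", "LargeZoneLowGrayLevelEmphasis",
            "LargeZoneHighGrayLevelEmphasis",
        )
    values = (
        sre / Nr, lre / Nr, gln / Nr, rln / Nr, Nr / n_voxels, lgl / Nr,
        hgl / Nr, rlv, srl / Nr, srh / Nr, glv, lrl / Nr, lrh / Nr,
    )
    return dict(zip(names, values))


def glrlm_features_oracle(matrices, n_voxels):
    accum = {}
    for mat in matrices:
        f = _rz_features_oracle(mat, n_voxels, "run")
        for k, v in f.items():
            accum[k] = accum.get(k, 0.0) + v
    return {k: v / len(matrices) for k, v in accum.items()}


def glszm_features_oracle(zones, n_voxels, n_levels):
    max_size = max((s for (_, s) in zones), default=1)
    mat = np.zeros((n_levels, max_size))
    for (g, s), c in zones.items():
        mat[g - 1, s - 1] = c
    return _rz_features_oracle(mat, n_voxels, "zone")


def ngtdm_features_oracle(n_i, s_i, total, n_levels):
    p = n_i / total
    present = [i for i in range(n_levels) if p[i] > 0]
    ps = sum(p[i] * s_i[i] for i in present)
    coarseness = min(1.0 / max(ps, 1e-9), 1e9)
    ngp = len(present)
    if ngp > 1:
        acc = 0.0
        for i in present:
            for j in present:
                acc += p[i] * p[j] * (i - j) ** 2
        contrast = acc / (ngp * (ngp - 1)) * (s_i.sum() / total)
        denom = 0.0
        for i in present:
            for j in present:
                denom += abs((i + 1) * p[i] - (j + 1) * p[j])
        busyness = ps / denom if denom > 0 else 0.0
        complexity = 0.0
        for i in present:
            for j in present:
                complexity += (
                    abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
                )
        complexity /= total
        strength_num = 0.0
        for i in present:
            for j in present:
                strength_num += (p[i] + p[j]) * (i - j) ** 2
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
        "Complexity": complexity, "Strength": strength,
    }
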