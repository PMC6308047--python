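"""3-D shape descriptors of the tumor subregion masks.

All descriptors are computed in mm from the voxel grid directly (no meshing):

* Volume: voxel count times voxel volume.
* Surface area: exact boundary-face count of the voxel mask times face area.
* Longest diameter: maximum pairwise Euclidean distance between voxel centers
  on the mask surface (computed via the convex hull for speed).
* Solidity: mask volume over convex-hull volume of the voxel centers.
* Eccentricity: sqrt(1 - lambda_min / lambda_max) of the voxel-coordinate
  covariance eigenvalues.
* Sphericity: pi^(1/3) (6V)^(2/3) / A; Spherical disproportion is its
  reciprocal; Compactness is the V / (sqrt(pi) A^(3/2)) variant.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .regions import BASE_REGION_NAMES, RegionSet


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Total area of voxel faces between mask and non-mask (exact)."""
    sz, sy, sx = spacing
    face_areas = (sy * sx, sz * sx, sz * sy)
    padded = np.pad(mask, 1)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += np.count_nonzero(diff) * fa
    return float(area)


def _surface_voxel_coords(mask: np.ndarray, spacing) -> np.ndarray:
    """mm coordinates of voxel centers on the mask surface."""
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1, 1:-1] & padded[2:, 1:-1, 1:-1]
        & padded[1:-1, :-2, 1:-1] & padded[1:-1, 2:, 1:-1]
        & padded[1:-1, 1:-1, :-2] & padded[1:-1, 1:-1, 2:]
    )
    surface = mask & ~interior
    coords = np.argwhere(surface).astype(np.float64)
    return coords * np.asarray(spacing)


def _longest_diameter(mask: np.ndarray, spacing) -> float:
    pts = _surface_voxel_coords(mask, spacing)
    if len(pts) < 2:
        return 0.0
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # degenerate (coplanar/collinear) sets: brute-force all points
    if len(pts) > 2000:  # extremely non-convex masks; cap the pair count
        pts = pts[:: len(pts) // 2000 + 1]
    return float(pdist(pts).max())


def _solidity(mask: np.ndarray, spacing, volume: float) -> float:
    coords = np.argwhere(mask).astype(np.float64) * np.asarray(spacing)
    if len(coords) < 5:
        return 1.0
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return 1.0
    if hull.volume <= 0:
        return 1.0
    # hull of voxel centers can be slightly smaller than the voxel volume;
    # clip so solidity stays in (0, 1]
    return float(min(volume / hull.volume, 1.0))


def _eccentricity(mask: np.ndarray, spacing) -> float:
    coords = np.argwhere(mask).astype(np.float64) * np.asarray(spacing)
    if len(coords) < 2:
        return 0.0
    cov = np.cov(coords, rowvar=False)
    eig = np.linalg.eigvalsh(cov)
    lam_min, lam_max = eig[0], eig[-1]
    if lam_max <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - lam_min / lam_max)))


def shape_descriptors(mask: np.ndarray, spacing, whole_volume_mm3: float) -> dict:
    """The 10 shape descriptors for one mask (tumor core or whole tumor)."""
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))
    n = int(mask.sum())
    if n == 0:
        return {name: np.nan for name in (
            "Volume", "SubregionProportion", "SurfaceArea", "LongestDiameter",
            "Solidity", "Eccentricity", "Compactness", "SphericalDisproportion",
            "SurfaceAreaToVolumeRatio", "Sphericity",
        )}
    volume = n * voxel_volume
    area = _surface_area(mask, spacing)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    return {
        "Volume": volume,
        "SubregionProportion": volume / whole_volume_mm3,
        "SurfaceArea": area,
        "LongestDiameter": _longest_diameter(mask, spacing),
        "Solidity": _solidity(mask, spacing, volume),
        "Eccentricity": _eccentricity(mask, spacing),
        "Compactness": volume / (np.sqrt(np.pi) * area ** 1.5),
        "SphericalDisproportion": 1.0 / sphericity,
        "SurfaceAreaToVolumeRatio": area / volume,
        "Sphericity": sphericity,
    }


def geometry_features(regions: RegionSet) -> dict:
    """All 28 geometry features, keyed by qualified catalog name.

    Empty base subregions contribute zero volume and zero proportion (they
    are genuinely absent, not unmeasured); an empty whole tumor is an error.
    """
    spacing = regions.spacing
    voxel_volume = float(np.prod(spacing))
    whole = regions["whole_tumor"]
    if not whole.any():
        raise ValueError("whole tumor mask is empty")
    whole_volume = float(whole.sum()) * voxel_volume

    out: dict = {}
    for region in ("tumor_core", "whole_tumor"):
        desc = shape_descriptors(regions[region], spacing, whole_volume)
        for feat, value in desc.items():
            out[f"geometry_{feat}_{region}"] = value
    for region in BASE_REGION_NAMES:
        volume = float(regions[region].sum()) * voxel_volume
        out[f"geometry_Volume_{region}"] = volume
        out[f"geometry_SubregionProportion_{region}"] = volume / whole_volume
    return out
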