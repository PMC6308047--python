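"""Shape descriptors and first-order intensity statistics."""

import numpy as np
import pytest

from glioradiomics.geometry import geometry_features, shape_descriptors
from glioradiomics.intensity import intensity_features
from glioradiomics.regions import derive_regions


def _ball_mask(radius, size):
    c = (size - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(size)] * 3, indexing="ij")
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


class TestShapeDescriptors:
    def test_cube_closed_form(self):
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[2:12, 2:12, 2:12] = True
        d = shape_descriptors(mask, (1.0, 1.0, 1.0), whole_volume_mm3=1000.0)
        assert d["Volume"] == 1000.0
        assert d["SurfaceArea"] == 600.0
        expected_sphericity = np.pi ** (1 / 3) * (6 * 1000.0) ** (2 / 3) / 600.0
        assert d["Sphericity"] == pytest.approx(expected_sphericity)
        assert d["Sphericity"] == pytest.approx(0.806, abs=1e-3)
        assert d["SphericalDisproportion"] == pytest.approx(1 / expected_sphericity)
        assert d["SurfaceAreaToVolumeRatio"] == pytest.approx(0.6)
        # a cube is convex and isotropic
        assert d["Solidity"] == pytest.approx(1.0, abs=0.05)
        assert d["Eccentricity"] == pytest.approx(0.0, abs=1e-9)
        # longest diameter is the main diagonal between surface voxel centers
        assert d["LongestDiameter"] == pytest.approx(9 * np.sqrt(3))

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        d = shape_descriptors(mask, (1.0, 1.0, 1.0), whole_volume_mm3=50.0)
        assert d["Volume"] == 1.0
        assert d["SubregionProportion"] == pytest.approx(1 / 50.0)
        assert d["SurfaceArea"] == 6.0
        assert d["LongestDiameter"] == 0.0

    def test_digital_balls_reciprocal_identity_and_limit(self):
        """Spherical disproportion is 1/sphericity at every radius, and the
        face-counted sphericity of digital balls approaches its staircase
        limit: face counting over-estimates a smooth sphere's area by a
        factor 3/2, so the limit is 2/3, not 1."""
        for radius in (3, 5, 8, 12):
            mask = _ball_mask(radius, 2 * radius + 5)
            d = shape_descriptors(mask, (1.0, 1.0, 1.0), 1.0)
            assert d["SphericalDisproportion"] == pytest.approx(
                1.0 / d["Sphericity"], rel=1e-12
            )
            if radius >= 8:
                assert d["Sphericity"] == pytest.approx(2.0 / 3.0, abs=0.03)


class TestGeometryFeatures:
    def test_phantom_block(self, tiny_spec):
        from glioradiomics import generate_phantom

        case = generate_phantom(tiny_spec, 4, idh1=0)
        regions = derive_regions(case.labels, case.spacing)
        feats = geometry_features(regions)
        assert len(feats) == 28
        volumes = sum(
            feats[f"geometry_Volume_{r}"]
            for r in ("necrosis", "edema", "non_enhancement", "enhancement")
        )
        assert volumes == pytest.approx(feats["geometry_Volume_whole_tumor"])
        props = [
            feats[f"geometry_SubregionProportion_{r}"]
            for r in ("necrosis", "edema", "non_enhancement", "enhancement")
        ]
        assert all(0 <= p <= 1 for p in props)
        assert sum(props) == pytest.approx(1.0)

    def test_empty_base_region_zeroed(self):
        labels = np.zeros((6, 6, 6), dtype=np.int8)
        labels[2:4, 2:4, 2:4] = 4  # enhancement only
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regions = derive_regions(labels)
        feats = geometry_features(regions)
        assert feats["geometry_Volume_necrosis"] == 0.0
        assert feats["geometry_SubregionProportion_necrosis"] == 0.0

    def test_empty_whole_tumor_errors(self):
        import warnings

        labels = np.zeros((4, 4, 4), dtype=np.int8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regions = derive_regions(labels)
        with pytest.raises(ValueError):
            geometry_features(regions)


class TestIntensityFeatures:
    def test_constant_region(self):
        v = 7.0
        n = 20
        f = intensity_features(np.full(n, v))
        assert f["MeanValue"] == v
        assert f["Variance"] == 0.0
        assert f["Range"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Energy"] == pytest.approx(n * v**2)
        assert f["RootMeanSquare"] == pytest.approx(abs(v))
        assert f["Skewness"] == 0.0

    def test_symmetric_sample(self):
        f = intensity_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["MeanValue"] == 2.5
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["MedianValue"] == 2.5

    def test_empty_mask_gives_missing(self):
        f = intensity_features(np.array([]))
        assert all(np.isnan(v) for v in f.values())

    def test_matches_loop_oracle(self, rng):
        x = rng.lognormal(1.0, 0.5, size=257)
        f = intensity_features(x)
        n = len(x)
        mean = sum(x) / n
        var = sum((v - mean) ** 2 for v in x) / n
        sd = var**0.5
        assert f["MeanValue"] == pytest.approx(mean)
        assert f["Variance"] == pytest.approx(var)
        assert f["StandardDeviation"] == pytest.approx(sd)
        assert f["Skewness"] == pytest.approx(
            sum((v - mean) ** 3 for v in x) / n / sd**3
        )
        assert f["Kurtosis"] == pytest.approx(
            sum((v - mean) ** 4 for v in x) / n / var**2
        )
        assert f["Energy"] == pytest.approx(sum(v**2 for v in x))
        assert f["RootMeanSquare"] == pytest.approx((sum(v**2 for v in x) / n) ** 0.5)
        assert f["MeanAbsoluteDeviation"] == pytest.approx(
            sum(abs(v - mean) for v in x) / n
        )
        assert f["MaxValue"] == max(x)
        assert f["MinValue"] == min(x)
        assert f["Range"] == max(x) - min(x)
        assert f["MedianValue"] == pytest.approx(sorted(x)[128])
        # histogram features against a manual 64-bin count
        counts, _ = np.histogram(x, bins=64)
        p = counts[counts > 0] / n
        assert f["Entropy"] == pytest.approx(float(-(p * np.log2(p)).sum()))
        assert f["Uniformity"] == pytest.approx(float((p**2).sum()))

    def test_quantized_histogram_used_when_given(self, rng):
        x = rng.normal(size=100)
        q = rng.integers(1, 5, size=100)
        f = intensity_features(x, quantized=q)
        counts = np.bincount(q)[1:]
        p = counts[counts > 0] / 100
        assert f["Uniformity"] == pytest.approx(float((p**2).sum()))
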