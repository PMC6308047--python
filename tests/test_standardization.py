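"""Landmark standardization and Lloyd-Max quantization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioradiomics import (
    DriftParams,
    LandmarkStandardizer,
    LloydMaxQuantizer,
    StandardScale,
    apply_scanner_drift,
    generate_phantom,
    learn_standard_scale,
    lloyd_max_quantize,
    standardize,
)
from glioradiomics.standardization import DEFAULT_PERCENTILES

from .oracles import percentile_sorted, uniform_binning_mse


def _phantom_volume(tiny_spec, seed):
    case = generate_phantom(tiny_spec, seed, idh1=0)
    return case.volumes["T1c"], case.brain_mask


class TestLearnScale:
    def test_single_volume_is_own_rescaled_percentiles(self, tiny_spec):
        vol, mask = _phantom_volume(tiny_spec, 3)
        est = LandmarkStandardizer(channel="T1c").fit([vol], [mask])
        lm = np.percentile(vol[mask], DEFAULT_PERCENTILES)
        rescaled = (lm - lm[0]) * 100.0 / (lm[-1] - lm[0])
        assert np.allclose(est.standard_values_, rescaled)

    def test_identical_volumes_idempotent_mean(self, tiny_spec):
        vol, mask = _phantom_volume(tiny_spec, 3)
        one = LandmarkStandardizer().fit([vol], [mask])
        two = LandmarkStandardizer().fit([vol, vol], [mask, mask])
        assert np.allclose(one.standard_values_, two.standard_values_)

    def test_matches_sort_based_percentile_oracle(self, tiny_spec):
        vols, masks = zip(*[_phantom_volume(tiny_spec, s) for s in (1, 2, 3)])
        est = LandmarkStandardizer().fit(list(vols), list(masks))
        rescaled = []
        for vol, mask in zip(vols, masks):
            lm = np.array(
                [percentile_sorted(vol[mask], q) for q in DEFAULT_PERCENTILES]
            )
            rescaled.append((lm - lm[0]) * 100.0 / (lm[-1] - lm[0]))
        assert np.allclose(est.standard_values_, np.mean(rescaled, axis=0))

    def test_no_volumes_errors(self):
        with pytest.raises(ValueError):
            LandmarkStandardizer().fit([])


class TestStandardize:
    def test_self_mapping_fixed_points(self, tiny_spec):
        vol, mask = _phantom_volume(tiny_spec, 5)
        scale = learn_standard_scale([vol], "T1c", masks=[mask])
        out = standardize(vol, mask, scale)
        lm = np.percentile(out[mask], DEFAULT_PERCENTILES)
        assert np.allclose(lm, scale.standard_values, atol=1e-8)

    def test_affine_drift_exactly_inverted(self, tiny_spec):
        case = generate_phantom(tiny_spec, 8, idh1=0)
        drifted = apply_scanner_drift(case, DriftParams(scale=1.7, offset=-13.0))
        est = LandmarkStandardizer().fit(
            [case.volumes["T2w"]], [case.brain_mask]
        )
        out_orig = est.transform(case.volumes["T2w"], case.brain_mask)
        out_drift = est.transform(drifted.volumes["T2w"], case.brain_mask)
        lm_o = np.percentile(out_orig[case.brain_mask], DEFAULT_PERCENTILES)
        lm_d = np.percentile(out_drift[case.brain_mask], DEFAULT_PERCENTILES)
        assert np.allclose(lm_d, lm_o, rtol=1e-6)
        assert np.allclose(out_drift, out_orig, rtol=1e-6, atol=1e-6)

    def test_voxelwise_monotone(self, tiny_spec):
        vol, mask = _phantom_volume(tiny_spec, 9)
        est = LandmarkStandardizer().fit([vol], [mask])
        out = est.transform(vol, mask)
        order = np.argsort(vol.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= -1e-12)

    def test_constant_volume_errors(self):
        est = LandmarkStandardizer().fit([np.random.default_rng(0).random((6, 6, 6))])
        with pytest.raises(ValueError):
            est.transform(np.full((5, 5, 5), 3.0))

    def test_scale_json_roundtrip(self, tiny_spec):
        vol, mask = _phantom_volume(tiny_spec, 2)
        scale = learn_standard_scale([vol], "FLAIR", masks=[mask])
        back = StandardScale.from_json(scale.to_json())
        assert back == scale


class TestLloydMax:
    def test_exactly_representable_input(self, rng):
        values = np.repeat(np.arange(64, dtype=float), 5)
        quant = LloydMaxQuantizer(n_levels=64).fit(values)
        assert quant.mse_ == 0.0
        assert np.allclose(quant.levels_, np.arange(64))
        labels = quant.transform(values)
        assert set(np.unique(labels)) == set(range(1, 65))

    def test_fewer_distinct_than_levels(self):
        codebook, labels = lloyd_max_quantize([1.0, 1.0, 5.0, 9.0], n_levels=64)
        assert codebook.n_used == 3
        assert codebook.mse == 0.0
        assert list(labels) == [1, 1, 2, 3]

    def test_two_tight_clusters(self, rng):
        values = np.concatenate(
            [rng.uniform(-0.1, 0.1, 200), 100 + rng.uniform(-0.1, 0.1, 200)]
        )
        quant = LloydMaxQuantizer(n_levels=2).fit(values)
        assert abs(quant.levels_[0] - values[:200].mean()) < 0.2
        assert abs(quant.levels_[1] - values[200:].mean()) < 0.2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beats_uniform_binning(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [rng.normal(0, 1, 400), rng.lognormal(1.0, 0.6, 400)]
        )
        quant = LloydMaxQuantizer(n_levels=16).fit(values)
        assert quant.mse_ <= uniform_binning_mse(values, 16) + 1e-12

    def test_mse_non_increasing(self, rng):
        values = rng.lognormal(0, 1, 2000)
        quant = LloydMaxQuantizer(n_levels=8).fit(values)
        diffs = np.diff(quant.mse_history_)
        assert np.all(diffs <= 1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            LloydMaxQuantizer().fit([])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_quantization_preserves_order(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=300)
        quant = LloydMaxQuantizer(n_levels=8).fit(values)
        labels = quant.transform(values)
        order = np.argsort(values)
        assert np.all(np.diff(labels[order]) >= 0)


def test_standardize_then_quantize_invariant_under_affine_drift(tiny_spec):
    """The full standardize+quantize chain gives identical level maps with or
    without an affine scanner drift on the raw volume."""
    case = generate_phantom(tiny_spec, 21, idh1=1)
    drifted = apply_scanner_drift(case, DriftParams(scale=0.85, offset=11.0))
    est = LandmarkStandardizer().fit([case.volumes["T1c"]], [case.brain_mask])
    std_o = est.transform(case.volumes["T1c"], case.brain_mask)
    std_d = est.transform(drifted.volumes["T1c"], case.brain_mask)
    tumor = case.labels > 0
    q_o = LloydMaxQuantizer(n_levels=32).fit(std_o[tumor]).transform(std_o[tumor])
    q_d = LloydMaxQuantizer(n_levels=32).fit(std_d[tumor]).transform(std_d[tumor])
    assert np.array_equal(q_o, q_d)
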