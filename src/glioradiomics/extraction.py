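"""Per-case feature extraction over the multiregional catalog.

For one case the pipeline is: derive the six region masks, standardize each
channel onto the learned standard scale, fit one Lloyd-Max 64-level quantizer
per channel on the whole-tumor voxels of that case (shared by all six regions
so gray levels mean the same thing across subregions of one tumor), then
compute geometry, first-order and texture features per catalog entry.

Features of an empty region are recorded as NaN (missing); geometry volume
and proportion of an empty base subregion are 0 (the region is genuinely
absent).  All computation is restricted to the whole-tumor bounding box.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .catalog import CLINICAL_COLUMNS, SEX_CODES, FeatureCatalog, build_catalog, encode_location
from .geometry import geometry_features
from .intensity import intensity_features
from .phantom import CHANNELS, MultiparametricCase
from .quantization import LloydMaxQuantizer
from .regions import EmptyRegionWarning, derive_regions
from .standardization import LandmarkStandardizer, StandardScale
from .texture import compute_texture_matrices, texture_features


def _bounding_box(mask: np.ndarray, margin: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _as_standardizer(scale) -> LandmarkStandardizer:
    if isinstance(scale, LandmarkStandardizer):
        return scale
    if isinstance(scale, StandardScale):
        return LandmarkStandardizer.from_scale(scale)
    raise TypeError(f"unsupported scale object: {type(scale)!r}")


def extract_case(
    case: MultiparametricCase,
    scales: dict,
    catalog: FeatureCatalog | None = None,
    n_levels: int = 64,
) -> pd.Series:
    """Extract one feature row (pd.Series indexed by catalog names).

    ``scales`` maps channel name to a fitted :class:`LandmarkStandardizer`
    (or a :class:`StandardScale`) learned on the training cohort.
    """
    if catalog is None:
        catalog = build_catalog()
    missing = [ch for ch in CHANNELS if ch not in scales]
    if missing:
        raise ValueError(f"missing standardization scales for channels {missing}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptyRegionWarning)
        regions = derive_regions(case.labels, case.spacing)

    needed_regions = sorted({d.region for d in catalog if d.region is not None})

    box = _bounding_box(regions["whole_tumor"])
    cropped_masks = {name: regions[name][box] for name in regions.masks}
    whole = cropped_masks["whole_tumor"]

    standardized = {}
    quantized = {}
    for ch in CHANNELS:
        est = _as_standardizer(scales[ch])
        vol = est.transform(case.volumes[ch], mask=case.brain_mask)
        cropped = vol[box]
        standardized[ch] = cropped
        quant = LloydMaxQuantizer(n_levels=n_levels)
        quant.fit(cropped[whole])
        quantized[ch] = quant.transform(cropped)

    values: dict = {}

    region_code, side_code = encode_location(case.location_region, case.location_side)
    values["location_region"] = region_code
    values["location_side"] = side_code

    values.update(geometry_features(regions))

    for region in needed_regions:
        mask = cropped_masks[region]
        n_vox = int(mask.sum())
        for ch in CHANNELS:
            if n_vox == 0:
                continue
            vals = standardized[ch][mask]
            qvals = quantized[ch][mask]
            feats = intensity_features(vals, quantized=qvals)
            for name, v in feats.items():
                values[f"intensity_{name}_{region}_{ch}"] = v
            tex = texture_features(
                compute_texture_matrices(quantized[ch], mask, n_levels)
            )
            for name, v in tex.items():
                values[f"texture_{name}_{region}_{ch}"] = v

    row = {}
    for d in catalog:
        if d.feature_class == "clinical":
            if d.base_name == "age":
                row["age"] = case.age
            elif d.base_name == "sex":
                row["sex"] = SEX_CODES[case.sex]
            elif d.base_name == "kps":
                row["kps"] = float(case.kps)
        else:
            row[d.name] = values.get(d.name, np.nan)
    return pd.Series(row, name=case.case_id)


def extract_cohort(
    cases,
    scales: dict,
    catalog: FeatureCatalog | None = None,
    n_levels: int = 64,
) -> pd.DataFrame:
    """Feature table for a list of cases; appends the binary ``idh1`` label."""
    if catalog is None:
        catalog = build_catalog()
    rows = [extract_case(case, scales, catalog, n_levels) for case in cases]
    table = pd.DataFrame(rows)
    table["idh1"] = [case.idh1 for case in cases]
    return table


def learn_cohort_scales(cases, percentiles=None) -> dict:
    """Fit one landmark standardizer per channel on a training cohort."""
    from .standardization import DEFAULT_PERCENTILES

    percentiles = percentiles or DEFAULT_PERCENTILES
    scales = {}
    for ch in CHANNELS:
        est = LandmarkStandardizer(percentiles=percentiles, channel=ch)
        est.fit(
            [case.volumes[ch] for case in cases],
            [case.brain_mask for case in cases],
        )
        scales[ch] = est
    return scales


def feature_columns(table: pd.DataFrame) -> list:
    """All columns of a feature table except the label."""
    return [c for c in table.columns if c != "idh1"]
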