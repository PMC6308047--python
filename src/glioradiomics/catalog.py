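"""The multiregional feature catalog.

The full catalog over six regions and four MR channels contains exactly 1614
features: 2 location + 28 geometry + 336 intensity (14 x 6 regions x 4
channels) + 1248 texture (52 x 6 x 4, split GLCM 21 / GLRLM 13 / GLSZM 13 /
NGTDM 5).  Geometry splits as the 10 shape descriptors for tumor core and
whole tumor (20) plus volume and subregion proportion for each of the four
base subregions (8).

Feature names are fully qualified and unique, e.g.
``texture_GLCM_Contrast_enhancement_T1c`` or ``geometry_Volume_necrosis``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phantom import CHANNELS, LOCATION_REGIONS, LOCATION_SIDES
from .regions import BASE_REGION_NAMES, COMPOSITE_REGION_NAMES, REGION_NAMES

INTENSITY_FEATURE_NAMES = (
    "MaxValue", "MedianValue", "MinValue", "MeanValue", "Range", "Energy",
    "Entropy", "Variance", "Kurtosis", "Uniformity", "RootMeanSquare",
    "Skewness", "StandardDeviation", "MeanAbsoluteDeviation",
)

SHAPE_FEATURE_NAMES = (
    "Volume", "SubregionProportion", "SurfaceArea", "LongestDiameter",
    "Solidity", "Eccentricity", "Compactness", "SphericalDisproportion",
    "SurfaceAreaToVolumeRatio", "Sphericity",
)

GLCM_FEATURE_NAMES = (
    "Contrast", "Correlation", "Autocorrelation", "Energy", "Variance",
    "Dissimilarity", "Entropy", "SumAverage", "SumEntropy", "SumVariance",
    "DifferenceVariance", "DifferenceEntropy", "ClusterProminence",
    "ClusterShade", "MaximumProbability", "Homogeneity1", "Homogeneity2",
    "InformationalMeasureOfCorrelation1", "InformationalMeasureOfCorrelation2",
    "InverseDifferenceMomentNormalized", "InverseDifferenceNormalized",
)

GLRLM_FEATURE_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonuniformity",
    "RunLengthNonuniformity", "RunPercentage", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "RunLengthVariance",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "GrayLevelVariance", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURE_NAMES = (
    "SmallZoneEmphasis", "LargeZoneEmphasis", "GrayLevelNonuniformity",
    "ZoneSizeNonuniformity", "ZonePercentage", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "ZoneSizeVariance",
    "SmallZoneLowGrayLevelEmphasis", "SmallZoneHighGrayLevelEmphasis",
    "GrayLevelVariance", "LargeZoneLowGrayLevelEmphasis",
    "LargeZoneHighGrayLevelEmphasis",
)

# "Busyness" appears as "Business" in some published feature lists; the
# canonical spelling is used here and an alias map is provided.
NGTDM_FEATURE_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
FEATURE_NAME_ALIASES = {"NGTDM_Business": "NGTDM_Busyness"}

TEXTURE_FAMILIES = {
    "GLCM": GLCM_FEATURE_NAMES,
    "GLRLM": GLRLM_FEATURE_NAMES,
    "GLSZM": GLSZM_FEATURE_NAMES,
    "NGTDM": NGTDM_FEATURE_NAMES,
}

#: Fixed categorical encodings for the two location features and sex.
LOCATION_REGION_CODES = {name: i for i, name in enumerate(LOCATION_REGIONS)}
LOCATION_SIDE_CODES = {name: i for i, name in enumerate(LOCATION_SIDES)}
SEX_CODES = {"Female": 0, "Male": 1}

CLINICAL_COLUMNS = ("age", "sex", "kps")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    feature_class: str  # location | geometry | intensity | texture | clinical
    region: str | None
    modality: str | None
    family: str | None  # GLCM | GLRLM | GLSZM | NGTDM | None
    base_name: str


class FeatureCatalog:
    """Ordered, immutable list of feature descriptors."""

    def __init__(self, descriptors):
        self.descriptors = tuple(descriptors)
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("catalog feature names are not unique")

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    @property
    def names(self) -> tuple:
        return tuple(d.name for d in self.descriptors)

    def counts_by_class(self) -> dict:
        counts: dict = {}
        for d in self.descriptors:
            counts[d.feature_class] = counts.get(d.feature_class, 0) + 1
        return counts

    def subset_classes(self, classes) -> "FeatureCatalog":
        return FeatureCatalog(
            d for d in self.descriptors if d.feature_class in classes
        )


def build_catalog(region_subset=None, include_clinical: bool = False) -> FeatureCatalog:
    """Build the deterministic ordered catalog for a region subset.

    With all six regions the catalog has exactly 1614 entries (plus three
    clinical columns when ``include_clinical``).  The two location features
    are tumor-level attributes and are included in every subset.
    """
    if region_subset is None:
        region_subset = REGION_NAMES
    region_subset = tuple(region_subset)
    if len(region_subset) == 0:
        raise ValueError("region subset must not be empty")
    unknown = set(region_subset) - set(REGION_NAMES)
    if unknown:
        raise ValueError(f"unknown region names: {sorted(unknown)}")

    desc = []
    desc.append(FeatureDescriptor("location_region", "location", None, None, None, "Region"))
    desc.append(FeatureDescriptor("location_side", "location", None, None, None, "Side"))

    for region in COMPOSITE_REGION_NAMES:
        if region in region_subset:
            for feat in SHAPE_FEATURE_NAMES:
                desc.append(
                    FeatureDescriptor(f"geometry_{feat}_{region}", "geometry", region, None, None, feat)
                )
    for region in BASE_REGION_NAMES:
        if region in region_subset:
            for feat in ("Volume", "SubregionProportion"):
                desc.append(
                    FeatureDescriptor(f"geometry_{feat}_{region}", "geometry", region, None, None, feat)
                )

    for region in REGION_NAMES:
        if region not in region_subset:
            continue
        for channel in CHANNELS:
            for feat in INTENSITY_FEATURE_NAMES:
                desc.append(
                    FeatureDescriptor(
                        f"intensity_{feat}_{region}_{channel}",
                        "intensity", region, channel, None, feat,
                    )
                )

    for region in REGION_NAMES:
        if region not in region_subset:
            continue
        for channel in CHANNELS:
            for family, names in TEXTURE_FAMILIES.items():
                for feat in names:
                    desc.append(
                        FeatureDescriptor(
                            f"texture_{family}_{feat}_{region}_{channel}",
                            "texture", region, channel, family, feat,
                        )
                    )

    if include_clinical:
        for col in CLINICAL_COLUMNS:
            desc.append(FeatureDescriptor(col, "clinical", None, None, None, col))

    return FeatureCatalog(desc)


def encode_location(location_region: str, location_side: str) -> tuple[int, int]:
    """Encode the two categorical location features with the fixed maps."""
    if location_region not in LOCATION_REGION_CODES:
        raise ValueError(f"unknown location region: {location_region!r}")
    if location_side not in LOCATION_SIDE_CODES:
        raise ValueError(f"unknown location side: {location_side!r}")
    return LOCATION_REGION_CODES[location_region], LOCATION_SIDE_CODES[location_side]
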