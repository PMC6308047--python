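"""Extraction regions: four base subregions plus two composites.

The label volume codes necrosis (1), edema (2), non-enhancement (3) and
enhancement (4).  Two composites are derived: the tumor core (everything
except edema: necrosis + non-enhancement + enhancement) and the whole tumor
(core + edema).  Non-tumor tissue never enters an extraction mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import (
    LABEL_EDEMA,
    LABEL_ENHANCEMENT,
    LABEL_NECROSIS,
    LABEL_NON_ENHANCEMENT,
)

BASE_REGION_NAMES = ("necrosis", "edema", "non_enhancement", "enhancement")
COMPOSITE_REGION_NAMES = ("tumor_core", "whole_tumor")
REGION_NAMES = BASE_REGION_NAMES + COMPOSITE_REGION_NAMES


class EmptyRegionWarning(UserWarning):
    """A base subregion has no voxels; its features will be missing."""


@dataclass
class RegionSet:
    """Named binary masks for the six extraction regions."""

    masks: dict  # region name -> bool ndarray
    spacing: tuple

    @property
    def voxel_counts(self) -> dict:
        return {name: int(m.sum()) for name, m in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


def derive_regions(labels: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> RegionSet:
    """Derive the six extraction masks from a base label map.

    Empty base subregions are legal but trigger an :class:`EmptyRegionWarning`
    so the caller can apply its missing-feature policy downstream.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if not np.all(np.isin(present, [0, 1, 2, 3, 4])):
        raise ValueError("label map contains codes outside {0,1,2,3,4}")
    masks = {
        "necrosis": labels == LABEL_NECROSIS,
        "edema": labels == LABEL_EDEMA,
        "non_enhancement": labels == LABEL_NON_ENHANCEMENT,
        "enhancement": labels == LABEL_ENHANCEMENT,
    }
    masks["tumor_core"] = (
        masks["necrosis"] | masks["non_enhancement"] | masks["enhancement"]
    )
    masks["whole_tumor"] = masks["tumor_core"] | masks["edema"]
    for name in BASE_REGION_NAMES:
        if not masks[name].any():
            warnings.warn(
                f"base subregion '{name}' is empty", EmptyRegionWarning, stacklevel=2
            )
    return RegionSet(masks=masks, spacing=tuple(spacing))
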