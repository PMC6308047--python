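"""Landmark-based piecewise-linear intensity standardization.

MRI intensities have no absolute scale; the same tissue maps to different
numbers on different scanners.  The standardizer learns, from training volumes
only, a set of mean landmark intensities (deciles plus the 1st/99th
percentiles by default) on a fixed standard range, then maps any new volume
onto that scale by piecewise-linear interpolation between its own landmarks
and the learned standard landmarks.  Any strictly monotone *affine* scanner
drift of the raw intensities is exactly undone by this map (percentiles are
affine-equivariant), which is the property the texture features downstream
rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

#: Deciles plus the 1st and 99th percentile: 12 landmarks.
DEFAULT_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)
DEFAULT_STANDARD_RANGE = (0.0, 100.0)


@dataclass(frozen=True)
class StandardScale:
    """Learned standard scale for one channel."""

    channel: str
    percentiles: tuple
    standard_values: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        v = np.asarray(self.standard_values, dtype=float)
        if p.ndim != 1 or len(p) != len(v):
            raise ValueError("percentiles and standard_values must align")
        if not (np.all(np.diff(p) > 0) and p[0] > 0 and p[-1] < 100):
            raise ValueError("percentiles must be strictly increasing in (0, 100)")
        if not np.all(np.diff(v) > 0):
            raise ValueError("standard_values must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "channel": self.channel,
                "percentiles": list(self.percentiles),
                "standard_values": list(self.standard_values),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StandardScale":
        d = json.loads(text)
        return cls(
            channel=d["channel"],
            percentiles=tuple(d["percentiles"]),
            standard_values=tuple(d["standard_values"]),
        )


def _masked_landmarks(volume: np.ndarray, mask: np.ndarray | None, percentiles) -> np.ndarray:
    values = np.asarray(volume, dtype=np.float64)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    else:
        values = values.ravel()
    if values.size == 0:
        raise ValueError("empty mask: no voxels to compute landmarks from")
    lm = np.percentile(values, percentiles)
    if not np.all(np.diff(lm) > 0):
        raise ValueError(
            "landmark percentiles are not strictly increasing "
            "(near-constant intensity distribution)"
        )
    return lm


class LandmarkStandardizer:
    """Piecewise-linear histogram standardizer (sklearn-style fit/transform).

    Parameters
    ----------
    percentiles
        Landmark percentiles in (0, 100), strictly increasing.
    standard_range
        Values that the first and last landmark map to on the standard scale.
    channel
        Optional channel name recorded in the serialized scale.

    Attributes
    ----------
    standard_values_ : ndarray
        Mean landmark intensities on the standard scale after fitting; the
        first and last equal ``standard_range`` exactly.
    """

    def __init__(
        self,
        percentiles=DEFAULT_PERCENTILES,
        standard_range=DEFAULT_STANDARD_RANGE,
        channel: str | None = None,
    ):
        self.percentiles = tuple(percentiles)
        self.standard_range = tuple(standard_range)
        self.channel = channel

    def get_params(self, deep=True) -> dict:
        return {
            "percentiles": self.percentiles,
            "standard_range": self.standard_range,
            "channel": self.channel,
        }

    def set_params(self, **params) -> "LandmarkStandardizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, volumes, masks=None) -> "LandmarkStandardizer":
        """Learn standard landmark values from training volumes.

        Each volume's landmarks are linearly rescaled so the first/last
        landmarks hit the standard range; the standard values are the mean of
        those rescaled landmarks across training volumes.
        """
        if masks is None:
            masks = [None] * len(volumes)
        if len(volumes) == 0:
            raise ValueError("need at least one training volume")
        lo, hi = self.standard_range
        rescaled = []
        for vol, mask in zip(volumes, masks):
            lm = _masked_landmarks(vol, mask, self.percentiles)
            rescaled.append(lo + (lm - lm[0]) * (hi - lo) / (lm[-1] - lm[0]))
        std = np.mean(rescaled, axis=0)
        if not np.all(np.diff(std) > 0):
            raise ValueError("learned standard landmarks are not strictly increasing")
        self.standard_values_ = std
        return self

    @property
    def scale_(self) -> StandardScale:
        return StandardScale(
            channel=self.channel or "",
            percentiles=self.percentiles,
            standard_values=tuple(float(v) for v in self.standard_values_),
        )

    @classmethod
    def from_scale(cls, scale: StandardScale) -> "LandmarkStandardizer":
        est = cls(percentiles=scale.percentiles, channel=scale.channel)
        est.standard_values_ = np.asarray(scale.standard_values, dtype=float)
        return est

    def transform(self, volume: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Map ``volume`` onto the standard scale.

        The volume's own landmark percentiles (over ``mask``) are matched to
        the learned standard values by piecewise-linear interpolation; values
        beyond the outer landmarks are extrapolated linearly with the slope of
        the end segments.  The map is non-decreasing in the input intensity.
        """
        if not hasattr(self, "standard_values_"):
            raise ValueError("standardizer is not fitted")
        own = _masked_landmarks(volume, mask, self.percentiles)
        std = self.standard_values_
        x = np.asarray(volume, dtype=np.float64)
        out = np.interp(x, own, std)
        # linear extrapolation beyond the outer landmarks
        lo_slope = (std[1] - std[0]) / (own[1] - own[0])
        hi_slope = (std[-1] - std[-2]) / (own[-1] - own[-2])
        below = x < own[0]
        above = x > own[-1]
        out[below] = std[0] + (x[below] - own[0]) * lo_slope
        out[above] = std[-1] + (x[above] - own[-1]) * hi_slope
        return out


def learn_standard_scale(
    training_volumes,
    channel: str,
    percentiles=DEFAULT_PERCENTILES,
    masks=None,
    standard_range=DEFAULT_STANDARD_RANGE,
) -> StandardScale:
    """Functional wrapper over :class:`LandmarkStandardizer.fit`."""
    est = LandmarkStandardizer(
        percentiles=percentiles, standard_range=standard_range, channel=channel
    )
    est.fit(training_volumes, masks)
    return est.scale_


def standardize(volume, mask, scale: StandardScale) -> np.ndarray:
    """Functional wrapper over :class:`LandmarkStandardizer.transform`."""
    return LandmarkStandardizer.from_scale(scale).transform(volume, mask)
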