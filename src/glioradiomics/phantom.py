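"""Synthetic multiparametric glioblastoma phantoms.

Real multicenter GBM cohorts (multiparametric MRI plus expert subregion
segmentations and IDH1 genotypes) cannot be redistributed, so the pipeline is
exercised on seeded digital phantoms that reproduce the *structure* the
analysis depends on: four co-registered channels (T1w, T1c, T2w, FLAIR), a
label volume with four nested tumor subregions (necrosis innermost, then
non-enhancement, enhancement, and edema outermost), per-region channel-mean
contrasts, additive Gaussian noise, heavy class imbalance (~9% mutated), and a
per-"scanner" strictly monotone intensity distortion that the landmark
standardization stage is expected to remove.

The mutated class is planted through two mechanisms so that both geometry and
texture features carry signal: mutated tumors have altered non-enhancement /
necrosis proportions (semi-axis rescaling), and the Gaussian-random-field
texture added inside the enhancement area has a longer spatial autocorrelation
length for mutated cases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

CHANNELS = ("T1w", "T1c", "T2w", "FLAIR")

#: Integer label coding of the base subregions.
LABEL_BACKGROUND = 0
LABEL_NECROSIS = 1
LABEL_EDEMA = 2
LABEL_NON_ENHANCEMENT = 3
LABEL_ENHANCEMENT = 4

BASE_REGIONS = ("necrosis", "edema", "non_enhancement", "enhancement")
REGION_LABELS = {
    "necrosis": LABEL_NECROSIS,
    "edema": LABEL_EDEMA,
    "non_enhancement": LABEL_NON_ENHANCEMENT,
    "enhancement": LABEL_ENHANCEMENT,
}

#: Nesting order, innermost first: each region's ellipsoid must lie strictly
#: inside the next one.
NESTING_ORDER = ("necrosis", "non_enhancement", "enhancement", "edema")

LOCATION_REGIONS = (
    "Frontal", "Temporal", "Insular", "Parietal", "Occipital",
    "Brainstem", "Cerebellum",
)
LOCATION_SIDES = ("Right", "Left", "Bilateral")

_DEFAULT_RADII = {
    "necrosis": (5.0, 4.5, 4.0),
    "non_enhancement": (9.0, 8.0, 7.5),
    "enhancement": (13.5, 12.0, 11.0),
    "edema": (20.0, 18.0, 16.5),
}

# Channel means in arbitrary standardizable units.  "brain" is the normal
# tissue inside the spherical head mask; outside the head the signal is ~0.
_DEFAULT_MEANS = {
    ("brain", "T1w"): 70.0, ("brain", "T1c"): 70.0,
    ("brain", "T2w"): 60.0, ("brain", "FLAIR"): 55.0,
    ("necrosis", "T1w"): 30.0, ("necrosis", "T1c"): 25.0,
    ("necrosis", "T2w"): 95.0, ("necrosis", "FLAIR"): 40.0,
    ("edema", "T1w"): 55.0, ("edema", "T1c"): 55.0,
    ("edema", "T2w"): 100.0, ("edema", "FLAIR"): 105.0,
    ("non_enhancement", "T1w"): 60.0, ("non_enhancement", "T1c"): 60.0,
    ("non_enhancement", "T2w"): 75.0, ("non_enhancement", "FLAIR"): 80.0,
    ("enhancement", "T1w"): 75.0, ("enhancement", "T1c"): 110.0,
    ("enhancement", "T2w"): 70.0, ("enhancement", "FLAIR"): 85.0,
}


@dataclass(frozen=True)
class ClassEffect:
    """Class-dependent signal planted into mutated phantoms.

    ``radius_scales`` rescales the named subregion semi-axes of mutated cases
    (geometry signal).  A Gaussian random field of amplitude
    ``texture_amplitude`` is added inside the enhancement area of *all* cases
    on ``texture_channels``; its smoothing length is ``corr_length_wild``
    voxels for wild-type and ``corr_length_mutated`` for mutated cases
    (texture signal).  Set the whole object to ``None`` on the spec for a
    signal-free null cohort.
    """

    radius_scales: dict = field(
        default_factory=lambda: {"non_enhancement": 1.30, "necrosis": 0.72}
    )
    texture_amplitude: float = 10.0
    corr_length_wild: float = 0.7
    corr_length_mutated: float = 2.2
    texture_channels: tuple = ("T1c", "T2w")


@dataclass(frozen=True)
class DriftParams:
    """Strictly monotone per-scanner intensity distortion.

    The map is ``f(x) = scale * sign(x) * |x|**gamma + offset`` which is
    strictly increasing for ``scale > 0`` and ``gamma > 0``; ``gamma`` bends
    the histogram (gamma-type drift) while ``scale``/``offset`` give an
    affine component.
    """

    scale: float = 1.0
    offset: float = 0.0
    gamma: float = 1.0

    def validate(self) -> None:
        if not (self.scale > 0 and self.gamma > 0):
            raise ValueError(
                f"drift must be strictly monotone increasing: requires "
                f"scale > 0 and gamma > 0, got scale={self.scale}, "
                f"gamma={self.gamma}"
            )

    def apply(self, x: np.ndarray) -> np.ndarray:
        self.validate()
        return self.scale * np.sign(x) * np.abs(x) ** self.gamma + self.offset


@dataclass(frozen=True)
class DriftRange:
    """Per-case sampling ranges for :class:`DriftParams`."""

    scale: tuple = (0.8, 1.25)
    offset: tuple = (-8.0, 8.0)
    gamma: tuple = (0.85, 1.2)

    def sample(self, rng: np.random.Generator) -> DriftParams:
        return DriftParams(
            scale=float(rng.uniform(*self.scale)),
            offset=float(rng.uniform(*self.offset)),
            gamma=float(rng.uniform(*self.gamma)),
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one synthetic cohort."""

    grid_shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)  # mm
    brain_radius: float = 29.0  # mm, spherical head mask
    region_radii: dict = field(default_factory=lambda: dict(_DEFAULT_RADII))
    channel_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    noise_sd: float = 2.0
    center_jitter: float = 2.0  # mm, per-case tumor center displacement
    radius_jitter: float = 0.06  # fractional per-case semi-axis jitter
    class_effect: ClassEffect | None = field(default_factory=ClassEffect)
    mutation_prevalence: float = 0.09
    scanner_drift: DriftRange | None = field(default_factory=DriftRange)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.mutation_prevalence < 1.0) and self.mutation_prevalence not in (0.0, 1.0):
            raise ValueError("mutation_prevalence must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        prev = None
        for region in NESTING_ORDER:
            radii = np.asarray(self.region_radii[region], dtype=float)
            if prev is not None and not np.all(radii > prev):
                raise ValueError(
                    f"region_radii must be strictly nested; {region} does not "
                    f"strictly contain the previous region"
                )
            prev = np.asarray(radii)


@dataclass
class MultiparametricCase:
    """One subject: four aligned channels, subregion labels, clinical data."""

    case_id: str
    volumes: dict  # channel -> float32 3D array
    labels: np.ndarray  # int8 3D array, coding per REGION_LABELS
    spacing: tuple
    brain_mask: np.ndarray  # head/tissue mask used for intensity landmarks
    age: float
    sex: str  # "Male" / "Female"
    kps: int
    location_region: str
    location_side: str
    idh1: int  # 1 = mutated, 0 = wild-type
    geometry: dict = field(default_factory=dict)  # sampled center/radii provenance

    def __post_init__(self) -> None:
        shape = self.labels.shape
        for ch in CHANNELS:
            if ch not in self.volumes:
                raise ValueError(f"missing channel {ch}")
            if self.volumes[ch].shape != shape:
                raise ValueError("all volumes must share the label-map shape")
        present = np.unique(self.labels)
        if not np.all(np.isin(present, [0, 1, 2, 3, 4])):
            raise ValueError("label map contains codes outside {0..4}")


def _ellipsoid_mask(shape, spacing, center, radii) -> np.ndarray:
    coords = [
        (np.arange(n) * s - c)
        for n, s, c in zip(shape, spacing, center)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    rz, ry, rx = radii
    return (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0


def generate_phantom(
    spec: PhantomSpec,
    case_seed: int,
    idh1: int,
    case_id: str = "case",
    clinical: dict | None = None,
) -> MultiparametricCase:
    """Generate one phantom case, deterministic in ``(spec, case_seed, idh1)``.

    The class effect (if configured on the spec) is applied iff
    ``idh1 == 1``: mutated cases get rescaled subregion semi-axes and a
    longer-correlation-length enhancement texture.
    """
    spec.validate()
    ss = np.random.SeedSequence(case_seed)
    geom_rng, tex_rng, noise_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    shape = tuple(spec.grid_shape)
    spacing = tuple(spec.spacing)
    extent = np.asarray(shape) * np.asarray(spacing)
    center = extent / 2.0 + geom_rng.uniform(
        -spec.center_jitter, spec.center_jitter, size=3
    )
    # One shared fractional jitter per case plus a small per-region wobble
    # keeps the nesting strict for the default jitter amplitude.
    shared = 1.0 + geom_rng.uniform(-spec.radius_jitter, spec.radius_jitter)
    radii = {}
    for region in NESTING_ORDER:
        base = np.asarray(spec.region_radii[region], dtype=float)
        wobble = 1.0 + geom_rng.uniform(
            -spec.radius_jitter / 3.0, spec.radius_jitter / 3.0, size=3
        )
        radii[region] = base * shared * wobble
    if idh1 and spec.class_effect is not None:
        for region, scale in spec.class_effect.radius_scales.items():
            radii[region] = radii[region] * scale
    prev = None
    for region in NESTING_ORDER:
        if prev is not None and not np.all(radii[region] > prev):
            raise ValueError(f"jittered radii lost strict nesting at {region}")
        prev = radii[region]

    labels = np.zeros(shape, dtype=np.int8)
    masks = {
        region: _ellipsoid_mask(shape, spacing, center, radii[region])
        for region in NESTING_ORDER
    }
    # Paint outermost first so inner regions overwrite.
    labels[masks["edema"]] = LABEL_EDEMA
    labels[masks["enhancement"]] = LABEL_ENHANCEMENT
    labels[masks["non_enhancement"]] = LABEL_NON_ENHANCEMENT
    labels[masks["necrosis"]] = LABEL_NECROSIS
    for region, code in REGION_LABELS.items():
        if not np.any(labels == code):
            raise ValueError(
                f"degenerate radii: subregion '{region}' is empty on the "
                f"{shape} grid"
            )

    brain_center = extent / 2.0
    brain_mask = _ellipsoid_mask(
        shape, spacing, brain_center, (spec.brain_radius,) * 3
    )

    texture = None
    if spec.class_effect is not None:
        eff = spec.class_effect
        corr = eff.corr_length_mutated if idh1 else eff.corr_length_wild
        white = tex_rng.standard_normal(shape)
        smooth = gaussian_filter(white, sigma=corr)
        sd = smooth.std()
        if sd > 0:
            texture = eff.texture_amplitude * smooth / sd

    volumes = {}
    for ch in CHANNELS:
        vol = np.zeros(shape, dtype=np.float64)
        vol[brain_mask] = spec.channel_means[("brain", ch)]
        for region, code in REGION_LABELS.items():
            vol[labels == code] = spec.channel_means[(region, ch)]
        if texture is not None and ch in spec.class_effect.texture_channels:
            enh = labels == LABEL_ENHANCEMENT
            vol[enh] += texture[enh]
        if spec.noise_sd > 0:
            vol += noise_rng.normal(0.0, spec.noise_sd, size=shape)
        volumes[ch] = vol

    clinical = clinical or {}
    return MultiparametricCase(
        case_id=case_id,
        volumes=volumes,
        labels=labels,
        spacing=spacing,
        brain_mask=brain_mask,
        age=clinical.get("age", 54.0),
        sex=clinical.get("sex", "Male"),
        kps=clinical.get("kps", 80),
        location_region=clinical.get("location_region", "Frontal"),
        location_side=clinical.get("location_side", "Right"),
        idh1=int(idh1),
        geometry={
            "center": tuple(float(c) for c in center),
            "radii": {r: tuple(float(v) for v in radii[r]) for r in NESTING_ORDER},
        },
    )


def apply_scanner_drift(
    case: MultiparametricCase, drift: DriftParams | dict
) -> MultiparametricCase:
    """Return a copy of ``case`` with the monotone drift applied voxel-wise.

    ``drift`` is either one :class:`DriftParams` applied to every channel or a
    mapping channel -> :class:`DriftParams`.  Rank order of voxel intensities
    is preserved within each channel.
    """
    if isinstance(drift, DriftParams):
        per_channel = {ch: drift for ch in CHANNELS}
    else:
        per_channel = dict(drift)
    volumes = {
        ch: per_channel[ch].apply(np.asarray(case.volumes[ch], dtype=np.float64))
        for ch in CHANNELS
    }
    return dataclasses.replace(case, volumes=volumes)


# Clinical sampling emulates the published training-cohort demographics:
# mean age ~54 y (range 9-85), ~60% male, KPS centered near 80, tumors
# predominantly frontal/temporal.  Clinical draws are class-independent.
_LOCATION_PROBS = (0.30, 0.30, 0.08, 0.15, 0.10, 0.04, 0.03)
_SIDE_PROBS = (0.46, 0.46, 0.08)
_KPS_VALUES = (50, 60, 70, 80, 90, 100)
_KPS_PROBS = (0.04, 0.10, 0.20, 0.32, 0.24, 0.10)


def _sample_clinical(rng: np.random.Generator) -> dict:
    return {
        "age": float(np.clip(rng.normal(54.0, 13.0), 9.0, 85.0)),
        "sex": "Male" if rng.random() < 0.60 else "Female",
        "kps": int(rng.choice(_KPS_VALUES, p=_KPS_PROBS)),
        "location_region": str(rng.choice(LOCATION_REGIONS, p=_LOCATION_PROBS)),
        "location_side": str(rng.choice(LOCATION_SIDES, p=_SIDE_PROBS)),
    }


def sample_cohort_plan(
    spec: PhantomSpec,
    n_cases: int,
    seed: int,
    cohort_name: str = "train",
) -> list[dict]:
    """Draw all per-case parameters (seed, label, clinical, drift) cheaply.

    This is the single source of randomness for :func:`generate_cohort`; it
    lets callers inspect e.g. the minority-class count before paying for
    volume synthesis.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    rng = np.random.default_rng(seed)
    plans = []
    for i in range(n_cases):
        plan = {
            "case_id": f"{cohort_name}-{i:04d}",
            "case_seed": int(rng.integers(0, 2**31 - 1)),
            "idh1": int(rng.random() < spec.mutation_prevalence),
            "clinical": _sample_clinical(rng),
            "drift": (
                spec.scanner_drift.sample(rng)
                if spec.scanner_drift is not None
                else None
            ),
        }
        plans.append(plan)
    return plans


def generate_cohort(
    spec: PhantomSpec,
    n_cases: int,
    seed: int,
    cohort_name: str = "train",
) -> tuple[list[MultiparametricCase], pd.DataFrame]:
    """Generate ``n_cases`` phantoms plus a manifest DataFrame.

    Mutation labels are Bernoulli(``spec.mutation_prevalence``) draws from the
    seeded stream; if ``spec.scanner_drift`` is set, each case receives an
    independently sampled monotone drift.
    """
    plans = sample_cohort_plan(spec, n_cases, seed, cohort_name)
    cases = []
    rows = []
    for plan in plans:
        case = generate_phantom(
            spec, plan["case_seed"], plan["idh1"], plan["case_id"], plan["clinical"]
        )
        if plan["drift"] is not None:
            case = apply_scanner_drift(case, plan["drift"])
        cases.append(case)
        rows.append(
            {
                "case_id": case.case_id,
                "age": case.age,
                "sex": case.sex,
                "kps": case.kps,
                "location_region": case.location_region,
                "location_side": case.location_side,
                "idh1": case.idh1,
                "cohort": cohort_name,
            }
        )
    manifest = pd.DataFrame(rows)
    return cases, manifest


def save_case(case: MultiparametricCase, out_dir: str | Path) -> None:
    """Write one case as NIfTI volumes plus labels and brain mask."""
    import nibabel as nib

    out = Path(out_dir) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(case.spacing) + [1.0])
    for ch in CHANNELS:
        nib.save(nib.Nifti1Image(case.volumes[ch], affine), out / f"{ch}.nii.gz")
    nib.save(nib.Nifti1Image(case.labels.astype(np.int16), affine), out / "labels.nii.gz")
    nib.save(
        nib.Nifti1Image(case.brain_mask.astype(np.uint8), affine),
        out / "brain_mask.nii.gz",
    )


def load_case(case_dir: str | Path, manifest_row: pd.Series) -> MultiparametricCase:
    """Load a case written by :func:`save_case`."""
    import nibabel as nib

    case_dir = Path(case_dir)
    volumes = {
        ch: np.asarray(nib.load(case_dir / f"{ch}.nii.gz").dataobj, dtype=np.float32)
        for ch in CHANNELS
    }
    img = nib.load(case_dir / "labels.nii.gz")
    labels = np.asarray(img.dataobj, dtype=np.int8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask_path = case_dir / "brain_mask.nii.gz"
    if mask_path.exists():
        brain_mask = np.asarray(nib.load(mask_path).dataobj).astype(bool)
    else:
        brain_mask = volumes["T1w"] > 0
    return MultiparametricCase(
        case_id=str(manifest_row["case_id"]),
        volumes=volumes,
        labels=labels,
        spacing=spacing,
        brain_mask=brain_mask,
        age=float(manifest_row["age"]),
        sex=str(manifest_row["sex"]),
        kps=int(manifest_row["kps"]),
        location_region=str(manifest_row["location_region"]),
        location_side=str(manifest_row["location_side"]),
        idh1=int(manifest_row["idh1"]),
    )
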