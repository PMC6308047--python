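import numpy as np
import pytest

from glioradiomics import PhantomSpec

#: Smaller radii tuned for a 24^3 grid so unit tests stay fast.
_TINY_RADII = {
    "necrosis": (2.4, 2.2, 2.0),
    "non_enhancement": (4.2, 3.8, 3.6),
    "enhancement": (6.2, 5.6, 5.2),
    "edema": (8.6, 7.8, 7.2),
}


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    """24^3 phantom spec for fast unit tests (no drift)."""
    return PhantomSpec(
        grid_shape=(24, 24, 24),
        brain_radius=11.0,
        region_radii=dict(_TINY_RADII),
        center_jitter=0.8,
        radius_jitter=0.04,
        scanner_drift=None,
    )


@pytest.fixture
def tiny_noise_free_spec(tiny_spec) -> PhantomSpec:
    import dataclasses

    return dataclasses.replace(
        tiny_spec, noise_sd=0.0, class_effect=None, center_jitter=0.0,
        radius_jitter=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def random_quantized_block(rng, max_side=6, n_levels=8):
    """Random quantized block + random mask for texture oracle checks."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int64)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    return levels, mask
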