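import dataclasses

import numpy as np
import pytest

from blockseg import PhantomSpec, generate_phantom


def spec64(**overrides) -> PhantomSpec:
    """The default phantom scaled to 64x64 (all lengths halved)."""
    base = dict(
        image_height=64, image_width=64, brain_center=(32, 32),
        brain_axes=(24, 28), skull_thickness=2, tumor_center=(25, 38),
        tumor_radius=5,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def random_tumor_spec(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """Default 128x128 spec with a random tumor center inside the brain.

    Centers are sampled inside the brain ellipse shrunk by the tumor radius
    plus a 4-pixel guard, so the lesion survives skull-strip erosion and a
    fully covering block exists inside the brain mask.
    """
    spec = PhantomSpec(**overrides) if overrides else PhantomSpec()
    margin = spec.tumor_radius + 4
    ar, ac = spec.brain_axes[0] - margin, spec.brain_axes[1] - margin
    while True:
        dr = rng.uniform(-ar, ar)
        dc = rng.uniform(-ac, ac)
        if (dr / ar) ** 2 + (dc / ac) ** 2 <= 1.0:
            break
    center = (int(spec.brain_center[0] + dr), int(spec.brain_center[1] + dc))
    return dataclasses.replace(spec, tumor_center=center)


@pytest.fixture(scope="session")
def default_pair():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def pair64():
    return generate_phantom(spec64())


@pytest.fixture(scope="session")
def pair64_noiseless():
    return generate_phantom(spec64(tissue_noise_sd=0.0))
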