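"""Seeded synthetic MRI-like phantom pairs for every downstream stage.

A phantom is a 2-D head slice: an elliptical brain of noisy tissue, a bright
skull ring around it, air (zero) background, and — in the diseased image
only — a hyperintense circular lesion, as a FLAIR/T1c tumor would appear.
The disease-free reference shares the *same* noise realization, so outside
the tumor the pair is pixel-identical: the lesion is the only systematic
difference, which is exactly the signal the ANOVA block fitness is meant to
detect in a registered pair.

``intensity_offset`` optionally shifts the diseased tissue (outside the
tumor) by a constant, emulating a global acquisition intensity difference
between the two scans; with a non-zero offset the pixel-identity invariant
intentionally no longer holds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

__all__ = ["PhantomSpec", "PhantomPair", "generate_phantom", "default_spec"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic head slice.

    All intensities are on the normalized [0, 1] scale; all geometry is in
    pixels with 0-based (row, col) coordinates.
    """

    image_height: int = 128
    image_width: int = 128
    brain_center: tuple[int, int] = (64, 64)
    brain_axes: tuple[int, int] = (48, 56)
    skull_thickness: int = 4
    skull_intensity: float = 0.95
    tissue_mean: float = 0.35
    tissue_noise_sd: float = 0.05
    tumor_center: tuple[int, int] = (50, 75)
    tumor_radius: int = 10
    tumor_intensity: float = 0.85
    intensity_offset: float = 0.0
    random_seed: int = 42

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated constraint."""
        cr, cc = self.brain_center
        ar, ac = self.brain_axes
        st = self.skull_thickness
        if ar <= 0 or ac <= 0:
            raise ValueError("brain_axes must be positive")
        if st < 0:
            raise ValueError("skull_thickness must be >= 0")
        if not (cr - ar - st >= 0 and cr + ar + st < self.image_height
                and cc - ac - st >= 0 and cc + ac + st < self.image_width):
            raise ValueError("brain ellipse plus skull ring must fit inside the image bounds")
        if self.tumor_radius < 0:
            raise ValueError("tumor_radius must be >= 0")
        if self.tumor_radius > 0:
            tr, tc = self.tumor_center
            # conservative inner-ellipse check: the tumor disk must sit inside
            # the brain ellipse shrunk by the tumor radius
            if self.tumor_radius >= min(ar, ac):
                raise ValueError("tumor disk must lie entirely inside the brain ellipse")
            u = (tr - cr) / (ar - self.tumor_radius)
            v = (tc - cc) / (ac - self.tumor_radius)
            if u * u + v * v > 1.0:
                raise ValueError("tumor disk must lie entirely inside the brain ellipse")
            if not self.tumor_intensity > self.tissue_mean + 3.0 * self.tissue_noise_sd:
                raise ValueError(
                    "tumor_intensity must exceed tissue_mean + 3*tissue_noise_sd "
                    "(the lesion is hyperintense)"
                )
        for name in ("skull_intensity", "tissue_mean", "tumor_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tissue_noise_sd < 0:
            raise ValueError("tissue_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("brain_center", "brain_axes", "tumor_center"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class PhantomPair:
    """A diseased/reference image pair with its ground-truth masks."""

    diseased: np.ndarray
    reference: np.ndarray
    tumor_mask: np.ndarray
    skull_mask: np.ndarray
    brain_mask: np.ndarray
    spec: PhantomSpec


def default_spec(**overrides) -> PhantomSpec:
    """The default 128x128 phantom, optionally with fields replaced."""
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


def _ellipse(rr, cc, center, axes) -> np.ndarray:
    return (((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render a phantom pair from its spec; same seed, same pixels."""
    spec.validate()
    H, W = spec.image_height, spec.image_width
    rr, cc = np.mgrid[0:H, 0:W].astype(float)

    brain = _ellipse(rr, cc, spec.brain_center, spec.brain_axes)
    outer = _ellipse(
        rr, cc, spec.brain_center,
        (spec.brain_axes[0] + spec.skull_thickness,
         spec.brain_axes[1] + spec.skull_thickness),
    )
    skull = outer & ~brain
    if spec.tumor_radius > 0:
        tr, tc = spec.tumor_center
        tumor = ((rr - tr) ** 2 + (cc - tc) ** 2) <= spec.tumor_radius ** 2
    else:
        tumor = np.zeros((H, W), dtype=bool)

    rng = np.random.default_rng(spec.random_seed)
    noise = rng.normal(0.0, spec.tissue_noise_sd, (H, W)) if spec.tissue_noise_sd > 0 \
        else np.zeros((H, W))

    reference = np.zeros((H, W))
    reference[brain] = spec.tissue_mean + noise[brain]
    reference[skull] = spec.skull_intensity

    diseased = reference.copy()
    if spec.intensity_offset != 0.0:
        diseased[brain] += spec.intensity_offset
    diseased[tumor] = spec.tumor_intensity

    return PhantomPair(
        diseased=np.clip(diseased, 0.0, 1.0),
        reference=np.clip(reference, 0.0, 1.0),
        tumor_mask=tumor,
        skull_mask=skull,
        brain_mask=brain,
        spec=spec,
    )
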