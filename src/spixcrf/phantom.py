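"""Synthetic brain-slice phantoms with ground-truth tumor masks.

The phantom emulates the appearance of a FLAIR/T2 axial slice: a dark
background, an elliptical "brain" of intermediate intensity, and a
hyperintense tumor consisting of a bright disk-shaped core surrounded by an
annular edema ring of intermediate brightness (core > edema > brain >
background).  Additive Gaussian noise and a smooth low-order multiplicative
bias field emulate acquisition noise and coil inhomogeneity.  Ground-truth
masks (whole tumor, core, edema) are noise-free, so every downstream stage of
the segmentation pipeline can be trained and scored without clinical data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "CohortJitter",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise configuration of one phantom slice.

    Intensities are in arbitrary units in [0, 1].  ``brain_axes`` are the
    (row, col) semi-axes of the brain ellipse in pixels; ``tumor_center`` is
    in (row, col) pixel coordinates and defaults to a point offset from the
    brain center.  ``bias_amplitude`` is the half-range of the multiplicative
    bias field, i.e. the field lies in [1 - a, 1 + a].
    """

    height: int = 128
    width: int = 128
    brain_axes: tuple[float, float] = (52.0, 44.0)
    core_radius: float = 12.0
    edema_width: float = 6.0
    tumor_center: tuple[float, float] | None = None
    background_level: float = 0.05
    brain_level: float = 0.35
    edema_level: float = 0.65
    core_level: float = 0.90
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")
        if self.edema_width < 0:
            raise ValueError("edema_width must be >= 0")
        if not (self.background_level < self.brain_level):
            raise ValueError("intensity ordering requires background < brain")
        if not (self.core_level > self.edema_level > self.brain_level):
            raise ValueError("intensity ordering requires core > edema > brain")
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be >= 0")
        cy, cx = self.resolved_center()
        r = self.core_radius + self.edema_width
        ay, ax = self.brain_axes
        by, bx = (self.height - 1) / 2.0, (self.width - 1) / 2.0
        if ay > by + 0.5 or ax > bx + 0.5:
            raise ValueError("brain ellipse exceeds image bounds")
        if cy - r < 0 or cy + r > self.height - 1 or cx - r < 0 or cx + r > self.width - 1:
            raise ValueError("tumor geometry exceeds image bounds")

    def resolved_center(self) -> tuple[float, float]:
        """Tumor center, defaulting to an off-center point inside the brain."""
        if self.tumor_center is not None:
            return self.tumor_center
        return (
            (self.height - 1) / 2.0 - 0.15 * self.brain_axes[0],
            (self.width - 1) / 2.0 + 0.20 * self.brain_axes[1],
        )


@dataclass
class PhantomSample:
    """One generated slice plus its noise-free ground-truth masks."""

    image: np.ndarray
    mask_whole: np.ndarray
    mask_core: np.ndarray
    mask_edema: np.ndarray
    spec: PhantomSpec

    def __post_init__(self) -> None:
        assert not np.any(self.mask_core & self.mask_edema)
        assert np.array_equal(self.mask_whole, self.mask_core | self.mask_edema)


def _bias_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1 - amplitude, 1 + amplitude].

    A random combination of low-order 2-D polynomials in normalized
    coordinates, rescaled so its extrema hit exactly +-amplitude.
    """
    if amplitude == 0:
        return np.ones(shape)
    h, w = shape
    yy = np.linspace(-1.0, 1.0, h)[:, None]
    xx = np.linspace(-1.0, 1.0, w)[None, :]
    coefs = rng.uniform(-1.0, 1.0, size=5)
    basis = coefs[0] * yy + coefs[1] * xx + coefs[2] * yy * xx
    basis = basis + coefs[3] * (yy**2 - 0.5) + coefs[4] * (xx**2 - 0.5)
    peak = np.abs(basis).max()
    if peak < 1e-12:  # all coefficients drawn ~0; flat field
        return np.ones(shape)
    return 1.0 + amplitude * basis / peak


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom slice from its spec; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    by, bx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = spec.brain_axes
    brain = ((yy - by) / ay) ** 2 + ((xx - bx) / ax) ** 2 <= 1.0

    cy, cx = spec.resolved_center()
    dist = np.hypot(yy - cy, xx - cx)
    mask_core = dist <= spec.core_radius
    mask_whole = dist <= spec.core_radius + spec.edema_width
    mask_edema = mask_whole & ~mask_core

    image = np.full((h, w), spec.background_level)
    image[brain] = spec.brain_level
    image[mask_edema] = spec.edema_level
    image[mask_core] = spec.core_level

    image = image * _bias_field((h, w), spec.bias_amplitude, rng)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(h, w))

    return PhantomSample(image=image, mask_whole=mask_whole, mask_core=mask_core,
                         mask_edema=mask_edema, spec=spec)


@dataclass(frozen=True)
class CohortJitter:
    """Per-sample jitter of tumor position and size within a cohort.

    The tumor center is drawn uniformly in a square of half-width
    ``center_jitter`` px around the template's resolved center; core radius
    and edema width are drawn uniformly from the given ranges.
    """

    center_jitter: float = 10.0
    core_radius_range: tuple[float, float] = (9.0, 15.0)
    edema_width_range: tuple[float, float] = (4.0, 8.0)

    def mean_whole_area(self) -> float:
        """Expected whole-tumor area (px) under the jitter distribution.

        E[pi (r + e)^2] with r, e independent uniforms.
        """
        r0, r1 = self.core_radius_range
        e0, e1 = self.edema_width_range
        mr, me = (r0 + r1) / 2.0, (e0 + e1) / 2.0
        vr = (r1 - r0) ** 2 / 12.0
        ve = (e1 - e0) ** 2 / 12.0
        return float(np.pi * ((mr + me) ** 2 + vr + ve))


def generate_cohort(
    template: PhantomSpec,
    n: int,
    seed: int,
    jitter: CohortJitter | None = None,
) -> list[PhantomSample]:
    """Draw ``n`` phantoms with jittered tumor position/size.

    Reproducible: the cohort seed drives both the jitter draws and each
    per-sample rendering seed.
    """
    if n < 1:
        raise ValueError("cohort size n must be >= 1")
    jitter = jitter or CohortJitter()
    rng = np.random.default_rng(seed)
    cy0, cx0 = template.resolved_center()
    samples = []
    for _ in range(n):
        cy = cy0 + rng.uniform(-jitter.center_jitter, jitter.center_jitter)
        cx = cx0 + rng.uniform(-jitter.center_jitter, jitter.center_jitter)
        r = rng.uniform(*jitter.core_radius_range)
        e = rng.uniform(*jitter.edema_width_range)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = dataclasses.replace(
            template,
            tumor_center=(float(cy), float(cx)),
            core_radius=float(r),
            edema_width=float(e),
            seed=sub_seed,
        )
        samples.append(generate_phantom(spec))
    return samples
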