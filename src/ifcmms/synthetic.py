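"""Seeded brain-phantom generator and salt-and-pepper corruption.

The phantom is a piecewise-constant stand-in for a FLAIR-like slice: a dark
background, an elliptical "brain", one or more tissue blobs, and one small
bright "tumor" blob, each with its own mean intensity plus within-class
Gaussian noise. The generating partition is returned as the ground-truth
label mask, so every algorithm stage can be evaluated without external data.
It deliberately omits bias fields, partial-volume mixing and Rician noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image import GrayImage

logger = logging.getLogger("ifcmms")


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (row, col) and radii, as fractions of
    the image side lengths."""

    center: tuple[float, float]
    radii: tuple[float, float]
    label: int


def default_geometry() -> tuple[Ellipse, ...]:
    """Brain ellipse, one tissue blob, one small bright tumor blob."""
    return (
        Ellipse(center=(0.50, 0.50), radii=(0.42, 0.36), label=1),  # brain
        Ellipse(center=(0.60, 0.44), radii=(0.16, 0.12), label=2),  # tissue
        Ellipse(center=(0.34, 0.62), radii=(0.065, 0.065), label=3),  # tumor
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom description; the defaults are the package's standard fixture.

    class_means : one intensity per label (background first). Means must be
        pairwise distinct so the partition is recoverable.
    class_noise_sd : within-class Gaussian standard deviation.
    """

    shape: tuple[int, int] = (128, 128)
    class_means: tuple[float, ...] = (10.0, 90.0, 140.0, 220.0)
    class_noise_sd: float = 4.0
    geometry: tuple[Ellipse, ...] = field(default_factory=default_geometry)
    seed: int = 0
    dtype_max: int = 255

    def __post_init__(self) -> None:
        if len(set(self.class_means)) != len(self.class_means):
            raise ValueError("class means must be pairwise distinct")
        if max(e.label for e in self.geometry) >= len(self.class_means):
            raise ValueError("geometry labels exceed the class-mean list")
        for e in self.geometry:
            if not (0 < e.center[0] < 1 and 0 < e.center[1] < 1):
                raise ValueError("blob centers must lie inside the image")
            if e.center[0] + e.radii[0] > 1 or e.center[0] - e.radii[0] < 0:
                raise ValueError("blob exceeds image bounds (rows)")
            if e.center[1] + e.radii[1] > 1 or e.center[1] - e.radii[1] < 0:
                raise ValueError("blob exceeds image bounds (cols)")


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[GrayImage, np.ndarray]:
    """Render the phantom; returns (image, exact ground-truth label mask).

    Deterministic given ``spec.seed``. Overlapping blobs are resolved by
    draw order (later wins), which is how the tumor sits inside the brain.
    """
    H, W = spec.shape
    rr, cc = np.indices((H, W))
    mask = np.zeros((H, W), dtype=np.int64)
    for e in spec.geometry:
        r0, c0 = e.center[0] * (H - 1), e.center[1] * (W - 1)
        ra, rb = max(e.radii[0] * H, 1.0), max(e.radii[1] * W, 1.0)
        inside = ((rr - r0) / ra) ** 2 + ((cc - c0) / rb) ** 2 <= 1.0
        if np.any(mask[inside] != 0):
            logger.debug("blob label %d overlaps earlier blobs; later wins", e.label)
        mask[inside] = e.label
    tumor_label = len(spec.class_means) - 1
    if (mask == tumor_label).sum() < 9:
        raise ValueError("tumor blob area must be at least 9 pixels")
    img = np.asarray(spec.class_means, dtype=np.float64)[mask]
    if spec.class_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(scale=spec.class_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, spec.dtype_max)
    dtype = np.uint8 if spec.dtype_max <= 255 else np.uint16
    return GrayImage(pixels=img.astype(dtype), dtype_max=spec.dtype_max), mask


def salt_and_pepper(image: GrayImage, intensity: float, seed: int = 0) -> GrayImage:
    """Corrupt an exact fraction of pixels to the intensity extremes.

    ``round(intensity * n)`` pixels are chosen without replacement and each
    set to 0 or dtype_max with equal probability — an exact-count mechanism
    so noise grids are reproducible per seed, not Bernoulli-approximate.
    """
    if not 0.0 <= intensity <= 0.5:
        raise ValueError("noise intensity must lie in [0, 0.5]")
    if intensity == 0.0:
        return image
    rng = np.random.default_rng(seed)
    n = image.n_pixels
    k = int(round(intensity * n))
    idx = rng.choice(n, size=k, replace=False)
    values = np.where(rng.random(k) < 0.5, 0, image.dtype_max)
    out = np.array(image.pixels, copy=True)
    out.ravel()[idx] = values.astype(out.dtype)
    return GrayImage(pixels=out, dtype_max=image.dtype_max)


NOISE_GRID = (0.0, 0.005, 0.01, 0.02)
"""Salt-and-pepper intensities used throughout the evaluation sweeps."""
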