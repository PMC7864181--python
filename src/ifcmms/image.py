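"""Grayscale image container and PNG/TIFF readers and writers.

Images are plain 2-D intensity grids with an explicit representable maximum
(255 for 8-bit, 65535 for 16-bit), which downstream code uses to map
intensities onto the unit interval.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("ifcmms")

_DTYPE_MAX = {np.dtype(np.uint8): 255, np.dtype(np.uint16): 65535}


@dataclass(frozen=True)
class GrayImage:
    """2-D scalar intensity field with its representable maximum.

    Parameters
    ----------
    pixels : ndarray
        2-D array of nonnegative intensities.
    dtype_max : int
        Largest representable intensity (255 or 65535 for integer inputs).
    """

    pixels: np.ndarray
    dtype_max: int = 255

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got shape {px.shape}")
        if self.dtype_max <= 0:
            raise ValueError("dtype_max must be positive")
        if px.size and (px.min() < 0 or px.max() > self.dtype_max):
            raise ValueError("pixel values outside [0, dtype_max]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.size)


def read_image(path: str | Path) -> GrayImage:
    """Read an 8/16-bit PNG or TIFF as a :class:`GrayImage`.

    Multi-channel inputs are collapsed to luminance with a logged warning;
    the bit depth of the stored data is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - imageio error text varies
        raise ValueError(f"cannot read {path} as PNG/TIFF: {exc}") from exc
    dtype_max = _DTYPE_MAX.get(arr.dtype, None)
    if arr.ndim == 3:
        logger.warning("multi-channel image %s converted to luminance", path)
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        # ITU-R 601 luma; equal channels map to the channel value exactly
        weights = np.array([0.299, 0.587, 0.114])
        arr = np.tensordot(arr.astype(np.float64), weights, axes=([2], [0]))
        if dtype_max is not None:
            arr = np.clip(np.rint(arr), 0, dtype_max)
    if arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image layout with shape {arr.shape}")
    if dtype_max is None:
        if np.issubdtype(arr.dtype, np.floating):
            dtype_max = 65535 if arr.max() > 255 else 255
        else:
            raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return GrayImage(pixels=arr, dtype_max=int(dtype_max))


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as PNG or TIFF (dtype chosen by dtype_max)."""
    dtype = np.uint8 if image.dtype_max <= 255 else np.uint16
    iio.imwrite(Path(path), np.clip(np.rint(image.pixels), 0, image.dtype_max).astype(dtype))


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a cluster-label map as a raw-index 8-bit PNG."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > 255:
        raise ValueError("more than 256 labels cannot be stored in an 8-bit PNG")
    iio.imwrite(Path(path), labels.astype(np.uint8))


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def colorize_labels(labels: np.ndarray) -> np.ndarray:
    """Map label indices to distinct RGB colors for visualization."""
    palette = np.array(
        [
            [0, 0, 0],
            [66, 135, 245],
            [52, 168, 83],
            [251, 188, 5],
            [234, 67, 53],
            [171, 71, 188],
            [0, 172, 193],
            [255, 112, 67],
        ],
        dtype=np.uint8,
    )
    return palette[np.asarray(labels) % len(palette)]


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a segmentation report (config, seed, trace, metrics) as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
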