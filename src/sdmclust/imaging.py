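"""Image and mask I/O plus RGB -> CIELAB conversion.

The clustering stage operates on the L* plane of CIELAB, so this module
is the single place where pixel data enter the pipeline: 8/16-bit
PNG/TIFF/BMP/JPEG sub-images are normalised to 8-bit RGB, converted with
sRGB/D65 conventions, and 3-label masks (0=background, 1=cytoplasm,
2=nucleus) round-trip through single-channel PNG.
"""

from __future__ import annotations

import os
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np
from skimage import color

#: label codes used throughout the package
BACKGROUND, CYTOPLASM, NUCLEUS = 0, 1, 2
VALID_LABELS = frozenset({BACKGROUND, CYTOPLASM, NUCLEUS})


class LabImage(NamedTuple):
    """Per-pixel CIELAB planes of a cell sub-image (L* in [0, 100])."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an RGB image as an H x W x 3 uint8 array.

    Grayscale inputs are replicated to three channels, an alpha channel
    is dropped, and 16-bit data are rescaled so 65535 maps to 255.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot decode image file {os.fspath(path)!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {os.fspath(path)!r}")
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image layout {arr.shape} in {os.fspath(path)!r}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"image {arr.shape[:2]} smaller than the 8x8 minimum")
    return arr


def rgb_to_cielab(img: np.ndarray) -> LabImage:
    """Convert an H x W x 3 RGB image (uint8 or float in [0,1]) to CIELAB.

    sRGB primaries and the D65 white point are assumed; L* stays on its
    native [0, 100] scale so thresholds remain interpretable.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {img.shape}")
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    lab = color.rgb2lab(img)
    return LabImage(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def cielab_to_rgb(lab: LabImage) -> np.ndarray:
    """Inverse of :func:`rgb_to_cielab`; returns uint8 RGB (gamut-clipped)."""
    stack = np.stack([lab.L, lab.a, lab.b], axis=-1)
    rgb = color.lab2rgb(stack)
    return (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    labels = set(np.unique(mask).tolist())
    if not labels <= VALID_LABELS:
        raise ValueError(f"mask contains invalid labels {sorted(labels - VALID_LABELS)}")
    return mask.astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1,2} label mask as a single-channel PNG (lossless)."""
    mask = _validate_mask(mask)
    try:
        iio.imwrite(path, mask, extension=".png")
    except OSError as exc:
        raise IOError(f"cannot write mask to {os.fspath(path)!r}: {exc}") from exc


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a label mask written by :func:`write_mask`."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return _validate_mask(arr)
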