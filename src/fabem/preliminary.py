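"""Preliminary segmentation of a head CT slice.

The working representation of a slice is ``E``, a 2-D uint8 grayscale image.
Skull and soft tissue are separated by *max-relative* thresholds: bone in CT
renders near the top of the 8-bit range, so the skull is everything within a
fixed margin of ``Max(E)`` and the soft-tissue band is everything at least a
slightly wider margin below it.  The band between the two margins is a
deliberate dead zone that belongs to neither class, absorbing partial-volume
pixels on the inner skull surface.

The thresholded skull ring is then filled (hole filling) to become the stage-1
mask, which multiplied with the soft-tissue image removes skull, scalp and
everything outside the cranial vault.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import FormatError, NoSkullDetected

# Max-relative threshold margins.  Skull: E >= Max(E) - SKULL_MARGIN.
# Soft tissue: 1 <= E <= Max(E) - SOFT_MARGIN.  The margins are deliberately
# unequal so that (Max-20, Max-15) is excluded from both classes.
SKULL_MARGIN = 15
SOFT_MARGIN = 20

# A slice whose maximum falls below this floor plausibly contains no bone at
# all; thresholding it would select nearly every pixel.
SKULL_FLOOR = 120

# ITU-R BT.601 luminance weights, used only when the three channels differ.
_LUMA = np.array([0.299, 0.587, 0.114])


def _as_gray(E) -> np.ndarray:
    E = np.asarray(E)
    if E.ndim != 2:
        raise FormatError(f"expected a 2-D grayscale image, got shape {E.shape}")
    if not np.issubdtype(E.dtype, np.integer):
        raise FormatError(f"expected integer intensities, got dtype {E.dtype}")
    if E.size and (E.min() < 0 or E.max() > 255):
        raise FormatError("intensities must lie in [0, 255]")
    return E.astype(np.uint8, copy=False)


def _as_mask(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise FormatError(f"expected a 2-D mask, got shape {mask.shape}")
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("mask values must be 0/1")
        mask = mask.astype(bool)
    return mask


def to_grayscale(img) -> np.ndarray:
    """Convert an H×W×3 8-bit image to a GraySlice.

    CT archives frequently store renderings as RGB with three identical
    channels; in that case the result is exactly one channel.  Otherwise a
    BT.601 luminance weighting is applied and rounded to nearest integer.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected an H×W×3 image, got shape {img.shape}")
    if img.dtype != np.uint8:
        if not np.issubdtype(img.dtype, np.integer):
            raise FormatError(f"expected 8-bit integer channels, got {img.dtype}")
        if img.size and (img.min() < 0 or img.max() > 255):
            raise FormatError("channel values must lie in [0, 255]")
        img = img.astype(np.uint8)
    if np.array_equal(img[..., 0], img[..., 1]) and np.array_equal(
        img[..., 0], img[..., 2]
    ):
        return img[..., 0].copy()
    return np.rint(img.astype(np.float64) @ _LUMA).clip(0, 255).astype(np.uint8)


def segment_skull(
    E, *, margin: int = SKULL_MARGIN, skull_floor: int = SKULL_FLOOR
) -> np.ndarray:
    """Binary skull mask e1: pixels within ``margin`` of the slice maximum."""
    E = _as_gray(E)
    mx = int(E.max())
    if mx < skull_floor:
        raise NoSkullDetected(
            f"slice maximum {mx} is below the skull floor {skull_floor}"
        )
    return E >= mx - margin


def segment_soft_tissue(
    E, *, margin: int = SOFT_MARGIN, skull_floor: int = SKULL_FLOOR
) -> np.ndarray:
    """Soft-tissue image e2: gray values kept inside [1, Max(E) − margin], 0 outside.

    Unlike the skull mask this is *not* binarized — intensities are preserved
    for the downstream median filtering / stage-2 mask.
    """
    E = _as_gray(E)
    mx = int(E.max())
    if mx < skull_floor:
        raise NoSkullDetected(
            f"slice maximum {mx} is below the skull floor {skull_floor}"
        )
    keep = (E >= 1) & (E <= mx - margin)
    return np.where(keep, E, 0).astype(np.uint8)


def fill_skull_template(e1) -> np.ndarray:
    """Fill the enclosed interior of the skull ring to form a stage-1 mask.

    A hole is a background region not connected to the image border under
    4-connectivity (so 8-connected 1-pixel ring walls are leak-proof).  If
    the ring is open the interior stays connected to the border and is left
    unfilled — exactly the condition the closure cycle detects.
    """
    e1 = _as_mask(e1)
    return ndimage.binary_fill_holes(e1)


def apply_mask(img, mask) -> np.ndarray:
    """Pixelwise product of an image with a binary mask (shape must match)."""
    img = np.asarray(img)
    mask = _as_mask(mask)
    if img.shape != mask.shape:
        raise FormatError(f"shape mismatch: image {img.shape} vs mask {mask.shape}")
    if img.dtype == bool:
        return img & mask
    return (img * mask.astype(img.dtype)).astype(img.dtype)
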