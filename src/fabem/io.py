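"""PNG (and optional DICOM) input/output helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import FormatError


def load_image(path) -> np.ndarray:
    """Load an 8-bit PNG as (H, W) grayscale or (H, W, 3) RGB uint8."""
    with Image.open(path) as im:
        if im.mode == "L":
            return np.asarray(im, dtype=np.uint8)
        if im.mode != "RGB":
            im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)


def load_mask(path) -> np.ndarray:
    """Load a binary mask PNG (any nonzero pixel is foreground)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def save_mask(path, mask) -> None:
    """Write a binary mask as PNG with {0, 255} encoding."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask > 0
    Image.fromarray((mask.astype(np.uint8) * 255)).save(path)


def save_image(path, img) -> None:
    img = np.asarray(img, dtype=np.uint8)
    Image.fromarray(img).save(path)


def load_dicom(path, window_center: float, window_width: float) -> np.ndarray:
    """Window a single-slice DICOM and rescale to 8-bit grayscale.

    Applies the stored rescale slope/intercept, then the given window
    (center/width in HU) mapped linearly onto [0, 255].
    """
    import pydicom  # optional dependency; only needed for DICOM input

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    if window_width <= 0:
        raise FormatError("window width must be positive")
    lo = window_center - window_width / 2.0
    scaled = (hu - lo) / window_width * 255.0
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def find_slices(directory) -> list:
    """Sorted PNG paths in a directory (deterministic batch order)."""
    return sorted(Path(directory).glob("*.png"))
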