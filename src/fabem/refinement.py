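"""Stage-2 mask creation and final-mask refinement.

The preliminary segmented image (soft tissue × stage-1 mask) is median
filtered to suppress few-pixel speckle and binarized into the *stage-2 mask*.
If that mask is a single connected region it is already the final mask.
Otherwise the slice is classified: single-region slices are trimmed by
seeded region growing — the seed is found by scanning the image midline from
the bottom up (everything below the brain was already removed, so the first
foreground hit is the inferior brain edge) and lifting it five rows to land
safely inside the parenchyma — while multi-region slices are handed to the
pluggable segmenter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage

from .closure import SliceClass
from .errors import EmptySeedRegion, FabemError
from .preliminary import _as_mask

logger = logging.getLogger(__name__)

DEFAULT_MEDIAN_KERNEL = 5
DEFAULT_BAND_HALFWIDTH = 5
DEFAULT_LIFT = 5


class SeedPoint(NamedTuple):
    row: int
    col: int


class Route(str, Enum):
    """Which branch produced the final mask."""

    DIRECT = "direct"
    REGION_GROW = "region_grow"
    SEGMENTER = "segmenter"


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise FabemError(f"connectivity must be 4 or 8, got {connectivity}")


def make_stage2(prelim, kernel: int = DEFAULT_MEDIAN_KERNEL) -> np.ndarray:
    """Median-filter the preliminary segmented image, then binarize (nonzero)."""
    if kernel < 1 or kernel % 2 == 0:
        raise FabemError(f"median kernel must be odd and >= 1, got {kernel}")
    prelim = np.asarray(prelim)
    if prelim.ndim != 2:
        raise FabemError(f"expected a 2-D image, got shape {prelim.shape}")
    filtered = ndimage.median_filter(prelim, size=kernel, mode="reflect")
    return filtered > 0


def count_connected_regions(mask, connectivity: int = 8) -> int:
    """Number of maximal connected foreground components."""
    mask = _as_mask(mask)
    _, n = ndimage.label(mask, structure=_structure(connectivity))
    return int(n)


def select_seed(
    mask,
    band_halfwidth: int = DEFAULT_BAND_HALFWIDTH,
    lift: int = DEFAULT_LIFT,
) -> SeedPoint:
    """Automatic seed for region growing.

    Scan rows bottom-up; within each row inspect the midline column band
    ``[W/2 − band_halfwidth, W/2 + band_halfwidth]``.  The first foreground
    pixel found is lifted ``lift`` rows to place the seed inside the brain
    rather than on its edge.  Fallbacks (candidate off-mask: walk further up
    the same column; band entirely empty or walk exhausted: foreground pixel
    nearest the image center) guarantee the returned seed lies on the mask.
    """
    mask = _as_mask(mask)
    if not mask.any():
        raise EmptySeedRegion("cannot seed an empty mask")
    H, W = mask.shape
    c0 = W // 2
    lo = max(0, c0 - band_halfwidth)
    hi = min(W - 1, c0 + band_halfwidth)

    hit = None
    band = mask[:, lo : hi + 1]
    for r in range(H - 1, -1, -1):
        cols = np.flatnonzero(band[r])
        if cols.size:
            hit = (r, lo + int(cols[0]))
            break

    if hit is not None:
        r, c = hit
        rr = r - lift
        if 0 <= rr and mask[rr, c]:
            return SeedPoint(rr, c)
        # Walk upward from the candidate at the same column.
        for r2 in range(min(rr, H - 1), -1, -1):
            if r2 >= 0 and mask[r2, c]:
                return SeedPoint(r2, c)

    # Nearest foreground pixel to the image center (row-major tie-break).
    rows, cols = np.nonzero(mask)
    d2 = (rows - (H - 1) / 2.0) ** 2 + (cols - (W - 1) / 2.0) ** 2
    k = int(np.argmin(d2))
    return SeedPoint(int(rows[k]), int(cols[k]))


def region_grow(mask, seed: SeedPoint, connectivity: int = 8) -> np.ndarray:
    """Connected component of the binary mask containing the seed.

    The homogeneity criterion is membership in the foreground, so growing
    reduces to selecting one component; everything else is zeroed.
    """
    mask = _as_mask(mask)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise FabemError(f"seed {(r, c)} out of bounds for shape {mask.shape}")
    if not mask[r, c]:
        raise FabemError(f"seed {(r, c)} lies on background")
    labels, _ = ndimage.label(mask, structure=_structure(connectivity))
    return labels == labels[r, c]


@dataclass
class RefineResult:
    final_mask: np.ndarray
    route: Route
    n_regions: int
    seed: Optional[SeedPoint] = None
    slice_class: Optional[SliceClass] = None


def refine(
    stage2,
    gray,
    classifier,
    segmenter,
    *,
    connectivity: int = 8,
    band_halfwidth: int = DEFAULT_BAND_HALFWIDTH,
    lift: int = DEFAULT_LIFT,
    intersect_stage2: bool = False,
) -> RefineResult:
    """Dispatch the stage-2 mask to its final-mask route.

    One connected region → the stage-2 mask *is* the final mask (DIRECT).
    Otherwise the classifier decides: multi-region slices go to the
    segmenter (its binarized brain map becomes the final mask, optionally
    ANDed with stage-2), single-region slices are trimmed by region growing
    from the automatically selected seed.
    """
    stage2 = _as_mask(stage2)
    n = count_connected_regions(stage2, connectivity)
    if n == 1:
        return RefineResult(stage2.copy(), Route.DIRECT, n)
    if n == 0:
        logger.warning("stage-2 mask is empty; returning empty final mask")
        return RefineResult(stage2.copy(), Route.DIRECT, n)

    slice_class = classifier.classify(gray, stage2)
    if slice_class is SliceClass.MULTI_REGION:
        seg = np.asarray(segmenter.segment(gray))
        if seg.shape != stage2.shape:
            raise FabemError(
                f"segmenter output shape {seg.shape} != stage2 shape {stage2.shape}"
            )
        final = seg.astype(bool)
        if intersect_stage2:
            final = final & stage2
        return RefineResult(final, Route.SEGMENTER, n, slice_class=slice_class)

    try:
        seed = select_seed(stage2, band_halfwidth, lift)
        final = region_grow(stage2, seed, connectivity)
    except EmptySeedRegion:  # unreachable when n >= 2; kept as a guard
        logger.warning("seed selection failed; keeping largest component")
        labels, k = ndimage.label(stage2, structure=_structure(connectivity))
        sizes = ndimage.sum_labels(stage2, labels, index=np.arange(1, k + 1))
        final = labels == (1 + int(np.argmax(sizes)))
        seed = None
    return RefineResult(final, Route.REGION_GROW, n, seed=seed, slice_class=slice_class)
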