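"""Fill detection and skull closure.

Skulls are not always closed on a single CT slice (bony sutures, fractures),
so filling the thresholded skull can silently fail: the interior stays
connected to the image border and nothing is filled.  The fill is judged by
the statistic

    q = (S_i - S_e1) / S_i

where ``S_i`` is the mask area after cycle ``i`` and ``S_e1`` the skull area,
i.e. q is the fraction of the mask contributed by filling.  If q exceeds a
threshold TV the fill is deemed complete; otherwise the slice is classified
once (basis-cranii slices get the constant TV = 0.2485, reflecting their
small brain-to-mask ratio) and, while q stays at or below TV, the skull is
morphologically closed with a disk whose radius grows by one each cycle,
refilled and re-measured, up to a hard cap of 10 cycles.

TV for non-basis layers is predicted by a linear regression on the
soft-tissue and skull area fractions of the slice (the expected brain-area
share of a completely filled mask, which lies strictly below the interior
share q reaches on a successful fill — that slack is what makes the test
discriminative).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import EmptyMaskError, FabemError
from .preliminary import _as_mask, fill_skull_template

logger = logging.getLogger(__name__)

#: Average brain-area share of a complete mask at the skull base; used as the
#: fixed TV for basis-cranii slices, where the regression fit is poor.
BASIS_CRANII_TV = 0.2485

#: Hard cap on closure cycles; prevents a dead loop on slices whose mask can
#: never fill (e.g. genuinely tiny brain area).
MAX_CYCLES = 10


class SliceClass(str, Enum):
    """Three-way slice category produced by the (pluggable) classifier."""

    MULTI_REGION = "multi_region"
    BASIS_CRANII = "basis_cranii"
    OTHER_LAYER = "other_layer"
    UNKNOWN = "unknown"


@dataclass
class TVModel:
    """Linear model predicting TV from normalized soft-tissue / skull areas.

    ``TV = intercept + soft_coef * soft_frac + skull_coef * skull_frac``,
    clamped to ``clamp``.  Basis-cranii slices bypass the regression and use
    ``basis_cranii_constant`` instead.
    """

    intercept: float
    soft_coef: float
    skull_coef: float
    basis_cranii_constant: float = BASIS_CRANII_TV
    provenance: str = "user"
    clamp: tuple = (0.05, 0.95)
    stats: Optional[dict] = field(default=None, repr=False)

    def predict(self, soft_frac: float, skull_frac: float) -> float:
        tv = (
            self.intercept
            + self.soft_coef * soft_frac
            + self.skull_coef * skull_frac
        )
        lo, hi = self.clamp
        return float(min(max(tv, lo), hi))

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "soft_coef": self.soft_coef,
            "skull_coef": self.skull_coef,
            "basis_cranii_constant": self.basis_cranii_constant,
            "provenance": self.provenance,
            "clamp": list(self.clamp),
        }
        if self.stats is not None:
            payload["stats"] = self.stats
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TVModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["clamp"] = tuple(payload.get("clamp", (0.05, 0.95)))
        return cls(**payload)


# Fit on the packaged phantom generator's reference corpus (60 closed-skull
# non-basis slices, seed 20240501); regenerate with `fabem fit-tv`.
DEFAULT_TV_MODEL = TVModel(
    intercept=-0.0993,
    soft_coef=2.5410,
    skull_coef=-3.3346,
    provenance="phantom-fit",
)


def fill_fraction(S_i: int, S_e1: int) -> float:
    """q = (S_i − S_e1)/S_i, the filled share of the mask area."""
    if S_i <= 0:
        raise EmptyMaskError("mask area S_i must be positive")
    if S_e1 < 0 or S_e1 > S_i:
        raise FabemError(f"invariant violated: need 0 <= S_e1 <= S_i, got {S_e1} > {S_i}")
    return (S_i - S_e1) / S_i


def compute_tv(
    slice_class: SliceClass,
    soft_area_frac: float,
    skull_area_frac: float,
    model: TVModel = DEFAULT_TV_MODEL,
) -> float:
    """Threshold value for the fill test; constant at the basis cranii,
    regression-predicted (and clamped) everywhere else."""
    if slice_class is SliceClass.BASIS_CRANII:
        return float(model.basis_cranii_constant)
    return model.predict(soft_area_frac, skull_area_frac)


def morphological_close(mask, radius: int) -> np.ndarray:
    """Morphological closing (dilate then erode) with a disk footprint.

    Borders are handled so the image frame never erodes the result: the
    dilation pads with background, the erosion pads with foreground.
    """
    if radius < 0:
        raise FabemError(f"radius must be >= 0, got {radius}")
    mask = _as_mask(mask)
    if radius == 0:
        return mask.copy()
    footprint = disk(radius).astype(bool)
    dilated = ndimage.maximum_filter(mask, footprint=footprint, mode="constant", cval=0)
    return ndimage.minimum_filter(dilated, footprint=footprint, mode="constant", cval=1)


@dataclass
class ClosureState:
    """Bookkeeping of one run of the closure cycle."""

    i: int
    radius: int
    S_i: int
    S_e1: int
    q: float
    tv: float
    slice_class: SliceClass

    def as_dict(self) -> dict:
        return {
            "cycles": self.i,
            "radius": self.radius,
            "mask_area": self.S_i,
            "skull_area": self.S_e1,
            "q": self.q,
            "tv": self.tv,
            "slice_class": self.slice_class.value,
        }


def closure_cycle(
    e1,
    soft_area_frac: float,
    classify: Optional[Callable[[], SliceClass]] = None,
    tv_model: TVModel = DEFAULT_TV_MODEL,
    max_cycles: int = MAX_CYCLES,
    closure_mode: str = "from_original",
) -> tuple:
    """Run the fill-detection / skull-closure cycle on a skull mask.

    ``classify`` is a zero-argument callable returning a :class:`SliceClass`;
    it is invoked at most once, only when the first fill fails the q > TV
    test (the class of a slice does not change across cycles).  A classifier
    failure falls back to the other-layer path.

    ``closure_mode`` selects whether each cycle closes the original skull
    with a radius-i disk (``"from_original"``, idempotent-safe default) or
    the previous cycle's closed skull (``"cumulative"``).

    Returns ``(stage1_mask, ClosureState)``; the mask always contains the
    input skull plus whatever interior was filled.
    """
    if closure_mode not in ("from_original", "cumulative"):
        raise FabemError(f"unknown closure_mode {closure_mode!r}")
    e1 = _as_mask(e1)
    S_e1 = int(e1.sum())
    if S_e1 == 0:
        raise EmptyMaskError("skull mask is empty")

    skull = e1
    filled = fill_skull_template(e1)
    S_i = int(filled.sum())
    q = fill_fraction(S_i, S_e1)
    skull_frac = S_e1 / e1.size

    tv = compute_tv(SliceClass.UNKNOWN, soft_area_frac, skull_frac, tv_model)
    slice_class = SliceClass.UNKNOWN
    i = 0

    if q <= tv and classify is not None:
        try:
            slice_class = classify()
        except Exception:  # pragma: no cover - defensive path, exercised in tests
            logger.warning("slice classifier failed; using other-layer TV", exc_info=True)
            slice_class = SliceClass.OTHER_LAYER
        if slice_class is SliceClass.BASIS_CRANII:
            tv = float(tv_model.basis_cranii_constant)
            # q is re-judged against the reassigned TV by the loop condition.

    while q <= tv and i < max_cycles:
        i += 1
        base = e1 if closure_mode == "from_original" else skull
        skull = morphological_close(base, i)
        filled = fill_skull_template(skull) | e1
        S_i = int(filled.sum())
        S_cur = int(skull.sum())
        q = fill_fraction(S_i, S_cur)

    state = ClosureState(
        i=i,
        radius=i,
        S_i=S_i,
        S_e1=int(skull.sum()),
        q=q,
        tv=tv,
        slice_class=slice_class,
    )
    return filled, state
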