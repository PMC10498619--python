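"""Pluggable slice classifier and brain segmenter.

The pipeline needs two learned components: a three-way slice classifier
(multi-region / basis-cranii / other layer) and a brain segmenter for
multi-region slices.  Both are expressed as small interfaces so trained
models can be slotted in; the package ships deterministic rule-based
baselines so the whole pipeline runs end-to-end with no weights.  The
baselines are explicit stand-ins, tuned on the phantom suite only — they are
not claimed to match trained-network accuracy on clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .closure import SliceClass, closure_cycle, morphological_close
from .errors import NoSkullDetected, PluginContractError, PluginNotFound
from .preliminary import (
    _as_gray,
    apply_mask,
    fill_skull_template,
    segment_skull,
    segment_soft_tissue,
)
from .refinement import _structure, make_stage2


@runtime_checkable
class ClassifierInterface(Protocol):
    name: str

    def classify(self, gray, stage2=None) -> SliceClass: ...


@runtime_checkable
class SegmenterInterface(Protocol):
    name: str

    def segment(self, gray) -> np.ndarray: ...


def _component_areas(mask, connectivity: int = 8) -> np.ndarray:
    labels, k = ndimage.label(mask, structure=_structure(connectivity))
    if k == 0:
        return np.zeros(0)
    return ndimage.sum_labels(mask, labels, index=np.arange(1, k + 1))


@dataclass
class BaselineClassifier:
    """Rule-based stand-in for the CNN slice classifier.

    Multi-region: at least two sizeable stage-2 components.  Basis cranii:
    heavy soft tissue in the lower third of the slice combined with a small
    brain-candidate area (the skull base carries facial/neck soft tissue and
    little brain).  Everything else: other layer.

    Unlike a trained classifier (which sees only the original image) the
    baseline may consume the stage-2 mask for robustness; when called before
    stage 2 exists it derives its own candidate via an aggressive one-shot
    closing of the skull.
    """

    min_area: int = 50
    basis_frac: float = 0.35
    brain_frac_max: float = 0.25
    connectivity: int = 8
    kernel: int = 5
    name: str = "baseline"

    def _candidate(self, gray, soft) -> np.ndarray:
        try:
            e1 = segment_skull(gray)
        except NoSkullDetected:
            return make_stage2(soft, self.kernel)
        interior = fill_skull_template(morphological_close(e1, 10))
        return make_stage2(apply_mask(soft, interior), self.kernel)

    def classify(self, gray, stage2=None) -> SliceClass:
        gray = _as_gray(gray)
        try:
            soft = segment_soft_tissue(gray)
        except NoSkullDetected:
            soft = np.where(gray >= 1, gray, 0).astype(np.uint8)
        cand = np.asarray(stage2).astype(bool) if stage2 is not None else None
        if cand is None:
            cand = self._candidate(gray, soft)
        areas = _component_areas(cand, self.connectivity)
        if (areas >= self.min_area).sum() >= 2:
            return SliceClass.MULTI_REGION
        lower = soft[2 * gray.shape[0] // 3 :, :]
        lower_frac = np.count_nonzero(lower) / lower.size
        brain_frac = cand.sum() / cand.size
        if lower_frac > self.basis_frac and brain_frac < self.brain_frac_max:
            return SliceClass.BASIS_CRANII
        return SliceClass.OTHER_LAYER


@dataclass
class BaselineSegmenter:
    """Rule-based stand-in for the FCN brain segmenter.

    Re-runs the preliminary segmentation and stage-2 creation internally,
    then keeps every connected component at least ``alpha`` times the size of
    the largest one, discarding components that touch the image border
    (pillow/table artifacts).
    """

    alpha: float = 0.1
    kernel: int = 5
    connectivity: int = 8
    name: str = "baseline"

    def segment(self, gray) -> np.ndarray:
        gray = _as_gray(gray)
        e1 = segment_skull(gray)  # NoSkullDetected propagates
        soft = segment_soft_tissue(gray)
        soft_frac = np.count_nonzero(soft) / soft.size
        stage1, _ = closure_cycle(e1, soft_frac, classify=lambda: SliceClass.OTHER_LAYER)
        stage2 = make_stage2(apply_mask(soft, stage1), self.kernel)

        labels, k = ndimage.label(stage2, structure=_structure(self.connectivity))
        out = np.zeros_like(stage2, dtype=bool)
        if k == 0:
            return out
        areas = ndimage.sum_labels(stage2, labels, index=np.arange(1, k + 1))
        border = np.zeros_like(stage2, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        border_labels = set(np.unique(labels[border])) - {0}
        keep = [
            lab
            for lab in range(1, k + 1)
            if lab not in border_labels and areas[lab - 1] >= self.alpha * areas.max()
        ]
        if keep:
            out = np.isin(labels, keep)
        return out


_CLASSIFIERS: Dict[str, Callable[..., ClassifierInterface]] = {}
_SEGMENTERS: Dict[str, Callable[..., SegmenterInterface]] = {}


def register_classifier(name: str, factory: Callable[..., ClassifierInterface]) -> None:
    probe = factory()
    if not callable(getattr(probe, "classify", None)):
        raise PluginContractError(f"classifier {name!r} lacks a classify() method")
    _CLASSIFIERS[name] = factory


def register_segmenter(name: str, factory: Callable[..., SegmenterInterface]) -> None:
    probe = factory()
    if not callable(getattr(probe, "segment", None)):
        raise PluginContractError(f"segmenter {name!r} lacks a segment() method")
    _SEGMENTERS[name] = factory


register_classifier("baseline", BaselineClassifier)
register_segmenter("baseline", BaselineSegmenter)


def load_plugin(kind: str, spec: Optional[dict] = None):
    """Instantiate a registered plugin from a config entry.

    ``spec`` is ``{"name": <registered name>, "params": {...}}``; omitted
    spec means the baseline.  Unknown names raise :class:`PluginNotFound`
    listing what is registered.
    """
    registry = {"classifier": _CLASSIFIERS, "segmenter": _SEGMENTERS}.get(kind)
    if registry is None:
        raise PluginNotFound(f"unknown plugin kind {kind!r} (classifier|segmenter)")
    spec = spec or {}
    name = spec.get("name", "baseline")
    params = spec.get("params", {}) or {}
    if name not in registry:
        raise PluginNotFound(
            f"no {kind} plugin named {name!r}; registered: {sorted(registry)}"
        )
    return registry[name](**params)
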