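"""Synthetic head-CT phantom slices with pixel-perfect ground truth.

A phantom emulates the intensity structure the pipeline exploits rather than
anatomy: a bright near-saturated skull ring (optionally with a gap), brain
parenchyma and extracranial soft tissue sharing a mid-gray band, and the
three slice regimes the classifier distinguishes — ordinary single-region
layers, skull-base (basis cranii) layers with heavy inferior soft tissue and
internal bone, and multi-region layers with disconnected brain blobs.
Optional inserts: hyperdense hematoma (between brain and bone), a
calcification speck, a scalp remnant just inside the vault (to exercise the
region-growing route), and a pillow bar touching the image border.

Every tissue gets Gaussian intensity noise, but intensities are clipped to
per-tissue bands chosen so that the max-relative threshold margins behave as
intended: skull stays within 10 gray levels of saturation and soft tissue
stays at least 25 levels below it, on both sides of the dead band.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .closure import SliceClass, TVModel
from .errors import FabemError, PhantomSpecError
from .preliminary import fill_skull_template, segment_skull, segment_soft_tissue

# Per-tissue clip bands (lo, hi) applied after noise; they enforce the
# skull > hematoma > brain ≈ soft-tissue intensity ordering.
_SKULL_BAND = (245, 255)
_HEMATOMA_BAND = (150, 225)
_SOFT_BAND = (5, 225)


@dataclass(frozen=True)
class EllipseSpec:
    """Axis-aligned ellipse: center (row, col), half-axes (rows, cols)."""

    center: Tuple[float, float]
    axes: Tuple[float, float]
    mean: float = 80.0
    sd: float = 8.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic slice; deterministic given ``seed``."""

    shape: Tuple[int, int] = (512, 512)
    skull_center: Tuple[float, float] = (256.0, 256.0)
    skull_axes: Tuple[float, float] = (185.0, 165.0)  # outer half-axes
    skull_thickness: float = 6.0
    skull_mean: float = 252.0
    skull_sd: float = 2.0
    gap: bool = False
    gap_angle: float = 0.0  # radians, 0 = image right, pi/2 = image bottom
    gap_width: float = 0.0  # pixels along the ring
    layout: SliceClass = SliceClass.OTHER_LAYER
    brain_blobs: Tuple[EllipseSpec, ...] = ()
    soft_thickness: float = 22.0
    soft_mean: float = 70.0
    soft_sd: float = 8.0
    bone_blobs: Tuple[EllipseSpec, ...] = ()  # internal bone (basis cranii)
    inferior_mass: Optional[EllipseSpec] = None  # neck/face soft tissue
    hematoma: Optional[EllipseSpec] = None
    calcification: Optional[Tuple[Tuple[float, float], float]] = None
    border_bar: bool = False
    scalp_remnant: Optional[EllipseSpec] = None
    noise_sd: float = 2.0
    seed: int = 0

    @property
    def inner_axes(self) -> Tuple[float, float]:
        return (
            self.skull_axes[0] - self.skull_thickness,
            self.skull_axes[1] - self.skull_thickness,
        )

    def validate(self) -> None:
        H, W = self.shape
        if H < 16 or W < 16:
            raise PhantomSpecError("image must be at least 16×16")
        if not self.brain_blobs:
            raise PhantomSpecError("at least one brain blob is required")
        ia, ib = self.inner_axes
        if ia <= 4 or ib <= 4:
            raise PhantomSpecError("skull thickness leaves no interior")
        for blob in self.brain_blobs:
            dr = abs(blob.center[0] - self.skull_center[0])
            dc = abs(blob.center[1] - self.skull_center[1])
            if dr + blob.axes[0] > ia - 1 or dc + blob.axes[1] > ib - 1:
                raise PhantomSpecError("brain blob not strictly inside the skull interior")
            if blob.mean + 3 * blob.sd > _SOFT_BAND[1]:
                raise PhantomSpecError("brain intensity too close to the skull band")
        if self.hematoma is not None:
            if not (
                max(b.mean for b in self.brain_blobs)
                < self.hematoma.mean
                < _SKULL_BAND[0]
            ):
                raise PhantomSpecError(
                    "intensity ordering skull > hematoma > brain violated"
                )
        if self.gap and not (0 < self.gap_width < 20):
            raise PhantomSpecError("gap width must lie in (0, 20) pixels")


@dataclass
class PhantomRecord:
    rgb: np.ndarray
    gray: np.ndarray
    gt_mask: np.ndarray
    label: SliceClass
    spec: PhantomSpec


def _grid(shape):
    return np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = _grid(shape)
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _skull_ring(spec: PhantomSpec) -> np.ndarray:
    outer = _ellipse_mask(spec.shape, spec.skull_center, spec.skull_axes)
    inner = _ellipse_mask(spec.shape, spec.skull_center, spec.inner_axes)
    ring = outer & ~inner
    if spec.gap and spec.gap_width > 0:
        rr, cc = _grid(spec.shape)
        theta = np.arctan2(rr - spec.skull_center[0], cc - spec.skull_center[1])
        r_mid = (sum(spec.skull_axes) + sum(spec.inner_axes)) / 4.0
        half_angle = (spec.gap_width / 2.0) / r_mid
        delta = np.angle(np.exp(1j * (theta - spec.gap_angle)))
        ring &= np.abs(delta) > half_angle
    return ring


def generate_slice(spec: PhantomSpec) -> PhantomRecord:
    """Rasterize one phantom; byte-identical for identical spec (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    img = np.zeros((H, W), dtype=np.float64)
    bands = np.zeros((H, W, 2), dtype=np.float64)  # per-pixel clip band

    def paint(mask, mean, sd, band):
        img[mask] = mean + sd * rng.standard_normal(int(mask.sum()))
        bands[mask] = band

    # Extracranial soft-tissue shell.
    shell_outer = (
        spec.skull_axes[0] + spec.soft_thickness,
        spec.skull_axes[1] + spec.soft_thickness,
    )
    shell = _ellipse_mask(spec.shape, spec.skull_center, shell_outer) & ~_ellipse_mask(
        spec.shape, spec.skull_center, spec.skull_axes
    )
    paint(shell, spec.soft_mean, spec.soft_sd, _SOFT_BAND)

    if spec.inferior_mass is not None:
        m = spec.inferior_mass
        # Strictly extracranial: never paint into the skull interior.
        outside = ~_ellipse_mask(spec.shape, spec.skull_center, spec.skull_axes)
        paint(
            _ellipse_mask(spec.shape, m.center, m.axes) & (img == 0) & outside,
            m.mean,
            m.sd,
            _SOFT_BAND,
        )
    if spec.border_bar:
        bar = np.zeros((H, W), dtype=bool)
        bar[H - 5 :, W // 4 : 3 * W // 4] = True
        paint(bar, spec.soft_mean, spec.soft_sd, _SOFT_BAND)

    ring = _skull_ring(spec)
    paint(ring, spec.skull_mean, spec.skull_sd, _SKULL_BAND)
    for bone in spec.bone_blobs:
        paint(
            _ellipse_mask(spec.shape, bone.center, bone.axes),
            spec.skull_mean,
            spec.skull_sd,
            _SKULL_BAND,
        )

    gt = np.zeros((H, W), dtype=bool)
    for blob in spec.brain_blobs:
        m = _ellipse_mask(spec.shape, blob.center, blob.axes)
        gt |= m
        paint(m, blob.mean, blob.sd, _SOFT_BAND)

    if spec.scalp_remnant is not None:
        r = spec.scalp_remnant
        paint(_ellipse_mask(spec.shape, r.center, r.axes), r.mean, r.sd, _SOFT_BAND)
    if spec.hematoma is not None:
        h = spec.hematoma
        paint(_ellipse_mask(spec.shape, h.center, h.axes), h.mean, h.sd, _HEMATOMA_BAND)
    if spec.calcification is not None:
        center, radius = spec.calcification
        paint(
            _ellipse_mask(spec.shape, center, (radius, radius)),
            250.0,
            1.5,
            _SKULL_BAND,
        )

    tissue = bands[..., 1] > 0
    img[tissue] += spec.noise_sd * rng.standard_normal(int(tissue.sum()))
    img[tissue] = np.clip(img[tissue], bands[..., 0][tissue], bands[..., 1][tissue])
    gray = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    return PhantomRecord(rgb=rgb, gray=gray, gt_mask=gt, label=spec.layout, spec=spec)


def random_spec(
    rng: np.random.Generator,
    layout: SliceClass = SliceClass.OTHER_LAYER,
    gapped: bool = False,
    shape: Tuple[int, int] = (512, 512),
    scalp_remnant: bool = False,
    hematoma: bool = False,
    calcification: bool = False,
    border_bar: bool = False,
) -> PhantomSpec:
    """Draw a jittered but valid spec for the requested slice regime."""
    H, W = shape
    cr = H / 2 + rng.uniform(-0.015, 0.015) * H
    cc = W / 2 + rng.uniform(-0.015, 0.015) * W
    a_out = rng.uniform(0.33, 0.375) * H
    b_out = rng.uniform(0.30, 0.34) * W
    t = max(3.0, rng.uniform(0.010, 0.016) * H)
    if layout is SliceClass.BASIS_CRANII:
        t *= 1.5
    soft_t = rng.uniform(0.035, 0.05) * H
    ia, ib = a_out - t, b_out - t

    blobs: List[EllipseSpec] = []
    bone: List[EllipseSpec] = []
    inferior = None
    remnant = None
    hema = None
    calc = None
    brain_mean = rng.uniform(70, 95)
    brain_sd = rng.uniform(6, 10)

    if layout is SliceClass.MULTI_REGION:
        off = 0.48 * ib
        ax = (0.50 * ia, 0.36 * ib)
        for sgn in (-1, 1):
            blobs.append(
                EllipseSpec(
                    center=(cr + rng.uniform(-2, 2), cc + sgn * off),
                    axes=ax,
                    mean=brain_mean,
                    sd=brain_sd,
                )
            )
    elif layout is SliceClass.BASIS_CRANII:
        blobs.append(
            EllipseSpec(
                center=(cr - 0.25 * ia, cc),
                axes=(0.32 * ia, 0.40 * ib),
                mean=brain_mean,
                sd=brain_sd,
            )
        )
        for sgn in (-1, 1):
            bone.append(
                EllipseSpec(
                    center=(cr + 0.45 * ia, cc + sgn * 0.32 * ib),
                    axes=(0.26 * ia, 0.28 * ib),
                )
            )
        inferior = EllipseSpec(
            center=(cr + a_out + 0.05 * H, cc),
            axes=(0.17 * H, 0.38 * W),
            mean=rng.uniform(60, 85),
            sd=8.0,
        )
    else:
        if scalp_remnant:
            brain_ar = min(rng.uniform(0.82, 0.90) * ia, ia - 16)
            scale = brain_ar / ia
            blobs.append(
                EllipseSpec(
                    center=(cr, cc + rng.uniform(-2, 2)),
                    axes=(brain_ar, scale * ib - 2),
                    mean=brain_mean,
                    sd=brain_sd,
                )
            )
            remnant = EllipseSpec(
                center=(cr - brain_ar - 9, cc + rng.uniform(-3, 3)),
                axes=(3.2, 3.2),
                mean=rng.uniform(60, 85),
                sd=6.0,
            )
        else:
            s = rng.uniform(0.88, 0.94)
            blobs.append(
                EllipseSpec(
                    center=(cr + rng.uniform(-2, 2), cc + rng.uniform(-2, 2)),
                    axes=(s * ia - 2, s * ib - 2),
                    mean=brain_mean,
                    sd=brain_sd,
                )
            )
        main = blobs[0]
        if hematoma:
            hema = EllipseSpec(
                center=(
                    main.center[0] + rng.uniform(-0.2, 0.2) * main.axes[0],
                    main.center[1] + rng.uniform(-0.2, 0.2) * main.axes[1],
                ),
                axes=(0.22 * main.axes[0], 0.22 * main.axes[1]),
                mean=rng.uniform(170, 200),
                sd=6.0,
            )
        if calcification:
            calc = ((main.center[0] - 0.3 * main.axes[0], main.center[1]), 2.0)

    return PhantomSpec(
        shape=shape,
        skull_center=(cr, cc),
        skull_axes=(a_out, b_out),
        skull_thickness=t,
        gap=gapped,
        gap_angle=rng.uniform(-math.pi, math.pi),
        gap_width=float(rng.integers(1, 10)) if gapped else 0.0,
        layout=layout,
        brain_blobs=tuple(blobs),
        soft_thickness=soft_t,
        soft_mean=rng.uniform(55, 85),
        bone_blobs=tuple(bone),
        inferior_mass=inferior,
        hematoma=hema,
        calcification=calc,
        border_bar=border_bar,
        scalp_remnant=remnant,
        seed=int(rng.integers(2**31 - 1)),
    )


def _spec_digest(spec: PhantomSpec) -> str:
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


_CLASS_ORDER = (SliceClass.OTHER_LAYER, SliceClass.BASIS_CRANII, SliceClass.MULTI_REGION)


def stratified_counts(n: int, class_mix: Sequence[float]) -> List[int]:
    """Largest-remainder apportionment of n slices across the class mix."""
    if len(class_mix) != 3 or abs(sum(class_mix) - 1.0) > 1e-9 or min(class_mix) < 0:
        raise FabemError("class_mix must be three non-negative proportions summing to 1")
    raw = [n * p for p in class_mix]
    counts = [int(math.floor(x)) for x in raw]
    order = sorted(range(3), key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[: n - sum(counts)]:
        counts[k] += 1
    return counts


def generate_corpus(
    n: int,
    class_mix: Sequence[float] = (0.5, 0.2, 0.3),
    gap_rate: float = 0.3,
    seed: int = 0,
    shape: Tuple[int, int] = (512, 512),
    out_dir=None,
    scalp_remnant_rate: float = 0.3,
    hematoma_rate: float = 0.2,
    calcification_rate: float = 0.1,
    border_bar_rate: float = 0.1,
) -> Tuple[List[PhantomRecord], List[dict]]:
    """Generate a stratified, fully seeded corpus; optionally write it out.

    ``class_mix`` orders (OTHER_LAYER, BASIS_CRANII, MULTI_REGION).  With
    ``out_dir`` set, images go to ``images/NNNN.png`` (RGB), ground-truth
    masks to ``masks/NNNN.png`` ({0,255}) and a JSON-lines manifest records
    filename, class, gap, spec digest and per-slice seed.
    """
    counts = stratified_counts(n, class_mix)
    master = np.random.default_rng(seed)
    records: List[PhantomRecord] = []
    manifest: List[dict] = []
    idx = 0
    for cls, count in zip(_CLASS_ORDER, counts):
        for _ in range(count):
            gapped = bool(master.random() < gap_rate)
            child = np.random.default_rng(int(master.integers(2**31 - 1)))
            kwargs = {}
            if cls is SliceClass.OTHER_LAYER:
                kwargs["scalp_remnant"] = bool(child.random() < scalp_remnant_rate)
                kwargs["hematoma"] = bool(child.random() < hematoma_rate)
                kwargs["calcification"] = bool(child.random() < calcification_rate)
            kwargs["border_bar"] = bool(child.random() < border_bar_rate)
            spec = random_spec(child, layout=cls, gapped=gapped, shape=shape, **kwargs)
            record = generate_slice(spec)
            records.append(record)
            manifest.append(
                {
                    "index": idx,
                    "image": f"images/{idx:04d}.png",
                    "mask": f"masks/{idx:04d}.png",
                    "class": cls.value,
                    "gap": gapped,
                    "gap_width": spec.gap_width,
                    "seed": spec.seed,
                    "spec_digest": _spec_digest(spec),
                }
            )
            idx += 1

    if out_dir is not None:
        from . import io as fio

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for rec, row in zip(records, manifest):
            fio.save_image(out / row["image"], rec.rgb)
            fio.save_mask(out / row["mask"], rec.gt_mask)
        with open(out / "manifest.jsonl", "w") as fh:
            for row in manifest:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    return records, manifest


def fit_tv_from_features(
    soft_fracs: Sequence[float],
    skull_fracs: Sequence[float],
    fill_targets: Sequence[float],
) -> TVModel:
    """OLS fit of the TV regression: target ~ 1 + soft_frac + skull_frac."""
    X = sm.add_constant(np.column_stack([soft_fracs, skull_fracs]))
    fit = sm.OLS(np.asarray(fill_targets, dtype=float), X).fit()
    b0, b1, b2 = fit.params
    return TVModel(
        intercept=float(b0),
        soft_coef=float(b1),
        skull_coef=float(b2),
        provenance="phantom-fit",
        stats={
            "r_squared": float(fit.rsquared),
            "stderr": [float(s) for s in fit.bse],
            "n": int(fit.nobs),
        },
    )


def fit_tv_regression(records: Sequence[PhantomRecord], min_slices: int = 30) -> TVModel:
    """Re-execute the TV regression on a phantom corpus.

    Uses only closed-skull, non-basis-cranii slices (the skull base keeps
    its fixed constant and would pollute the fit); the target is the
    ground-truth brain area as a fraction of the filled stage-1 mask area.
    """
    soft_fracs, skull_fracs, targets = [], [], []
    for rec in records:
        if rec.spec.layout is SliceClass.BASIS_CRANII or rec.spec.gap:
            continue
        e1 = segment_skull(rec.gray)
        e2 = segment_soft_tissue(rec.gray)
        filled = fill_skull_template(e1)
        S = int(filled.sum())
        if S == 0:
            continue
        soft_fracs.append(np.count_nonzero(e2) / e2.size)
        skull_fracs.append(e1.sum() / e1.size)
        targets.append(rec.gt_mask.sum() / S)
    if len(targets) < min_slices:
        raise FabemError(
            f"need at least {min_slices} closed-skull non-basis slices, got {len(targets)}"
        )
    return fit_tv_from_features(soft_fracs, skull_fracs, targets)
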