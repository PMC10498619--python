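# Methods

## Pipeline model and assumptions

`fabem` operates on single 2-D 8-bit head-CT slices (512×512 typical; any
size ≥ 16×16). Slices are processed independently — no inter-slice mask
propagation — and the method assumes the rendering conventions of 8-bit CT
exports: bone near saturation, brain parenchyma and extracranial soft
tissue sharing a mid-gray band well below it, hyperdense lesions
(hematoma, calcification) in between. It is not applicable to MR, where
none of these intensity assumptions hold, nor to Hounsfield-calibrated
data without prior windowing (the optional DICOM reader windows and
rescales to 8-bit before the pipeline sees the slice).

### Thresholds

Skull: `E ≥ Max(E) − 15`. Soft tissue: `1 ≤ E ≤ Max(E) − 20`, gray values
preserved. Both margins are max-relative so they tolerate variation in
window settings, and the gap between them, `(Max−20, Max−15)`, is a
deliberate dead band assigned to neither class. The margins are config
fields (`skull_margin`, `soft_margin`) with those defaults; whether they
should scale with window width is an open question we leave to the
configuration surface.

A guard rejects slices whose maximum falls below `skull_floor`
(default 120): on a near-empty slice the max-relative rule would select
almost everything. Such slices raise `NoSkullDetected`; the batch runner
skips them with a logged reason, consistent with removing
non-brain-bearing slices before processing.

### Fill detection and closure

Hole filling defines a hole as a background region not 4-connected to the
image border, with 8-connected foreground — the standard dual-connectivity
pairing that prevents diagonal leaks through 1-pixel ring walls.

The fill statistic is `q = (S_i − S_e1)/S_i`. `S_e1` is taken as the area
of the *current* (closed) skull each cycle, so `S_i − S_e1` is exactly the
filled interior; measuring against the original thresholded skull would
count ring pixels added by closing as "filled area", which contradicts
the quantity's definition. A consequence worth knowing: after the gap is
bridged, growing the disk further thickens the closed ring and q drifts
*down* slightly — q is a step function of radius (≈0 before bridging, a
jump at the bridging radius), not a strictly monotone one. The exit test
is strict (`q > TV`).

The closing element is a disk of radius *i* at cycle *i* (isotropic with
respect to gap orientation; the shape is not otherwise constrained by the
method). By default each cycle closes the *original* skull with the
current radius (`closure_mode: from_original`) — re-closing the original
with a larger element is idempotent-safe; `cumulative` mode (closing the
previous cycle's result) is available and tested. The cycle cap is 10.

The slice classifier is consulted once, lazily, only when the first fill
fails — the class of a slice does not change across cycles. A basis-cranii
verdict reassigns TV to the constant 0.2485 (the mean brain-area share of
a complete mask at the skull base, where the regression fit is poor) and
q is re-judged; if it still fails, the slice proceeds into the closing
loop exactly like other layers. A classifier exception falls back to the
other-layer path and is logged.

### The TV regression

`TV = β0 + β1·(soft-tissue area / image area) + β2·(skull area / image
area)`, ordinary least squares, prediction clamped to [0.05, 0.95]. The
fit target is the ground-truth brain area as a fraction of the filled
mask area. This target sits strictly *below* the interior fraction q
reaches on a successful fill (the interior also contains non-brain
content), which is precisely the slack that makes `q > TV` discriminative:
a complete fill clears TV comfortably, a failed fill (q ≈ 0) never does.

The shipped default coefficients (−0.0993, 2.5410, −3.3346) were fit on
the package's reference phantom corpus (60 closed-skull non-basis slices,
seed 20240501, R² = 0.925) and carry provenance `"phantom-fit"`; refit
with `fabem fit-tv` or override via `tv_model_path` (JSON). Basis-cranii
and gapped slices are excluded from any fit: the former use the constant,
the latter have corrupted fill targets.

### Stage 2 and refinement

The median kernel is 5×5 by default (removes few-pixel speckle at 512×512
without materially eroding the brain boundary; configurable). Median
filtering enters the pipeline only at stage-2 creation. Foreground
connectivity is 8 throughout.

Seed selection scans rows bottom-up within a midline band of half-width 5
columns (a band rather than the single midline column, to survive a
1-pixel gap at the exact midline), takes the first foreground pixel, and
lifts it 5 rows. Fallback chain when the lifted candidate misses the
mask: walk further up the same column; if that exhausts, take the
foreground pixel nearest the image center (row-major tie-break); an empty
mask raises `EmptySeedRegion`. The returned seed always lies on the mask,
and region growing over a binary mask is exactly the connected component
containing the seed.

Multi-region slices take the segmenter's binarized brain map as the final
mask; `intersect_stage2: true` optionally ANDs it with stage 2 (default
false — the new mask replaces, not restricts).

### Baseline plugins

The baseline classifier is rule-based: ≥ 2 stage-2 components of ≥ 50 px
→ multi-region; else heavy soft tissue in the lower third (> 0.35 of
those pixels) combined with a small brain-candidate fraction (< 0.25) →
basis cranii; else other layer. Unlike a trained CNN it may consume the
stage-2 mask; when called before stage 2 exists (the closure-cycle call
site) it derives its own candidate from a one-shot radius-10 closing and
fill. The baseline segmenter re-runs the preliminary segmentation and
stage-2 creation, drops components touching the image border
(pillow/table artifacts) and keeps components ≥ 0.1× the largest. Both
are deterministic stand-ins tuned on phantoms only; trained models
register through the plugin API and slot into the same routes.

## Metrics conventions

Two classes (brain / non-brain). MPA and MIoU are per-slice class means,
then averaged over slices. Boundary pixels are foreground pixels
8-adjacent to background or to the image border (inner boundary);
distances are Euclidean via an exact distance transform; the default
tolerance is 0.75 % of the image diagonal (≈ 5.43 px at 512×512). A class
absent from both masks scores 1.0; both boundaries empty scores 1.0, and
exactly one empty scores 0.0 — these conventions avoid NaNs and never
trigger on the phantom suite's brain class. AET is wall-clock and
hardware-dependent; it is reported for completeness, not compared.

## The phantom generator

Phantoms emulate the intensity topology the pipeline exploits, not
anatomy: elliptical skull ring (optionally with a 1–9 px gap at a random
angle), elliptical brain blobs strictly inside the vault, an extracranial
soft-tissue shell in the brain's intensity band, and the three slice
regimes (ordinary, skull-base with internal bone and heavy inferior soft
tissue, multi-region with two separated blobs). Optional inserts:
hematoma (intensity between brain and bone), calcification speck, a small
scalp remnant just inside the vault (forces the region-growing route),
and a border-touching pillow bar. Every tissue gets Gaussian noise, but
values are clipped to per-tissue bands (skull ∈ [245, 255], soft/brain
≤ 225) so the threshold margins behave deterministically; non-tissue
pixels are exactly 0.

What passing tests on phantoms therefore show: correctness of the
thresholds, fill/closure logic, dispatch, seed selection and metrics on
inputs satisfying the method's intensity assumptions — and what they do
not show: performance under partial-volume gradients, beam-hardening and
streak artifacts, anisotropic noise, or anatomical boundary complexity.
The near-perfect corpus scores (IoU ≈ 1) are a property of the idealized
phantoms, not a clinical claim.

Corpus generation is fully seeded: a master generator draws the gap flag
and a per-slice child seed in a fixed order, so manifests and images are
byte-reproducible and the gapped count is exactly replayable.

## Problem sizes and numerical choices

The reference evaluations run a 100-slice 512×512 corpus (mix 50/20/30,
gap rate 0.3) and 50 gapped-skull phantoms; unit tests use 128×128
phantoms and ≤ 64×64 random instances against brute-force oracles —
sizes chosen so the full suite re-derives every expected value rather
than asserting stored constants. Morphological closing is implemented as
maximum/minimum filters with explicit border values (dilation pads
background, erosion pads foreground) so the image frame never erodes the
result. Grayscale conversion returns a channel verbatim when the three
channels are identical (the common CT-export case) and BT.601 luminance
rounded half-to-even otherwise. Ties and scan orders (seed search,
nearest-to-center fallback) are fixed row-major, making every pipeline
output a pure function of (slice, config, plugins).

## Known limitations

- 2-D only; no volumetric consistency between slices.
- The baseline classifier/segmenter are phantom-tuned heuristics; on
  clinical data they are placeholders for trained plugins.
- The TV regression defaults are phantom-fit; scanners or window settings
  with different soft-tissue/skull area relationships warrant a refit.
- Slices whose brain area is genuinely tiny can exhaust the 10-cycle cap
  with `q ≤ TV`; the best-effort mask is returned and flagged in
  provenance rather than rejected.
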