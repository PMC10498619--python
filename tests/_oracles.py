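"""Independent brute-force oracles for the test suite.

Everything here is written as plain per-pixel Python (BFS, sliding windows,
pairwise distances) deliberately independent of the library implementations
it checks.
"""

from collections import deque
from fractions import Fraction

import numpy as np


def luma_oracle(img):
    """Per-pixel BT.601 weighted sum, rounded half-to-even."""
    H, W, _ = img.shape
    out = np.zeros((H, W), dtype=np.uint8)
    for r in range(H):
        for c in range(W):
            R, G, B = (int(v) for v in img[r, c])
            out[r, c] = min(255, max(0, round(0.299 * R + 0.587 * G + 0.114 * B)))
    return out


def skull_oracle(E):
    mx = int(E.max())
    out = np.zeros(E.shape, dtype=bool)
    for r in range(E.shape[0]):
        for c in range(E.shape[1]):
            out[r, c] = int(E[r, c]) >= mx - 15
    return out


def soft_oracle(E):
    mx = int(E.max())
    out = np.zeros(E.shape, dtype=np.uint8)
    for r in range(E.shape[0]):
        for c in range(E.shape[1]):
            v = int(E[r, c])
            out[r, c] = v if 1 <= v <= mx - 20 else 0
    return out


def fill_oracle(mask):
    """Flood-fill background from the border (4-connectivity); anything not
    reached is a hole and gets filled."""
    H, W = mask.shape
    reached = np.zeros((H, W), dtype=bool)
    queue = deque()
    for r in range(H):
        for c in (0, W - 1):
            if not mask[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    for c in range(W):
        for r in (0, H - 1):
            if not mask[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and not mask[rr, cc] and not reached[rr, cc]:
                reached[rr, cc] = True
                queue.append((rr, cc))
    return mask | ~reached


def product_oracle(img, mask):
    out = np.zeros_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = img[r, c] * int(mask[r, c])
    return out


def median_oracle(img, k):
    """Sliding-window median with edge-inclusive reflect padding, then
    nonzero binarize."""
    pad = k // 2
    padded = np.pad(img, pad, mode="symmetric")
    H, W = img.shape
    out = np.zeros((H, W), dtype=img.dtype)
    for r in range(H):
        for c in range(W):
            window = sorted(padded[r : r + k, c : c + k].ravel().tolist())
            out[r, c] = window[len(window) // 2]
    return out > 0


def _neighbors(conn):
    if conn == 4:
        return ((1, 0), (-1, 0), (0, 1), (0, -1))
    return tuple(
        (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
    )


def label_oracle(mask, conn=8):
    """BFS labeling; returns (labels, count)."""
    H, W = mask.shape
    labels = np.zeros((H, W), dtype=int)
    count = 0
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and labels[r0, c0] == 0:
                count += 1
                labels[r0, c0] = count
                queue = deque([(r0, c0)])
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in _neighbors(conn):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < H
                            and 0 <= cc < W
                            and mask[rr, cc]
                            and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = count
                            queue.append((rr, cc))
    return labels, count


def region_grow_oracle(mask, seed, conn=8):
    labels, _ = label_oracle(mask, conn)
    return labels == labels[seed[0], seed[1]]


def confusion_oracle(pred, gt):
    tp = fp = fn = tn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            p, g = bool(pred[r, c]), bool(gt[r, c])
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and g:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def mpa_oracle(pred, gt):
    tp, fp, fn, tn = confusion_oracle(pred, gt)
    brain = tp / (tp + fn) if tp + fn else 1.0
    bg = tn / (tn + fp) if tn + fp else 1.0
    return (brain + bg) / 2


def miou_oracle(pred, gt):
    tp, fp, fn, tn = confusion_oracle(pred, gt)
    brain = tp / (tp + fp + fn) if tp + fp + fn else 1.0
    bg = tn / (tn + fn + fp) if tn + fn + fp else 1.0
    return (brain + bg) / 2


def boundary_oracle(mask):
    """Foreground pixels 8-adjacent to background or to the image border."""
    H, W = mask.shape
    out = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            edge = False
            for dr, dc in _neighbors(8):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < H and 0 <= cc < W) or not mask[rr, cc]:
                    edge = True
                    break
            out[r, c] = edge
    return out


def bf_oracle(pred, gt, theta):
    """O(B^2) pairwise-distance boundary F1 for the foreground class."""
    pb = np.argwhere(boundary_oracle(pred))
    gb = np.argwhere(boundary_oracle(gt))
    if len(pb) == 0 and len(gb) == 0:
        return 1.0
    if (len(pb) == 0) != (len(gb) == 0):
        return 0.0
    d = np.sqrt(
        ((pb[:, None, :] - gb[None, :, :]) ** 2).sum(axis=2).astype(float)
    )
    precision = float((d.min(axis=1) <= theta).mean())
    recall = float((d.min(axis=0) <= theta).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def fill_fraction_oracle(S_i, S_e1):
    return Fraction(S_i - S_e1, S_i)


def disk_offsets(radius):
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def closing_oracle(mask, radius):
    """Dilate then erode with a disk, border treated as background for the
    dilation and foreground for the erosion."""
    H, W = mask.shape
    offs = disk_offsets(radius)
    dil = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            if mask[r, c]:
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W:
                        dil[rr, cc] = True
    out = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            keep = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and not dil[rr, cc]:
                    keep = False
                    break
            out[r, c] = keep
    return out
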