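"""Whole-slide inference: tiling, cross-tile merging and slide scoring.

A slide is covered by overlapping tiles (default overlap at least one cell
diameter), each tile runs through the detector, detections are shifted to
slide coordinates and de-duplicated with class-agnostic greedy NMS, and the
surviving detections feed the hemosiderin scoring plus a per-tile score map
for visual review.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotations import GradeCounts
from .detector import Detection, box_iou_matrix
from .scoring import SlideScore

DEFAULT_OVERLAP = 128


@dataclass
class TilingPlan:
    patch: int
    overlap: int
    origins: list[tuple[int, int]]
    nx: int
    ny: int


def plan_tiles(width: int, height: int, patch: int = 1024,
               overlap: int = DEFAULT_OVERLAP) -> TilingPlan:
    """Full-coverage tile origins; the final tile per axis is clamped inside."""
    if patch > width or patch > height:
        raise ValueError("patch larger than slide")
    if not 0 <= overlap < patch:
        raise ValueError("overlap must satisfy 0 <= overlap < patch")
    stride = patch - overlap

    def axis_origins(extent: int) -> list[int]:
        n = int(np.ceil((extent - patch) / stride)) + 1
        xs = [min(i * stride, extent - patch) for i in range(n)]
        return xs

    xs = axis_origins(width)
    ys = axis_origins(height)
    origins = [(x, y) for y in ys for x in xs]
    return TilingPlan(patch, overlap, origins, nx=len(xs), ny=len(ys))


def iou(box_a: tuple, box_b: tuple) -> float:
    """IoU of two corner-form boxes (x, y, w, h)."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("box sizes must be positive")
    iw = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    ih = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def merge_detections(detections: list[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Class-agnostic greedy non-maximum suppression by descending confidence.

    Ties in confidence break by input order (stable).  Kept detections
    retain their class posterior and continuous cell score.
    """
    if not detections:
        return []
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    boxes = np.array([detections[i].box for i in order], dtype=float)
    centers = boxes.copy()
    centers[:, 0] += centers[:, 2] / 2
    centers[:, 1] += centers[:, 3] / 2
    iou_mat = box_iou_matrix(centers, centers)
    keep: list[int] = []
    suppressed = np.zeros(len(order), dtype=bool)
    for i in range(len(order)):
        if suppressed[i]:
            continue
        keep.append(order[i])
        suppressed |= iou_mat[i] > iou_threshold
        suppressed[i] = True
    return [detections[i] for i in sorted(keep)]


def _shift(det: Detection, dx: float, dy: float) -> Detection:
    x, y, w, h = det.box
    return replace(det, box=(x + dx, y + dy, w, h))


def predict_slide(image, model, tiling: TilingPlan | None = None,
                  nms_iou: float = 0.5, conf_threshold: float = 0.5,
                  overlap: int | None = None):
    """Tile-wise detection over a slide.

    ``image`` is either an (H, W, 3) array or a callable
    ``(x, y, size) -> tile`` for slides too large to hold in memory; only
    one tile's pixels are materialised at a time in the callable case.
    Returns ``(detections, SlideScore or None, score_map)`` where the score
    map holds each tile's mean predicted grade (NaN for empty tiles).  The
    slide grade of a detection is its argmax class.
    """
    if callable(image):
        read_tile = image
        if tiling is None:
            raise ValueError("a TilingPlan is required with a tile reader")
    else:
        h, w = image.shape[:2]
        if tiling is None:
            patch = model.config.patch_size
            ov = DEFAULT_OVERLAP if overlap is None else overlap
            tiling = plan_tiles(w, h, patch, min(ov, patch - 1))

        def read_tile(x: int, y: int, size: int):
            return np.ascontiguousarray(image[y:y + size, x:x + size])

    all_dets: list[Detection] = []
    score_map = np.full((tiling.ny, tiling.nx), np.nan)
    bad_tiles = []
    for t, (x, y) in enumerate(tiling.origins):
        try:
            tile = read_tile(x, y, tiling.patch)
        except Exception:
            bad_tiles.append((x, y))
            continue
        dets = model.predict_patch(tile, conf_threshold=conf_threshold)
        if dets:
            score_map[t // tiling.nx, t % tiling.nx] = float(
                np.mean([d.grade_class for d in dets])
            )
        all_dets.extend(_shift(d, x, y) for d in dets)
    if bad_tiles:
        raise IOError(f"unreadable tiles at origins {bad_tiles}")

    merged = merge_detections(all_dets, iou_threshold=nms_iou)
    if merged:
        n = [0] * 5
        for d in merged:
            n[d.grade_class] += 1
        score = SlideScore.from_counts(GradeCounts(*n))
    else:
        score = None  # no detections: slide score undefined
    return merged, score, score_map
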