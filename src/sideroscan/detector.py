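"""Single-level anchor-based hemosiderophage detector.

A RetinaNet-style network restricted to one feature-pyramid level: a small
residual-free convolutional backbone downsamples the input patch to a
single stride-``feature_stride`` feature map on which four heads operate —

* a classification head (five grades + background, focal loss),
* a box-regression head (center-offset / log-size coding, smooth-L1),
* a per-anchor cell-score regression head (scaled sigmoid to [-0.5, 4.5],
  MSE against the matched cell's grade), and
* a patch-score regression head on globally pooled backbone features (MSE
  against the mean grade of the cells in the patch; 0 for empty patches).

The training loss is the sum of the four terms.  Anchors are square by
default (cells are round); cells are matched to anchors by IoU with
positive/negative thresholds plus a best-anchor force match so that small
cells off the anchor grid still receive a positive.  Training uses Adam and
geometric augmentation only (rotations and flips) — intensity augmentation
is rejected outright, because shifting staining intensity would change the
apparent hemosiderin content and hence the grade label itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .annotations import CellAnnotation

GEOMETRIC_AUGMENTATIONS = ("rotate90", "hflip", "vflip")
_FORBIDDEN_AUGMENTATIONS = ("intensity", "brightness", "contrast", "hue",
                            "saturation", "gamma", "noise")

SCALED_SIGMOID_MIN = -0.5
SCALED_SIGMOID_MAX = 4.5


def scaled_sigmoid(z):
    """5*sigmoid(z) - 0.5: continuous grade score in (-0.5, 4.5)."""
    return 5.0 * nn.sigmoid(z) - 0.5


def scaled_sigmoid_grad(z):
    s = nn.sigmoid(z)
    return 5.0 * s * (1.0 - s)


def focal_loss(p_t, alpha_t: float, gamma: float, clamp: float = 1e-12):
    """-alpha_t * (1 - p_t)^gamma * log(p_t), elementwise.

    ``p_t`` is the predicted probability of the true class.  Values are
    clamped at ``clamp`` before the log; non-positive inputs are a domain
    error.
    """
    p = np.asarray(p_t, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError("focal loss undefined for p_t <= 0")
    p = np.clip(p, clamp, 1.0)
    out = -alpha_t * (1.0 - p) ** gamma * np.log(p)
    return float(out) if np.isscalar(p_t) else out


def smooth_l1(x, y):
    """Huber-style smooth L1: 0.5 d^2 for |d| < 1 else |d| - 0.5."""
    d = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float))
    out = np.where(d < 1.0, 0.5 * d * d, d - 0.5)
    return float(out) if out.ndim == 0 else out


def smooth_l1_grad(x, y):
    return np.clip(np.asarray(x, dtype=float) - np.asarray(y, dtype=float), -1.0, 1.0)


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture, matching, loss and schedule parameters.

    ``backbone_channels`` lists the output channels of the stride-2 stages;
    their count must equal log2(feature_stride) so the map is exactly the
    single stride-``feature_stride`` level.
    """

    backbone_channels: tuple = (16, 32, 64, 128, 256)
    feature_stride: int = 32
    patch_size: int = 1024
    anchor_sizes: tuple = (64, 96, 128)
    anchor_aspect_ratios: tuple = (1.0,)
    n_classes: int = 6  # five grades + background
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    match_iou_pos: float = 0.5
    match_iou_neg: float = 0.4
    force_match: bool = True
    head_channels: int = 64
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    augmentations: tuple = GEOMETRIC_AUGMENTATIONS
    box_weight: float = 1.0
    cell_score_weight: float = 1.0
    patch_score_weight: float = 1.0

    def __post_init__(self) -> None:
        stages = int(round(math.log2(self.feature_stride)))
        if 2 ** stages != self.feature_stride:
            raise ValueError("feature_stride must be a power of two")
        if len(self.backbone_channels) != stages:
            raise ValueError(
                f"{len(self.backbone_channels)} backbone stages cannot produce "
                f"stride {self.feature_stride}; need {stages}"
            )
        if self.patch_size % self.feature_stride:
            raise ValueError("feature_stride must divide patch_size")
        if not 0.0 < self.focal_alpha < 1.0:
            raise ValueError("focal_alpha must lie in (0, 1)")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.match_iou_pos < self.match_iou_neg:
            raise ValueError("match_iou_pos must be >= match_iou_neg")
        for aug in self.augmentations:
            if aug in _FORBIDDEN_AUGMENTATIONS:
                raise ValueError(
                    f"augmentation {aug!r} alters staining intensity and would "
                    f"change cell grades; only geometric augmentation is allowed"
                )
            if aug not in GEOMETRIC_AUGMENTATIONS:
                raise ValueError(f"unknown augmentation {aug!r}")

    @property
    def anchors_per_position(self) -> int:
        return len(self.anchor_sizes) * len(self.anchor_aspect_ratios)


def tiny_preset(**overrides) -> DetectorConfig:
    """Desk-scale preset: 128 px patches, stride 16, small cells/anchors."""
    base = dict(
        backbone_channels=(8, 16, 32, 64),
        feature_stride=16,
        patch_size=128,
        anchor_sizes=(44, 52, 60),
        head_channels=32,
        batch_size=8,
        epochs=60,
        box_weight=2.0,
    )
    base.update(overrides)
    return DetectorConfig(**base)


@dataclass
class LossTerms:
    """The four components of the composite training loss."""

    focal: float
    box: float
    cell_score_mse: float
    patch_score_mse: float

    @property
    def total(self) -> float:
        return self.focal + self.box + self.cell_score_mse + self.patch_score_mse


@dataclass
class Detection:
    """One predicted cell: corner-form box, grade and scores."""

    box: tuple  # (x, y, w, h), corner form
    grade_class: int
    class_posterior: np.ndarray  # 5 grade probabilities
    cell_score: float
    confidence: float


# ---------------------------------------------------------------------------
# geometry: anchors, IoU, matching, box coding (center form cx, cy, w, h)


def generate_anchors(config: DetectorConfig, patch_size: int | None = None) -> np.ndarray:
    """(A, 4) center-form anchors over the stride grid, row-major.

    Centers form an fmap-sized grid with spacing ``feature_stride`` offset
    by half a stride; per position one anchor per (size x aspect ratio).
    """
    patch = patch_size or config.patch_size
    s = config.feature_stride
    if patch % s:
        raise ValueError("feature_stride must divide the patch size")
    nmap = patch // s
    centers = s / 2.0 + s * np.arange(nmap)
    shapes = []
    for size in config.anchor_sizes:
        for ratio in config.anchor_aspect_ratios:
            shapes.append((size * math.sqrt(ratio), size / math.sqrt(ratio)))
    anchors = np.empty((nmap, nmap, len(shapes), 4), dtype=float)
    anchors[..., 0] = centers[None, :, None]  # cx varies along columns
    anchors[..., 1] = centers[:, None, None]  # cy varies along rows
    for i, (w, h) in enumerate(shapes):
        anchors[:, :, i, 2] = w
        anchors[:, :, i, 3] = h
    return anchors.reshape(-1, 4)


def _center_to_corner(boxes: np.ndarray) -> np.ndarray:
    out = boxes.astype(float).copy()
    out[:, 0] -= out[:, 2] / 2
    out[:, 1] -= out[:, 3] / 2
    return out


def box_iou_matrix(a_center: np.ndarray, b_center: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two center-form box sets: (len(a), len(b))."""
    if len(a_center) == 0 or len(b_center) == 0:
        return np.zeros((len(a_center), len(b_center)))
    a = _center_to_corner(np.atleast_2d(a_center))
    b = _center_to_corner(np.atleast_2d(b_center))
    ax0, ay0 = a[:, 0:1], a[:, 1:2]
    ax1, ay1 = ax0 + a[:, 2:3], ay0 + a[:, 3:4]
    bx0, by0 = b[None, :, 0], b[None, :, 1]
    bx1, by1 = bx0 + b[None, :, 2], by0 + b[None, :, 3]
    iw = np.clip(np.minimum(ax1, bx1) - np.maximum(ax0, bx0), 0, None)
    ih = np.clip(np.minimum(ay1, by1) - np.maximum(ay0, by0), 0, None)
    inter = iw * ih
    union = (a[:, 2:3] * a[:, 3:4]) + (b[None, :, 2] * b[None, :, 3]) - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


IGNORED = -2
NEGATIVE = -1


def match_anchors(anchors: np.ndarray, truth_boxes: np.ndarray,
                  iou_pos: float = 0.5, iou_neg: float = 0.4,
                  force_match: bool = True) -> np.ndarray:
    """Assign each anchor a truth index, NEGATIVE (-1), or IGNORED (-2).

    An anchor is positive for its max-IoU truth when that IoU >= iou_pos,
    negative below iou_neg, ignored in between.  With ``force_match`` each
    truth additionally claims its single best-IoU anchor (if IoU > 0), so
    no annotated cell goes unsupervised.
    """
    if iou_pos < iou_neg:
        raise ValueError("iou_pos must be >= iou_neg")
    n = len(anchors)
    if len(truth_boxes) == 0:
        return np.full(n, NEGATIVE, dtype=int)
    iou = box_iou_matrix(anchors, truth_boxes)
    best_truth = iou.argmax(axis=1)
    best_iou = iou[np.arange(n), best_truth]
    assign = np.full(n, IGNORED, dtype=int)
    assign[best_iou < iou_neg] = NEGATIVE
    pos = best_iou >= iou_pos
    assign[pos] = best_truth[pos]
    if force_match:
        best_anchor = iou.argmax(axis=0)
        for t, a in enumerate(best_anchor):
            if iou[a, t] > 0.0:
                assign[a] = t
    return assign


def encode_boxes(anchors: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Center-offset / log-size offsets of center-form boxes vs anchors."""
    anchors = np.atleast_2d(anchors).astype(float)
    boxes = np.atleast_2d(boxes).astype(float)
    if np.any(boxes[:, 2:] <= 0) or np.any(anchors[:, 2:] <= 0):
        raise ValueError("box and anchor sizes must be positive")
    t = np.empty_like(boxes)
    t[:, 0] = (boxes[:, 0] - anchors[:, 0]) / anchors[:, 2]
    t[:, 1] = (boxes[:, 1] - anchors[:, 1]) / anchors[:, 3]
    t[:, 2] = np.log(boxes[:, 2] / anchors[:, 2])
    t[:, 3] = np.log(boxes[:, 3] / anchors[:, 3])
    return t


def decode_boxes(anchors: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    anchors = np.atleast_2d(anchors).astype(float)
    offsets = np.atleast_2d(offsets).astype(float)
    b = np.empty_like(offsets)
    b[:, 0] = anchors[:, 0] + offsets[:, 0] * anchors[:, 2]
    b[:, 1] = anchors[:, 1] + offsets[:, 1] * anchors[:, 3]
    b[:, 2] = anchors[:, 2] * np.exp(np.clip(offsets[:, 2], -8, 8))
    b[:, 3] = anchors[:, 3] * np.exp(np.clip(offsets[:, 3], -8, 8))
    return b


# ---------------------------------------------------------------------------
# network


class RetinaNetDetector:
    """Backbone + single stride level + four heads (see module docstring)."""

    BACKGROUND = 5

    def __init__(self, config: DetectorConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        blocks = []
        cin = 3
        for cout in config.backbone_channels:
            blocks.append(nn.conv_block(cin, cout, stride=2, rng=rng))
            cin = cout
        self.backbone = nn.Sequential(*blocks)
        a = config.anchors_per_position
        c = config.head_channels
        self.trunk = nn.Sequential(nn.Conv2d(cin, c, 3, rng=rng), nn.ReLU())
        self.cls_head = nn.Conv2d(c, a * config.n_classes, 1, pad=0, rng=rng)
        self.box_head = nn.Conv2d(c, a * 4, 1, pad=0, rng=rng)
        self.score_head = nn.Conv2d(c, a, 1, pad=0, rng=rng)
        self.patch_pool = nn.GlobalAvgPool2d()
        self.patch_head = nn.Sequential(nn.Linear(cin, 32, rng=rng), nn.ReLU(),
                                        nn.Linear(32, 1, rng=rng))
        # bias the classification head towards background so early training
        # is not swamped by false positives (the focal-loss prior trick)
        bias = self.cls_head.b.value.reshape(a, config.n_classes)
        bias[:, self.BACKGROUND] = math.log((1 - 0.01) / 0.01 * (config.n_classes - 1))
        self._anchors = generate_anchors(config)

    @property
    def anchors(self) -> np.ndarray:
        return self._anchors

    def params(self) -> list[nn.Param]:
        return (self.backbone.params() + self.trunk.params()
                + self.cls_head.params() + self.box_head.params()
                + self.score_head.params() + self.patch_head.params())

    def train(self, mode: bool = True) -> "RetinaNetDetector":
        for m in (self.backbone, self.trunk, self.cls_head, self.box_head,
                  self.score_head, self.patch_head):
            m.train(mode)
        return self

    def forward(self, images: np.ndarray) -> dict:
        """images: (N, H, W, 3) uint8/float -> raw head outputs per anchor."""
        x = np.ascontiguousarray(
            images.astype(np.float32) / 255.0 - 0.5
        ).transpose(0, 3, 1, 2)
        feats = self.backbone.forward(x)
        trunk = self.trunk.forward(feats)
        n = x.shape[0]
        ncls = self.config.n_classes
        a = self.config.anchors_per_position

        def to_anchor_major(t: np.ndarray, per: int) -> np.ndarray:
            # (N, a*per, Hf, Wf) -> (N, Hf*Wf*a, per): row-major grid, then
            # anchor shape index, matching generate_anchors ordering
            nb, _, hf, wf = t.shape
            return np.ascontiguousarray(
                t.reshape(nb, a, per, hf, wf).transpose(0, 3, 4, 1, 2)
            ).reshape(nb, hf * wf * a, per)

        cls = to_anchor_major(self.cls_head.forward(trunk), ncls)
        box = to_anchor_major(self.box_head.forward(trunk), 4)
        score = to_anchor_major(self.score_head.forward(trunk), 1)[..., 0]
        pooled = self.patch_pool.forward(feats)
        patch_z = self.patch_head.forward(pooled)[:, 0]
        self._fmap_shape = trunk.shape
        return {"cls_logits": cls, "box_offsets": box, "cell_score_z": score,
                "patch_score_z": patch_z}

    def backward(self, grads: dict) -> None:
        n, c, hf, wf = self._fmap_shape
        a = self.config.anchors_per_position
        ncls = self.config.n_classes

        def from_anchor_major(g: np.ndarray, per: int) -> np.ndarray:
            return np.ascontiguousarray(
                g.reshape(n, hf, wf, a, per).transpose(0, 3, 4, 1, 2)
            ).reshape(n, a * per, hf, wf).astype(np.float32)

        dtrunk = self.cls_head.backward(from_anchor_major(grads["cls_logits"], ncls))
        dtrunk = dtrunk + self.box_head.backward(from_anchor_major(grads["box_offsets"], 4))
        dtrunk = dtrunk + self.score_head.backward(
            from_anchor_major(grads["cell_score_z"][..., None], 1)
        )
        dfeats = self.trunk.backward(dtrunk)
        dpooled = self.patch_head.backward(
            grads["patch_score_z"][:, None].astype(np.float32)
        )
        dfeats = dfeats + self.patch_pool.backward(dpooled)
        self.backbone.backward(dfeats)

    def _modules(self):
        return (self.backbone, self.trunk, self.cls_head, self.box_head,
                self.score_head, self.patch_head)

    def buffers(self) -> list[np.ndarray]:
        out = []
        for m in self._modules():
            out.extend(m.buffers())
        return out

    def save(self, path) -> None:
        """Self-describing checkpoint: config JSON + all weights/buffers."""
        import json

        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        arrays.update({f"b{i}": b for i, b in enumerate(self.buffers())})
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.config.__dict__.items()}
        np.savez(path, __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "RetinaNetDetector":
        import json

        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["__config__"]))
        for key in ("backbone_channels", "anchor_sizes", "anchor_aspect_ratios",
                    "augmentations"):
            cfg[key] = tuple(cfg[key])
        model = cls(DetectorConfig(**cfg))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for i, b in enumerate(model.buffers()):
            b[...] = data[f"b{i}"]
        return model

    # -- inference ---------------------------------------------------------

    def predict_patch(self, image: np.ndarray, conf_threshold: float = 0.5) -> list[Detection]:
        """Detections above threshold on one patch (no NMS here)."""
        self.train(False)
        out = self.forward(image[None])
        probs = nn.softmax(out["cls_logits"][0], axis=-1)
        posterior = probs[:, :5]
        conf = posterior.max(axis=1)
        keep = np.nonzero(conf > conf_threshold)[0]
        boxes = decode_boxes(self._anchors[keep], out["box_offsets"][0][keep]) \
            if keep.size else np.zeros((0, 4))
        scores = scaled_sigmoid(out["cell_score_z"][0][keep]) if keep.size else []
        detections = []
        for i, idx in enumerate(keep):
            x, y, w, h = _center_to_corner(boxes[i:i + 1])[0]
            detections.append(Detection(
                box=(float(x), float(y), float(w), float(h)),
                grade_class=int(posterior[idx].argmax()),
                class_posterior=posterior[idx].copy(),
                cell_score=float(scores[i]),
                confidence=float(conf[idx]),
            ))
        return detections

    def predict_patch_score(self, image: np.ndarray) -> float:
        """Standalone patch-level grade regression (the deep patch head)."""
        self.train(False)
        out = self.forward(image[None])
        return float(scaled_sigmoid(out["patch_score_z"][0]))


# ---------------------------------------------------------------------------
# loss


@dataclass
class PatchTarget:
    """Ground truth for one training patch: cell boxes + grades."""

    boxes: np.ndarray  # (M, 4) center form
    grades: np.ndarray  # (M,) int

    @classmethod
    def from_cells(cls, cells: Sequence[CellAnnotation]) -> "PatchTarget":
        if not cells:
            return cls(np.zeros((0, 4)), np.zeros(0, dtype=int))
        boxes = np.array([[c.cx, c.cy, c.w, c.h] for c in cells], dtype=float)
        grades = np.array([c.grade for c in cells], dtype=int)
        return cls(boxes, grades)

    @property
    def mean_grade(self) -> float:
        return float(self.grades.mean()) if len(self.grades) else 0.0


def total_loss(targets: Sequence[PatchTarget], predictions: dict,
               config: DetectorConfig, anchors: np.ndarray | None = None,
               return_grads: bool = False):
    """Composite four-term training loss over a batch; optionally its gradients.

    Focal term: mean over all non-ignored anchors of the focal loss of the
    true class (background for negatives) under a 6-way softmax.  Box term:
    mean smooth-L1 over positive-anchor offset components.  Cell-score
    term: MSE between matched anchors' scaled-sigmoid score and the matched
    cell's grade.  Patch-score term: MSE between the patch head's score and
    the patch's mean grade (0 for empty patches).  Batches with no positive
    anchors report 0 for the box and cell terms.
    """
    if anchors is None:
        anchors = generate_anchors(config)
    cls_logits = predictions["cls_logits"]
    box_offsets = predictions["box_offsets"]
    cell_z = predictions["cell_score_z"]
    patch_z = predictions["patch_score_z"]
    n_img, n_anchor, ncls = cls_logits.shape
    bg = ncls - 1

    d_cls = np.zeros_like(cls_logits)
    d_box = np.zeros_like(box_offsets)
    d_cell = np.zeros_like(cell_z)
    d_patch = np.zeros_like(patch_z)

    focal_sum = 0.0
    n_focal = 0
    box_sum = 0.0
    n_box = 0
    cell_sum = 0.0
    n_cell = 0
    patch_sum = 0.0

    alpha, gamma = config.focal_alpha, config.focal_gamma
    per_image = []
    for i, target in enumerate(targets):
        assign = match_anchors(anchors, target.boxes, config.match_iou_pos,
                               config.match_iou_neg, config.force_match)
        included = assign != IGNORED
        per_image.append((assign, included))
        n_focal += int(included.sum())
        n_box += 4 * int((assign >= 0).sum())
        n_cell += int((assign >= 0).sum())
    n_focal = max(n_focal, 1)
    n_box_div = max(n_box, 1)
    n_cell_div = max(n_cell, 1)

    for i, target in enumerate(targets):
        assign, included = per_image[i]
        if len(target.grades):
            labels = np.where(assign >= 0, target.grades[np.maximum(assign, 0)], bg)
        else:
            labels = np.full(n_anchor, bg)
        probs = nn.softmax(cls_logits[i], axis=-1)
        p_t = np.clip(probs[np.arange(n_anchor), labels], 1e-12, 1.0)
        fl = -alpha * (1.0 - p_t) ** gamma * np.log(p_t)
        focal_sum += float(fl[included].sum())
        # d focal / d logits
        one_minus = 1.0 - p_t
        dfl_dpt = alpha * (gamma * np.where(one_minus > 0,
                                            one_minus ** np.maximum(gamma - 1, 0),
                                            0.0) * np.log(p_t)
                           - one_minus ** gamma / p_t)
        onehot = np.zeros_like(probs)
        onehot[np.arange(n_anchor), labels] = 1.0
        dpt_dlogit = p_t[:, None] * (onehot - probs)
        dcls = dfl_dpt[:, None] * dpt_dlogit
        dcls[~included] = 0.0
        d_cls[i] = dcls / n_focal

        pos = np.nonzero(assign >= 0)[0]
        if pos.size:
            t_true = encode_boxes(anchors[pos], target.boxes[assign[pos]])
            t_pred = box_offsets[i][pos]
            box_sum += float(smooth_l1(t_pred, t_true).sum())
            d_box[i][pos] = smooth_l1_grad(t_pred, t_true) / n_box_div

            z = cell_z[i][pos]
            s = scaled_sigmoid(z)
            g = target.grades[assign[pos]].astype(float)
            cell_sum += float(((s - g) ** 2).sum())
            d_cell[i][pos] = 2.0 * (s - g) * scaled_sigmoid_grad(z) / n_cell_div

        ps = scaled_sigmoid(patch_z[i])
        pg = target.mean_grade
        patch_sum += (ps - pg) ** 2
        d_patch[i] = 2.0 * (ps - pg) * scaled_sigmoid_grad(patch_z[i]) / n_img

    terms = LossTerms(
        focal=focal_sum / n_focal,
        box=config.box_weight * box_sum / n_box_div,
        cell_score_mse=config.cell_score_weight * cell_sum / n_cell_div,
        patch_score_mse=config.patch_score_weight * patch_sum / n_img,
    )
    if not return_grads:
        return terms
    grads = {
        "cls_logits": d_cls,
        "box_offsets": config.box_weight * d_box,
        "cell_score_z": config.cell_score_weight * d_cell,
        "patch_score_z": config.patch_score_weight * d_patch,
    }
    return terms, grads


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingPatch:
    """A pixel patch with its contained cells (patch coordinates)."""

    image: np.ndarray  # (size, size, 3) uint8
    cells: list[CellAnnotation]


def extract_training_patch(slide_image: np.ndarray, sample) -> TrainingPatch:
    """Crop the pixels for a sampling.PatchSample from the slide image."""
    crop = slide_image[sample.y:sample.y + sample.size,
                       sample.x:sample.x + sample.size]
    return TrainingPatch(np.ascontiguousarray(crop), list(sample.cells))


def _augment(patch: TrainingPatch, config: DetectorConfig,
             rng: np.random.Generator) -> TrainingPatch:
    img = patch.image
    size = img.shape[0]
    cells = [(c.cx, c.cy, c.w, c.h, c.grade, c.slide_id) for c in patch.cells]
    if "rotate90" in config.augmentations:
        k = int(rng.integers(0, 4))
        for _ in range(k):
            img = np.rot90(img)  # (x, y) -> (y, size - 1 - x)
            cells = [(cy, size - 1 - cx, ch, cw, g, sid)
                     for cx, cy, cw, ch, g, sid in cells]
    if "hflip" in config.augmentations and rng.integers(0, 2):
        img = img[:, ::-1]
        cells = [(size - 1 - cx, cy, cw, ch, g, sid)
                 for cx, cy, cw, ch, g, sid in cells]
    if "vflip" in config.augmentations and rng.integers(0, 2):
        img = img[::-1]
        cells = [(cx, size - 1 - cy, cw, ch, g, sid)
                 for cx, cy, cw, ch, g, sid in cells]
    return TrainingPatch(
        np.ascontiguousarray(img),
        [CellAnnotation(sid, cx, cy, cw, ch, g)
         for cx, cy, cw, ch, g, sid in cells],
    )


def train_detector(patches: Sequence[TrainingPatch], config: DetectorConfig,
                   model: RetinaNetDetector | None = None,
                   augment: bool = True,
                   callback=None) -> tuple[RetinaNetDetector, list[LossTerms]]:
    """Train on a fixed patch set; returns the model and per-epoch losses.

    Deterministic given the config seed.  Raises on non-finite loss.
    """
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = RetinaNetDetector(config, rng=np.random.default_rng(config.seed + 1))
    optimizer = nn.Adam(model.params(), lr=config.lr)
    anchors = model.anchors
    history: list[LossTerms] = []
    order = np.arange(len(patches))
    for epoch in range(config.epochs):
        model.train(True)
        rng.shuffle(order)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [patches[j] for j in idx]
            if augment:
                batch = [_augment(p, config, rng) for p in batch]
            images = np.stack([p.image for p in batch])
            targets = [PatchTarget.from_cells(p.cells) for p in batch]
            preds = model.forward(images)
            terms, grads = total_loss(targets, preds, config, anchors,
                                      return_grads=True)
            if not np.isfinite(terms.total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={terms.total}"
                )
            optimizer.zero_grad()
            model.backward(grads)
            optimizer.step()
            sums += (terms.focal, terms.box, terms.cell_score_mse,
                     terms.patch_score_mse)
            n_batches += 1
        epoch_terms = LossTerms(*(sums / max(n_batches, 1)))
        history.append(epoch_terms)
        if callback is not None:
            callback(epoch, epoch_terms)
    return model, history
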