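"""Single-cell grading of pre-localized hemosiderophage crops.

Two formulations of the same task: a 5-way softmax classifier mirroring the
discrete Golde grades, and a regressor with a scaled sigmoid output in
[-0.5, 4.5] acknowledging that hemosiderin uptake is continuous.  Both
share a small convolutional feature extractor and a two-layer head and are
trained in two stages with Adam under a maximal-learning-rate (cosine)
schedule: first only the head (the extractor frozen), then the whole
network fine-tunes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .annotations import CellAnnotation
from .detector import scaled_sigmoid, scaled_sigmoid_grad


@dataclass
class CellCrop:
    """Square RGB crop centered on one cell, with optional true grade."""

    image: np.ndarray
    true_grade: int | None = None

    def __post_init__(self) -> None:
        if self.image.size == 0:
            raise ValueError("empty crop")


@dataclass(frozen=True)
class CellModelConfig:
    crop_side: int = 128
    input_side: int = 32  # crops are resized to this before the network
    channels: tuple = (8, 16, 32)
    head_hidden: int = 32
    max_lr: float = 0.01
    head_epochs: int = 3
    finetune_epochs: int = 20
    batch_size: int = 32
    seed: int = 0


def extract_crop(image: np.ndarray, cell: CellAnnotation, side: int = 128) -> CellCrop:
    """Square crop centered on the cell, edge-padded at slide borders."""
    h, w = image.shape[:2]
    half = side // 2
    cy, cx = int(round(cell.cy)), int(round(cell.cx))
    y0, y1 = cy - half, cy - half + side
    x0, x1 = cx - half, cx - half + side
    pad_y = (max(0, -y0), max(0, y1 - h))
    pad_x = (max(0, -x0), max(0, x1 - w))
    crop = image[max(y0, 0):min(y1, h), max(x0, 0):min(x1, w)]
    if any(pad_y) or any(pad_x):
        crop = np.pad(crop, (pad_y, pad_x, (0, 0)), mode="edge")
    return CellCrop(np.ascontiguousarray(crop), cell.grade)


class _CellNet:
    """Shared feature extractor + two-layer head (n_out logits)."""

    def __init__(self, config: CellModelConfig, n_out: int,
                 rng: np.random.Generator):
        blocks = []
        cin = 3
        for cout in config.channels:
            blocks.append(nn.conv_block(cin, cout, stride=2, rng=rng))
            cin = cout
        self.features = nn.Sequential(*blocks, nn.GlobalAvgPool2d())
        self.head = nn.Sequential(nn.Linear(cin, config.head_hidden, rng=rng),
                                  nn.ReLU(), nn.Linear(config.head_hidden, n_out, rng=rng))
        self.config = config

    def train(self, mode: bool) -> None:
        self.features.train(mode)
        self.head.train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.features.forward(x))

    def backward(self, dout: np.ndarray, head_only: bool) -> None:
        dfeat = self.head.backward(dout)
        if not head_only:
            self.features.backward(dfeat)


def _prepare(crops: list[CellCrop], config: CellModelConfig) -> np.ndarray:
    side = config.input_side
    out = np.empty((len(crops), 3, side, side), dtype=np.float32)
    for i, crop in enumerate(crops):
        img = crop.image
        if img.shape[0] != side or img.shape[1] != side:
            img = resize(img, (side, side), preserve_range=True,
                         anti_aliasing=True)
        out[i] = (img.astype(np.float32) / 255.0 - 0.5).transpose(2, 0, 1)
    return out


def _check_classes(crops: list[CellCrop]) -> np.ndarray:
    grades = np.array([c.true_grade for c in crops])
    if any(g is None for g in grades):
        raise ValueError("all training crops need a true grade")
    if len(np.unique(grades)) < 2:
        raise ValueError("training requires at least 2 distinct grades")
    return grades.astype(int)


class CellGrader:
    """Trained single-cell model (classifier or regressor)."""

    def __init__(self, net: _CellNet, mode: str):
        self.net = net
        self.mode = mode

    def predict_scores(self, crops: list[CellCrop]) -> np.ndarray:
        """Posterior (n, 5) for classify mode; continuous score (n,) else."""
        self.net.train(False)
        x = _prepare(crops, self.net.config)
        out = []
        bs = self.net.config.batch_size
        for start in range(0, len(crops), bs):
            logits = self.net.forward(x[start:start + bs])
            if self.mode == "classify":
                out.append(nn.softmax(logits, axis=-1))
            else:
                out.append(scaled_sigmoid(logits[:, 0]))
        return np.concatenate(out)

    def predict_grades(self, crops: list[CellCrop]) -> np.ndarray:
        scores = self.predict_scores(crops)
        if self.mode == "classify":
            return scores.argmax(axis=1)
        return grade_from_score(scores)


def grade_from_score(score) -> np.ndarray:
    """Continuous score -> grade: round to nearest, clip to 0..4."""
    return np.clip(np.floor(np.asarray(score) + 0.5), 0, 4).astype(int)


def _train(crops: list[CellCrop], config: CellModelConfig, mode: str,
           rng_seed_offset: int = 0) -> tuple[CellGrader, list[float]]:
    grades = _check_classes(crops)
    rng = np.random.default_rng(config.seed + rng_seed_offset)
    n_out = 5 if mode == "classify" else 1
    net = _CellNet(config, n_out, rng=np.random.default_rng(config.seed + 7))
    x = _prepare(crops, config)
    y = grades

    history: list[float] = []
    order = np.arange(len(crops))

    def run_stage(epochs: int, head_only: bool) -> None:
        params = net.head.params() if head_only else (
            net.features.params() + net.head.params())
        optimizer = nn.Adam(params, lr=config.max_lr)
        for epoch in range(epochs):
            optimizer.lr = nn.cosine_lr(config.max_lr, epoch, epochs)
            net.train(True)
            rng.shuffle(order)
            total = 0.0
            nb = 0
            for start in range(0, len(order), config.batch_size):
                idx = order[start:start + config.batch_size]
                logits = net.forward(x[idx])
                if mode == "classify":
                    probs = nn.softmax(logits, axis=-1)
                    p_t = np.clip(probs[np.arange(len(idx)), y[idx]], 1e-12, 1)
                    loss = float(-np.log(p_t).mean())
                    dlogits = probs.copy()
                    dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                    dlogits /= len(idx)
                else:
                    z = logits[:, 0]
                    s = scaled_sigmoid(z)
                    diff = s - y[idx]
                    loss = float((diff ** 2).mean())
                    dlogits = (2.0 * diff * scaled_sigmoid_grad(z) / len(idx))[:, None]
                optimizer.zero_grad()
                net.backward(dlogits.astype(np.float32), head_only)
                optimizer.step()
                total += loss
                nb += 1
            history.append(total / max(nb, 1))

    # stage 1: head only, frozen features; stage 2: fine-tune everything
    run_stage(config.head_epochs, head_only=True)
    run_stage(config.finetune_epochs, head_only=False)
    return CellGrader(net, mode), history


def train_cell_classifier(crops: list[CellCrop],
                          config: CellModelConfig = CellModelConfig()
                          ) -> tuple[CellGrader, list[float]]:
    """5-way softmax grade classifier (categorical cross entropy)."""
    return _train(crops, config, "classify")


def train_cell_regressor(crops: list[CellCrop],
                         config: CellModelConfig = CellModelConfig()
                         ) -> tuple[CellGrader, list[float]]:
    """Continuous grade regressor, scaled sigmoid to [-0.5, 4.5], MSE loss."""
    return _train(crops, config, "regress")


def build_test_sets(pool: list[CellCrop], rng: np.random.Generator,
                    n_representative: int = 1000, per_grade: int = 200
                    ) -> tuple[list[CellCrop], list[CellCrop]]:
    """Representative and balanced single-cell test sets.

    Set 1 samples uniformly (without replacement) from the pool, keeping
    the pool's grade distribution; set 2 holds exactly ``per_grade`` cells
    of every grade.  Each set is internally free of duplicates.
    """
    if len(pool) < n_representative:
        raise ValueError(f"pool of {len(pool)} too small for a "
                         f"{n_representative}-cell representative set")
    by_grade: dict[int, list[int]] = {g: [] for g in range(5)}
    for i, crop in enumerate(pool):
        if crop.true_grade is None:
            raise ValueError("pool crops must carry true grades")
        by_grade[crop.true_grade].append(i)
    for g in range(5):
        if len(by_grade[g]) < per_grade:
            raise ValueError(
                f"grade {g} has only {len(by_grade[g])} cells; "
                f"{per_grade} needed for the balanced set"
            )
    rep_idx = rng.choice(len(pool), size=n_representative, replace=False)
    representative = [pool[i] for i in rep_idx]
    balanced = []
    for g in range(5):
        chosen = rng.choice(len(by_grade[g]), size=per_grade, replace=False)
        balanced.extend(pool[by_grade[g][j]] for j in chosen)
    return representative, balanced
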