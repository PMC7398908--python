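"""Synthetic stained-cytology slide generator with ground-truth graded cells.

Emulates iron-stained (Prussian/Turnbull blue) equine BALF cytospin
preparations: alveolar macrophages drawn as ellipses with a pale cytoplasm,
a light-red nucleus (nuclear fast red counterstain) and dark-blue
hemosiderin granules whose cytoplasmic area fraction increases with the
Golde grade.  Unannotated distractors — hair streaks and extracellular
pigment clumps — exercise false-positive behavior downstream.

The pigment of a grade-g cell covers ``pigment_fraction_per_grade[g]`` of
the cell ellipse (to within rasterization error): granule texture comes
from thresholding a smoothed noise field at the target quantile, which
pins the covered fraction exactly while keeping a blobby granular look.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import gaussian

from .annotations import CellAnnotation, SlideRecord

#: pooled per-grade proportions of the 17-slide reference data set
DEFAULT_GRADE_DISTRIBUTION = (
    29055 / 78047,
    26925 / 78047,
    13524 / 78047,
    7070 / 78047,
    1473 / 78047,
)

DEFAULT_PIGMENT_FRACTIONS = (0.0, 0.15, 0.40, 0.70, 0.95)

#: recover a grade from a measured pigment fraction: midpoints between the
#: default per-grade fractions
GRADE_THRESHOLDS = (0.075, 0.275, 0.55, 0.825)

# palette (RGB, uint8 ranges)
_BACKGROUND = np.array([245.0, 240.0, 242.0])
_CYTOPLASM = np.array([211.0, 201.0, 207.0])
_NUCLEUS = np.array([226.0, 158.0, 168.0])
_PIGMENT = np.array([32.0, 38.0, 118.0])
_HAIR = np.array([82.0, 68.0, 52.0])


class CapacityError(RuntimeError):
    """The requested cells could not be placed within the overlap budget."""


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic slide."""

    width: int = 2048
    height: int = 2048
    n_cells: int = 100
    grade_distribution: tuple = DEFAULT_GRADE_DISTRIBUTION
    cell_diameter_range: tuple = (60, 140)
    pigment_fraction_per_grade: tuple = DEFAULT_PIGMENT_FRACTIONS
    n_hair_artifacts: int = 2
    n_pigment_clumps: int = 3
    max_center_overlap: float = 0.15
    seed: int = 0
    slide_id: str = "synthetic"
    staining: str = "prussian"

    def __post_init__(self) -> None:
        if len(self.grade_distribution) != 5:
            raise ValueError("grade_distribution needs 5 probabilities")
        if abs(sum(self.grade_distribution) - 1.0) > 1e-9:
            raise ValueError("grade_distribution must sum to 1")
        fr = self.pigment_fraction_per_grade
        if len(fr) != 5 or any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("pigment fractions must be 5 strictly increasing values")
        if not all(0.0 <= f <= 1.0 for f in fr):
            raise ValueError("pigment fractions must lie in [0, 1]")
        lo, hi = self.cell_diameter_range
        if lo <= 0 or hi < lo:
            raise ValueError("cell diameters must be positive and ordered")


def _paint(img: np.ndarray, rr: np.ndarray, cc: np.ndarray, color: np.ndarray,
           rng: np.random.Generator, jitter: float = 5.0) -> None:
    noise = rng.normal(0.0, jitter, size=(rr.size, 3))
    img[rr, cc] = np.clip(color[None, :] + noise, 0, 255)


def _granule_mask(shape: tuple[int, int], inside: np.ndarray, fraction: float,
                  rng: np.random.Generator, blob_sigma: float) -> np.ndarray:
    """Boolean mask covering exactly `fraction` of `inside`, blob-textured."""
    if fraction <= 0.0 or not inside.any():
        return np.zeros(shape, dtype=bool)
    fld = gaussian(rng.normal(size=shape), sigma=blob_sigma, preserve_range=True)
    vals = fld[inside]
    thresh = np.quantile(vals, fraction)
    return inside & (fld <= thresh)


def _draw_cell(img: np.ndarray, cell: CellAnnotation, fraction: float,
               rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    a, b = cell.h / 2.0, cell.w / 2.0  # row/col half-axes
    rr, cc = draw_ellipse(cell.cy, cell.cx, a, b, shape=(h, w))
    _paint(img, rr, cc, _CYTOPLASM, rng)

    # nucleus: smaller offset ellipse, light red
    off_r = rng.uniform(-0.25, 0.25) * a
    off_c = rng.uniform(-0.25, 0.25) * b
    nr, nc = draw_ellipse(cell.cy + off_r, cell.cx + off_c, 0.42 * a, 0.42 * b,
                          shape=(h, w))
    _paint(img, nr, nc, _NUCLEUS, rng)

    if fraction > 0.0:
        # work on the local bounding window only
        r0, r1 = max(int(cell.cy - a) - 1, 0), min(int(cell.cy + a) + 2, h)
        c0, c1 = max(int(cell.cx - b) - 1, 0), min(int(cell.cx + b) + 2, w)
        local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        local[rr - r0, cc - c0] = True
        sigma = max(1.0, min(cell.w, cell.h) / 24.0)
        gm = _granule_mask(local.shape, local, fraction, rng, blob_sigma=sigma)
        gr, gc = np.nonzero(gm)
        if gr.size:
            _paint(img, gr + r0, gc + c0, _PIGMENT, rng, jitter=8.0)


def _draw_hair(img: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    y = float(rng.uniform(0, h))
    x = float(rng.uniform(0, w))
    angle = rng.uniform(0, 2 * np.pi)
    thickness = int(rng.integers(1, 3))
    for _ in range(int(rng.integers(120, 360))):
        angle += rng.normal(0.0, 0.08)
        y += np.sin(angle) * 2.0
        x += np.cos(angle) * 2.0
        iy, ix = int(y), int(x)
        if not (0 <= iy < h and 0 <= ix < w):
            break
        r0, r1 = max(iy - thickness, 0), min(iy + thickness + 1, h)
        c0, c1 = max(ix - thickness, 0), min(ix + thickness + 1, w)
        img[r0:r1, c0:c1] = np.clip(
            _HAIR[None, None, :] + rng.normal(0, 6, (r1 - r0, c1 - c0, 3)), 0, 255
        )


def _draw_clump(img: np.ndarray, rng: np.random.Generator, diameter: float) -> None:
    h, w = img.shape[:2]
    cy = rng.uniform(0, h)
    cx = rng.uniform(0, w)
    rr, cc = draw_ellipse(cy, cx, diameter / 2, diameter / 2, shape=(h, w))
    if rr.size == 0:
        return
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[rr - r0, cc - c0] = True
    gm = _granule_mask(local.shape, local, 0.6, rng, blob_sigma=max(1.0, diameter / 10))
    gr, gc = np.nonzero(gm)
    if gr.size:
        _paint(img, gr + r0, gc + c0, _PIGMENT, rng, jitter=10.0)


def _boxes_overlap(box_a, box_b, max_iou: float) -> bool:
    ax0, ay0, aw, ah = box_a
    bx0, by0, bw, bh = box_b
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    if inter == 0.0:
        return False
    union = aw * ah + bw * bh - inter
    return inter / union > max_iou


def _place_cells(config: SynthConfig, rng: np.random.Generator) -> list[CellAnnotation]:
    lo, hi = config.cell_diameter_range
    grades = rng.choice(5, size=config.n_cells, p=np.asarray(config.grade_distribution))
    cells: list[CellAnnotation] = []
    boxes: list[tuple[float, float, float, float]] = []
    max_tries = 200 * max(config.n_cells, 1)
    tries = 0
    for grade in grades:
        while True:
            tries += 1
            if tries > max_tries:
                raise CapacityError(
                    f"could not place {config.n_cells} cells of diameter "
                    f"{lo}-{hi} px on a {config.width}x{config.height} slide "
                    f"within the overlap budget"
                )
            w = float(rng.uniform(lo, hi))
            h = float(w * rng.uniform(0.85, 1.15))
            h = min(h, float(hi))
            cx = float(rng.uniform(w / 2 + 1, config.width - w / 2 - 1))
            cy = float(rng.uniform(h / 2 + 1, config.height - h / 2 - 1))
            box = (cx - w / 2, cy - h / 2, w, h)
            if any(_boxes_overlap(box, other, config.max_center_overlap)
                   for other in boxes):
                continue
            boxes.append(box)
            cells.append(CellAnnotation(config.slide_id, cx, cy, w, h, int(grade)))
            break
    return cells


def generate_slide(config: SynthConfig) -> tuple[np.ndarray, SlideRecord]:
    """Render a synthetic slide; returns (RGB uint8 image, slide record).

    Identical configs (including seed) produce bit-identical output.
    Distractors carry no annotation.
    """
    rng = np.random.default_rng(config.seed)
    img = np.clip(
        _BACKGROUND[None, None, :]
        + rng.normal(0.0, 2.5, size=(config.height, config.width, 3)),
        0, 255,
    )

    cells = _place_cells(config, rng)

    for _ in range(config.n_hair_artifacts):
        _draw_hair(img, rng)
    lo, _hi = config.cell_diameter_range
    for _ in range(config.n_pigment_clumps):
        _draw_clump(img, rng, diameter=float(rng.uniform(0.4 * lo, 1.2 * lo)))

    fractions = config.pigment_fraction_per_grade
    for cell in cells:
        _draw_cell(img, cell, fractions[cell.grade], rng)

    record = SlideRecord(
        slide_id=config.slide_id,
        width=config.width,
        height=config.height,
        staining=config.staining,
        annotations=cells,
    )
    return img.astype(np.uint8), record


def split_half(record: SlideRecord) -> tuple[list[CellAnnotation], list[CellAnnotation]]:
    """Upper-half cells for training, lower-half for validation.

    The boundary row cy == height/2 belongs to validation (half-open upper
    interval), so the split is an exact partition.
    """
    if record.height is None:
        raise ValueError("slide height unknown; cannot split")
    half = record.height / 2.0
    train = [c for c in record.annotations if c.cy < half]
    val = [c for c in record.annotations if c.cy >= half]
    return train, val


def is_pigment(pixels: np.ndarray) -> np.ndarray:
    """Blue-pigment pixel rule: strongly blue-dominant hue, non-bright."""
    px = pixels.astype(np.int32)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    return (b > r + 30) & (b > g + 30) & (px.sum(axis=-1) < 600)


def measure_pigment_fraction(image: np.ndarray, cell: CellAnnotation) -> float:
    """Fraction of the cell ellipse classified as blue pigment.

    The cytoplasm region is taken as the ellipse inscribed in the
    annotation box.  Acts as the generator's inverse self-check.
    """
    h, w = image.shape[:2]
    if cell.w < 2 or cell.h < 2:
        raise ValueError("degenerate cell box")
    x0, y0 = cell.cx - cell.w / 2, cell.cy - cell.h / 2
    if x0 < 0 or y0 < 0 or x0 + cell.w > w or y0 + cell.h > h:
        raise ValueError("cell box outside image")
    rr, cc = draw_ellipse(cell.cy, cell.cx, cell.h / 2, cell.w / 2, shape=(h, w))
    if rr.size == 0:
        raise ValueError("degenerate cell box")
    return float(is_pigment(image[rr, cc]).mean())


def grade_from_fraction(fraction: float) -> int:
    """Threshold rule recovering a grade from a measured pigment fraction."""
    grade = 0
    for t in GRADE_THRESHOLDS:
        if fraction > t:
            grade += 1
    return grade
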