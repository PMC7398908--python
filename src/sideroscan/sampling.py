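"""Training-patch sampling strategies for sparse, imbalanced slides.

High-grade hemosiderophages are rare: on a gigapixel slide a uniformly
placed 1024 px patch covers any one fixed cell with probability
``patch_area / slide_area`` (~8.5e-4, i.e. 0.08%, for a 35,999 x 34,118
slide), so purely random sampling almost never shows the network a grade-4
cell.  Three strategies are provided:

* ``sample_random`` — uniform patch placement (the slow-converging baseline);
* ``sample_cluster`` — two-stage: pick a grade cluster uniformly among the
  grades present, then a cell within it, then shift a patch around it;
* quadtree sampling — ``build_quadtree`` recursively quarters the slide,
  assigns each sibling set probabilities that up-weight rare grades
  (inverse global grade frequency with +1 smoothing, floored at a minimum
  probability so empty regions stay reachable), and ``sample_quadtree``
  walks root-to-leaf by those probabilities before drawing a patch that
  intersects the reached leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .annotations import CellAnnotation, GradeCounts, SlideRecord, counts_from_annotations

DEFAULT_PATCH = 1024
DEFAULT_MIN_CELLS = 300
DEFAULT_MIN_PROB = 0.01


@dataclass
class PatchSample:
    """A training patch: top-left corner, size and the cells it contains.

    Cell containment is by center; contained cells are re-expressed in
    patch coordinates (in ``[0, size)``).
    """

    slide_id: str
    x: int
    y: int
    size: int
    cells: list[CellAnnotation] = field(default_factory=list)


def _cells_in_patch(record: SlideRecord, x: int, y: int, size: int) -> list[CellAnnotation]:
    out = []
    for c in record.annotations:
        if x <= c.cx < x + size and y <= c.cy < y + size:
            out.append(CellAnnotation(c.slide_id, c.cx - x, c.cy - y, c.w, c.h, c.grade))
    return out


def _make_patch(record: SlideRecord, x: int, y: int, size: int) -> PatchSample:
    return PatchSample(record.slide_id, int(x), int(y), int(size),
                       _cells_in_patch(record, int(x), int(y), size))


def random_hit_probability(image_w: int, image_h: int,
                           patch_w: int, patch_h: int) -> float:
    """Area-ratio probability that a uniform patch covers one fixed point."""
    if image_w <= 0 or image_h <= 0:
        raise ValueError("image area must be positive")
    if patch_w > image_w or patch_h > image_h:
        raise ValueError("patch larger than image")
    return (patch_w * patch_h) / (image_w * image_h)


def sample_random(record: SlideRecord, patch_size: int,
                  rng: np.random.Generator) -> PatchSample:
    """Uniformly placed patch fully inside the slide."""
    if record.width is None or record.height is None:
        raise ValueError("slide bounds unknown")
    if record.width < patch_size or record.height < patch_size:
        raise ValueError("slide smaller than patch")
    x = int(rng.integers(0, record.width - patch_size + 1))
    y = int(rng.integers(0, record.height - patch_size + 1))
    return _make_patch(record, x, y, patch_size)


def sample_cluster(record: SlideRecord, patch_size: int,
                   rng: np.random.Generator) -> PatchSample:
    """Two-stage cluster sampling: grade cluster, then cell, then shift.

    Stage 1 picks uniformly among the grades present on the slide, stage 2
    a cell uniformly within that cluster; the patch offset is uniform among
    positions keeping the chosen cell's center inside the patch (and the
    patch inside the slide).
    """
    if not record.annotations:
        raise ValueError("slide has no annotations; use sample_random instead")
    if record.width is None or record.height is None:
        raise ValueError("slide bounds unknown")
    by_grade: dict[int, list[CellAnnotation]] = {}
    for c in record.annotations:
        by_grade.setdefault(c.grade, []).append(c)
    grades = sorted(by_grade)
    grade = grades[int(rng.integers(0, len(grades)))]
    cluster = by_grade[grade]
    cell = cluster[int(rng.integers(0, len(cluster)))]
    # positions with x <= cx < x + size, clamped inside the slide
    x_lo = max(0, int(np.floor(cell.cx)) - patch_size + 1)
    x_hi = min(record.width - patch_size, int(np.floor(cell.cx)))
    y_lo = max(0, int(np.floor(cell.cy)) - patch_size + 1)
    y_hi = min(record.height - patch_size, int(np.floor(cell.cy)))
    x = int(rng.integers(x_lo, x_hi + 1))
    y = int(rng.integers(y_lo, y_hi + 1))
    return _make_patch(record, x, y, patch_size)


# ---------------------------------------------------------------------------
# Quadtree


def inverse_frequency_weight(global_counts: GradeCounts) -> Callable[[int], float]:
    """Default grade weight 1 / (global n_g + 1): rare grades weigh more."""
    n = global_counts.as_tuple()

    def weight(grade: int) -> float:
        return 1.0 / (n[grade] + 1)

    return weight


@dataclass
class QuadtreeNode:
    """A spatial node: bounds, contained cells, sibling-relative probability."""

    x: int
    y: int
    w: int
    h: int
    depth: int
    cells: list[CellAnnotation] = field(default_factory=list)
    probability: float = 1.0
    children: list["QuadtreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self):
        yield self
        for child in self.children:
            yield from child.iter_nodes()


def node_probabilities(siblings: Sequence[QuadtreeNode],
                       global_counts: GradeCounts,
                       weights: Callable[[int], float] | None = None,
                       min_prob: float = DEFAULT_MIN_PROB) -> np.ndarray:
    """Sibling sampling probabilities from rarity-weighted cell content.

    Raw score of a node = sum over its cells of weight(grade); each raw
    score is floored at ``min_prob`` times the total sibling mass (so empty
    nodes stay sampleable), then the set is normalized to sum to 1.
    """
    if not siblings:
        raise ValueError("empty sibling set")
    if weights is None:
        weights = inverse_frequency_weight(global_counts)
    raw = np.array(
        [sum(weights(c.grade) for c in node.cells) for node in siblings],
        dtype=float,
    )
    mass = raw.sum()
    if mass <= 0.0:
        return np.full(len(siblings), 1.0 / len(siblings))
    raw = np.maximum(raw, min_prob * mass)
    return raw / raw.sum()


def _quarters(node: QuadtreeNode) -> list[tuple[int, int, int, int]]:
    # integer quadrants; right/bottom halves absorb odd pixels
    w0 = node.w // 2
    h0 = node.h // 2
    return [
        (node.x, node.y, w0, h0),
        (node.x + w0, node.y, node.w - w0, h0),
        (node.x, node.y + h0, w0, node.h - h0),
        (node.x + w0, node.y + h0, node.w - w0, node.h - h0),
    ]


def build_quadtree(record: SlideRecord, max_depth: int = 3,
                   min_cells: int = DEFAULT_MIN_CELLS,
                   min_prob: float = DEFAULT_MIN_PROB,
                   weights: Callable[[int], float] | None = None,
                   split_rule: str = "min_cells",
                   patch_size: int = DEFAULT_PATCH) -> QuadtreeNode:
    """Build the sampling quadtree over a slide.

    Two stopping rules are supported: ``min_cells`` (a node splits only if
    every resulting quadrant would hold at least ``min_cells`` cells) and
    ``patch_size`` (quadrants are split until a child's side would fall
    below the training patch size).  Construction is deterministic.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if split_rule not in ("min_cells", "patch_size"):
        raise ValueError(f"unknown split rule {split_rule!r}")
    if record.width is None or record.height is None:
        raise ValueError("slide bounds unknown")

    global_counts = counts_from_annotations(record.annotations)

    def contains(node: QuadtreeNode, c: CellAnnotation) -> bool:
        return (node.x <= c.cx < node.x + node.w
                and node.y <= c.cy < node.y + node.h)

    def split(node: QuadtreeNode) -> None:
        if node.depth >= max_depth:
            return
        quarters = _quarters(node)
        child_cells = [[] for _ in quarters]
        for c in node.cells:
            for i, (qx, qy, qw, qh) in enumerate(quarters):
                if qx <= c.cx < qx + qw and qy <= c.cy < qy + qh:
                    child_cells[i].append(c)
                    break
        if split_rule == "min_cells":
            if any(len(cc) < min_cells for cc in child_cells):
                return
        else:  # patch_size rule: stop before children get smaller than a patch
            if any(qw < patch_size or qh < patch_size for _, _, qw, qh in quarters):
                return
        node.children = [
            QuadtreeNode(qx, qy, qw, qh, node.depth + 1, cells=cc)
            for (qx, qy, qw, qh), cc in zip(quarters, child_cells)
        ]
        probs = node_probabilities(node.children, global_counts, weights, min_prob)
        for child, p in zip(node.children, probs):
            child.probability = float(p)
            split(child)

    root = QuadtreeNode(0, 0, record.width, record.height, depth=0,
                        cells=list(record.annotations))
    split(root)
    return root


def sample_quadtree(record: SlideRecord, root: QuadtreeNode, patch_size: int,
                    rng: np.random.Generator) -> PatchSample:
    """Traverse the tree by sibling probabilities, then draw a patch.

    At the reached leaf, the patch top-left is uniform among positions
    whose patch intersects the leaf bounds while staying inside the slide;
    leaf-boundary cells therefore remain reachable.
    """
    if record.width is None or record.height is None:
        raise ValueError("slide bounds unknown")
    node = root
    while not node.is_leaf:
        probs = np.array([child.probability for child in node.children])
        idx = int(rng.choice(len(node.children), p=probs / probs.sum()))
        node = node.children[idx]
    x_lo = max(0, node.x - patch_size + 1)
    x_hi = min(record.width - patch_size, node.x + node.w - 1)
    y_lo = max(0, node.y - patch_size + 1)
    y_hi = min(record.height - patch_size, node.y + node.h - 1)
    if x_hi < x_lo or y_hi < y_lo:
        raise ValueError("slide smaller than patch")
    x = int(rng.integers(x_lo, x_hi + 1))
    y = int(rng.integers(y_lo, y_hi + 1))
    return _make_patch(record, x, y, patch_size)


def make_sampler(strategy: str, record: SlideRecord, patch_size: int,
                 **tree_kwargs) -> Callable[[np.random.Generator], PatchSample]:
    """Bind a strategy name to a `rng -> PatchSample` callable."""
    if strategy == "random":
        return lambda rng: sample_random(record, patch_size, rng)
    if strategy == "cluster":
        return lambda rng: sample_cluster(record, patch_size, rng)
    if strategy == "quadtree":
        tree_kwargs.setdefault("patch_size", patch_size)
        root = build_quadtree(record, **tree_kwargs)
        return lambda rng: sample_quadtree(record, root, patch_size, rng)
    raise ValueError(f"unknown sampling strategy {strategy!r}")
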