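"""Patch-level score regression baselines.

Instead of detecting individual cells, these methods predict the mean
hemosiderin grade of an image patch directly and average patch predictions
into a slide score: a classical baseline (per-channel intensity histograms
into an RBF support-vector regressor with C = 0.1) and, via the detector
module's patch head, a deep regression alternative.  Both expose the same
predict-patches/aggregate interface so slide-level THS errors are directly
comparable across methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR

from .annotations import SlideRecord
from .sampling import PatchSample, make_sampler
from .scoring import _round_half_away

N_BINS = 32


@dataclass
class PatchFeature:
    """Concatenated per-channel histograms (3 x N_BINS, each density 1)."""

    histogram: np.ndarray
    target: float

    def __post_init__(self) -> None:
        if abs(self.histogram.sum() - 3.0) > 1e-6:
            raise ValueError("histogram channels must each normalize to 1")
        if not 0.0 <= self.target <= 4.0:
            raise ValueError("target grade outside [0, 4]")


def patch_histogram(patch_pixels: np.ndarray, bins: int = N_BINS) -> np.ndarray:
    """Per-channel intensity histogram, density-normalized per channel."""
    feats = []
    for ch in range(3):
        hist, _ = np.histogram(patch_pixels[..., ch], bins=bins, range=(0, 256))
        feats.append(hist / max(hist.sum(), 1))
    return np.concatenate(feats)


def _patch_target(sample: PatchSample) -> float:
    if not sample.cells:
        return 0.0
    return float(np.mean([c.grade for c in sample.cells]))


def extract_patch_features(record: SlideRecord, image: np.ndarray,
                           rng: np.random.Generator, n_patches: int = 100,
                           patch_size: int = 1024, sampler=None,
                           strategy: str = "quadtree",
                           **sampler_kwargs) -> list[PatchFeature]:
    """Histogram features of ``n_patches`` sampled patches of one slide.

    The default sampler is the quadtree strategy; a prebuilt
    ``rng -> PatchSample`` callable can be injected instead.
    """
    if sampler is None:
        sampler = make_sampler(strategy, record, patch_size, **sampler_kwargs)
    features = []
    for _ in range(n_patches):
        sample = sampler(rng)
        pixels = image[sample.y:sample.y + sample.size,
                       sample.x:sample.x + sample.size]
        features.append(PatchFeature(patch_histogram(pixels), _patch_target(sample)))
    return features


class SvmScoreRegressor:
    """RBF support-vector regression of patch mean grade from histograms."""

    def __init__(self, complexity: float = 0.1):
        self.svr = SVR(kernel="rbf", C=complexity)

    def fit(self, features: list[PatchFeature]) -> "SvmScoreRegressor":
        if not features:
            raise ValueError("no training features")
        x = np.stack([f.histogram for f in features])
        y = np.array([f.target for f in features])
        if not np.all(np.isfinite(x)):
            raise ValueError("degenerate (non-finite) features")
        self.svr.fit(x, y)
        return self

    def predict(self, features: list[PatchFeature]) -> np.ndarray:
        x = np.stack([f.histogram for f in features])
        return np.clip(self.svr.predict(x), 0.0, 4.0)


def train_svm_regressor(features: list[PatchFeature],
                        complexity: float = 0.1) -> SvmScoreRegressor:
    return SvmScoreRegressor(complexity=complexity).fit(features)


def slide_score_from_patches(patch_predictions) -> tuple[float, int]:
    """Slide grade = mean of patch predictions; THS = round(100 x mean)."""
    preds = np.asarray(patch_predictions, dtype=float)
    if preds.size == 0:
        raise ValueError("no patch predictions to aggregate")
    mean = float(preds.mean())
    return mean, _round_half_away(100.0 * mean)
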