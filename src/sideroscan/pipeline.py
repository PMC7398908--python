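"""End-to-end demo workflow: synthesize -> sample -> train -> infer -> score.

`run_end_to_end` composes the whole pipeline on synthetic slides at a
CPU-friendly scale: generate training slides and one held-out slide, sample
training patches (two-stage cluster sampling by default), train the compact
single-level detector, run tiled inference on the held-out slide and report
the slide THS against ground truth together with detection mAP.  A single
global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence.spawn`` so stages are individually reproducible
without seed collisions.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import detector as det
from . import inference, sampling
from .annotations import counts_from_annotations
from .evaluation import evaluate_detections
from .scoring import SlideScore
from .synthetic import SynthConfig, generate_slide


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of the end-to-end demo."""

    seed: int = 0
    out_dir: str | None = None
    n_train_slides: int = 2
    slide_size: int = 512
    cells_per_slide: int = 40
    cell_diameter_range: tuple = (44, 64)
    grade_distribution: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    n_hair_artifacts: int = 1
    n_pigment_clumps: int = 1
    sampling_strategy: str = "cluster"
    n_patches_per_slide: int = 120
    epochs: int = 60
    conf_threshold: float = 0.5
    nms_iou: float = 0.3
    overlap: int = 64
    detector_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cell_diameter_range", "grade_distribution"):
            if key in data and isinstance(data[key], list):
                data = {**data, key: tuple(data[key])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)


def stage_seeds(global_seed: int, n: int = 8) -> list[int]:
    """Fan a global seed out into per-stage 31-bit seeds."""
    children = np.random.SeedSequence(global_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def _synth_config(run: RunConfig, seed: int, slide_id: str) -> SynthConfig:
    return SynthConfig(
        width=run.slide_size,
        height=run.slide_size,
        n_cells=run.cells_per_slide,
        grade_distribution=run.grade_distribution,
        cell_diameter_range=run.cell_diameter_range,
        n_hair_artifacts=run.n_hair_artifacts,
        n_pigment_clumps=run.n_pigment_clumps,
        max_center_overlap=0.0,
        seed=seed,
        slide_id=slide_id,
    )


def run_end_to_end(run: RunConfig, return_artifacts: bool = False):
    """Execute the full demo pipeline; returns (and optionally writes) the report.

    With ``return_artifacts`` the trained model and held-out slide are
    returned alongside the report for further analysis.
    """
    seeds = stage_seeds(run.seed)
    t0 = time.time()

    # 1. synthesize
    train_slides = [
        generate_slide(_synth_config(run, seeds[0] + i, f"train_{i:02d}"))
        for i in range(run.n_train_slides)
    ]
    test_image, test_record = generate_slide(
        _synth_config(run, seeds[1], "heldout")
    )

    # 2. sample training patches
    config = det.tiny_preset(seed=seeds[3], epochs=run.epochs,
                             **run.detector_overrides)
    rng = np.random.default_rng(seeds[2])
    patches = []
    for image, record in train_slides:
        sampler = sampling.make_sampler(run.sampling_strategy, record,
                                        config.patch_size)
        for _ in range(run.n_patches_per_slide):
            patches.append(det.extract_training_patch(image, sampler(rng)))

    # 3. train
    model, history = det.train_detector(patches, config)

    # 4. tiled inference on the held-out slide
    tiling = inference.plan_tiles(test_record.width, test_record.height,
                                  config.patch_size, run.overlap)
    detections, pred_score, score_map = inference.predict_slide(
        test_image, model, tiling, nms_iou=run.nms_iou,
        conf_threshold=run.conf_threshold,
    )

    # 5. score + evaluate
    gt_score = SlideScore.from_counts(
        counts_from_annotations(test_record.annotations)
    )
    metrics = evaluate_detections(detections, test_record.annotations)

    report = {
        "seed": run.seed,
        "stage_seeds": seeds,
        "n_training_patches": len(patches),
        "final_loss": dataclasses.asdict(history[-1]) | {"total": history[-1].total},
        "n_detections": len(detections),
        "ths_ground_truth": gt_score.ths,
        "ths_predicted": pred_score.ths if pred_score else None,
        "ths_error": (abs(gt_score.ths - pred_score.ths)
                      if pred_score else None),
        "map": metrics["map"],
        "ap_per_grade": {g: c.ap for g, c in metrics["per_grade"].items()},
        "excluded_grades": metrics["excluded_grades"],
        "runtime_s": round(time.time() - t0, 1),
    }
    if run.out_dir:
        out = Path(run.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    if return_artifacts:
        artifacts = {
            "model": model,
            "config": config,
            "history": history,
            "test_image": test_image,
            "test_record": test_record,
            "detections": detections,
            "score_map": score_map,
            "tiling": tiling,
        }
        return report, artifacts
    return report
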