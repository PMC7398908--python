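"""Shared fixtures.

Training runs are expensive, so the end-to-end pipeline and the single-cell
crop pool are session-scoped and shared by every test that needs a trained
model or graded crops.
"""

import numpy as np
import pytest

from sideroscan import synthetic
from sideroscan.pipeline import RunConfig, run_end_to_end
from sideroscan.single_cell import extract_crop


@pytest.fixture(scope="session")
def e2e():
    """One full pipeline run (synth -> sample -> train -> infer -> score)."""
    report, artifacts = run_end_to_end(RunConfig(seed=1), return_artifacts=True)
    return report, artifacts


@pytest.fixture(scope="session")
def small_slide():
    """A 512-px synthetic slide with 30 well-separated cells, all grades."""
    cfg = synthetic.SynthConfig(
        width=512, height=512, n_cells=30,
        grade_distribution=(0.2, 0.2, 0.2, 0.2, 0.2),
        cell_diameter_range=(44, 64), max_center_overlap=0.0, seed=3,
        slide_id="unit",
    )
    image, record = synthetic.generate_slide(cfg)
    return image, record


@pytest.fixture(scope="session")
def crop_pool():
    """~500 graded single-cell crops (balanced grades) from synthetic slides."""
    crops = []
    for i in range(2):
        cfg = synthetic.SynthConfig(
            width=2048, height=2048, n_cells=250,
            grade_distribution=(0.2, 0.2, 0.2, 0.2, 0.2),
            cell_diameter_range=(44, 64), max_center_overlap=0.05,
            seed=100 + i, slide_id=f"pool_{i}",
        )
        image, record = synthetic.generate_slide(cfg)
        crops.extend(extract_crop(image, c, side=72) for c in record.annotations)
    return crops


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
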