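"""Detector components: activations, losses, anchors, matching, training."""

import math

import numpy as np
import pytest

from sideroscan import detector as det
from sideroscan.annotations import CellAnnotation
from sideroscan.detector import (
    Detection,
    DetectorConfig,
    PatchTarget,
    RetinaNetDetector,
    box_iou_matrix,
    decode_boxes,
    encode_boxes,
    focal_loss,
    generate_anchors,
    match_anchors,
    scaled_sigmoid,
    smooth_l1,
    tiny_preset,
    total_loss,
    train_detector,
)


class TestScaledSigmoid:
    def test_midpoint(self):
        assert scaled_sigmoid(0.0) == pytest.approx(2.0)

    def test_asymptotes(self):
        assert scaled_sigmoid(80.0) == pytest.approx(4.5)
        assert scaled_sigmoid(-80.0) == pytest.approx(-0.5)

    def test_closed_form_point(self):
        # sigma(ln 3) = 0.75 -> 5 * 0.75 - 0.5
        assert scaled_sigmoid(math.log(3)) == pytest.approx(3.25)

    def test_strictly_increasing(self):
        z = np.linspace(-10, 10, 101)
        assert np.all(np.diff(scaled_sigmoid(z)) > 0)


class TestFocalLoss:
    def test_perfect_prediction(self):
        assert focal_loss(1.0, 0.25, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_reduces_to_cross_entropy(self):
        p = 0.3
        assert focal_loss(p, 1.0, 0.0) == pytest.approx(-math.log(p))

    def test_hand_value(self):
        # 0.25 * (1-0.5)^2 * (-ln 0.5) = 0.25 * 0.25 * ln 2
        assert focal_loss(0.5, 0.25, 2.0) == pytest.approx(0.25 * 0.25 * math.log(2))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            focal_loss(0.0, 0.25, 2.0)

    def test_gradient_matches_finite_difference(self, rng):
        # d/dp [-a (1-p)^g log p] checked numerically at 10 random points
        alpha, gamma = 0.25, 2.0
        for p in rng.uniform(0.05, 0.95, size=10):
            eps = 1e-6
            num = (focal_loss(p + eps, alpha, gamma)
                   - focal_loss(p - eps, alpha, gamma)) / (2 * eps)
            ana = alpha * (gamma * (1 - p) ** (gamma - 1) * math.log(p)
                           - (1 - p) ** gamma / p)
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(ana))


class TestSmoothL1:
    def test_zero_at_equality(self):
        assert smooth_l1(3.0, 3.0) == 0.0

    def test_continuity_at_one(self):
        assert smooth_l1(1.0, 0.0) == pytest.approx(0.5)
        assert smooth_l1(1.0 - 1e-9, 0.0) == pytest.approx(0.5, abs=1e-6)

    def test_linear_branch(self):
        assert smooth_l1(2.0, 0.0) == pytest.approx(1.5)

    def test_gradient_matches_finite_difference(self, rng):
        for x in rng.uniform(-3, 3, size=10):
            eps = 1e-6
            num = (smooth_l1(x + eps, 0.0) - smooth_l1(x - eps, 0.0)) / (2 * eps)
            ana = det.smooth_l1_grad(x, 0.0)
            assert abs(num - ana) <= 1e-4


class TestAnchors:
    def test_full_scale_count(self):
        cfg = DetectorConfig()  # stride 32, 1024 patch, 3 sizes, 1 ratio
        anchors = generate_anchors(cfg)
        assert anchors.shape == (32 * 32 * 3, 4)

    def test_grid_geometry(self):
        cfg = DetectorConfig()
        anchors = generate_anchors(cfg)
        centers = np.unique(anchors[:, 0])
        assert centers[0] == 16
        assert np.all(np.diff(centers) == 32)
        assert len(centers) == 32

    def test_coverage_oracle_large_cells(self, rng):
        # brute-force IoU: every cell of diameter >= 90 px has an anchor at
        # IoU >= 0.5; across the full 60-140 px range the guarantee is 0.4
        # (a cell smaller than ~88 px can sit mid-grid where no stride-32
        # anchor reaches 0.5)
        cfg = DetectorConfig()
        anchors = generate_anchors(cfg)
        for lo, hi, bound in [(90, 140, 0.5), (60, 140, 0.4)]:
            worst = 1.0
            for _ in range(1000):
                d = rng.uniform(lo, hi)
                cx, cy = rng.uniform(d / 2, 1024 - d / 2, size=2)
                iou = box_iou_matrix(anchors, np.array([[cx, cy, d, d]]))
                worst = min(worst, float(iou.max()))
            assert worst >= bound, (lo, hi, worst)

    def test_tiny_preset_coverage_at_half_iou(self, rng):
        cfg = tiny_preset()
        anchors = generate_anchors(cfg)
        for _ in range(1000):
            d = rng.uniform(44, 64)
            cx, cy = rng.uniform(d / 2, cfg.patch_size - d / 2, size=2)
            iou = box_iou_matrix(anchors, np.array([[cx, cy, d, d]]))
            assert float(iou.max()) >= 0.5


class TestMatching:
    def test_identical_anchor_positive(self):
        anchors = np.array([[100.0, 100.0, 64, 64], [400.0, 400.0, 64, 64]])
        truths = np.array([[100.0, 100.0, 64, 64]])
        assign = match_anchors(anchors, truths)
        assert assign[0] == 0
        assert assign[1] == det.NEGATIVE

    def test_empty_truths_all_negative(self):
        anchors = np.array([[100.0, 100.0, 64, 64]])
        assign = match_anchors(anchors, np.zeros((0, 4)))
        assert np.all(assign == det.NEGATIVE)

    def test_brute_force_oracle(self, rng):
        anchors = np.column_stack([
            rng.uniform(50, 450, size=(10, 2)), rng.uniform(40, 90, size=(10, 2))
        ])
        truths = np.column_stack([
            rng.uniform(50, 450, size=(3, 2)), rng.uniform(40, 90, size=(3, 2))
        ])
        assign = match_anchors(anchors, truths, 0.5, 0.4, force_match=False)
        iou = box_iou_matrix(anchors, truths)
        for i in range(10):
            best = iou[i].argmax()
            if iou[i, best] >= 0.5:
                assert assign[i] == best
            elif iou[i, best] < 0.4:
                assert assign[i] == det.NEGATIVE
            else:
                assert assign[i] == det.IGNORED

    def test_force_match_claims_best_anchor(self):
        anchors = np.array([[100.0, 100.0, 64, 64], [132.0, 100.0, 64, 64]])
        truths = np.array([[116.0, 100.0, 40, 40]])  # IoU < 0.5 with both
        assign = match_anchors(anchors, truths, 0.5, 0.4, force_match=True)
        assert (assign >= 0).sum() == 1


class TestBoxCoding:
    def test_box_equals_anchor(self):
        a = np.array([[100.0, 100.0, 64, 64]])
        assert np.allclose(encode_boxes(a, a), 0.0)

    def test_round_trip_random(self, rng):
        anchors = np.column_stack([rng.uniform(0, 1000, size=(1000, 2)),
                                   rng.uniform(30, 120, size=(1000, 2))])
        boxes = np.column_stack([rng.uniform(0, 1000, size=(1000, 2)),
                                 rng.uniform(20, 150, size=(1000, 2))])
        back = decode_boxes(anchors, encode_boxes(anchors, boxes))
        assert np.abs(back - boxes).max() < 1e-5

    def test_width_doubling_gives_log_two(self):
        a = np.array([[0.0, 0.0, 50, 50]])
        b = np.array([[0.0, 0.0, 100, 50]])
        assert encode_boxes(a, b)[0, 2] == pytest.approx(math.log(2))

    def test_nonpositive_size_error(self):
        a = np.array([[0.0, 0.0, 50, 50]])
        with pytest.raises(ValueError):
            encode_boxes(a, np.array([[0.0, 0.0, -5, 50]]))


class TestConfigValidation:
    def test_intensity_augmentation_rejected(self):
        with pytest.raises(ValueError, match="intensity"):
            DetectorConfig(augmentations=("rotate90", "intensity"))

    def test_stride_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(backbone_channels=(8, 16), feature_stride=32)

    def test_threshold_ordering(self):
        with pytest.raises(ValueError):
            DetectorConfig(match_iou_pos=0.3, match_iou_neg=0.5)


def _aligned_scenario(cfg):
    """One cell exactly on an anchor, plus crafted predictions."""
    anchors = generate_anchors(cfg)
    cell_anchor = len(anchors) // 2
    cell = anchors[cell_anchor].copy()
    target = PatchTarget(cell[None, :], np.array([2]))
    return anchors, cell_anchor, target


class TestTotalLoss:
    def test_perfect_predictions_near_zero(self):
        cfg = tiny_preset()
        anchors, idx, target = _aligned_scenario(cfg)
        n = len(anchors)
        assign = match_anchors(anchors, target.boxes, cfg.match_iou_pos,
                               cfg.match_iou_neg)
        logits = np.zeros((1, n, 6))
        logits[0, :, 5] = 40.0  # background everywhere ...
        logits[0, assign >= 0] = 0.0
        logits[0, assign >= 0, 2] = 40.0  # ... except the true grade-2 cell
        z2 = math.log((2.5 / 5) / (1 - 2.5 / 5))  # scaled sigmoid inverse of 2.0
        offsets = np.zeros((1, n, 4))
        pos = np.nonzero(assign >= 0)[0]
        offsets[0, pos] = det.encode_boxes(anchors[pos], target.boxes[assign[pos]])
        preds = {
            "cls_logits": logits,
            "box_offsets": offsets,
            "cell_score_z": np.full((1, n), z2),
            "patch_score_z": np.array([z2]),
        }
        terms = total_loss([target], preds, cfg, anchors)
        assert terms.total <= 1e-6

    def test_zeroed_score_heads_patch_mse_four(self):
        # patch of mean grade 2; both score heads output the score 0
        cfg = tiny_preset()
        anchors, idx, target = _aligned_scenario(cfg)
        n = len(anchors)
        z0 = math.log((0.5 / 5) / (1 - 0.5 / 5))  # scaled_sigmoid(z0) == 0
        preds = {
            "cls_logits": np.zeros((1, n, 6)),
            "box_offsets": np.zeros((1, n, 4)),
            "cell_score_z": np.full((1, n), z0),
            "patch_score_z": np.array([z0]),
        }
        terms = total_loss([target], preds, cfg, anchors)
        assert terms.patch_score_mse == pytest.approx(4.0, abs=1e-9)

    def test_term_by_term_oracle(self, rng):
        # independent recomputation of all four closed-form terms
        cfg = tiny_preset()
        anchors = generate_anchors(cfg)
        n = len(anchors)
        boxes = np.column_stack([rng.uniform(30, 90, size=(3, 2)),
                                 rng.uniform(40, 60, size=(3, 2))])
        grades = rng.integers(0, 5, size=3)
        target = PatchTarget(boxes, grades)
        preds = {
            "cls_logits": rng.normal(size=(1, n, 6)),
            "box_offsets": rng.normal(scale=0.3, size=(1, n, 4)),
            "cell_score_z": rng.normal(size=(1, n)),
            "patch_score_z": rng.normal(size=1),
        }
        terms = total_loss([target], preds, cfg, anchors)

        assign = match_anchors(anchors, boxes, cfg.match_iou_pos,
                               cfg.match_iou_neg, cfg.force_match)
        probs = np.exp(preds["cls_logits"][0])
        probs /= probs.sum(-1, keepdims=True)
        included = assign != det.IGNORED
        labels = np.where(assign >= 0, grades[np.maximum(assign, 0)], 5)
        fl = [focal_loss(probs[a, labels[a]], cfg.focal_alpha, cfg.focal_gamma)
              for a in range(n) if included[a]]
        assert terms.focal == pytest.approx(np.mean(fl))

        pos = np.nonzero(assign >= 0)[0]
        sl = smooth_l1(preds["box_offsets"][0][pos],
                       encode_boxes(anchors[pos], boxes[assign[pos]]))
        assert terms.box == pytest.approx(cfg.box_weight * sl.mean())

        cs = (scaled_sigmoid(preds["cell_score_z"][0][pos])
              - grades[assign[pos]]) ** 2
        assert terms.cell_score_mse == pytest.approx(cs.mean())

        pmse = (scaled_sigmoid(preds["patch_score_z"][0]) - grades.mean()) ** 2
        assert terms.patch_score_mse == pytest.approx(pmse)

    def test_decomposition_exact(self, rng):
        cfg = tiny_preset()
        anchors = generate_anchors(cfg)
        n = len(anchors)
        preds = {
            "cls_logits": rng.normal(size=(2, n, 6)),
            "box_offsets": rng.normal(size=(2, n, 4)),
            "cell_score_z": rng.normal(size=(2, n)),
            "patch_score_z": rng.normal(size=2),
        }
        targets = [PatchTarget(np.array([[64.0, 64.0, 50, 50]]), np.array([1])),
                   PatchTarget(np.zeros((0, 4)), np.zeros(0, dtype=int))]
        terms = total_loss(targets, preds, cfg, anchors)
        assert terms.total == terms.focal + terms.box + terms.cell_score_mse \
            + terms.patch_score_mse

    def test_no_positive_anchors_zero_box_terms(self):
        cfg = tiny_preset()
        anchors = generate_anchors(cfg)
        n = len(anchors)
        preds = {
            "cls_logits": np.zeros((1, n, 6)),
            "box_offsets": np.ones((1, n, 4)),
            "cell_score_z": np.ones((1, n)),
            "patch_score_z": np.zeros(1),
        }
        target = PatchTarget(np.zeros((0, 4)), np.zeros(0, dtype=int))
        terms = total_loss([target], preds, cfg, anchors)
        assert terms.box == 0.0
        assert terms.cell_score_mse == 0.0

    def test_loss_gradients_match_finite_differences(self, rng):
        cfg = tiny_preset()
        anchors = generate_anchors(cfg)
        n = len(anchors)
        boxes = np.array([[64.0, 64.0, 50.0, 50.0]])
        target = PatchTarget(boxes, np.array([3]))
        preds = {
            "cls_logits": rng.normal(size=(1, n, 6)),
            "box_offsets": rng.normal(scale=0.2, size=(1, n, 4)),
            "cell_score_z": rng.normal(size=(1, n)),
            "patch_score_z": rng.normal(size=1),
        }
        terms, grads = total_loss([target], preds, cfg, anchors,
                                  return_grads=True)
        eps = 1e-5
        for key in preds:
            flat = preds[key].reshape(-1)
            for _ in range(3):
                j = int(rng.integers(0, flat.size))
                orig = flat[j]
                flat[j] = orig + eps
                lp = total_loss([target], preds, cfg, anchors).total
                flat[j] = orig - eps
                lm = total_loss([target], preds, cfg, anchors).total
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].reshape(-1)[j]
                assert abs(num - ana) <= 2e-4 * max(1.0, abs(num)), key


@pytest.fixture(scope="module")
def smoke_run(small_slide):
    from sideroscan.sampling import make_sampler

    image, record = small_slide
    cfg = tiny_preset(seed=0, epochs=6)
    sampler = make_sampler("cluster", record, cfg.patch_size)
    rng = np.random.default_rng(0)
    patches = [det.extract_training_patch(image, sampler(rng))
               for _ in range(40)]
    model, history = train_detector(patches, cfg)
    return patches, cfg, model, history


class TestTraining:
    def test_loss_decreases_over_first_epochs(self, smoke_run):
        _, _, _, history = smoke_run
        totals = [h.total for h in history[:5]]
        assert all(b < a for a, b in zip(totals, totals[1:]))

    def test_seed_determinism_of_first_epoch(self, smoke_run):
        patches, cfg, _, _ = smoke_run
        cfg1 = tiny_preset(seed=0, epochs=1)
        _, h1 = train_detector(patches, cfg1, augment=False)
        _, h2 = train_detector(patches, cfg1, augment=False)
        assert h1[0].total == h2[0].total

    def test_checkpoint_round_trip(self, smoke_run, tmp_path):
        patches, _, model, _ = smoke_run
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = RetinaNetDetector.load(path)
        img = patches[0].image
        d1 = model.predict_patch(img, conf_threshold=0.3)
        d2 = loaded.predict_patch(img, conf_threshold=0.3)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert a.box == b.box and a.grade_class == b.grade_class

    def test_augmentation_preserves_cell_count(self, smoke_run, rng):
        patches, cfg, _, _ = smoke_run
        for p in patches[:10]:
            aug = det._augment(p, cfg, rng)
            assert len(aug.cells) == len(p.cells)
            assert aug.image.shape == p.image.shape
            for c in aug.cells:
                assert 0 <= c.cx < cfg.patch_size
                assert 0 <= c.cy < cfg.patch_size
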