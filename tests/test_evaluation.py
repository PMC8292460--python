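"""IoU matching and detection scores, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

import spheropick as sp
from spheropick.evaluation import (DEFAULT_TAU_GRID, classical_precision,
                                   iou_matrix)


def brute_force_match(pred, gt, tau):
    """Exhaustive search over all one-to-one assignments: maximise total IoU
    over pairs with IoU >= tau. Independent of the assignment solver."""
    iou = iou_matrix(gt, pred)
    n_gt, n_pred = iou.shape
    best_total, best_pairs = 0.0, []
    gt_idx = list(range(n_gt))
    for k in range(0, min(n_gt, n_pred) + 1):
        for gts in itertools.combinations(gt_idx, k):
            for preds in itertools.permutations(range(n_pred), k):
                if any(iou[g, p] < tau for g, p in zip(gts, preds)):
                    continue
                total = sum(iou[g, p] for g, p in zip(gts, preds))
                if total > best_total + 1e-12:
                    best_total, best_pairs = total, list(zip(gts, preds))
    tp = len(best_pairs)
    return tp, n_pred - tp, n_gt - tp


def random_layout(rng, shape=(40, 40), max_objects=5):
    """Random label mask of overlapping-free rectangles."""
    mask = np.zeros(shape, dtype=np.int32)
    n = rng.integers(0, max_objects + 1)
    label = 0
    for _ in range(n):
        h = rng.integers(4, 15)
        w = rng.integers(4, 15)
        r = rng.integers(0, shape[0] - h)
        c = rng.integers(0, shape[1] - w)
        region = mask[r:r + h, c:c + w]
        if region.any():
            continue
        label += 1
        region[:] = label
    return mask


class TestObjectIoU:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), dtype=bool)
        a[:5, :5] = True
        b = np.zeros((10, 10), dtype=bool)
        b[6:, 6:] = True
        assert sp.object_iou(a, a) == 1.0
        assert sp.object_iou(a, b) == 0.0

    def test_shifted_square_counts_pixels(self):
        a = np.zeros((20, 20), dtype=bool)
        a[5:15, 0:10] = True
        b = np.zeros((20, 20), dtype=bool)
        b[5:15, 5:15] = True
        assert sp.object_iou(a, b) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        a = rng.random((15, 15)) > 0.6
        b = rng.random((15, 15)) > 0.6
        if not (a.any() or b.any()):
            a[0, 0] = True
        assert sp.object_iou(a, b) == sp.object_iou(b, a)

    def test_both_empty_raises(self):
        z = np.zeros((5, 5), dtype=bool)
        with pytest.raises(ValueError):
            sp.object_iou(z, z)


class TestMatchObjects:
    def test_perfect_prediction(self, rng):
        gt = random_layout(rng)
        while gt.max() < 3:
            gt = random_layout(rng)
        for tau in (0.5, 0.95):
            c, _ = sp.match_objects(gt, gt, tau)
            assert (c.tp, c.fp, c.fn) == (gt.max(), 0, 0)

    def test_missed_object(self):
        gt = np.zeros((30, 30), dtype=np.int32)
        gt[2:12, 2:12] = 1
        gt[18:28, 18:28] = 2
        pred = np.zeros_like(gt)
        pred[2:12, 2:8] = 1  # IoU 0.6 with gt 1
        c, matches = sp.match_objects(pred, gt, 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)
        assert matches == [(1, 1, pytest.approx(0.6))]

    def test_split_object_counts_one_match_one_fp(self):
        gt = np.zeros((20, 20), dtype=np.int32)
        gt[5:15, 2:18] = 1
        pred = np.zeros_like(gt)
        pred[5:15, 2:10] = 1   # left half, IoU 0.5
        pred[5:15, 10:18] = 2  # right half, IoU 0.5
        c, _ = sp.match_objects(pred, gt, 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            sp.match_objects(np.zeros((4, 4), dtype=np.int32),
                             np.zeros((5, 5), dtype=np.int32), 0.5)

    def test_assignment_equals_exhaustive_search(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            gt = random_layout(rng)
            pred = random_layout(rng)
            for tau in (0.3, 0.5, 0.7):
                c, _ = sp.match_objects(pred, gt, tau)
                assert (c.tp, c.fp, c.fn) == brute_force_match(pred, gt, tau)


class TestScores:
    @pytest.mark.parametrize("tp, fp, fn, expected", [
        (1, 0, 1, 0.5), (4, 0, 0, 1.0), (0, 3, 2, 0.0),
    ])
    def test_detection_quality_score(self, tp, fp, fn, expected):
        c = sp.EvalCounts(tp=tp, fp=fp, fn=fn, n_gt=tp + fn, iou_threshold=0.5)
        assert sp.precision_score(c) == pytest.approx(expected)

    def test_empty_image_scores_one_by_convention(self):
        c = sp.EvalCounts(tp=0, fp=0, fn=0, n_gt=0, iou_threshold=0.5)
        assert sp.precision_score(c) == 1.0

    def test_classical_precision_distinct(self):
        c = sp.EvalCounts(tp=1, fp=0, fn=1, n_gt=2, iou_threshold=0.5)
        assert classical_precision(c) == 1.0
        assert sp.precision_score(c) == 0.5

    @pytest.mark.parametrize("tp, n_gt, expected", [(3, 3, 1.0), (1, 2, 0.5), (0, 5, 0.0)])
    def test_sensitivity(self, tp, n_gt, expected):
        c = sp.EvalCounts(tp=tp, fp=0, fn=n_gt - tp, n_gt=n_gt, iou_threshold=0.5)
        assert sp.sensitivity_score(c) == pytest.approx(expected)

    def test_sensitivity_undefined_without_ground_truth(self):
        c = sp.EvalCounts(tp=0, fp=2, fn=0, n_gt=0, iou_threshold=0.5)
        with pytest.raises(ValueError):
            sp.sensitivity_score(c)

    def test_counts_consistency_enforced(self):
        with pytest.raises(ValueError):
            sp.EvalCounts(tp=2, fp=0, fn=0, n_gt=3, iou_threshold=0.5)


class TestEvaluateDataset:
    def test_perfect_predictions_flat_curve(self, rng):
        masks = [random_layout(rng) for _ in range(5)]
        masks = [m for m in masks if m.max() > 0][:3]
        ev = sp.evaluate_dataset([(m, m) for m in masks])
        for _, p, s in ev.pooled.points:
            assert p == 1.0 and s == 1.0

    def test_default_grid_has_ten_points(self, rng):
        m = random_layout(rng)
        while m.max() == 0:
            m = random_layout(rng)
        ev = sp.evaluate_dataset([(m, m)])
        assert len(ev.pooled.points) == 10
        assert ev.pooled.taus == pytest.approx(list(DEFAULT_TAU_GRID))

    def test_pooled_equals_summed_counts(self, rng):
        pairs = []
        while len(pairs) < 4:
            gt = random_layout(rng)
            if gt.max():
                pairs.append((random_layout(rng), gt))
        ev = sp.evaluate_dataset(pairs, taus=[0.5])
        total_tp = total_fp = total_fn = 0
        for pred, gt in pairs:
            c, _ = sp.match_objects(pred, gt, 0.5)
            total_tp += c.tp
            total_fp += c.fp
            total_fn += c.fn
        assert ev.pooled.counts[0].tp == total_tp
        expected_p = total_tp / (total_tp + total_fp + total_fn)
        assert ev.pooled.precision_at(0.5) == pytest.approx(expected_p)

    def test_threshold_monotonicity(self, clean_set):
        pairs, _ = clean_set
        preds = [sp.segment_otsu(img) for img, _ in pairs[:5]]
        ev = sp.evaluate_dataset([(p, gt) for p, (_, gt) in zip(preds, pairs[:5])])
        ps = [p for _, p, _ in ev.pooled.points]
        ss = [s for _, _, s in ev.pooled.points]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(ss, ss[1:]))

    def test_degradation_never_helps(self, clean_set):
        # same scenes re-rendered with noise and defocus: pooled detection
        # quality of the threshold pipeline must not improve
        import dataclasses

        pairs, specs = clean_set
        noisy_pairs = []
        for spec in specs[:5]:
            objs = [dataclasses.replace(o, defocus_sigma_px=2.5) for o in spec.objects]
            noisy = dataclasses.replace(spec, objects=objs, noise_sigma=0.06)
            noisy_pairs.append(sp.render_scene(noisy))
        def pooled_p(pp):
            preds = [(sp.segment_otsu(img), gt) for img, gt in pp]
            return sp.evaluate_dataset(preds, taus=[0.8]).pooled.precision_at(0.8)
        assert pooled_p(noisy_pairs) <= pooled_p(pairs[:5]) + 1e-12

    def test_empty_grid_rejected(self, rng):
        m = random_layout(rng)
        with pytest.raises(ValueError):
            sp.evaluate_dataset([(m, m)], taus=[])
        with pytest.raises(ValueError):
            sp.evaluate_dataset([(m, m)], taus=[0.9, 0.5])
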