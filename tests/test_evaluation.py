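import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mandfrac.evaluation import (DetectionResult, FrocCurve, detection_counts,
                                 dice, froc, froc_auc, iou, match_detections,
                                 precision_sensitivity)
from mandfrac.inference import FractureProposal


def _prop(voxels, conf):
    return FractureProposal(np.asarray(voxels), "stage2", conf, len(voxels))


def _mask(shape, where):
    m = np.zeros(shape, dtype=np.uint8)
    for w in where:
        m[tuple(w)] = 1
    return m


class TestOverlapMetrics:
    def test_identical_and_disjoint(self):
        a = _mask((8, 8, 8), [(1, 1, 1), (2, 2, 2)])
        b = _mask((8, 8, 8), [(5, 5, 5)])
        assert dice(a, a) == 1.0 and iou(a, a) == 1.0
        assert dice(a, b) == 0.0 and iou(a, b) == 0.0

    def test_count_arithmetic(self):
        a = np.zeros((30, 1, 1), np.uint8)
        b = np.zeros((30, 1, 1), np.uint8)
        a[:10] = 1
        b[2:12] = 1  # |a|=10, |b|=10, overlap 8
        assert dice(a, b) == pytest.approx(0.8)
        assert iou(a, b) == pytest.approx(8 / 12)

    def test_both_empty(self):
        z = np.zeros((4, 4, 4), np.uint8)
        assert dice(z, z) == 1.0 and iou(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))

    @given(st.integers(0, 2 ** 27 - 1), st.integers(0, 2 ** 27 - 1))
    @settings(max_examples=100, deadline=None)
    def test_identity_iou_from_dice(self, seed_a, seed_b):
        """IoU = Dice / (2 − Dice) for arbitrary random mask pairs."""
        rng = np.random.default_rng(seed_a * 2 ** 27 + seed_b)
        a = rng.random((6, 6, 6)) > rng.uniform(0.2, 0.9)
        b = rng.random((6, 6, 6)) > rng.uniform(0.2, 0.9)
        d, j = dice(a, b), iou(a, b)
        assert j == pytest.approx(d / (2.0 - d), abs=1e-12)


class TestMatching:
    SHAPE = (16, 16, 16)

    def _gt(self, blobs):
        g = np.zeros(self.SHAPE, np.uint8)
        for lab, vox in enumerate(blobs, start=1):
            for v in vox:
                g[tuple(v)] = lab
        return g

    def test_perfect_overlap(self):
        gt = self._gt([[(3, 3, 3)], [(10, 10, 10)]])
        props = [_prop([[3, 3, 3]], 0.9), _prop([[10, 10, 10]], 0.8)]
        r = match_detections(props, gt, gt_dilation_vox=0)
        assert r.tp == 2 and r.fp == 0 and r.fn == 0

    def test_one_proposal_two_fractures(self):
        """The single-match rule yields 1 TP + 1 FN."""
        gt = self._gt([[(3, 3, 3)], [(3, 3, 5)]])
        props = [_prop([[3, 3, 3], [3, 3, 4], [3, 3, 5]], 0.9)]
        r = match_detections(props, gt, gt_dilation_vox=0)
        assert r.tp == 1 and r.fn == 1 and r.fp == 0

    def test_false_positive(self):
        gt = self._gt([[(3, 3, 3)]])
        props = [_prop([[12, 12, 12]], 0.9)]
        r = match_detections(props, gt, gt_dilation_vox=2)
        assert r.tp == 0 and r.fp == 1 and r.fn == 1

    def test_dilation_tolerance(self):
        gt = self._gt([[(8, 8, 8)]])
        props = [_prop([[8, 8, 10]], 0.9)]
        assert match_detections(props, gt, gt_dilation_vox=0).tp == 0
        assert match_detections(props, gt, gt_dilation_vox=2).tp == 1

    def test_conservation(self):
        gt = self._gt([[(2, 2, 2)], [(8, 8, 8)], [(13, 13, 13)]])
        props = [_prop([[2, 2, 2]], 0.9), _prop([[5, 5, 5]], 0.4)]
        r = match_detections(props, gt, gt_dilation_vox=0)
        assert r.tp + r.fn == 3
        assert r.tp + r.fp == len(props)


class TestPrecisionSensitivity:
    def test_clinical_scale_counts(self):
        # 45 fractures with 2 missed and 1 false positive
        p, s, flag = detection_counts(tp=43, fp=1, fn=2)
        assert s == pytest.approx(0.956, abs=5e-4)
        assert p == pytest.approx(0.978, abs=1.5e-3)
        assert not flag

    def test_degenerate(self):
        p, s, flag = detection_counts(0, 0, 0)
        assert (p, s, flag) == (1.0, 1.0, True)

    def test_simple(self):
        p, s, flag = detection_counts(1, 1, 1)
        assert (p, s) == (0.5, 0.5)

    def test_from_result(self):
        r = DetectionResult([(0, 1)], [1], [2], 1)
        p, s, _ = precision_sensitivity(r)
        assert p == 0.5 and s == 0.5


def _scan(shape, gt_blobs, props):
    g = np.zeros(shape, np.uint8)
    for lab, vox in enumerate(gt_blobs, start=1):
        for v in vox:
            g[tuple(v)] = lab
    return [(_prop(v, c)) for v, c in props], g


class TestFroc:
    def test_perfect_detector(self):
        props, gt = _scan((8, 8, 8), [[(2, 2, 2)]], [([[2, 2, 2]], 1.0)])
        curve = froc([(props, gt)], gt_dilation_vox=0)
        assert (1.0, 1.0, 0.0) in [(t if np.isfinite(t) else 1.0, s, f)
                                   for t, s, f in curve.points]
        assert froc_auc(curve) == 1.0

    def test_empty_detector(self):
        _, gt = _scan((8, 8, 8), [[(2, 2, 2)]], [])
        curve = froc([([], gt)])
        assert froc_auc(curve) == 0.0

    def test_no_gt_anywhere_raises(self):
        with pytest.raises(ValueError):
            froc([([], np.zeros((4, 4, 4), np.uint8))])

    def test_three_point_enumeration(self):
        """2 scans, confidences (0.9 TP, 0.7 FP, 0.4 TP)."""
        s1_props, s1_gt = _scan((8, 8, 8), [[(2, 2, 2)]],
                                [([[2, 2, 2]], 0.9), ([[6, 6, 6]], 0.7)])
        s2_props, s2_gt = _scan((8, 8, 8), [[(3, 3, 3)]],
                                [([[3, 3, 3]], 0.4)])
        curve = froc([(s1_props, s1_gt), (s2_props, s2_gt)], gt_dilation_vox=0)
        ops = [(s, f) for t, s, f in curve.points if np.isfinite(t)]
        assert ops == [(0.5, 0.0), (0.5, 0.5), (1.0, 0.5)]

    def test_monotone_sensitivity_vs_fp_budget(self):
        rng = np.random.default_rng(0)
        scans = []
        for _ in range(4):
            blobs = [[(int(rng.integers(12)),) * 3]]
            props = [([[int(rng.integers(12))] * 3], float(rng.random()))
                     for _ in range(5)]
            scans.append(_scan((12, 12, 12), blobs, props))
        curve = froc(scans)
        # along descending tau both sensitivity and FP/scan never decrease
        sens = curve.sensitivities()
        fps = curve.fp_rates()
        assert np.all(np.diff(sens) >= -1e-12)
        assert np.all(np.diff(fps) >= -1e-12)
        # conservation: TP + FN is fixed at every operating point
        assert np.all(sens * curve.n_gt <= curve.n_gt)


class TestFrocAuc:
    def test_step_function_example(self):
        curve = FrocCurve([(np.inf, 0.0, 0.0), (0.9, 0.8, 0.0),
                           (0.5, 1.0, 0.75)], n_scans=4, n_gt=5)
        assert froc_auc(curve) == pytest.approx((0.8 * 4 + 1.0) / 5)

    def test_bounds(self):
        curve = FrocCurve([(np.inf, 0.0, 0.0)], 1, 1)
        assert froc_auc(curve) == 0.0
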