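"""Segmentation metrics, fracture-level detection matching, and FROC.

Voxel overlap is scored by the Dice coefficient 2TP/(2TP+FP+FN) and the
intersection over union TP/(TP+FP+FN), related by IoU = Dice/(2−Dice).
Detection performance compares fracture proposals with labeled ground-truth
fractures: a proposal hits a fracture if it intersects the fracture's voxels
dilated by a small margin; assignment is greedy by descending confidence
with each side matched at most once. Sensitivity against false positives
per scan over all confidence operating points forms the FROC curve,
summarized by averaging sensitivity at 1/16, 1/8, 1/4, 1/2 and 1 FP/scan.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .inference import FractureProposal

FROC_FP_RATES = (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0)


def _as_bool(a) -> np.ndarray:
    return np.asarray(a).astype(bool)


def dice(a, b) -> float:
    """2|a∩b| / (|a|+|b|); two empty masks count as perfect agreement."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou(a, b) -> float:
    """|a∩b| / |a∪b|; two empty masks count as 1.0."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def detection_counts(tp: int, fp: int, fn: int) -> Tuple[float, float, bool]:
    """precision TP/(TP+FP), sensitivity TP/(TP+FN); degenerate -> 1.0 + flag."""
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp > 0 else 1.0
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 1.0
    return precision, sensitivity, degenerate


@dataclasses.dataclass
class DetectionResult:
    """Matching outcome over one or more scans."""

    matches: List[Tuple[int, int]]      # (proposal index, ground-truth id)
    unmatched_proposals: List[int]      # FP
    unmatched_gt: List[int]             # FN
    n_scans: int = 1

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fp(self) -> int:
        return len(self.unmatched_proposals)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    def combined(self, other: "DetectionResult") -> "DetectionResult":
        return DetectionResult(self.matches + other.matches,
                               self.unmatched_proposals + other.unmatched_proposals,
                               self.unmatched_gt + other.unmatched_gt,
                               self.n_scans + other.n_scans)


def _gt_dilated_sets(gt_labeled: np.ndarray,
                     gt_dilation_vox: int) -> Dict[int, set]:
    """Flat-index voxel sets of each labeled fracture, dilated for matching."""
    gt_labeled = np.asarray(gt_labeled)
    struct = ndimage.generate_binary_structure(3, 3)
    gt_sets: Dict[int, set] = {}
    for g in sorted(int(v) for v in np.unique(gt_labeled) if v != 0):
        m = gt_labeled == g
        if gt_dilation_vox > 0:
            m = ndimage.binary_dilation(m, struct, iterations=gt_dilation_vox)
        gt_sets[g] = set(np.flatnonzero(m.ravel()).tolist())
    return gt_sets


def _match_against_sets(proposals: Sequence[FractureProposal],
                        gt_sets: Dict[int, set],
                        shape) -> DetectionResult:
    gt_ids = sorted(gt_sets)
    order = sorted(range(len(proposals)),
                   key=lambda i: -proposals[i].confidence)
    matched_gt = set()
    matches, fps = [], []
    for i in order:
        vox = proposals[i].voxels
        flat = set(np.ravel_multi_index(vox.T, shape).tolist())
        best, best_overlap = None, 0
        for g in gt_ids:
            if g in matched_gt:
                continue
            ov = len(flat & gt_sets[g])
            if ov > best_overlap:
                best, best_overlap = g, ov
        if best is not None:
            matches.append((i, best))
            matched_gt.add(best)
        else:
            fps.append(i)
    fns = [g for g in gt_ids if g not in matched_gt]
    return DetectionResult(matches, fps, fns, n_scans=1)


def match_detections(proposals: Sequence[FractureProposal],
                     gt_labeled: np.ndarray,
                     gt_dilation_vox: int = 2) -> DetectionResult:
    """Greedy one-to-one matching of proposals against labeled fractures.

    A proposal hits fracture g if its voxels intersect g's voxels dilated by
    ``gt_dilation_vox``; proposals are visited in descending confidence and
    each proposal / fracture is matched at most once.
    """
    gt_labeled = np.asarray(gt_labeled)
    gt_sets = _gt_dilated_sets(gt_labeled, gt_dilation_vox)
    return _match_against_sets(proposals, gt_sets, gt_labeled.shape)


def precision_sensitivity(r: DetectionResult) -> Tuple[float, float, bool]:
    return detection_counts(r.tp, r.fp, r.fn)


@dataclasses.dataclass
class FrocCurve:
    """Operating points (tau, sensitivity, fp_per_scan), tau descending."""

    points: List[Tuple[float, float, float]]
    n_scans: int
    n_gt: int

    def sensitivities(self):
        return np.array([p[1] for p in self.points])

    def fp_rates(self):
        return np.array([p[2] for p in self.points])


def froc(scan_results: Sequence[Tuple[Sequence[FractureProposal], np.ndarray]],
         gt_dilation_vox: int = 2) -> FrocCurve:
    """FROC over all distinct proposal confidences.

    ``scan_results`` is a list of (proposals, labeled ground truth) per scan.
    For each distinct confidence tau (descending) the matching is recomputed
    on proposals with confidence ≥ tau. The curve includes the empty
    endpoint (tau above every confidence: sensitivity 0, 0 FP/scan).
    """
    n_scans = len(scan_results)
    n_gt = sum(len([g for g in np.unique(gt) if g != 0])
               for _, gt in scan_results)
    if n_gt == 0:
        raise ValueError("no ground-truth fractures; sensitivity undefined")
    confs = sorted({p.confidence for props, _ in scan_results for p in props},
                   reverse=True)
    prepared = [(props, _gt_dilated_sets(gt, gt_dilation_vox), np.asarray(gt).shape)
                for props, gt in scan_results]
    points = [(np.inf, 0.0, 0.0)]
    for tau in confs:
        tp = fp = 0
        for props, gt_sets, shape in prepared:
            kept = [p for p in props if p.confidence >= tau]
            r = _match_against_sets(kept, gt_sets, shape)
            tp += r.tp
            fp += r.fp
        points.append((tau, tp / n_gt, fp / n_scans))
    return FrocCurve(points, n_scans, n_gt)


def froc_auc(curve: FrocCurve, fp_rates=FROC_FP_RATES) -> float:
    """Average, over the target FP/scan rates, of the best sensitivity
    achievable at or below each rate (0 if no operating point qualifies)."""
    sens = curve.sensitivities()
    fps = curve.fp_rates()
    vals = []
    for rate in fp_rates:
        ok = fps <= rate + 1e-12
        vals.append(float(sens[ok].max()) if ok.any() else 0.0)
    return float(np.mean(vals))


def evaluate_scans(scan_results, gt_dilation_vox: int = 2,
                   gt_kinds=None) -> dict:
    """Aggregate detection report over scans: counts, ratios and FROC.

    ``gt_kinds``, when given, maps (scan index, ground-truth label) to a
    fracture kind ("nondisplaced"/"displaced"); the report then carries
    per-kind sensitivity (precision has no per-kind analogue because
    proposals are not typed).
    """
    total = DetectionResult([], [], [], 0)
    kind_counts: Dict[str, List[int]] = {}
    for idx, (props, gt) in enumerate(scan_results):
        r = match_detections(props, gt, gt_dilation_vox)
        total = total.combined(r)
        if gt_kinds is not None:
            for _, g in r.matches:
                k = gt_kinds.get((idx, g))
                if k:
                    kind_counts.setdefault(k, [0, 0])[0] += 1
            for g in r.unmatched_gt:
                k = gt_kinds.get((idx, g))
                if k:
                    kind_counts.setdefault(k, [0, 0])[1] += 1
    precision, sensitivity, degenerate = precision_sensitivity(total)
    report = dict(tp=total.tp, fp=total.fp, fn=total.fn,
                  n_scans=len(scan_results),
                  precision=precision, sensitivity=sensitivity,
                  degenerate=degenerate)
    if gt_kinds is not None:
        report["sensitivity_by_kind"] = {
            k: tp / (tp + fn) if tp + fn else 1.0
            for k, (tp, fn) in sorted(kind_counts.items())}
    try:
        curve = froc(scan_results, gt_dilation_vox)
        report["froc_points"] = [(float(t) if np.isfinite(t) else None, s, f)
                                 for t, s, f in curve.points]
        report["froc_auc"] = froc_auc(curve)
    except ValueError:
        report["froc_auc"] = None
    return report
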