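"""Detection and pose evaluation.

Implements the evaluation chain used throughout the toolkit: axis-aligned
IoU, confidence filtering (default threshold 0.001 for detection, 0.2 for
pose), greedy NMS at IoU 0.65, COCO-style AP/AR averaged over IoU thresholds
0.50:0.05:0.95 (101-point interpolated precision, max-recall AR, single
category, up to 100 detections per image), object keypoint similarity (OKS),
the per-person IoU scoring rule (matched IoU counted only when it reaches
0.75, else 0), and the ln(width/height) bounding-box aspect diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cocoio import AnnotationRecord, Detection
from .errors import ParameterError

__all__ = [
    "EvalConfig",
    "ScoreEntry",
    "ScoreVector",
    "EvalSummary",
    "KEYPOINT_SIGMAS",
    "iou",
    "filter_confidence",
    "nms",
    "score_persons",
    "ap_ar",
    "oks",
    "aspect_log_ratio",
]

#: Per-keypoint COCO falloff constants sigma; the OKS kernel uses k = 2*sigma.
KEYPOINT_SIGMAS = np.array(
    [
        0.026, 0.025, 0.025, 0.035, 0.035, 0.079, 0.079, 0.072, 0.072,
        0.062, 0.062, 0.107, 0.107, 0.087, 0.087, 0.089, 0.089,
    ]
)


@dataclass(frozen=True)
class EvalConfig:
    conf_threshold_detect: float = 0.001
    conf_threshold_pose: float = 0.2
    nms_iou: float = 0.65
    score_iou_threshold: float = 0.75
    binary_score: bool = False  # score 1/0 instead of matched-IoU/0
    max_detections: int = 100
    ap_iou_grid: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))

    def __post_init__(self) -> None:
        for t in (
            self.conf_threshold_detect,
            self.conf_threshold_pose,
            self.nms_iou,
            self.score_iou_threshold,
        ):
            if not (0.0 <= t <= 1.0):
                raise ParameterError("thresholds must lie in [0, 1]")
        if np.any(np.diff(self.ap_iou_grid) <= 0):
            raise ParameterError("IoU grid must be strictly increasing")


@dataclass(frozen=True)
class ScoreEntry:
    image_id: int
    gt_id: int
    matched_iou: float
    score: float


@dataclass
class ScoreVector:
    """One entry per ground-truth person; the input to all statistics."""

    entries: list[ScoreEntry] = field(default_factory=list)

    @property
    def scores(self) -> np.ndarray:
        return np.array([e.score for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EvalSummary:
    """Mean AP / AR over the IoU grid, in percent, with the per-threshold sweep."""

    ap: float | None
    ar: float | None
    per_threshold: dict[float, tuple[float, float]]


# ---------------------------------------------------------------------------
# primitives


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two continuous [x, y, w, h] boxes."""
    xa, ya, wa, ha = box_a
    xb, yb, wb, hb = box_b
    if min(wa, ha, wb, hb) < 0:
        raise ParameterError("boxes must have non-negative width/height")
    ix = max(0.0, min(xa + wa, xb + wb) - max(xa, xb))
    iy = max(0.0, min(ya + ha, yb + hb) - max(ya, yb))
    inter = ix * iy
    union = wa * ha + wb * hb - inter
    if union <= 0:
        return 0.0
    # clamp: roundoff in (x + w) - x can nudge the ratio past 1
    return min(1.0, max(0.0, inter / union))


def filter_confidence(
    detections: list[Detection], threshold: float
) -> list[Detection]:
    """Keep detections with confidence >= threshold, preserving order."""
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError("threshold must lie in [0, 1]")
    return [d for d in detections if d.confidence >= threshold]


def nms(detections: list[Detection], iou_threshold: float = 0.65) -> list[Detection]:
    """Greedy non-maximum suppression within each image.

    Repeatedly keeps the highest-confidence remaining detection and discards
    others overlapping it with IoU > threshold. Ties in confidence are broken
    by input order (earlier wins), making the result deterministic.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ParameterError("iou_threshold must lie in [0, 1]")
    kept: list[Detection] = []
    by_image: dict[int, list[tuple[int, Detection]]] = {}
    for i, d in enumerate(detections):
        by_image.setdefault(d.image_id, []).append((i, d))
    for _, group in sorted(by_image.items()):
        # stable sort: equal confidences stay in input order
        group = sorted(group, key=lambda t: -t[1].confidence)
        alive = list(group)
        while alive:
            _, best = alive.pop(0)
            kept.append(best)
            alive = [
                (i, d) for i, d in alive if iou(best.bbox, d.bbox) <= iou_threshold
            ]
    return kept


# ---------------------------------------------------------------------------
# per-person scoring


def score_persons(
    ground_truths: list[AnnotationRecord],
    detections: list[Detection],
    config: EvalConfig = EvalConfig(),
) -> ScoreVector:
    """Per ground-truth person score under the 0.75-IoU rule.

    Matching is one-to-one and globally greedy: the highest-IoU unmatched
    (ground truth, detection) pair is fixed first, ties broken by higher
    detection confidence then lower ground-truth id. A person scores its
    matched IoU when that reaches ``score_iou_threshold`` and 0 otherwise
    (or 1/0 with ``binary_score``); unmatched persons score 0. Detections are
    expected to be confidence-filtered and NMS-processed already.
    """
    entries: list[ScoreEntry] = []
    gts_by_image: dict[int, list[AnnotationRecord]] = {}
    for gt in ground_truths:
        gts_by_image.setdefault(gt.image_id, []).append(gt)
    dets_by_image: dict[int, list[Detection]] = {}
    for d in detections:
        dets_by_image.setdefault(d.image_id, []).append(d)

    for image_id, gts in sorted(gts_by_image.items()):
        dets = dets_by_image.get(image_id, [])
        pairs = [
            (iou(gt.bbox, d.bbox), d.confidence, gt.id, gi, di)
            for gi, gt in enumerate(gts)
            for di, d in enumerate(dets)
        ]
        pairs.sort(key=lambda p: (-p[0], -p[1], p[2]))
        matched_gt: dict[int, float] = {}
        used_det: set[int] = set()
        for ov, _conf, _gid, gi, di in pairs:
            if gi in matched_gt or di in used_det or ov <= 0.0:
                continue
            matched_gt[gi] = ov
            used_det.add(di)
        for gi, gt in enumerate(gts):
            ov = matched_gt.get(gi, 0.0)
            if ov >= config.score_iou_threshold:
                score = 1.0 if config.binary_score else ov
            else:
                score = 0.0
            entries.append(ScoreEntry(image_id, gt.id, ov, score))
    return ScoreVector(entries)


# ---------------------------------------------------------------------------
# AP / AR

_RECALL_GRID = np.linspace(0.0, 1.0, 101)


def _match_at_threshold(
    gts_by_image: dict[int, list[AnnotationRecord]],
    dets: list[Detection],
    thr: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Confidence-ranked greedy matching (COCO convention) at one threshold."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    n_gt = sum(len(g) for g in gts_by_image.values())
    matched: dict[int, set[int]] = {im: set() for im in gts_by_image}
    tp = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        d = dets[i]
        gts = gts_by_image.get(d.image_id, [])
        best, best_ov = -1, thr
        for gi, gt in enumerate(gts):
            if gi in matched.get(d.image_id, set()):
                continue
            ov = iou(gt.bbox, d.bbox)
            if ov >= best_ov:
                best, best_ov = gi, ov
        if best >= 0:
            matched[d.image_id].add(best)
            tp[rank] = True
    return tp, np.array([dets[i].confidence for i in order]), n_gt


def ap_ar(
    ground_truths: list[AnnotationRecord],
    detections: list[Detection],
    config: EvalConfig = EvalConfig(),
) -> EvalSummary:
    """COCO-style mean AP / AR over the IoU grid, in percent.

    Per threshold: detections (top ``max_detections`` per image by
    confidence) are greedily matched across the whole set in global
    confidence order; AP is the 101-point interpolated area under the
    precision-recall curve and AR the final recall. Returns None markers when
    there are no ground truths.
    """
    if not ground_truths:
        return EvalSummary(None, None, {})
    gts_by_image: dict[int, list[AnnotationRecord]] = {}
    for gt in ground_truths:
        gts_by_image.setdefault(gt.image_id, []).append(gt)
    by_image: dict[int, list[Detection]] = {}
    for d in detections:
        by_image.setdefault(d.image_id, []).append(d)
    capped: list[Detection] = []
    for im in sorted(by_image):
        group = sorted(by_image[im], key=lambda d: -d.confidence)
        capped.extend(group[: config.max_detections])

    per_threshold: dict[float, tuple[float, float]] = {}
    for thr in config.ap_iou_grid:
        if not capped:
            per_threshold[thr] = (0.0, 0.0)
            continue
        tp, _conf, n_gt = _match_at_threshold(gts_by_image, capped, thr)
        cum_tp = np.cumsum(tp)
        precision = cum_tp / np.arange(1, len(tp) + 1)
        recall = cum_tp / n_gt
        # monotone envelope, then 101-point interpolation
        for i in range(len(precision) - 2, -1, -1):
            precision[i] = max(precision[i], precision[i + 1])
        idx = np.searchsorted(recall, _RECALL_GRID, side="left")
        interp = np.where(idx < len(precision), precision[np.minimum(idx, len(precision) - 1)], 0.0)
        ap = float(np.mean(interp))
        ar = float(recall[-1]) if len(recall) else 0.0
        per_threshold[thr] = (100.0 * ap, 100.0 * ar)
    aps = [v[0] for v in per_threshold.values()]
    ars = [v[1] for v in per_threshold.values()]
    return EvalSummary(float(np.mean(aps)), float(np.mean(ars)), per_threshold)


# ---------------------------------------------------------------------------
# OKS and aspect diagnostics


def oks(
    gt: AnnotationRecord,
    pred_keypoints: np.ndarray,
    sigmas: np.ndarray = KEYPOINT_SIGMAS,
) -> float | None:
    """Object keypoint similarity between a ground truth and a prediction.

    ``OKS = mean_i exp(-d_i^2 / (2 s^2 k_i^2))`` over labelled keypoints
    (v > 0), with d_i the pixel distance, s^2 the ground-truth area and
    k_i = 2 * sigma_i. Returns None when no keypoint is labelled.
    """
    if gt.area <= 0:
        raise ParameterError("ground truth must have positive area")
    if gt.keypoints is None:
        return None
    labelled = gt.keypoints[:, 2] > 0
    if not labelled.any():
        return None
    pred = np.asarray(pred_keypoints, float)[:, :2]
    d2 = np.sum((pred[labelled] - gt.keypoints[labelled, :2]) ** 2, axis=1)
    k = 2.0 * np.asarray(sigmas)[labelled]
    return float(np.mean(np.exp(-d2 / (2.0 * gt.area * k**2))))


def aspect_log_ratio(
    bboxes: np.ndarray, bins: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-box ln(width/height) plus a normalised histogram density.

    Lower values indicate more upright instances, higher values more
    lying-down ones; 0 is a square box. Returns (values, bin_edges, density)
    with the density integrating to 1.
    """
    boxes = np.atleast_2d(np.asarray(bboxes, float))
    w, h = boxes[:, 2], boxes[:, 3]
    if np.any(w <= 0) or np.any(h <= 0):
        raise ParameterError("boxes must have positive width and height")
    values = np.log(w / h)
    density, edges = np.histogram(values, bins=bins, density=True)
    return values, edges, density
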