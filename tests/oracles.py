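"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain loops, separate from the
vectorised library code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def iou_cell_count(box_a, box_b) -> float:
    """IoU of two integer-coordinate boxes by exhaustive unit-cell counting."""
    ax, ay, aw, ah = (int(v) for v in box_a)
    bx, by, bw, bh = (int(v) for v in box_b)
    cells_a = {(x, y) for x in range(ax, ax + aw) for y in range(ay, ay + ah)}
    cells_b = {(x, y) for x in range(bx, bx + bw) for y in range(by, by + bh)}
    union = cells_a | cells_b
    if not union:
        return 0.0
    return len(cells_a & cells_b) / len(union)


def iou_float(box_a, box_b) -> float:
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix = min(ax + aw, bx + bw) - max(ax, bx)
    iy = min(ay + ah, by + bh) - max(ay, by)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (aw * ah + bw * bh - inter)


def greedy_nms(boxes, scores, threshold):
    """Reference greedy NMS; returns kept indices in keep order."""
    remaining = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            i for i in remaining if iou_float(boxes[best], boxes[i]) <= threshold
        ]
    return kept


def reference_ap_ar(gts, dets, thresholds, max_det=100):
    """Loop-based COCO-style AP/AR (percent), single category.

    ``gts``: list of (image_id, box). ``dets``: list of (image_id, box,
    score). 101-point interpolated AP, final recall as AR, averaged over
    thresholds.
    """
    aps, ars = [], []
    image_ids = sorted({im for im, _ in gts} | {im for im, _, _ in dets})
    capped = []
    for im in image_ids:
        group = [d for d in dets if d[0] == im]
        group.sort(key=lambda d: -d[2])
        capped.extend(group[:max_det])
    n_gt = len(gts)
    for thr in thresholds:
        order = sorted(range(len(capped)), key=lambda i: (-capped[i][2], i))
        matched = set()
        flags = []
        for i in order:
            im, box, _ = capped[i]
            best_gi, best_ov = None, thr
            for gi, (gim, gbox) in enumerate(gts):
                if gim != im or gi in matched:
                    continue
                ov = iou_float(gbox, box)
                if ov >= best_ov:
                    best_gi, best_ov = gi, ov
            if best_gi is not None:
                matched.add(best_gi)
                flags.append(True)
            else:
                flags.append(False)
        tp = 0
        precisions, recalls = [], []
        for k, is_tp in enumerate(flags):
            tp += is_tp
            precisions.append(tp / (k + 1))
            recalls.append(tp / n_gt)
        for i in range(len(precisions) - 2, -1, -1):
            precisions[i] = max(precisions[i], precisions[i + 1])
        ap = 0.0
        for r in np.linspace(0, 1, 101):
            p = 0.0
            for prec, rec in zip(precisions, recalls):
                if rec >= r - 1e-12:
                    p = prec
                    break
            ap += p / 101.0
        aps.append(100.0 * ap)
        ars.append(100.0 * (recalls[-1] if recalls else 0.0))
    return float(np.mean(aps)), float(np.mean(ars))


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p-value by full sign enumeration."""
    d = np.asarray([x for x in diffs if x != 0], float)
    n = d.size
    ranks = np.empty(n)
    order = np.argsort(np.abs(d))
    ranks[order] = np.arange(1, n + 1)
    w_plus = float(np.sum(ranks[d > 0]))
    total = 0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(np.sum(ranks[np.array(signs, bool)]))
        stat = min(w, n * (n + 1) / 2 - w)
        if stat <= min(w_plus, n * (n + 1) / 2 - w_plus) + 1e-12:
            count += 1
        total += 1
    return count / total


def triangle_coverage(tri, width, height):
    """Pixel centres inside a 2D triangle by explicit half-plane tests."""
    (x0, y0), (x1, y1), (x2, y2) = tri
    covered = set()

    def edge(ax, ay, bx, by, px, py):
        return (bx - ax) * (py - ay) - (by - ay) * (px - ax)

    area = edge(x0, y0, x1, y1, x2, y2)
    for px in range(width):
        for py in range(height):
            cx, cy = px + 0.5, py + 0.5
            e0 = edge(x0, y0, x1, y1, cx, cy) * np.sign(area)
            e1 = edge(x1, y1, x2, y2, cx, cy) * np.sign(area)
            e2 = edge(x2, y2, x0, y0, cx, cy) * np.sign(area)
            if e0 >= 0 and e1 >= 0 and e2 >= 0:
                covered.add((px, py))
    return covered


def mesh_volume(vertices, faces) -> float:
    """Divergence-theorem volume of a consistently wound triangle soup."""
    tri = vertices[faces]
    return float(
        np.sum(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0
    )
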