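"""Independent brute-force oracles used by the test suite.

Deliberately naive (explicit loops, exhaustive enumeration, grid search) and
kept free of any code path from the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def gamma_table_bruteforce(L, bins):
    """Per-level histogram statistics and gamma exponents via explicit loops."""
    flat = [float(v) for row in L for v in row]
    n_p = len(flat)
    counts = [0] * bins
    for v in flat:
        lvl = int(min(v, math.nextafter(1.0, 0.0)) * bins)
        counts[lvl] += 1
    pdf = [c / n_p for c in counts]
    p_min, p_max = min(pdf), max(pdf)
    occupied = sum(1 for c in counts if c > 0)
    if p_max == p_min or occupied <= 1:
        return {"counts": counts, "pdf": pdf, "weights": [0.0] * bins,
                "sp": 0.0, "gamma": [1.0] * bins, "degenerate": True}
    weights = [(p - p_min) / (p_max - p_min) for p in pdf]
    sp = sum(weights)
    gamma, acc = [], 0.0
    for l in range(bins):
        acc += weights[l]
        gamma.append(min(1.0, max(0.0, 1.0 - acc / sp)))
    return {"counts": counts, "pdf": pdf, "weights": weights,
            "sp": sp, "gamma": gamma, "degenerate": False}


def wls_objective(points_xyw, m, b):
    return sum(w * (y - (m * x + b)) ** 2 for x, y, w in points_xyw)


def wls_grid_search(points_xyw, m_range=(-5.0, 5.0), b_range=(-30.0, 30.0),
                    grid=81, rounds=9):
    """Minimise the weighted residual sum over a zooming (m, b) grid.

    The zoom window shrinks by only 4x per round so the narrow diagonal
    valley of the (m, b) objective cannot escape it between rounds.
    """
    x = np.array([p[0] for p in points_xyw])
    y = np.array([p[1] for p in points_xyw])
    w = np.array([p[2] for p in points_xyw])
    m_lo, m_hi = m_range
    b_lo, b_hi = b_range
    best = (0.0, 0.0)
    for _ in range(rounds):
        ms = np.linspace(m_lo, m_hi, grid)
        bs = np.linspace(b_lo, b_hi, grid)
        S = ((w[None, None, :] *
              (y[None, None, :] - (ms[:, None, None] * x[None, None, :]
                                   + bs[None, :, None])) ** 2).sum(axis=2))
        i, j = np.unravel_index(np.argmin(S), S.shape)
        best = (float(ms[i]), float(bs[j]))
        m_half, b_half = (m_hi - m_lo) / 8, (b_hi - b_lo) / 8
        m_lo, m_hi = best[0] - m_half, best[0] + m_half
        b_lo, b_hi = best[1] - b_half, best[1] + b_half
    return best


def wls_normal_equations(points_xyw):
    """Closed-form 2x2 weighted normal equations via Cramer's rule."""
    sw = sum(w for _, _, w in points_xyw)
    sx = sum(w * x for x, _, w in points_xyw)
    sy = sum(w * y for _, y, w in points_xyw)
    sxx = sum(w * x * x for x, _, w in points_xyw)
    sxy = sum(w * x * y for x, y, w in points_xyw)
    det = sxx * sw - sx * sx
    return ((sxy * sw - sx * sy) / det, (sxx * sy - sx * sxy) / det)


def iou_corners(a, b):
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def optimal_assignment_counts(det_corners, gt_corners, iou_min):
    """Maximum-TP one-to-one assignment by exhaustive enumeration (small n)."""
    n_d, n_g = len(det_corners), len(gt_corners)
    best_tp = 0
    gt_idx = list(range(n_g))
    for k in range(min(n_d, n_g), 0, -1):
        for det_subset in itertools.combinations(range(n_d), k):
            for gt_perm in itertools.permutations(gt_idx, k):
                if all(iou_corners(det_corners[d], gt_corners[g]) >= iou_min
                       for d, g in zip(det_subset, gt_perm)):
                    best_tp = max(best_tp, k)
                    break
            if best_tp == k:
                break
        if best_tp:
            break
    return {"tp": best_tp, "fp": n_d - best_tp, "fn": n_g - best_tp}


def ap_threshold_enumeration(dets, gts, iou_min):
    """AP by explicit rank-by-rank PR construction and envelope integration.

    dets: list of (corners, confidence); gts: list of corners.  Greedy
    confidence-descending matching recomputed from scratch at every rank
    (equivalent to sweeping the confidence threshold through every value).
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    pr_points = []
    for rank in range(1, len(dets) + 1):
        kept = [dets[i][0] for i in order[:rank]]
        taken = [False] * len(gts)
        tp = 0
        for d in kept:
            best, best_iou = -1, iou_min
            for j, g in enumerate(gts):
                if taken[j]:
                    continue
                v = iou_corners(d, g)
                if v >= best_iou and v > 0 and (v > best_iou or best < 0):
                    best, best_iou = j, v
            if best >= 0:
                taken[best] = True
                tp += 1
        pr_points.append((tp / len(gts), tp / rank))
    ap = 0.0
    prev_r = 0.0
    for idx, (r, _) in enumerate(pr_points):
        env = max(p for rr, p in pr_points[idx:])
        ap += (r - prev_r) * env
        prev_r = r
    return ap


def nearest_odd_kernel(c_in):
    """Exhaustive nearest-odd evaluation of (log2 C + 1)/2; midpoint -> larger."""
    t = (math.log2(c_in) + 1.0) / 2.0
    return max(1, min(range(1, 33, 2), key=lambda k: (abs(t - k), -k)))


def maxpool_naive(t, k):
    """Stride-1 kxk max pool with -inf padding, explicit loops."""
    C, H, W = t.shape
    r = k // 2
    out = np.empty_like(t)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                ys = slice(max(0, i - r), min(H, i + r + 1))
                xs = slice(max(0, j - r), min(W, j + r + 1))
                out[c, i, j] = t[c, ys, xs].max()
    return out
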