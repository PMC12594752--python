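"""Independent brute-force oracles used by the test suite.

These deliberately use naive enumeration (explicit loops over pairs, window
positions and candidate thresholds) so they share no code path with the
package implementations they check.
"""

import numpy as np


def auroc_pairs(scores, labels):
    """Mann-Whitney by direct enumeration of (abnormal, normal) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def auprc_stepwise(scores, labels):
    """Step-wise PR area: sum (R_k - R_{k-1}) P_k over descending thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def dice_direct(pred, gt):
    p = np.asarray(pred, dtype=bool)
    g = np.asarray(gt, dtype=bool)
    if p.sum() + g.sum() == 0:
        return 1.0
    return 2.0 * np.logical_and(p, g).sum() / (p.sum() + g.sum())


def patch_max_windows(vals, p, s):
    """Max of window means over an edge-aligned sliding grid, by loops."""
    h, w = vals.shape

    def positions(extent):
        pos = list(range(0, extent - p + 1, s))
        if pos[-1] != extent - p:
            pos.append(extent - p)
        return pos

    best = -np.inf
    for i in positions(h):
        for j in positions(w):
            best = max(best, vals[i : i + p, j : j + p].mean())
    return best


def best_accuracy_scan(scores, labels_bool):
    """Best achievable accuracy of 'abnormal iff score > thr' over all
    candidate thresholds (midpoints plus extremes)."""
    uniq = np.unique(scores)
    cands = [uniq[0] - 1] + list((uniq[:-1] + uniq[1:]) / 2) + [uniq[-1] + 1]
    return max(np.mean((scores > t) == labels_bool) for t in cands)


def mean_dice_at(maps, masks, lam):
    return float(
        np.mean([dice_direct(m > lam, g) for m, g in zip(maps, masks)])
    )
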