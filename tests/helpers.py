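"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by brute force (pair counting,
exhaustive chord checks, direct count enumeration) so that curve-based
implementations are checked against a second, unrelated route.
"""

from __future__ import annotations

import numpy as np

from curveval import ScoredDataset


def pair_count_auc(ds: ScoredDataset) -> float:
    """Mann-Whitney pair-counting AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = ds.scores[ds.labels]
    neg = ds.scores[~ds.labels]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def upper_hull_bruteforce(x: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    """O(n^3) upper-hull oracle: keep a point iff no chord of the point set
    passes strictly above it (on or above, for interior collinear points)."""
    pts = list(zip(x, y))
    keep = []
    for i, (px, py) in enumerate(pts):
        dominated = any(
            qx == px and qy > py for j, (qx, qy) in enumerate(pts) if j != i
        )
        for j in range(len(pts)):
            for k in range(len(pts)):
                ax, ay = pts[j]
                bx, by = pts[k]
                if ax <= px <= bx and bx > ax and (j != i and k != i):
                    chord = ay + (by - ay) * (px - ax) / (bx - ax)
                    if chord >= py - 1e-12:
                        dominated = True
        if not dominated:
            keep.append((px, py))
    # endpoints always belong to the hull
    for p in (pts[0], pts[-1]):
        if p not in keep:
            keep.append(p)
    return sorted(set(keep))


def pr_points_bruteforce(ds: ScoredDataset) -> list[tuple[int, int]]:
    """All (tp, fp) supports over distinct thresholds, by direct counting."""
    thresholds = np.unique(ds.scores)[::-1]
    out = []
    for t in thresholds:
        pred = ds.scores >= t
        out.append((int((pred & ds.labels).sum()), int((pred & ~ds.labels).sum())))
    return out


def auc_prc_bruteforce(ds: ScoredDataset) -> float:
    """Exhaustive PR area: every threshold, every unit-TP interpolation point,
    trapezoids over recall with the limit anchor at recall 0."""
    supports = [(0, 0)] + pr_points_bruteforce(ds)
    n_pos = ds.n_pos
    rec, prec = [], []
    for (tp_a, fp_a), (tp_b, fp_b) in zip(supports, supports[1:]):
        dtp = tp_b - tp_a
        if dtp == 0:
            if tp_b + fp_b > 0:
                rec.append(tp_b / n_pos)
                prec.append(tp_b / (tp_b + fp_b))
            continue
        skew = (fp_b - fp_a) / dtp
        for x in range(0, dtp + 1):
            tp = tp_a + x
            fp = fp_a + skew * x
            if tp + fp == 0:
                continue
            r = tp / n_pos
            p = tp / (tp + fp)
            if x == 0 and rec and rec[-1] == r:
                continue  # endpoint A already emitted
            rec.append(r)
            prec.append(p)
    if rec[0] > 0:  # anchor with the x -> 0 limit of the first segment
        tp1, fp1 = next(s for s in supports[1:] if sum(s) > 0)
        rec.insert(0, 0.0)
        prec.insert(0, tp1 / (tp1 + fp1) if tp1 > 0 else 0.0)
    return float(np.trapezoid(prec, rec))


def random_dataset(rng: np.random.Generator, n_pos: int, n_neg: int,
                   tie_fraction: float = 0.0) -> ScoredDataset:
    """Random scored dataset; with tie_fraction > 0 scores are discretised
    onto a coarse grid so tie blocks appear."""
    scores = rng.normal(size=n_pos + n_neg)
    if tie_fraction > 0:
        levels = max(2, int(round((n_pos + n_neg) * (1 - tie_fraction))))
        scores = np.round(scores * levels) / levels
    labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
    return ScoredDataset(scores, labels, np.zeros(n_pos + n_neg, bool))
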