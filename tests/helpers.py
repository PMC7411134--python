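"""Independent oracles used by the test suite.

Everything here is deliberately written as plain enumeration/arithmetic,
independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def gini(labels) -> float:
    labels = list(labels)
    n = len(labels)
    if n == 0:
        return 0.0
    p = sum(1 for y in labels if y == 1) / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def leaf_oracle(labels) -> tuple[int, float]:
    labels = list(labels)
    n_pos = sum(1 for y in labels if y == 1)
    n_neg = len(labels) - n_pos
    if n_pos > n_neg:
        return 1, n_pos / len(labels)
    return -1, n_neg / len(labels) if labels else 1.0


def brute_force_stump(features, labels):
    """Exhaustive Gini minimization over all midpoint thresholds.

    Returns (threshold, class_low, class_high, prob_low, prob_high) with the
    documented tie conventions: impurity ties -> smallest threshold, leaf
    majority ties -> -1, degenerate input -> threshold -inf.
    """
    pairs = sorted(zip(features, labels), key=lambda t: t[0])
    fs = [f for f, _ in pairs]
    ys = [y for _, y in pairs]
    n = len(ys)
    distinct = sorted(set(fs))
    if len(distinct) < 2 or len(set(ys)) < 2:
        cls, prob = leaf_oracle(ys)
        return float("-inf"), cls, cls, prob, prob
    best = None
    for a, b in zip(distinct[:-1], distinct[1:]):
        thr = (a + b) / 2.0
        left = [y for f, y in zip(fs, ys) if f <= thr]
        right = [y for f, y in zip(fs, ys) if f > thr]
        impurity = (len(left) * gini(left) + len(right) * gini(right)) / n
        if best is None or impurity < best[0] - 1e-12:
            best = (impurity, thr, left, right)
    _, thr, left, right = best
    cls_low, prob_low = leaf_oracle(left)
    cls_high, prob_high = leaf_oracle(right)
    return thr, cls_low, cls_high, prob_low, prob_high


def mcc_oracle(tp: int, tn: int, fp: int, fn: int) -> float:
    """Direct arithmetic of the Matthews correlation coefficient."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def rank_oracle(feature_matrix, labels, names):
    """Stable descending sort of scales by brute-force stump training MCC."""
    scored = []
    for j, name in enumerate(names):
        thr, cl, ch, _, _ = brute_force_stump(feature_matrix[:, j], labels)
        pred = [cl if f <= thr else ch for f in feature_matrix[:, j]]
        tp = sum(1 for y, p in zip(labels, pred) if y == 1 and p == 1)
        tn = sum(1 for y, p in zip(labels, pred) if y == -1 and p == -1)
        fp = sum(1 for y, p in zip(labels, pred) if y == -1 and p == 1)
        fn = sum(1 for y, p in zip(labels, pred) if y == 1 and p == -1)
        scored.append((name, mcc_oracle(tp, tn, fp, fn)))
    order = sorted(range(len(scored)), key=lambda j: -scored[j][1])
    return [scored[j] for j in order]


def ols_oracle(x, y):
    """Closed-form simple OLS slope/intercept/R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - ybar) ** 2)
    return slope, intercept, 1.0 - ss_res / ss_tot


def balanced_strategy_null_labels(strategy_ids, rng):
    """Labels exactly balanced within each strategy, independent of sequence."""
    strategy_ids = np.asarray(strategy_ids)
    labels = np.empty(strategy_ids.size, dtype=int)
    for sid in np.unique(strategy_ids):
        idx = np.flatnonzero(strategy_ids == sid)
        half = idx.size // 2
        block = np.array([1] * half + [-1] * (idx.size - half))
        rng.shuffle(block)
        labels[idx] = block
    return labels
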