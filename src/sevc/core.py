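"""Decision-stump ensemble with soft voting and Monte Carlo cross-validation.

One stump is trained per hydrophobicity scale on that scale's summed
feature, by exhaustive Gini-impurity threshold search.  Each stump votes
with its leaf's majority-class probability, signed by the class; the
ensemble prediction is the mean vote of the ``n`` most important stumps,
where importance is the stump's Matthews correlation coefficient on the
training data.  Model sizes 1..k are screened by repeated random 1:1
train/validation splits of the training set (MC-CV).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

NEG_INF = float("-inf")


@dataclass(frozen=True)
class DecisionStump:
    """One-level decision tree over a single scale's feature.

    Observations with feature <= ``threshold`` fall into the low leaf.
    ``prob_low``/``prob_high`` are the majority-class fractions of the
    corresponding training leaves, so votes are ``class * prob``.
    """

    scale_name: str
    threshold: float
    class_low: int
    class_high: int
    prob_low: float
    prob_high: float

    def vote(self, feature: float) -> float:
        if feature <= self.threshold:
            return self.class_low * self.prob_low
        return self.class_high * self.prob_high

    def votes(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        low = features <= self.threshold
        return np.where(low, self.class_low * self.prob_low, self.class_high * self.prob_high)

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        return np.where(features <= self.threshold, self.class_low, self.class_high)

    def to_dict(self) -> dict:
        return {
            "scale_name": self.scale_name,
            "threshold": self.threshold,
            "class_low": self.class_low,
            "class_high": self.class_high,
            "prob_low": self.prob_low,
            "prob_high": self.prob_high,
        }


def _leaf(labels: np.ndarray) -> tuple[int, float]:
    """Majority class and majority fraction; ties go to insoluble (-1)."""
    n_pos = int(np.sum(labels == 1))
    n = labels.size
    n_neg = n - n_pos
    if n_pos > n_neg:
        return 1, n_pos / n
    return -1, n_neg / n if n else 1.0


def train_stump(features: np.ndarray, labels: np.ndarray, scale_name: str = "") -> DecisionStump:
    """Fit a stump by minimizing leaf-size-weighted Gini impurity.

    Candidate thresholds are midpoints between consecutive distinct sorted
    feature values.  Impurity ties break toward the smallest threshold; leaf
    majority ties default to -1.  Single-class labels or constant features
    yield a degenerate stump with both leaves set to the overall majority and
    threshold at -inf.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 1 or features.shape != labels.shape:
        raise ValueError("features and labels must be equal-length 1-D arrays")
    if features.size < 1:
        raise ValueError("need at least one observation")
    n = features.size
    order = np.argsort(features, kind="stable")
    fs = features[order]
    ys = labels[order]

    boundaries = np.flatnonzero(fs[:-1] < fs[1:])  # split after index i
    single_class = np.all(ys == ys[0])
    if boundaries.size == 0 or single_class:
        cls, prob = _leaf(ys)
        return DecisionStump(scale_name, NEG_INF, cls, cls, prob, prob)

    cum_pos = np.cumsum(ys == 1)
    total_pos = cum_pos[-1]
    n_left = boundaries + 1
    pos_left = cum_pos[boundaries]
    n_right = n - n_left
    pos_right = total_pos - pos_left

    p_left = pos_left / n_left
    p_right = pos_right / n_right
    gini_left = 1.0 - p_left**2 - (1.0 - p_left) ** 2
    gini_right = 1.0 - p_right**2 - (1.0 - p_right) ** 2
    weighted = (n_left * gini_left + n_right * gini_right) / n

    # Impurity ties (exact or float-level) break toward the smallest threshold.
    best = int(np.flatnonzero(weighted <= weighted.min() + 1e-12)[0])
    i = boundaries[best]
    threshold = (fs[i] + fs[i + 1]) / 2.0
    cls_low, prob_low = _leaf(ys[: i + 1])
    cls_high, prob_high = _leaf(ys[i + 1 :])
    return DecisionStump(scale_name, threshold, cls_low, cls_high, prob_low, prob_high)


def stump_vote(stump: DecisionStump, feature: float) -> float:
    return stump.vote(feature)


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ContingencyMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ContingencyMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )

    def __add__(self, other: "ContingencyMatrix") -> "ContingencyMatrix":
        return ContingencyMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def mcc(c: ContingencyMatrix) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if c.total == 0:
        raise ValueError("empty contingency matrix")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def accuracy(c: ContingencyMatrix) -> float:
    if c.total == 0:
        raise ValueError("empty contingency matrix")
    return (c.tp + c.tn) / c.total


def _mcc_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return mcc(ContingencyMatrix.from_predictions(y_true, y_pred))


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class EnsembleModel:
    """Stumps in descending feature-importance order; the first ``n_included``
    vote."""

    stumps: list[DecisionStump]
    n_included: int
    modifier: "Mapping[str, float] | None" = None  # strategy_id -> offset on p

    def __post_init__(self) -> None:
        if not 1 <= self.n_included <= len(self.stumps):
            raise ValueError(
                f"n_included {self.n_included} out of range 1..{len(self.stumps)}"
            )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_included": self.n_included,
            "stumps": [s.to_dict() for s in self.stumps],
            "modifier": dict(self.modifier) if self.modifier is not None else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        payload = json.loads(Path(path).read_text())
        stumps = [DecisionStump(**d) for d in payload["stumps"]]
        return cls(stumps, payload["n_included"], payload["modifier"])


def _modifier_offsets(
    modifier: Mapping[str, float] | None, strategy_ids: Sequence[str] | None, n: int
) -> np.ndarray:
    if modifier is None:
        return np.zeros(n)
    if strategy_ids is None:
        raise ValueError("a modifier is set but no strategy ids were provided")
    get = modifier.get if hasattr(modifier, "get") else modifier.offsets.get  # type: ignore
    return np.asarray([get(s, 0.0) for s in strategy_ids], dtype=float)


def ensemble_predict(
    model: EnsembleModel,
    fm: FeatureMatrix,
    strategy_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous prediction p (mean vote + strategy offset) and class.

    Class is +1 iff p > 0, else -1.
    """
    included = model.stumps[: model.n_included]
    votes = np.column_stack([st.votes(fm.column(st.scale_name)) for st in included])
    p = votes.mean(axis=1)
    offsets = _modifier_offsets(model.modifier, strategy_ids, fm.n_constructs)
    p = p + offsets
    cls = np.where(p > 0, 1, -1)
    return p, cls


def rank_by_importance(
    fm: FeatureMatrix, labels: np.ndarray
) -> list[tuple[str, float]]:
    """Scales ordered by descending training MCC of their stump (stable)."""
    labels = np.asarray(labels, dtype=int)
    scores = []
    for j, name in enumerate(fm.scale_names):
        stump = train_stump(fm.values[:, j], labels, scale_name=name)
        scores.append((name, _mcc_from_labels(labels, stump.predict(fm.values[:, j]))))
    order = sorted(range(len(scores)), key=lambda j: -scores[j][1])  # stable
    return [scores[j] for j in order]


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation


@dataclass
class MCCVResult:
    """Per-(run, model size) validation metrics from repeated 1:1 splits.

    ``classes``/``continuous`` (optional) hold the per-observation discrete
    and continuous validation predictions, shaped (runs, sizes, n_val).
    """

    model_sizes: np.ndarray
    mcc: np.ndarray  # (runs, sizes)
    accuracy: np.ndarray  # (runs, sizes)
    val_indices: np.ndarray  # (runs, n_val) indices into the training set
    classes: np.ndarray | None = None  # int8 (runs, sizes, n_val)
    continuous: np.ndarray | None = None  # float32 (runs, sizes, n_val)

    @property
    def n_runs(self) -> int:
        return self.mcc.shape[0]

    def median_mcc(self) -> np.ndarray:
        return np.median(self.mcc, axis=0)

    def mad_mcc(self) -> np.ndarray:
        med = np.median(self.mcc, axis=0)
        return np.median(np.abs(self.mcc - med), axis=0)

    def median_accuracy(self) -> np.ndarray:
        return np.median(self.accuracy, axis=0)

    def mad_accuracy(self) -> np.ndarray:
        med = np.median(self.accuracy, axis=0)
        return np.median(np.abs(self.accuracy - med), axis=0)

    def overall_median_mcc(self) -> float:
        """Median over model sizes of the per-size median validation MCC."""
        return float(np.median(self.median_mcc()))

    def to_frame(self) -> pd.DataFrame:
        runs, sizes = self.mcc.shape
        return pd.DataFrame(
            {
                "run": np.repeat(np.arange(runs), sizes),
                "model_size": np.tile(self.model_sizes, runs),
                "mcc": self.mcc.ravel(),
                "accuracy": self.accuracy.ravel(),
            }
        )


def mc_cv(
    fm: FeatureMatrix,
    labels: np.ndarray,
    n_runs: int,
    seed: int | np.random.Generator,
    modifier: Mapping[str, float] | None = None,
    strategy_ids: Sequence[str] | None = None,
    model_sizes: Sequence[int] | None = None,
    keep_classes: bool = False,
    keep_continuous: bool = False,
) -> MCCVResult:
    """Monte Carlo cross-validation of ensembles of size 1..k.

    Each run draws an unstratified uniform 1:1 split of the provided
    training set, trains and ranks one stump per scale on the run's training
    half, and evaluates every requested model size on the identical
    validation half.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    labels = np.asarray(labels, dtype=int)
    n = fm.n_constructs
    if labels.shape != (n,):
        raise ValueError("labels must match the feature matrix rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = fm.n_scales
    sizes = np.asarray(model_sizes if model_sizes is not None else range(1, k + 1), dtype=int)
    if sizes.min() < 1 or sizes.max() > k:
        raise ValueError(f"model sizes must lie in 1..{k}")

    n_val = n // 2
    offsets_all = _modifier_offsets(modifier, strategy_ids, n)

    mcc_out = np.empty((n_runs, sizes.size))
    acc_out = np.empty((n_runs, sizes.size))
    val_out = np.empty((n_runs, n_val), dtype=np.int64)
    cls_out = np.empty((n_runs, sizes.size, n_val), dtype=np.int8) if keep_classes else None
    cont_out = (
        np.empty((n_runs, sizes.size, n_val), dtype=np.float32) if keep_continuous else None
    )

    F = fm.values
    for r in range(n_runs):
        perm = rng.permutation(n)
        val_idx = perm[:n_val]
        train_idx = perm[n_val:]
        y_train = labels[train_idx]
        y_val = labels[val_idx]

        stump_mcc = np.empty(k)
        votes_val = np.empty((n_val, k))
        for j in range(k):
            stump = train_stump(F[train_idx, j], y_train)
            pred_train = stump.predict(F[train_idx, j])
            stump_mcc[j] = _mcc_from_labels(y_train, pred_train)
            votes_val[:, j] = stump.votes(F[val_idx, j])

        order = np.argsort(-stump_mcc, kind="stable")
        cum = np.cumsum(votes_val[:, order], axis=1)
        p_all = cum / np.arange(1, k + 1)  # (n_val, k): p at every size
        p_sel = p_all[:, sizes - 1] + offsets_all[val_idx][:, None]
        cls = np.where(p_sel > 0, 1, -1)

        for si in range(sizes.size):
            cm = ContingencyMatrix.from_predictions(y_val, cls[:, si])
            mcc_out[r, si] = mcc(cm)
            acc_out[r, si] = accuracy(cm)
        val_out[r] = val_idx
        if cls_out is not None:
            cls_out[r] = cls.T
        if cont_out is not None:
            cont_out[r] = p_sel.T

    return MCCVResult(sizes, mcc_out, acc_out, val_out, cls_out, cont_out)


def select_model_size(result: MCCVResult) -> int:
    """Model size maximizing median validation MCC; ties -> smallest size."""
    med = result.median_mcc()
    if med.size == 0:
        raise ValueError("empty MC-CV result")
    return int(result.model_sizes[int(np.argmax(med))])


def fit_ensemble(
    fm: FeatureMatrix,
    labels: np.ndarray,
    n_included: int | None = None,
    modifier: Mapping[str, float] | None = None,
) -> EnsembleModel:
    """Train one stump per scale on the full data, ordered by importance."""
    labels = np.asarray(labels, dtype=int)
    ranking = rank_by_importance(fm, labels)
    stumps = [
        train_stump(fm.column(name), labels, scale_name=name) for name, _ in ranking
    ]
    if n_included is None:
        n_included = len(stumps)
    return EnsembleModel(stumps, n_included, modifier)
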