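"""Hill-climbing of per-insertion-strategy offsets on the continuous vote.

Each iteration evaluates the current offset vector in a short MC-CV,
accumulates a per-strategy validation contingency matrix, and nudges the
offset of the strategy with the largest |FN - FP| imbalance by a fixed
step, signed so that excess false negatives push predictions up and excess
false positives push them down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ContingencyMatrix, MCCVResult, mc_cv
from .features import FeatureMatrix

STATUS_NEW_BEST = "new_best"
STATUS_ACCEPTED = "accepted_within_margin"
STATUS_RESET = "reset"


@dataclass(frozen=True)
class ModificationVector:
    """Additive per-strategy offsets applied to the continuous prediction."""

    offsets: Mapping[str, float]
    step: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", dict(self.offsets))
        for sid, off in self.offsets.items():
            ratio = off / self.step if self.step else 0.0
            if self.step and abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"offset {off} for strategy {sid!r} is not a multiple of step {self.step}"
                )

    def get(self, strategy_id: str, default: float = 0.0) -> float:
        return self.offsets.get(strategy_id, default)

    def items(self):
        return self.offsets.items()

    def nudged(self, strategy_id: str, direction: int) -> "ModificationVector":
        new = dict(self.offsets)
        new[strategy_id] = round(new.get(strategy_id, 0.0) + direction * self.step, 10)
        return ModificationVector(new, self.step)

    def max_abs(self) -> float:
        return max((abs(v) for v in self.offsets.values()), default=0.0)

    @classmethod
    def zeros(cls, strategy_ids: Sequence[str], step: float = 0.01) -> "ModificationVector":
        return cls({sid: 0.0 for sid in strategy_ids}, step)


def accumulate_strategy_contingency(
    result: MCCVResult,
    labels: np.ndarray,
    strategy_ids: Sequence[str],
    model_size: int | None = None,
) -> dict[str, ContingencyMatrix]:
    """Sum validation TP/TN/FP/FN per strategy over all runs and model sizes.

    ``model_size`` restricts the accumulation to a single size; the default
    pools every evaluated size, mirroring the optimization target (median
    over the full 1..n model space).
    """
    if result.classes is None:
        raise ValueError("MCCVResult lacks per-observation classes (keep_classes=True)")
    strategy_ids = list(strategy_ids)
    labels = np.asarray(labels, dtype=int)
    if len(strategy_ids) != labels.size:
        raise ValueError("strategy annotations must cover every observation")

    if model_size is not None:
        size_sel = np.flatnonzero(result.model_sizes == model_size)
        if size_sel.size == 0:
            raise ValueError(f"model size {model_size} not in result")
    else:
        size_sel = np.arange(result.model_sizes.size)

    order = sorted(set(strategy_ids), key=strategy_ids.index)  # first-appearance order
    sid_codes = {sid: i for i, sid in enumerate(order)}
    codes = np.asarray([sid_codes[s] for s in strategy_ids])

    counts = np.zeros((len(order), 4), dtype=np.int64)  # tp tn fp fn
    for r in range(result.n_runs):
        val_idx = result.val_indices[r]
        y_val = labels[val_idx]
        c_val = codes[val_idx]
        for si in size_sel:
            pred = result.classes[r, si]
            tp = (y_val == 1) & (pred == 1)
            tn = (y_val == -1) & (pred == -1)
            fp = (y_val == -1) & (pred == 1)
            fn = (y_val == 1) & (pred == -1)
            for gi, mask in enumerate((tp, tn, fp, fn)):
                np.add.at(counts[:, gi], c_val[mask], 1)
    return {
        sid: ContingencyMatrix(*counts[sid_codes[sid]].tolist()) for sid in order
    }


def update_modifier(
    contingency: Mapping[str, ContingencyMatrix], current: ModificationVector
) -> ModificationVector:
    """Nudge the strategy with the largest |FN - FP| by one signed step.

    Ties break toward the first strategy in mapping order; a uniformly
    balanced contingency (FN = FP everywhere) leaves the vector unchanged.
    """
    if not contingency:
        raise ValueError("contingency mapping is empty")
    best_sid, best_diff = None, 0
    for sid, cm in contingency.items():
        diff = cm.fn - cm.fp
        if abs(diff) > abs(best_diff):
            best_sid, best_diff = sid, diff
    if best_sid is None:
        return current
    return current.nudged(best_sid, 1 if best_diff > 0 else -1)


@dataclass
class StrategyOptIteration:
    iteration: int
    target_mcc: float
    status: str
    no_improvement: int
    offsets: dict[str, float]


@dataclass
class StrategyOptTrace:
    iterations: list[StrategyOptIteration] = field(default_factory=list)

    def best_so_far(self) -> np.ndarray:
        best = -np.inf
        out = []
        for it in self.iterations:
            if it.status == STATUS_NEW_BEST:
                best = it.target_mcc
            out.append(best)
        return np.asarray(out)

    def to_frame(self) -> pd.DataFrame:
        strategy_cols = sorted({k for it in self.iterations for k in it.offsets})
        rows = []
        for it in self.iterations:
            row = {
                "iteration": it.iteration,
                "target_mcc": it.target_mcc,
                "status": it.status,
                "no_improvement": it.no_improvement,
            }
            row.update({f"offset_{sid}": it.offsets.get(sid, 0.0) for sid in strategy_cols})
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def optimize_strategies(
    fm: FeatureMatrix,
    labels: np.ndarray,
    strategy_ids: Sequence[str],
    seed: int | np.random.Generator,
    runs_per_iter: int = 25,
    step: float = 0.01,
    margin: float = 0.05,
    patience: int = 50,
    max_iterations: int = 2000,
    contingency_model_size: int | None = None,
) -> tuple[ModificationVector, StrategyOptTrace]:
    """Hill-climb the per-strategy offset vector.

    Per iteration the current vector is scored by the median, over model
    sizes, of the per-size median validation MCC of a ``runs_per_iter``-fold
    MC-CV.  A score above the best so far becomes the new best; a score
    within ``margin`` of it keeps the current vector; anything worse resets
    to the best vector (which is then re-evaluated with fresh splits on the
    next iteration).  The loop stops after ``patience`` consecutive
    iterations without a new best.
    """
    strategy_ids = list(strategy_ids)
    unique_strategies = sorted(set(strategy_ids))
    if len(unique_strategies) < 2:
        raise ValueError("need at least two distinct strategies to optimize")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    current = ModificationVector.zeros(unique_strategies, step)
    best_vector = current
    best_mcc = -np.inf
    no_improvement = 0
    trace = StrategyOptTrace()

    for iteration in range(max_iterations):
        result = mc_cv(
            fm,
            labels,
            n_runs=runs_per_iter,
            seed=rng,
            modifier=current,
            strategy_ids=strategy_ids,
            keep_classes=True,
        )
        target = result.overall_median_mcc()

        if target > best_mcc:
            best_mcc = target
            best_vector = current
            status = STATUS_NEW_BEST
            no_improvement = 0
        elif target >= best_mcc - margin:
            status = STATUS_ACCEPTED
            no_improvement += 1
        else:
            status = STATUS_RESET
            no_improvement += 1

        trace.iterations.append(
            StrategyOptIteration(iteration, target, status, no_improvement, dict(current.offsets))
        )
        if no_improvement >= patience:
            break

        if status == STATUS_RESET:
            # Re-evaluate the best vector with fresh splits before updating.
            current = best_vector
        else:
            contingency = accumulate_strategy_contingency(
                result, labels, strategy_ids, model_size=contingency_model_size
            )
            current = update_modifier(contingency, current)

    return best_vector, trace
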