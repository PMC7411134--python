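"""Hill-climbing synthesis and optimization of amino-acid scales.

The single scale under optimization drives a one-stump model.  Each
iteration pools the false-negative and false-positive validation groups of
a short MC-CV, derives a 20-vector modifier from the product of the group
feature-value gap and the per-residue composition gap, standardizes it,
and steps the scale a small fraction of unit variance in that direction.
Candidate scales are accepted or rejected against the best median
validation MCC seen so far.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import mc_cv
from .features import FeatureMatrix
from .scales import (
    CANONICAL_RESIDUES,
    AminoAcidScale,
    DegenerateScaleError,
    ScaleTable,
    normalize_scale,
    random_scale,
)

STATUS_NEW_BEST = "new_best"
STATUS_ACCEPTED = "accepted_within_margin"
STATUS_RESET = "reset"
STATUS_NO_UPDATE = "no_update"

#: Default modification rates: 1% of unit variance when synthesizing from a
#: random initial scale, 5% when optimizing an existing scale.
SYNTHESIS_RATE = 0.01
OPTIMIZATION_RATE = 0.05


@dataclass(frozen=True)
class GroupCompositionStats:
    """Composition and feature statistics of pooled FN/FP validation groups.

    ``a_fn``/``a_fp`` are mean per-sequence residue-count vectors (canonical
    order); ``f_fn``/``f_fp`` their dot products with the current scale.
    ``m = delta_f * delta_a`` elementwise.
    """

    a_fn: np.ndarray
    a_fp: np.ndarray
    f_fn: float
    f_fp: float
    delta_f: float
    delta_a: np.ndarray
    m: np.ndarray

    @property
    def defined(self) -> bool:
        return bool(np.any(self.m != 0.0))


class EmptyGroupError(RuntimeError):
    """FN or FP validation group is empty; no modifier can be derived."""


def compute_group_stats(
    fn_counts: np.ndarray,
    fp_counts: np.ndarray,
    scale: AminoAcidScale,
    modifier_sign: int = -1,
) -> GroupCompositionStats:
    """Derive the scale modifier from FN/FP group composition.

    Parameters
    ----------
    fn_counts, fp_counts
        Residue-count rows (one per pooled FN / FP validation occurrence).
    scale
        The scale the groups were classified under.
    modifier_sign
        Overall sign applied to ``m``.  The default -1 steps residues
        overrepresented in the FN group toward lower values (and FP toward
        higher), moving both groups' mean features back across the stump
        threshold; +1 applies the raw product instead.
    """
    fn_counts = np.atleast_2d(np.asarray(fn_counts, dtype=float))
    fp_counts = np.atleast_2d(np.asarray(fp_counts, dtype=float))
    if fn_counts.shape[0] == 0 or fp_counts.shape[0] == 0:
        raise EmptyGroupError("FN and FP groups must both be non-empty")
    s = scale.as_array()
    a_fn = fn_counts.mean(axis=0)
    a_fp = fp_counts.mean(axis=0)
    f_fn = float(a_fn @ s)
    f_fp = float(a_fp @ s)
    delta_f = f_fn - f_fp
    delta_a = a_fn - a_fp
    m = modifier_sign * delta_f * delta_a
    return GroupCompositionStats(a_fn, a_fp, f_fn, f_fp, delta_f, delta_a, m)


def modify_scale(s: AminoAcidScale, m: np.ndarray, rate: float) -> AminoAcidScale:
    """Step the scale by ``rate`` times the standardized modifier.

    The modifier is centered and scaled to unit variance before the step;
    the result is re-normalized, so each step moves the scale by an average
    of ``rate`` of unit variance.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (20,):
        raise ValueError(f"modifier must have 20 entries, got shape {m.shape}")
    if rate == 0.0:
        return s
    sd = m.std(ddof=1)
    if sd == 0.0:
        raise DegenerateScaleError("constant modifier cannot be standardized")
    m_bar = (m - m.mean()) / sd
    stepped = AminoAcidScale.from_array(s.name, s.as_array() + rate * m_bar)
    return normalize_scale(stepped)


@dataclass
class ScaleOptIteration:
    iteration: int
    median_mcc: float
    status: str
    no_improvement: int


@dataclass
class ScaleOptTrace:
    iterations: list[ScaleOptIteration] = field(default_factory=list)
    initial_mcc: float = float("nan")

    def best_so_far(self) -> np.ndarray:
        best = self.initial_mcc
        out = []
        for it in self.iterations:
            if it.status == STATUS_NEW_BEST:
                best = it.median_mcc
            out.append(best)
        return np.asarray(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [it.iteration for it in self.iterations],
                "median_mcc": [it.median_mcc for it in self.iterations],
                "status": [it.status for it in self.iterations],
                "no_improvement": [it.no_improvement for it in self.iterations],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _single_scale_fm(counts: np.ndarray, scale: AminoAcidScale, ids: list[str]) -> FeatureMatrix:
    return FeatureMatrix((counts @ scale.as_array())[:, None], ids, [scale.name])


def _single_stump_median_mcc(
    counts: np.ndarray,
    labels: np.ndarray,
    scale: AminoAcidScale,
    ids: list[str],
    n_runs: int,
    rng: np.random.Generator,
) -> float:
    res = mc_cv(_single_scale_fm(counts, scale, ids), labels, n_runs=n_runs, seed=rng)
    return float(res.median_mcc()[0])


def optimize_scale(
    initial: AminoAcidScale,
    counts: np.ndarray,
    labels: np.ndarray,
    seed: int | np.random.Generator,
    rate: float = SYNTHESIS_RATE,
    stats_runs: int = 25,
    eval_runs: int = 100,
    margin: float = 0.2,
    patience: int = 50,
    max_iterations: int = 2000,
    modifier_sign: int = -1,
) -> tuple[AminoAcidScale, ScaleOptTrace]:
    """Hill-climb a single scale against single-stump MC-CV performance.

    Parameters
    ----------
    initial
        Starting scale; normalized before use.
    counts
        n x 20 residue-count matrix of the (sub)training set.
    labels
        +-1 labels.
    rate
        Fraction of unit variance moved per step (0.01 synthesis,
        0.05 literature-scale optimization).

    Returns the best scale (by median validation MCC of ``eval_runs``-fold
    MC-CV) and the full iteration trace.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != 20:
        raise ValueError("counts must be an n x 20 matrix")
    if counts.shape[0] != labels.size:
        raise ValueError("counts and labels must align")
    if len(set(labels.tolist())) < 2:
        raise ValueError("subset must contain both classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [f"obs{i}" for i in range(counts.shape[0])]

    current = normalize_scale(initial)
    best = current
    best_mcc = _single_stump_median_mcc(counts, labels, current, ids, eval_runs, rng)
    trace = ScaleOptTrace(initial_mcc=best_mcc)
    no_improvement = 0

    for iteration in range(max_iterations):
        # Stats pass: pooled FN/FP validation groups under the current scale.
        stats_res = mc_cv(
            _single_scale_fm(counts, current, ids),
            labels,
            n_runs=stats_runs,
            seed=rng,
            keep_classes=True,
        )
        fn_rows, fp_rows = [], []
        for r in range(stats_res.n_runs):
            val_idx = stats_res.val_indices[r]
            pred = stats_res.classes[r, 0]
            y_val = labels[val_idx]
            fn_rows.append(counts[val_idx[(y_val == 1) & (pred == -1)]])
            fp_rows.append(counts[val_idx[(y_val == -1) & (pred == 1)]])
        fn_counts = np.vstack(fn_rows)
        fp_counts = np.vstack(fp_rows)

        status = None
        if fn_counts.shape[0] == 0 or fp_counts.shape[0] == 0:
            status = STATUS_NO_UPDATE
        else:
            stats = compute_group_stats(fn_counts, fp_counts, current, modifier_sign)
            if not stats.defined or stats.m.std(ddof=1) == 0.0:
                status = STATUS_NO_UPDATE

        if status == STATUS_NO_UPDATE:
            no_improvement += 1
            trace.iterations.append(
                ScaleOptIteration(iteration, best_mcc, status, no_improvement)
            )
            if no_improvement >= patience:
                break
            continue

        candidate = modify_scale(current, stats.m, rate)
        cand_mcc = _single_stump_median_mcc(counts, labels, candidate, ids, eval_runs, rng)

        if cand_mcc > best_mcc:
            best, best_mcc = candidate, cand_mcc
            current = candidate
            status = STATUS_NEW_BEST
            no_improvement = 0
        elif cand_mcc >= best_mcc - margin:
            current = candidate
            status = STATUS_ACCEPTED
            no_improvement += 1
        else:
            current = best
            status = STATUS_RESET
            no_improvement += 1

        trace.iterations.append(ScaleOptIteration(iteration, cand_mcc, status, no_improvement))
        if no_improvement >= patience:
            break

    return best, trace


def synthesize_scale_table(
    counts: np.ndarray,
    labels: np.ndarray,
    seed: int | np.random.Generator,
    k_subsets: int = 1,
    mode: str = "random",
    strategy_ids: Sequence[str] | None = None,
    min_subset_size: int = 24,
    name_prefix: str = "S",
    **optimize_kwargs,
) -> tuple[ScaleTable, list[ScaleOptTrace]]:
    """Synthesize ``k_subsets`` scales, one per disjoint training subset.

    ``random`` mode shuffles and chunks the training set into equally sized
    subsets; ``by_strategy`` mode uses one subset per insertion strategy and
    requires ``k_subsets`` to equal the number of distinct strategies.  Each
    subset seeds an independent hill-climb from a fresh random scale.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = counts.shape[0]
    if not 1 <= k_subsets <= 16:
        raise ValueError("k_subsets must lie in 1..16")
    if n < k_subsets * min_subset_size:
        raise ValueError(
            f"{n} observations cannot form {k_subsets} subsets of >= {min_subset_size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if mode == "random":
        perm = rng.permutation(n)
        subsets = [np.sort(chunk) for chunk in np.array_split(perm, k_subsets)]
    elif mode == "by_strategy":
        if strategy_ids is None:
            raise ValueError("by_strategy mode requires strategy_ids")
        strategy_ids = list(strategy_ids)
        unique = sorted(set(strategy_ids))
        if k_subsets != len(unique):
            raise ValueError(
                f"by_strategy mode needs k_subsets == #strategies ({len(unique)}), got {k_subsets}"
            )
        codes = np.asarray([unique.index(s) for s in strategy_ids])
        subsets = [np.flatnonzero(codes == c) for c in range(len(unique))]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    scales, traces = [], []
    for i, idx in enumerate(subsets):
        init = random_scale(rng, name=f"{name_prefix}{k_subsets}_{i + 1}")
        best, trace = optimize_scale(init, counts[idx], labels[idx], seed=rng, **optimize_kwargs)
        scales.append(AminoAcidScale.from_array(f"{name_prefix}{k_subsets}_{i + 1}", best.as_array()))
        traces.append(trace)
    return ScaleTable(scales, provenance="synthesized"), traces


def optimize_scale_table(
    table: ScaleTable,
    counts: np.ndarray,
    labels: np.ndarray,
    seed: int | np.random.Generator,
    rate: float = OPTIMIZATION_RATE,
    **optimize_kwargs,
) -> tuple[ScaleTable, list[ScaleOptTrace]]:
    """Independently optimize every scale of an existing table."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scales, traces = [], []
    for s in table:
        best, trace = optimize_scale(
            normalize_scale(s), counts, labels, seed=rng, rate=rate, **optimize_kwargs
        )
        scales.append(best)
        traces.append(trace)
    return ScaleTable(scales, provenance="optimized"), traces
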