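"""Final-model evaluation, performance-change reporting, and scale PCA."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ContingencyMatrix,
    accuracy,
    ensemble_predict,
    fit_ensemble,
    mc_cv,
    mcc,
    select_model_size,
)
from .features import FeatureMatrix
from .scales import ScaleTable, normalize_scale


@dataclass
class EvaluationReport:
    """Validation curves plus external-test metrics per model size.

    ``mcc_vali_max`` is the test MCC at the size maximizing median
    validation MCC; ``mcc_max`` the maximum test MCC over all sizes.
    """

    model_sizes: np.ndarray
    vali_median_mcc: np.ndarray
    vali_mad_mcc: np.ndarray
    vali_median_accuracy: np.ndarray
    vali_mad_accuracy: np.ndarray
    test_mcc: np.ndarray
    test_accuracy: np.ndarray
    selected_size: int
    mcc_max: float
    mcc_vali_max: float
    a_vali_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model_size": self.model_sizes,
                "vali_median_mcc": self.vali_median_mcc,
                "vali_mad_mcc": self.vali_mad_mcc,
                "vali_median_accuracy": self.vali_median_accuracy,
                "vali_mad_accuracy": self.vali_mad_accuracy,
                "test_mcc": self.test_mcc,
                "test_accuracy": self.test_accuracy,
            }
        )

    def summary(self) -> dict:
        return {
            "selected_size": int(self.selected_size),
            "mcc_max": float(self.mcc_max),
            "mcc_vali_max": float(self.mcc_vali_max),
            "a_vali_max": float(self.a_vali_max),
        }

    def write(self, csv_path: str | Path, json_path: str | Path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def evaluate_model(
    train_fm: FeatureMatrix,
    train_labels: np.ndarray,
    test_fm: FeatureMatrix,
    test_labels: np.ndarray,
    seed: int | np.random.Generator,
    runs: int = 1000,
    modifier: Mapping[str, float] | None = None,
    train_strategy_ids: Sequence[str] | None = None,
    test_strategy_ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Validation curves from MC-CV plus test metrics from full-train models.

    Test metrics at every model size come from the single ensemble trained
    on the complete training set; validation medians only guide size
    selection.
    """
    overlap = set(train_fm.construct_ids) & set(test_fm.construct_ids)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
    train_labels = np.asarray(train_labels, dtype=int)
    test_labels = np.asarray(test_labels, dtype=int)

    result = mc_cv(
        train_fm,
        train_labels,
        n_runs=runs,
        seed=seed,
        modifier=modifier,
        strategy_ids=train_strategy_ids,
    )
    sizes = result.model_sizes
    model = fit_ensemble(train_fm, train_labels, modifier=modifier)

    test_mcc = np.empty(sizes.size)
    test_acc = np.empty(sizes.size)
    for i, size in enumerate(sizes):
        model.n_included = int(size)
        _, cls = ensemble_predict(model, test_fm, strategy_ids=test_strategy_ids)
        cm = ContingencyMatrix.from_predictions(test_labels, cls)
        test_mcc[i] = mcc(cm)
        test_acc[i] = accuracy(cm)

    selected = select_model_size(result)
    sel_i = int(np.flatnonzero(sizes == selected)[0])
    return EvaluationReport(
        model_sizes=sizes,
        vali_median_mcc=result.median_mcc(),
        vali_mad_mcc=result.mad_mcc(),
        vali_median_accuracy=result.median_accuracy(),
        vali_mad_accuracy=result.mad_accuracy(),
        test_mcc=test_mcc,
        test_accuracy=test_acc,
        selected_size=selected,
        mcc_max=float(test_mcc.max()),
        mcc_vali_max=float(test_mcc[sel_i]),
        a_vali_max=float(test_acc[sel_i]),
    )


def change_metric(before: float, after: float, metric_range: float) -> int:
    """Performance change as integer percent of the metric's maximum range.

    Ranges are 1 for accuracy and 2 for MCC.
    """
    if metric_range <= 0:
        raise ValueError("metric_range must be positive")
    return round(100.0 * (after - before) / metric_range)


def pc1_explained_variance(table: ScaleTable) -> float:
    """Fraction of variance on the first principal component of a scale table.

    Scales are normalized (zero mean, unit variance over the 20 residues)
    and treated as variables with residues as observations; no further
    centering is applied.
    """
    if len(table) < 2:
        raise ValueError("need at least two scales for PCA")
    M = np.column_stack([normalize_scale(s).as_array() for s in table])
    sv = np.linalg.svd(M, compute_uv=False)
    total = float(np.sum(sv**2))
    if total == 0.0:
        raise ValueError("scale table has zero total variance")
    return float(sv[0] ** 2 / total)


def plot_evaluation(report: EvaluationReport, path: str | Path) -> None:
    """MCC-vs-size curves with a MAD band around the validation median."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = report.model_sizes
    ax.plot(x, report.vali_median_mcc, label="validation (median)", color="tab:blue")
    ax.fill_between(
        x,
        report.vali_median_mcc - report.vali_mad_mcc,
        report.vali_median_mcc + report.vali_mad_mcc,
        alpha=0.25,
        color="tab:blue",
    )
    ax.plot(x, report.test_mcc, label="test", color="tab:red")
    ax.axvline(report.selected_size, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("included classifiers")
    ax.set_ylabel("MCC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
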