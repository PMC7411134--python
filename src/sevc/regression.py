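"""Continuous-vote regression against precipitant concentrations.

The undiscretized ensemble prediction, averaged over the MC-CV runs in
which a construct fell into the validation half, is correlated by ordinary
least squares with the ammonium-sulfate molarity required to precipitate
that construct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import mc_cv
from .features import FeatureMatrix


@dataclass
class RegressionResult:
    slope: float  # M per vote unit
    intercept: float  # M
    r_squared: float
    x: np.ndarray  # observed predictions
    y: np.ndarray  # observed concentrations (M)
    conf_lower: np.ndarray  # 95% bounds of the fitted mean response at x
    conf_upper: np.ndarray

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def mean_continuous_prediction(
    fm: FeatureMatrix,
    labels: np.ndarray,
    seed: int | np.random.Generator,
    runs: int = 1000,
    model_size: int | None = None,
    modifier: Mapping[str, float] | None = None,
    strategy_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Mean continuous validation prediction per construct over MC-CV runs.

    ``model_size`` defaults to all scales in the feature matrix.  Raises if
    a construct never appears in any validation half.
    """
    size = model_size if model_size is not None else fm.n_scales
    result = mc_cv(
        fm,
        np.asarray(labels, dtype=int),
        n_runs=runs,
        seed=seed,
        modifier=modifier,
        strategy_ids=strategy_ids,
        model_sizes=[size],
        keep_continuous=True,
    )
    n = fm.n_constructs
    sums = np.zeros(n)
    counts = np.zeros(n)
    for r in range(result.n_runs):
        idx = result.val_indices[r]
        sums[idx] += result.continuous[r, 0]
        counts[idx] += 1
    never = np.flatnonzero(counts == 0)
    if never.size:
        missing = [fm.construct_ids[i] for i in never]
        raise RuntimeError(f"construct(s) never in validation: {missing}")
    return pd.Series(sums / counts, index=fm.construct_ids, name="mean_prediction")


def read_precipitation_csv(path: str | Path) -> pd.Series:
    """Read construct_id -> ammonium sulfate molarity records."""
    df = pd.read_csv(path, dtype={"construct_id": str})
    if "construct_id" not in df.columns or "as_conc_M" not in df.columns:
        raise ValueError(f"{path}: expected columns construct_id, as_conc_M")
    if (df["as_conc_M"] <= 0).any():
        bad = df.loc[df["as_conc_M"] <= 0, "construct_id"].tolist()
        raise ValueError(f"non-positive concentration(s) for {bad}")
    return pd.Series(df["as_conc_M"].to_numpy(), index=df["construct_id"], name="as_conc_M")


def fit_precipitation_model(preds: pd.Series, records: pd.Series) -> RegressionResult:
    """OLS of concentration on mean continuous prediction, with 95% CI."""
    common = preds.index.intersection(records.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 matched construct pairs, got {len(common)}")
    x = preds.loc[common].to_numpy(dtype=float)
    y = records.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0.0:
        raise ValueError("zero variance in predictions")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.get_prediction(X).conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        x=x,
        y=y,
        conf_lower=ci[:, 0],
        conf_upper=ci[:, 1],
    )


def plot_regression(result: RegressionResult, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(result.x)
    x = result.x[order]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.x, result.y, color="k", zorder=3)
    ax.plot(x, result.intercept + result.slope * x, color="tab:red")
    ax.fill_between(
        x, result.conf_lower[order], result.conf_upper[order], alpha=0.25, color="tab:red"
    )
    ax.set_xlabel("mean continuous prediction")
    ax.set_ylabel("ammonium sulfate (M)")
    ax.set_title(f"R² = {result.r_squared:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
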