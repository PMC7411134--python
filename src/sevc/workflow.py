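"""End-to-end experiment orchestration.

A pipeline run chains: simulate -> featurize -> crossval ->
synth-scales -> optimize-strategy -> evaluate -> regress, writing each
stage's artifacts plus a config snapshot and a log into one output
directory.  A single master seed fans out to per-stage seeds, so stages
are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core, evaluation, regression, scale_opt, simulate, strategy_opt
from .features import (
    build_feature_matrix,
    read_constructs_csv,
    residue_count_matrix,
    write_constructs_csv,
    write_fasta,
    write_strategies_yaml,
)
from .scales import ScaleTable, load_scale_table, random_scale, write_scale_table

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "featurize",
    "crossval",
    "synth_scales",
    "optimize_strategy",
    "evaluate",
    "regress",
)


@dataclass
class ExperimentConfig:
    """All pipeline hyperparameters, with defaults matching the method."""

    out_dir: str = "sevc_run"
    master_seed: int = 0
    # data
    constructs_csv: str | None = None  # external data; otherwise simulated
    scales_csv: str | None = None  # literature scales; otherwise random panel
    precip_csv: str | None = None
    n_random_scales: int = 12  # fallback panel when no scales_csv is given
    n_train: int = 384
    # simulate
    n_inserts: int = 71
    n_strategies: int = 8
    noise_sd: float = 0.25
    strategy_offsets: dict[str, float] = field(default_factory=dict)
    # crossval / evaluation
    crossval_runs: int = 25
    eval_runs: int = 1000
    # strategy optimization
    strategy_runs_per_iter: int = 25
    strategy_step: float = 0.01
    strategy_margin: float = 0.05
    strategy_patience: int = 50
    # scale synthesis
    synth_subsets: int = 1
    synth_mode: str = "random"
    synth_rate: float = 0.01
    synth_margin: float = 0.2
    synth_patience: int = 50
    synth_stats_runs: int = 25
    synth_eval_runs: int = 100
    # regression
    regress_strategy: str = "H"
    regress_runs: int = 1000

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class PipelineError(RuntimeError):
    pass


class PipelineState:
    """In-memory artifacts shared between stages."""

    def __init__(self) -> None:
        self.constructs = None
        self.ground_truth = None
        self.train_ids: list[str] | None = None
        self.test_ids: list[str] | None = None
        self.table: ScaleTable | None = None
        self.synth_table: ScaleTable | None = None
        self.modifier = None

    def require(self, attr: str, stage: str, produced_by: str) -> object:
        value = getattr(self, attr)
        if value is None:
            raise PipelineError(
                f"stage {stage!r} needs {attr!r}; run the {produced_by!r} stage first "
                "or provide it via the config"
            )
        return value


def _train_test(state: PipelineState, stage: str):
    constructs = state.require("constructs", stage, "simulate")
    by_id = {c.id: c for c in constructs}
    train = [by_id[i] for i in state.require("train_ids", stage, "simulate")]
    test = [by_id[i] for i in state.require("test_ids", stage, "simulate")]
    return train, test


def run_pipeline(
    cfg: ExperimentConfig, stages: Sequence[str] | None = None, timestamp: bool = False
) -> Path:
    """Execute the requested stages in order; returns the artifact directory."""
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    stages = [s for s in ALL_STAGES if s in stages]  # canonical order

    out = Path(cfg.out_dir)
    if timestamp:
        out = out / time.strftime("%Y%m%d-%H%M%S")
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    state = PipelineState()
    seed = simulate.stage_rng  # alias

    # Inputs that may come from files instead of earlier stages.
    if cfg.constructs_csv:
        state.constructs = read_constructs_csv(cfg.constructs_csv)
    if cfg.scales_csv:
        state.table = load_scale_table(cfg.scales_csv)
    else:
        rng = seed(cfg.master_seed, "scale-panel")
        state.table = ScaleTable(
            [random_scale(rng, name=f"rand{i + 1:02d}") for i in range(cfg.n_random_scales)],
            provenance="literature",
        )

    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            sim_cfg = simulate.SyntheticConfig(
                n_inserts=cfg.n_inserts,
                n_strategies=cfg.n_strategies,
                noise_sd=cfg.noise_sd,
                strategy_offsets=cfg.strategy_offsets,
                seed=cfg.master_seed,
            )
            constructs, gt = simulate.generate_dataset(sim_cfg)
            state.constructs, state.ground_truth = constructs, gt
            state.train_ids, state.test_ids = simulate.stratified_split(
                constructs, cfg.n_train, seed=seed(cfg.master_seed, "split")
            )
            write_constructs_csv(constructs, out / "constructs.csv")
            write_fasta({"backbone": gt.backbone}, out / "backbone.fasta")
            write_fasta(gt.inserts, out / "inserts.fasta")
            write_strategies_yaml(gt.strategies, out / "strategies.yaml")
            write_scale_table(ScaleTable([gt.scale]), out / "ground_truth_scale.csv")
            pd.DataFrame(
                {
                    "id": state.train_ids + state.test_ids,
                    "partition": ["train"] * len(state.train_ids)
                    + ["test"] * len(state.test_ids),
                }
            ).to_csv(out / "split.csv", index=False)
            log(f"simulate: {len(constructs)} constructs, "
                f"{len(state.train_ids)}/{len(state.test_ids)} train/test")
        elif stage == "featurize":
            constructs = state.require("constructs", stage, "simulate")
            fm = build_feature_matrix(constructs, state.table)
            fm.to_frame().to_csv(out / "features.csv")
            log(f"featurize: {fm.n_constructs} x {fm.n_scales} feature matrix")
        elif stage == "crossval":
            train, _ = _train_test(state, stage)
            fm = build_feature_matrix(train, state.table)
            labels = np.asarray([c.label for c in train])
            res = core.mc_cv(
                fm, labels, n_runs=cfg.crossval_runs, seed=seed(cfg.master_seed, "crossval")
            )
            res.to_frame().to_csv(out / "crossval.csv", index=False)
            summary = {
                "selected_size": core.select_model_size(res),
                "overall_median_mcc": res.overall_median_mcc(),
            }
            (out / "crossval_summary.json").write_text(json.dumps(summary, indent=2))
            log(f"crossval: {cfg.crossval_runs} runs, summary {summary}")
        elif stage == "synth_scales":
            train, _ = _train_test(state, stage)
            counts = residue_count_matrix(c.sequence for c in train)
            labels = np.asarray([c.label for c in train])
            table, traces = scale_opt.synthesize_scale_table(
                counts,
                labels,
                seed=seed(cfg.master_seed, "synth-scales"),
                k_subsets=cfg.synth_subsets,
                mode=cfg.synth_mode,
                strategy_ids=[c.strategy_id for c in train],
                rate=cfg.synth_rate,
                margin=cfg.synth_margin,
                patience=cfg.synth_patience,
                stats_runs=cfg.synth_stats_runs,
                eval_runs=cfg.synth_eval_runs,
            )
            state.synth_table = table
            write_scale_table(table, out / "synthesized_scales.csv")
            for i, trace in enumerate(traces):
                trace.write_csv(out / f"synth_trace_{i + 1}.csv")
            meta = {
                "k_subsets": cfg.synth_subsets,
                "mode": cfg.synth_mode,
                "rate": cfg.synth_rate,
                "margin": cfg.synth_margin,
                "patience": cfg.synth_patience,
                "seed": cfg.master_seed,
            }
            (out / "synthesized_scales.json").write_text(json.dumps(meta, indent=2))
            log(f"synth_scales: {len(table)} scales synthesized")
        elif stage == "optimize_strategy":
            train, _ = _train_test(state, stage)
            table = state.synth_table or state.table
            fm = build_feature_matrix(train, table)
            labels = np.asarray([c.label for c in train])
            best, trace = strategy_opt.optimize_strategies(
                fm,
                labels,
                [c.strategy_id for c in train],
                seed=seed(cfg.master_seed, "optimize-strategy"),
                runs_per_iter=cfg.strategy_runs_per_iter,
                step=cfg.strategy_step,
                margin=cfg.strategy_margin,
                patience=cfg.strategy_patience,
            )
            state.modifier = best
            trace.write_csv(out / "strategy_trace.csv")
            (out / "best_modifier.json").write_text(json.dumps(dict(best.offsets), indent=2))
            log(f"optimize_strategy: best offsets {dict(best.offsets)}")
        elif stage == "evaluate":
            train, test = _train_test(state, stage)
            table = state.synth_table or state.table
            train_fm = build_feature_matrix(train, table)
            test_fm = build_feature_matrix(test, table)
            report = evaluation.evaluate_model(
                train_fm,
                np.asarray([c.label for c in train]),
                test_fm,
                np.asarray([c.label for c in test]),
                seed=seed(cfg.master_seed, "evaluate"),
                runs=cfg.eval_runs,
                modifier=state.modifier,
                train_strategy_ids=[c.strategy_id for c in train],
                test_strategy_ids=[c.strategy_id for c in test],
            )
            report.write(out / "evaluation.csv", out / "evaluation_summary.json")
            provenance = {
                "scale_table": table.provenance,
                "modifier": dict(state.modifier.offsets) if state.modifier else None,
            }
            (out / "evaluation_provenance.json").write_text(json.dumps(provenance, indent=2))
            log(f"evaluate: {report.summary()}")
        elif stage == "regress":
            constructs = state.require("constructs", stage, "simulate")
            table = state.synth_table or state.table
            subset = [
                c for c in constructs if c.strategy_id == cfg.regress_strategy
            ]
            if not subset:
                raise PipelineError(f"no constructs with strategy {cfg.regress_strategy!r}")
            fm = build_feature_matrix(subset, table)
            labels = np.asarray([c.label for c in subset])
            preds = regression.mean_continuous_prediction(
                fm, labels, seed=seed(cfg.master_seed, "regress"), runs=cfg.regress_runs
            )
            if cfg.precip_csv:
                records = regression.read_precipitation_csv(cfg.precip_csv)
            else:
                gt = state.require("ground_truth", stage, "simulate")
                df = simulate.generate_precipitation_data(
                    subset, gt, seed=seed(cfg.master_seed, "precip"),
                    strategy_id=cfg.regress_strategy,
                )
                df.to_csv(out / "precipitation.csv", index=False)
                records = pd.Series(
                    df["as_conc_M"].to_numpy(), index=df["construct_id"], name="as_conc_M"
                )
            fit = regression.fit_precipitation_model(preds, records)
            fit.write_json(out / "regression.json")
            preds.rename_axis("construct_id").to_csv(out / "mean_predictions.csv")
            log(f"regress: R^2 = {fit.r_squared:.3f}")
        dt = time.time() - t0
        log(f"stage {stage} done in {dt:.1f}s")

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
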