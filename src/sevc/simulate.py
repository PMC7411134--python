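"""Synthetic construct grids with known ground truth.

The generator mirrors the real experimental design: a fixed backbone, a
panel of insert peptides, and a handful of parameterized insertion
strategies combined into a full grid.  Labels derive from a hidden latent
insolubility score — the ground-truth scale's summed feature of the full
chimeric sequence, plus a per-strategy offset and Gaussian noise —
thresholded at an empirical quantile so the classes come out balanced.
Every algorithm in the package can therefore be tested for parameter
recovery without the confidential dataset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    Construct,
    InsertionStrategy,
    build_construct_grid,
    residue_count_matrix,
)
from .scales import CANONICAL_RESIDUES, AminoAcidScale, random_scale

RESIDUES = np.array(list(CANONICAL_RESIDUES))


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from a master seed and a name."""
    return np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic grid generator (defaults echo the real design)."""

    n_inserts: int = 71
    n_strategies: int = 8
    insert_length_range: tuple[int, int] = (9, 30)
    backbone_length: int = 149
    ground_truth_scale: AminoAcidScale | None = None
    strategy_offsets: Mapping[str, float] | None = None
    noise_sd: float = 0.0
    noise_mode: str = "relative"  # "relative": noise_sd x sd of noise-free latent
    label_balance_target: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inserts < 1 or self.n_strategies < 1:
            raise ValueError("need at least one insert and one strategy")
        if self.n_strategies > 26:
            raise ValueError("at most 26 strategies (single-letter ids)")
        lo, hi = self.insert_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad insert length range {self.insert_length_range}")
        if self.backbone_length < 1:
            raise ValueError("backbone length must be positive")
        if not 0.0 < self.label_balance_target < 1.0:
            raise ValueError("label balance target must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")


@dataclass
class GroundTruth:
    """Everything needed to verify recovery of the generating process."""

    scale: AminoAcidScale
    strategy_offsets: dict[str, float]
    tau: float
    latent: pd.Series  # per construct id
    latent_sd: float  # sd of the noise-free latent
    backbone: str
    inserts: dict[str, str]
    strategies: list[InsertionStrategy]


def default_strategies(backbone_length: int = 149, n: int = 8) -> list[InsertionStrategy]:
    """Parameterized strategies at distinct positions in a loop-like window.

    Positions cluster around the middle of the backbone with varying
    deletion counts and occasional short linkers, so constructs of different
    strategies differ systematically in composition and length.
    """
    center = backbone_length // 2 + 5
    specs = [
        ("A", center - 4, 0, "", ""),
        ("B", center - 3, 1, "", ""),
        ("C", center - 2, 2, "", ""),
        ("D", center - 1, 3, "", ""),
        ("E", center, 0, "GG", ""),
        ("F", center + 1, 2, "GG", "GS"),
        ("G", center + 2, 4, "", "GS"),
        ("H", center + 3, 3, "GSG", "GSG"),
    ]
    if n > len(specs):
        raise ValueError(f"at most {len(specs)} default strategies available")
    out = []
    for sid, pos, ndel, lb, la in specs[:n]:
        if pos + ndel > backbone_length:
            raise ValueError("backbone too short for default strategies")
        out.append(InsertionStrategy(sid, pos, ndel, lb, la))
    return out


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RESIDUES, size=length))


def generate_dataset(cfg: SyntheticConfig) -> tuple[list[Construct], GroundTruth]:
    """Build the labeled synthetic grid and its generating ground truth."""
    backbone = _random_sequence(stage_rng(cfg.seed, "backbone"), cfg.backbone_length)
    insert_rng = stage_rng(cfg.seed, "inserts")
    lo, hi = cfg.insert_length_range
    inserts = {
        f"ins{i + 1:03d}": _random_sequence(insert_rng, int(insert_rng.integers(lo, hi + 1)))
        for i in range(cfg.n_inserts)
    }
    strategies = default_strategies(cfg.backbone_length, cfg.n_strategies)
    constructs = build_construct_grid(backbone, inserts, strategies)

    gt_scale = cfg.ground_truth_scale
    if gt_scale is None:
        gt_scale = random_scale(stage_rng(cfg.seed, "ground-truth-scale"), name="ground_truth")

    offsets = dict(cfg.strategy_offsets or {})
    for strat in strategies:
        offsets.setdefault(strat.id, 0.0)

    counts = residue_count_matrix(c.sequence for c in constructs)
    base = counts @ gt_scale.as_array()
    base = base + np.asarray([offsets[c.strategy_id] for c in constructs])
    base_sd = float(base.std(ddof=1))
    if cfg.noise_sd > 0:
        sd = cfg.noise_sd * base_sd if cfg.noise_mode == "relative" else cfg.noise_sd
        noise = stage_rng(cfg.seed, "label-noise").normal(0.0, sd, size=base.size)
    else:
        noise = np.zeros_like(base)
    latent = base + noise

    # Higher latent = more insoluble; threshold at the quantile that yields
    # the requested soluble fraction.
    tau = float(np.quantile(latent, cfg.label_balance_target))
    labels = np.where(latent <= tau, 1, -1)

    labeled = [
        Construct(c.id, c.insert_id, c.strategy_id, c.sequence, int(lbl))
        for c, lbl in zip(constructs, labels)
    ]
    gt = GroundTruth(
        scale=gt_scale,
        strategy_offsets=offsets,
        tau=tau,
        latent=pd.Series(latent, index=[c.id for c in constructs], name="latent"),
        latent_sd=base_sd,
        backbone=backbone,
        inserts=inserts,
        strategies=strategies,
    )
    return labeled, gt


def stratified_split(
    constructs: Sequence[Construct], n_train: int = 384, seed: int | np.random.Generator = 0
) -> tuple[list[str], list[str]]:
    """Split preserving both insert and strategy marginals.

    Works on full (or near-full) insert x strategy grids: per-insert and
    per-strategy training quotas are set by largest-remainder apportionment
    and satisfied by a greedy assignment that always books an insert's quota
    against the strategies with the most remaining capacity.
    """
    n_total = len(constructs)
    if not 0 < n_train < n_total:
        raise ValueError(f"n_train must lie strictly between 0 and {n_total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    insert_ids = sorted({c.insert_id for c in constructs})
    strategy_ids = sorted({c.strategy_id for c in constructs})
    cell = {(c.insert_id, c.strategy_id): c.id for c in constructs}
    if len(cell) != n_total:
        raise ValueError("duplicate (insert, strategy) cells")

    def apportion(group_counts: dict[str, int]) -> dict[str, int]:
        exact = {g: n_train * cnt / n_total for g, cnt in group_counts.items()}
        quota = {g: int(np.floor(v)) for g, v in exact.items()}
        shortfall = n_train - sum(quota.values())
        remainders = sorted(exact, key=lambda g: (-(exact[g] - quota[g]), g))
        for g in remainders[:shortfall]:
            quota[g] += 1
        return quota

    insert_counts = {i: sum(1 for c in constructs if c.insert_id == i) for i in insert_ids}
    strategy_counts = {s: sum(1 for c in constructs if c.strategy_id == s) for s in strategy_ids}
    insert_quota = apportion(insert_counts)
    capacity = apportion(strategy_counts)

    train_ids: list[str] = []
    order = list(insert_ids)
    rng.shuffle(order)
    for iid in order:
        available = [s for s in strategy_ids if (iid, s) in cell and capacity[s] > 0]
        q = insert_quota[iid]
        if q > len(available):
            raise ValueError(f"infeasible stratification: insert {iid!r} quota {q}")
        # Book against the strategies with most remaining capacity; random
        # tie-break keeps the split seed-dependent.
        tie = rng.random(len(available))
        ranked = sorted(
            range(len(available)), key=lambda j: (-capacity[available[j]], tie[j])
        )
        for j in ranked[:q]:
            sid = available[j]
            capacity[sid] -= 1
            train_ids.append(cell[(iid, sid)])
    if any(v != 0 for v in capacity.values()):
        raise ValueError("infeasible stratification: strategy quotas not satisfiable")

    train_set = set(train_ids)
    test_ids = [c.id for c in constructs if c.id not in train_set]
    order_index = {c.id: i for i, c in enumerate(constructs)}
    train_ids.sort(key=order_index.__getitem__)
    return train_ids, test_ids


def generate_precipitation_data(
    constructs: Sequence[Construct],
    gt: GroundTruth,
    seed: int | np.random.Generator,
    strategy_id: str = "H",
    n_records: int = 10,
    beta0: float = 0.4,
    beta1: float = 0.2,
    noise_sd: float = 0.05,
    floor: float = 0.05,
) -> pd.DataFrame:
    """Ammonium-sulfate molarities for soluble constructs of one strategy.

    Concentration falls linearly with the construct's distance below the
    label threshold (scaled by the latent spread), plus Gaussian noise,
    floored at ``floor`` molar.  Defaults put most records in 0.5-0.7 M
    with occasional outliers toward 0.1 and 1 M.
    """
    soluble = [c for c in constructs if c.strategy_id == strategy_id and c.label == 1]
    if not soluble:
        raise ValueError(f"no soluble constructs with strategy {strategy_id!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = list(soluble)
    if len(chosen) > n_records:
        idx = rng.choice(len(chosen), size=n_records, replace=False)
        chosen = [chosen[i] for i in sorted(idx)]
    margin = (gt.tau - gt.latent.loc[[c.id for c in chosen]].to_numpy()) / gt.latent_sd
    conc = beta0 + beta1 * margin
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=conc.size)
    conc = np.maximum(conc, floor)
    return pd.DataFrame({"construct_id": [c.id for c in chosen], "as_conc_M": conc})
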