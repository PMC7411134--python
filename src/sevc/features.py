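"""Chimeric construct assembly and composition-based feature computation.

A construct is built by splicing an insert peptide (optionally flanked by
linkers) into a backbone at a strategy-defined position, deleting a
strategy-defined number of backbone residues.  The feature of a sequence
under a scale is the plain sum of per-residue scale values, so features
depend on composition only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import CANONICAL_RESIDUES, RESIDUE_INDEX, AminoAcidScale, ScaleTable

SOLUBLE = 1
INSOLUBLE = -1


class SequenceError(ValueError):
    pass


def _check_sequence(seq: str, context: str = "sequence") -> None:
    for i, aa in enumerate(seq):
        if aa not in RESIDUE_INDEX:
            raise SequenceError(f"{context}: non-canonical residue {aa!r} at position {i}")


@dataclass(frozen=True)
class InsertionStrategy:
    """Recipe for placing an insert into a backbone.

    ``insertion_position`` is a 0-based index; the insert (with linkers) is
    placed before it and ``n_deleted`` backbone residues are removed forward
    from it.
    """

    id: str
    insertion_position: int
    n_deleted: int = 0
    linker_before: str = ""
    linker_after: str = ""

    def __post_init__(self) -> None:
        if self.insertion_position < 0:
            raise ValueError(f"strategy {self.id!r}: negative insertion position")
        if self.n_deleted < 0:
            raise ValueError(f"strategy {self.id!r}: negative deletion count")
        _check_sequence(self.linker_before, f"strategy {self.id!r} linker_before")
        _check_sequence(self.linker_after, f"strategy {self.id!r} linker_after")


@dataclass(frozen=True)
class Construct:
    id: str
    insert_id: str
    strategy_id: str
    sequence: str
    label: int | None = None  # +1 soluble / -1 insoluble

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"construct {self.id!r}: empty sequence")
        _check_sequence(self.sequence, f"construct {self.id!r}")
        if self.label is not None and self.label not in (SOLUBLE, INSOLUBLE):
            raise ValueError(f"construct {self.id!r}: label must be +1/-1, got {self.label}")


def apply_insertion_strategy(backbone: str, insert: str, strategy: InsertionStrategy) -> str:
    """Splice ``insert`` into ``backbone`` according to ``strategy``."""
    _check_sequence(backbone, "backbone")
    _check_sequence(insert, "insert")
    pos, ndel = strategy.insertion_position, strategy.n_deleted
    if pos + ndel > len(backbone):
        raise IndexError(
            f"strategy {strategy.id!r}: position {pos} + {ndel} deletions exceeds "
            f"backbone length {len(backbone)}"
        )
    return (
        backbone[:pos]
        + strategy.linker_before
        + insert
        + strategy.linker_after
        + backbone[pos + ndel:]
    )


def build_construct_grid(
    backbone: str,
    inserts: dict[str, str] | Sequence[tuple[str, str]],
    strategies: Sequence[InsertionStrategy],
) -> list[Construct]:
    """All insert x strategy combinations, with ids ``<insert>_<strategy>``."""
    items = list(inserts.items()) if isinstance(inserts, dict) else list(inserts)
    ids = [iid for iid, _ in items]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate insert id(s): {dupes}")
    constructs = []
    for insert_id, insert_seq in items:
        for strat in strategies:
            seq = apply_insertion_strategy(backbone, insert_seq, strat)
            constructs.append(
                Construct(
                    id=f"{insert_id}_{strat.id}",
                    insert_id=insert_id,
                    strategy_id=strat.id,
                    sequence=seq,
                )
            )
    return constructs


def residue_counts(sequence: str) -> np.ndarray:
    """Length-20 residue count vector in canonical order."""
    _check_sequence(sequence)
    counts = np.zeros(20, dtype=float)
    for aa in sequence:
        counts[RESIDUE_INDEX[aa]] += 1
    return counts


_RESIDUE_LUT = np.full(128, -1, dtype=np.int64)
for _aa, _j in RESIDUE_INDEX.items():
    _RESIDUE_LUT[ord(_aa)] = _j


def residue_count_matrix(sequences: Iterable[str]) -> np.ndarray:
    """n x 20 matrix of residue counts, one row per sequence."""
    seqs = list(sequences)
    mat = np.zeros((len(seqs), 20), dtype=float)
    for i, seq in enumerate(seqs):
        _check_sequence(seq, f"sequence {i}")
        idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        mat[i] = np.bincount(_RESIDUE_LUT[idx], minlength=20)
    return mat


def compute_feature(sequence: str, scale: AminoAcidScale) -> float:
    """Sum of per-residue scale values over the whole sequence."""
    return float(residue_counts(sequence) @ scale.as_array())


@dataclass
class FeatureMatrix:
    """Constructs-by-scales matrix of summed hydrophobicity features."""

    values: np.ndarray
    construct_ids: list[str]
    scale_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.construct_ids), len(self.scale_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.construct_ids)} constructs x {len(self.scale_names)} scales"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_constructs(self) -> int:
        return len(self.construct_ids)

    @property
    def n_scales(self) -> int:
        return len(self.scale_names)

    def column(self, scale_name: str) -> np.ndarray:
        try:
            j = self.scale_names.index(scale_name)
        except ValueError:
            raise KeyError(f"no feature column for scale {scale_name!r}") from None
        return self.values[:, j]

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[idx], [self.construct_ids[i] for i in idx], list(self.scale_names)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.construct_ids, columns=self.scale_names)


def build_feature_matrix(constructs: Sequence[Construct], table: ScaleTable) -> FeatureMatrix:
    if not constructs or len(table) == 0:
        raise ValueError("need at least one construct and one scale")
    try:
        counts = residue_count_matrix(c.sequence for c in constructs)
    except SequenceError as exc:
        raise SequenceError(str(exc)) from exc
    values = counts @ table.matrix()
    return FeatureMatrix(values, [c.id for c in constructs], table.names)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def constructs_to_frame(constructs: Sequence[Construct]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in constructs],
            "insert_id": [c.insert_id for c in constructs],
            "strategy_id": [c.strategy_id for c in constructs],
            "sequence": [c.sequence for c in constructs],
            "label": [c.label if c.label is not None else "" for c in constructs],
        }
    )


def write_constructs_csv(constructs: Sequence[Construct], path: str | Path) -> None:
    constructs_to_frame(constructs).to_csv(path, index=False)


def read_constructs_csv(path: str | Path) -> list[Construct]:
    df = pd.read_csv(path, dtype={"id": str, "insert_id": str, "strategy_id": str})
    out = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", None)
        if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
            label = None
        else:
            label = int(label)
        out.append(
            Construct(
                id=row.id,
                insert_id=row.insert_id,
                strategy_id=row.strategy_id,
                sequence=row.sequence,
                label=label,
            )
        )
    return out


def write_strategies_yaml(strategies: Sequence[InsertionStrategy], path: str | Path) -> None:
    data = [
        {
            "id": s.id,
            "insertion_position": s.insertion_position,
            "n_deleted": s.n_deleted,
            "linker_before": s.linker_before,
            "linker_after": s.linker_after,
        }
        for s in strategies
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_strategies_yaml(path: str | Path) -> list[InsertionStrategy]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        InsertionStrategy(
            id=str(d["id"]),
            insertion_position=int(d["insertion_position"]),
            n_deleted=int(d.get("n_deleted", 0)),
            linker_before=str(d.get("linker_before", "") or ""),
            linker_after=str(d.get("linker_after", "") or ""),
        )
        for d in data
    ]
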