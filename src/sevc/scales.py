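"""Amino-acid hydrophobicity scale tables.

A scale maps each of the 20 canonical residues to a real number; sequence
features are sums of these values.  Scales are stored in a "wide" CSV
dialect: a ``residue`` column of one-letter codes followed by one column
per scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical one-letter residue codes, alphabetical.  All arrays indexed by
#: residue follow this order.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_INDEX: Mapping[str, int] = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}

#: Correlation at or below which two scales are considered mutual reversals.
REVERSAL_CORRELATION_THRESHOLD: float = -0.999


class ScaleError(ValueError):
    """Base class for scale validation/parsing problems."""


class ScaleValidationError(ScaleError):
    pass


class ScaleParseError(ScaleError):
    pass


class DegenerateScaleError(ScaleError):
    """Raised when a scale has zero variance and cannot be normalized."""


@dataclass(frozen=True)
class AminoAcidScale:
    """A named mapping from the 20 canonical residues to real values."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        canonical = set(CANONICAL_RESIDUES)
        missing = canonical - keys
        if missing:
            raise ScaleValidationError(
                f"scale {self.name!r}: missing residue(s) {sorted(missing)}"
            )
        extra = keys - canonical
        if extra:
            raise ScaleValidationError(
                f"scale {self.name!r}: non-canonical residue(s) {sorted(extra)}"
            )
        vals = np.asarray([float(self.values[aa]) for aa in CANONICAL_RESIDUES])
        if not np.all(np.isfinite(vals)):
            bad = [aa for aa in CANONICAL_RESIDUES if not np.isfinite(float(self.values[aa]))]
            raise ScaleValidationError(f"scale {self.name!r}: non-finite value(s) for {bad}")
        object.__setattr__(self, "values", dict(self.values))

    def as_array(self) -> np.ndarray:
        """Values ordered by :data:`CANONICAL_RESIDUES`."""
        return np.asarray([self.values[aa] for aa in CANONICAL_RESIDUES], dtype=float)

    @classmethod
    def from_array(cls, name: str, arr: Sequence[float]) -> "AminoAcidScale":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (20,):
            raise ScaleValidationError(f"expected 20 values, got shape {arr.shape}")
        return cls(name, dict(zip(CANONICAL_RESIDUES, arr.tolist())))

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass
class ScaleTable:
    """Ordered collection of uniquely named scales."""

    scales: list[AminoAcidScale]
    provenance: str = "literature"

    def __post_init__(self) -> None:
        names = [s.name for s in self.scales]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ScaleValidationError(f"duplicate scale name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self) -> Iterator[AminoAcidScale]:
        return iter(self.scales)

    def __getitem__(self, key: int | str) -> AminoAcidScale:
        if isinstance(key, str):
            for s in self.scales:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.scales[key]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.scales]

    def matrix(self) -> np.ndarray:
        """20 x k matrix, residues (canonical order) by scales (table order)."""
        return np.column_stack([s.as_array() for s in self.scales])


def normalize_scale(s: AminoAcidScale) -> AminoAcidScale:
    """Center to zero mean and scale to unit sample variance (ddof=1).

    Raises
    ------
    DegenerateScaleError
        If all 20 values are equal.
    """
    arr = s.as_array()
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise DegenerateScaleError(f"scale {s.name!r} has zero variance")
    return AminoAcidScale.from_array(s.name, (arr - arr.mean()) / sd)


def normalize_table(t: ScaleTable) -> ScaleTable:
    return ScaleTable([normalize_scale(s) for s in t.scales], provenance=t.provenance)


def dedupe_reversed(t: ScaleTable) -> ScaleTable:
    """Drop scales that are reversals of an earlier scale in the table.

    Two scales count as reversals of each other when the Pearson correlation
    of their values is at or below :data:`REVERSAL_CORRELATION_THRESHOLD`.
    The earlier-listed member of each pair is kept.
    """
    if len(t) == 0:
        raise ScaleValidationError("empty scale table")
    arrs = [s.as_array() for s in t.scales]
    kept: list[AminoAcidScale] = []
    kept_arrs: list[np.ndarray] = []
    for scale, arr in zip(t.scales, arrs):
        reversed_of = None
        for other, other_arr in zip(kept, kept_arrs):
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(arr, other_arr)[0, 1]
            if np.isfinite(corr) and corr <= REVERSAL_CORRELATION_THRESHOLD:
                reversed_of = other.name
                break
        if reversed_of is None:
            kept.append(scale)
            kept_arrs.append(arr)
        else:
            logger.info("dropping scale %r: reversal of %r", scale.name, reversed_of)
    return ScaleTable(kept, provenance=t.provenance)


def random_scale(seed: int | np.random.Generator, name: str = "random") -> AminoAcidScale:
    """Draw 20 standard-normal values and normalize them into a scale."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.standard_normal(20)
    return normalize_scale(AminoAcidScale.from_array(name, draws))


def load_scale_table(path: str | Path, provenance: str = "literature") -> ScaleTable:
    """Read a wide-CSV scale table (``residue`` column + one column per scale)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ScaleParseError(f"{path}: need a residue column plus at least one scale column")
    residue_col = df.columns[0]
    residues = df[residue_col].astype(str).str.strip().tolist()
    missing = sorted(set(CANONICAL_RESIDUES) - set(residues))
    if missing:
        raise ScaleValidationError(f"{path}: missing residue row(s) {missing}")
    extra = sorted(set(residues) - set(CANONICAL_RESIDUES))
    if extra:
        raise ScaleValidationError(f"{path}: non-canonical residue row(s) {extra}")
    scales = []
    for col in df.columns[1:]:
        values = {}
        for row_i, (aa, raw) in enumerate(zip(residues, df[col])):
            try:
                values[aa] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ScaleParseError(
                    f"{path}: non-numeric cell at row {row_i + 2}, column {col!r}: {raw!r}"
                ) from exc
        scales.append(AminoAcidScale(str(col), values))
    return ScaleTable(scales, provenance=provenance)


def write_scale_table(t: ScaleTable, path: str | Path) -> None:
    """Write the wide-CSV dialect read by :func:`load_scale_table`."""
    df = pd.DataFrame(
        {"residue": list(CANONICAL_RESIDUES)}
        | {s.name: s.as_array() for s in t.scales}
    )
    df.to_csv(path, index=False)
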