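"""Core in-memory containers shared by every pipeline stage.

The pipeline starts from a gene-by-sample abundance matrix (raw counts or
log2 values), gene-set collections in the MSigDB GMT dialect, two-column
mouse-to-human homolog maps, per-sample clinical/alteration tables and
gene-level segmented copy-number tables.  Each container validates its
invariants on construction so downstream operations can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IdentifierCollisionError, ValidationError

COUNTS = "counts"
LOG2 = "log2"
_SCALES = (COUNTS, LOG2)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise IdentifierCollisionError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


class ExpressionMatrix:
    """A genes x samples numeric matrix with a value-scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Row and column order are preserved.
    scale:
        ``"counts"`` (non-negative, no missing values) or ``"log2"``
        (unrestricted reals).
    """

    def __init__(self, data: pd.DataFrame, scale: str):
        if scale not in _SCALES:
            raise ValidationError(f"scale must be one of {_SCALES}, got {scale!r}")
        _check_unique(list(data.index.astype(str)), "gene")
        _check_unique(list(data.columns.astype(str)), "sample")
        values = data.to_numpy(dtype=float)
        if scale == COUNTS:
            if np.isnan(values).any():
                raise ValidationError("counts-scale matrix contains missing values")
            if (values < 0).any():
                bad = data.index[np.where(values < 0)[0][0]]
                raise ValidationError(
                    f"counts-scale matrix contains negative values (gene {bad!r})"
                )
        self._data = data.astype(float)
        self.scale = scale

    # -- accessors -------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self._data.index]
        return ExpressionMatrix(self._data.loc[genes], self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self._data.columns]
        if missing:
            raise ValidationError(f"unknown sample identifiers: {missing}")
        return ExpressionMatrix(self._data.loc[:, list(samples)], self.scale)

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, scale={self.scale})"


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"gene (set {self.name!r})")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Named gene sets; set names unique, every set non-empty."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise IdentifierCollisionError(f"duplicate set name: {s.name!r}")
            self._sets[s.name] = s

    @property
    def sets(self) -> Mapping[str, GeneSet]:
        return self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)


@dataclass
class HomologMap:
    """Source-to-target gene identifier pairs (e.g. mouse symbol -> human).

    Duplicate pairs are a construction error; real homology tables also
    contain many-to-many entries, which are kept here and filtered only at
    collapse time (strict 1:1 policy).
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            dupes = [p for p in self.pairs if self.pairs.count(p) > 1]
            raise ValidationError(f"duplicate homolog pairs: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.pairs)

    def one_to_one(self) -> list[tuple[str, str]]:
        """Pairs whose source and target each occur exactly once in the map."""
        src = pd.Series([s for s, _ in self.pairs])
        tgt = pd.Series([t for _, t in self.pairs])
        src_ok = set(src[~src.duplicated(keep=False)])
        tgt_ok = set(tgt[~tgt.duplicated(keep=False)])
        return [(s, t) for s, t in self.pairs if s in src_ok and t in tgt_ok]


# Clinical tables are plain DataFrames with documented columns; a validator
# keeps the invariants in one place without wrapping pandas.
CLINICAL_COLUMNS = ("time", "event")


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Check survival-record invariants: time > 0, event in {0, 1}."""
    for col in CLINICAL_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    recorded = table["time"].notna()
    if (table.loc[recorded, "time"] <= 0).any():
        bad = table.index[recorded & (table["time"] <= 0)][0]
        raise ValidationError(f"non-positive survival time for sample {bad!r}")
    ev = table.loc[table["event"].notna(), "event"]
    if not ev.isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 (censored) or 1 (death)")
    return table


class CopyNumberTable:
    """Gene-level segmented copy values with genomic positions.

    ``positions``: DataFrame indexed by gene with columns chromosome, start,
    end (1-based inclusive).  ``values``: genes x samples DataFrame on the
    segmented-copy scale (diploid ~ 2).
    """

    def __init__(self, positions: pd.DataFrame, values: pd.DataFrame):
        for col in ("chromosome", "start", "end"):
            if col not in positions.columns:
                raise ValidationError(f"positions missing column {col!r}")
        if not positions.index.equals(values.index):
            raise ValidationError("positions and values must share the same genes")
        _check_unique(list(positions.index.astype(str)), "gene")
        if (positions["start"] > positions["end"]).any():
            bad = positions.index[positions["start"] > positions["end"]][0]
            raise ValidationError(f"start > end for gene {bad!r}")
        self.positions = positions
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.positions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sorted_by_position(self) -> "CopyNumberTable":
        order = self.positions.sort_values(
            ["chromosome", "start"], kind="mergesort"
        ).index
        return CopyNumberTable(self.positions.loc[order], self.values.loc[order])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CopyNumberTable({len(self.gene_ids)} genes x "
            f"{len(self.sample_ids)} samples)"
        )
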