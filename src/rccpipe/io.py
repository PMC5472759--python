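"""Readers and writers for the flat-file dialects the pipeline consumes.

Canonical dialect is tab-separated text with a header row, matching the
flat files distributed for TCGA/GEO cohorts: expression tables are gene x
sample with gene identifiers in the first column; clinical tables are one
row per sample; copy-number tables carry chromosome/start/end columns
(1-based inclusive) before the per-sample copy values.  Missing clinical
values are the literal ``NA``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IdentifierCollisionError, ValidationError
from .types import (
    COUNTS,
    CopyNumberTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    HomologMap,
    validate_clinical,
)

logger = logging.getLogger("rccpipe")

_ROMAN_STAGE = {"I": 1, "II": 2, "III": 3, "IV": 4}
_STAGE_ROMAN = {v: k for k, v in _ROMAN_STAGE.items()}


def read_expression_tsv(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a gene-by-sample expression table.

    First column holds gene identifiers, header row the sample identifiers.
    Row and column order are preserved.  Duplicate identifiers and (under
    ``scale="counts"``) negative or missing values are rejected.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    body = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        raw_na = frame[col].isna() | (frame[col].astype(str).str.strip() == "NA")
        bad = converted.isna() & ~raw_na
        if bad.any():
            gene = frame.index[bad][0]
            raise FormatError(
                f"{path.name}: non-numeric value at gene {gene!r}, "
                f"sample {col!r} (column {j + 1})"
            )
        body[col] = converted
    return ExpressionMatrix(body, scale=scale)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name, description, then gene ids.

    Duplicate genes within a line are deduplicated with a logged warning;
    a line with fewer than three fields or a repeated set name is an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs name, description "
                    f"and at least one gene ({len(fields)} fields found)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in seen:
                raise IdentifierCollisionError(
                    f"{path.name}:{lineno}: duplicate set name {name!r}"
                )
            seen.add(name)
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "GMT set %s: %d duplicate gene entries collapsed",
                    name,
                    len(genes) - len(unique),
                )
            sets.append(GeneSet(name, description, unique))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_homolog_map(path: str | Path, header: bool = False) -> HomologMap:
    """Read a two-column source-to-target homolog table.

    ``header=True`` skips the first line.  Duplicate pairs collapse with a
    warning; an empty file yields an empty map with a warning.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    unique = list(dict.fromkeys(pairs))
    if len(unique) != len(pairs):
        logger.warning(
            "homolog map %s: %d duplicate pairs collapsed",
            path.name,
            len(pairs) - len(unique),
        )
    if not unique:
        logger.warning("homolog map %s is empty", path.name)
    return HomologMap(unique)


def write_homolog_map(hmap: HomologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, t in hmap.pairs:
            fh.write(f"{s}\t{t}\n")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-sample clinical/alteration table.

    Expected columns: ``sample`` (index), ``time`` (days), ``event`` (0/1);
    optional ``stage`` (I-IV or NA), ``grade`` (1-4 or NA), ``genotype`` and
    boolean alteration flags (0/1).  Stage roman numerals are converted to
    ordinal integers.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    table.index = table.index.astype(str)
    if "stage" in table.columns:
        table["stage"] = table["stage"].map(
            lambda v: _ROMAN_STAGE.get(str(v).strip(), v)
            if pd.notna(v)
            else np.nan
        )
        table["stage"] = pd.to_numeric(table["stage"], errors="raise")
    return validate_clinical(table)


def write_clinical_tsv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    if "stage" in out.columns:
        out["stage"] = out["stage"].map(
            lambda v: _STAGE_ROMAN.get(int(v), v) if pd.notna(v) else np.nan
        )
    out.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


def read_copy_number_tsv(path: str | Path) -> CopyNumberTable:
    """Read a gene-level copy table: gene, chromosome, start, end, samples..."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    frame.index = frame.index.astype(str)
    for col in ("chromosome", "start", "end"):
        if col not in frame.columns:
            raise FormatError(f"copy-number table missing column {col!r}")
    positions = frame[["chromosome", "start", "end"]].copy()
    positions["chromosome"] = positions["chromosome"].astype(str)
    values = frame.drop(columns=["chromosome", "start", "end"]).astype(float)
    if values.shape[1] == 0:
        raise FormatError("copy-number table has no sample columns")
    return CopyNumberTable(positions, values)


def write_copy_number_tsv(table: CopyNumberTable, path: str | Path) -> None:
    out = pd.concat([table.positions, table.values], axis=1)
    out.to_csv(path, sep="\t", index_label="gene", na_rep="NA")
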