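"""Readers and writers for the pipeline's TSV contracts.

All files are tab-delimited UTF-8 with a mandatory header row.

* genome metadata: ``genome_id``, ``clade``, optional ``display_name``
* presence, long layout: ``family_id``, ``genome_id`` (one row per
  occurrence; duplicates collapse)
* presence, matrix layout: ``family_id`` then one column per genome,
  cells 0/1
* essentiality: ``species``, ``protein_id``, ``is_ribosomal``,
  ``is_essential``, ``in_target_subset``
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .model import (
    CladeLabel,
    EssentialityRecord,
    GenomeRecord,
    PresenceMatrix,
    SchemaError,
)

__all__ = [
    "read_genome_metadata",
    "write_genome_metadata",
    "read_presence",
    "write_presence",
    "read_essentiality",
    "write_essentiality",
    "write_tsv_report",
]

_BOOL_STRINGS = {
    "0": False, "1": True,
    "true": True, "false": False,
    "yes": True, "no": False,
}


def _parse_bool(value: str, column: str, line: int) -> bool:
    try:
        return _BOOL_STRINGS[value.strip().lower()]
    except KeyError:
        raise SchemaError(
            f"line {line}: column {column!r}: {value!r} is not a boolean "
            "(accepted: 0/1/true/false/yes/no)"
        ) from None


def _require_columns(header: list[str], required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _read_rows(path: Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file (header row required)") from None
        return header, list(reader)


def read_genome_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read the genome metadata table.

    Clade strings are matched case-insensitively against the four valid
    labels; duplicate genome ids and unknown clades are errors.
    """
    path = Path(path)
    header, rows = _read_rows(path)
    _require_columns(header, ["genome_id", "clade"], path)
    idx = {name: i for i, name in enumerate(header)}
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for line_no, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        gid = row[idx["genome_id"]].strip()
        if gid in seen:
            raise SchemaError(f"{path}: line {line_no}: duplicate genome_id {gid!r}")
        seen.add(gid)
        try:
            clade = CladeLabel.parse(row[idx["clade"]])
        except SchemaError as exc:
            raise SchemaError(f"{path}: line {line_no}: {exc}") from None
        display = None
        if "display_name" in idx and len(row) > idx["display_name"]:
            display = row[idx["display_name"]].strip() or None
        records.append(GenomeRecord(gid, clade, display))
    return records


def write_genome_metadata(genomes: list[GenomeRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "clade": [g.clade.value for g in genomes],
            "display_name": [g.display_name or "" for g in genomes],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_presence(
    path: str | Path,
    layout: str,
    genomes: list[GenomeRecord] | None = None,
) -> PresenceMatrix:
    """Read a presence/absence table in ``long`` or ``matrix`` layout.

    In long layout the full genome set must be supplied via ``genomes``
    so that genomes carrying no families still enter the matrix as
    all-zero columns (coverage denominators come from metadata, not from
    the file).  In matrix layout ``genomes``, when given, is used to
    verify that every column resolves to a known genome.
    """
    path = Path(path)
    if layout == "long":
        if genomes is None:
            raise SchemaError("long layout requires the genome metadata")
        header, rows = _read_rows(path)
        _require_columns(header, ["family_id", "genome_id"], path)
        idx = {name: i for i, name in enumerate(header)}
        pairs = [
            (row[idx["family_id"]].strip(), row[idx["genome_id"]].strip())
            for row in rows
            if row and any(c.strip() for c in row)
        ]
        return PresenceMatrix.from_long(pairs, [g.genome_id for g in genomes])
    if layout == "matrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        try:
            numeric = frame.astype(float)
        except ValueError as exc:
            raise SchemaError(f"{path}: non-numeric presence cell ({exc})") from None
        matrix = PresenceMatrix(numeric)
        if genomes is not None:
            matrix.check_genomes(genomes)
        return matrix
    raise SchemaError(f"unknown presence layout {layout!r} (use 'long' or 'matrix')")


def write_presence(matrix: PresenceMatrix, path: str | Path, layout: str) -> None:
    """Write a presence matrix in either layout (round-trips exactly)."""
    path = Path(path)
    if layout == "matrix":
        frame = matrix.frame.copy()
        frame.index.name = "family_id"
        frame.to_csv(path, sep="\t")
        return
    if layout == "long":
        fam_idx, gen_idx = np.nonzero(matrix.frame.to_numpy())
        frame = pd.DataFrame(
            {
                "family_id": [matrix.family_ids[i] for i in fam_idx],
                "genome_id": [matrix.genome_ids[j] for j in gen_idx],
            }
        )
        frame.to_csv(path, sep="\t", index=False)
        return
    raise SchemaError(f"unknown presence layout {layout!r} (use 'long' or 'matrix')")


def read_essentiality(path: str | Path) -> list[EssentialityRecord]:
    """Read the per-species protein essentiality table."""
    path = Path(path)
    header, rows = _read_rows(path)
    required = ["species", "protein_id", "is_ribosomal", "is_essential", "in_target_subset"]
    _require_columns(header, required, path)
    idx = {name: i for i, name in enumerate(header)}
    records: list[EssentialityRecord] = []
    for line_no, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            rec = EssentialityRecord(
                species=row[idx["species"]].strip(),
                protein_id=row[idx["protein_id"]].strip(),
                is_ribosomal=_parse_bool(row[idx["is_ribosomal"]], "is_ribosomal", line_no),
                is_essential=_parse_bool(row[idx["is_essential"]], "is_essential", line_no),
                in_target_subset=_parse_bool(
                    row[idx["in_target_subset"]], "in_target_subset", line_no
                ),
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: line {line_no}: {exc}") from None
        records.append(rec)
    return records


def write_essentiality(records: Iterable[EssentialityRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "protein_id": [r.protein_id for r in records],
            "is_ribosomal": [int(r.is_ribosomal) for r in records],
            "is_essential": [int(r.is_essential) for r in records],
            "in_target_subset": [int(r.in_target_subset) for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_tsv_report(
    rows: list[dict[str, Any]],
    path: str | Path,
    columns: list[str] | None = None,
    rounding_digits: int = 4,
) -> None:
    """Write a stage result as a deterministic TSV report.

    Column order is fixed (from ``columns`` or the first row); floats are
    printed with ``rounding_digits`` decimals using round-half-even.
    Writing the same result twice yields byte-identical files.
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            out = []
            for col in columns:
                value = row.get(col, "")
                if isinstance(value, float) and not isinstance(value, bool):
                    out.append(format(round(value, rounding_digits), f".{rounding_digits}f"))
                else:
                    out.append(value)
            writer.writerow(out)
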