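"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: expression TSV (header row = sample ids, first column = gene id),
sample sheet TSV, GMT gene sets, BED6 TSS records, BED4 TFBS records and
the motif → TF mapping TSV.  Coordinates are BED-native 0-based half-open
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, GeneSetCatalog, SampleDesign


class BedParseError(ValueError):
    """Malformed BED line; message carries the 1-based line number."""


@dataclass(frozen=True)
class BedRecord:
    """One BED interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "+"


# ---------------------------------------------------------------- expression

def read_expression(path, origin: pd.Series | None = None,
                    state: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, state=state, origin=origin)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_sample_sheet(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_origin(path) -> pd.Series:
    """Two-column TSV gene_id ⇥ origin → Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index(df.columns[0])[df.columns[1]]


def write_origin(origin: pd.Series, path) -> None:
    origin.rename("origin").to_csv(path, sep="\t", index_label="gene_id")


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> GeneSetCatalog:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line needs ≥3 tab-separated fields: {line[:60]!r}")
        name, desc, *members = fields
        sets[name] = [m for m in members if m]
        descriptions[name] = desc
    return GeneSetCatalog(sets, descriptions)


def write_gmt(catalog: GeneSetCatalog, path) -> None:
    lines = []
    for name, members in catalog.sets.items():
        desc = catalog.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------- BED

def read_bed(path, min_fields: int = 4) -> list[BedRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < min_fields:
            raise BedParseError(
                f"{path}:{lineno}: expected ≥{min_fields} fields, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end < start:
            raise BedParseError(f"{path}:{lineno}: end < start")
        score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else 0.0
        strand = fields[5] if len(fields) > 5 else "+"
        records.append(BedRecord(fields[0], start, end, fields[3], score, strand))
    return records


def write_bed(records: list[BedRecord], path, fields: int = 6) -> None:
    lines = []
    for r in records:
        cols = [r.chrom, str(r.start), str(r.end), r.name]
        if fields >= 5:
            cols.append(f"{r.score:g}")
        if fields >= 6:
            cols.append(r.strand)
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------- motif map

def read_motif_map(path) -> dict[str, str]:
    """motif_id ⇥ tf_name TSV (header optional) → dict."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        motif, tf = line.rstrip("\n").split("\t")[:2]
        if motif == "motif_id":  # header row
            continue
        mapping[motif] = tf
    return mapping


def write_motif_map(mapping: dict[str, str], path) -> None:
    lines = ["motif_id\ttf_name"]
    lines += [f"{m}\t{t}" for m, t in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")
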