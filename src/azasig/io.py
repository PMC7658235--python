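"""Readers and writers for the pipeline's on-disk formats.

Everything is tab-separated plain text: expression TSV (genes x samples),
phenotype TSV, GMT gene-set files, and two-column edge lists. Lines whose
first character is ``#`` are comments. Readers validate strictly and fail
with an error naming the offending line or identifier; round trips are
lossless to 12 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    NON_RESPONDER,
    RESPONDER,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeTable,
    RegulatoryNetwork,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
]

_FLOAT_FMT = "%.12g"


def _data_lines(path: Path | str):
    """Yield (1-based line number, stripped line) skipping comments/blanks."""
    with open(path, "rt", encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield i, line


def read_expression(path: Path | str) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV.

    The header row carries sample IDs; the first column holds gene IDs.
    Duplicate IDs, negative or non-numeric values and ragged rows are
    rejected with an error naming the row or column.
    """
    rows = list(_data_lines(path))
    if not rows:
        raise ValidationError(f"{path}: empty expression file")
    header = rows[0][1].split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ValidationError(f"{path}: duplicate sample column {dup!r}")
    gene_ids: list[str] = []
    values: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise ValidationError(
                f"{path}:{lineno}: expected {len(samples) + 1} fields, "
                f"found {len(fields)}"
            )
        gene = fields[0]
        if gene in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene row {gene!r}")
        seen.add(gene)
        try:
            row = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-numeric value ({exc})")
        gene_ids.append(gene)
        values.append(row)
    frame = pd.DataFrame(values, index=gene_ids, columns=samples, dtype=float)
    return ExpressionMatrix(frame)


def write_expression(matrix: ExpressionMatrix, path: Path | str) -> None:
    matrix.data.to_csv(
        path, sep="\t", index_label="gene", float_format=_FLOAT_FMT
    )


def read_phenotypes(path: Path | str) -> PhenotypeTable:
    """Read a phenotype TSV: sample_id, group [, time, event].

    Group labels must be ``responder`` / ``non_responder`` / ``unknown``;
    event must be 0 or 1 (empty for unknown); time is months.
    """
    rows = list(_data_lines(path))
    if not rows:
        raise ValidationError(f"{path}: empty phenotype file")
    header = rows[0][1].split("\t")
    if header[0] != "sample_id" or "group" not in header:
        raise ValidationError(
            f"{path}: header must start with 'sample_id' and include 'group'"
        )
    records = []
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        rec = dict(zip(header, fields))
        row: dict[str, object] = {"sample_id": rec["sample_id"], "group": rec["group"]}
        if rec["group"] not in (RESPONDER, NON_RESPONDER, "unknown"):
            raise ValidationError(
                f"{path}:{lineno}: unrecognized group {rec['group']!r}"
            )
        for col in ("time", "event"):
            if col in rec:
                val = rec[col]
                row[col] = float(val) if val not in ("", "NA") else np.nan
        if "event" in row and not np.isnan(row["event"]):  # type: ignore[arg-type]
            if row["event"] not in (0.0, 1.0):
                raise ValidationError(
                    f"{path}:{lineno}: event must be 0 or 1, found {rec['event']!r}"
                )
        records.append(row)
    frame = pd.DataFrame.from_records(records).set_index("sample_id")
    return PhenotypeTable(frame)


def write_phenotypes(phenotypes: PhenotypeTable, path: Path | str) -> None:
    df = phenotypes.data.copy()
    if "event" in df.columns:
        df["event"] = df["event"].map(
            lambda x: "" if pd.isna(x) else str(int(x))
        )
    df.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


def read_gmt(path: Path | str) -> GeneSetCollection:
    """Read an MSigDB-style GMT file: name, description, then gene IDs.

    Duplicate genes within a line are dropped with a warning; a duplicated
    set name is an error.
    """
    collection = GeneSetCollection()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
            )
        name, description = fields[0], fields[1]
        genes: list[str] = []
        seen: set[str] = set()
        for g in fields[2:]:
            if not g:
                continue
            if g in seen:
                logger.warning(
                    "%s:%d: duplicate gene %r in set %r dropped",
                    path, lineno, g, name,
                )
                continue
            seen.add(g)
            genes.append(g)
        if name in collection:
            raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
        collection.add(GeneSet(name, description, tuple(genes)))
    if len(collection) == 0:
        raise ValidationError(f"{path}: empty GMT file")
    return collection


def write_gmt(collection: GeneSetCollection, path: Path | str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_network(path: Path | str) -> RegulatoryNetwork:
    """Read a two-column edge-list TSV (SIF-compatible without relation)."""
    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if first and fields[:2] == ["gene_a", "gene_b"]:
            first = False
            continue
        first = False
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: edge line needs 2 fields")
        a, b = fields[0], fields[1]
        if a == b:
            raise ValidationError(f"{path}:{lineno}: self-loop on {a!r}")
        key = frozenset((a, b))
        if key in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate edge {a!r}-{b!r}")
        seen.add(key)
        edges.append((a, b))
    return RegulatoryNetwork.from_edges(edges)


def write_network(network: RegulatoryNetwork, path: Path | str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in network.edges:
            fh.write(f"{a}\t{b}\n")
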