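"""Readers and writers for the table formats the pipeline consumes.

Supported dialects (all plain-text, delimiter auto-detected among tab and
comma unless given explicitly):

* miRDeep2-style quantifier output: a header row with a miRNA-id column
  (``#miRNA`` or ``miRNA``, else the first column) and one or more
  ``read_count`` columns.  A bare ``read_count`` column is a single sample
  named after the file stem; multi-sample files use ``read_count_<sample>``.
  A ``precursor`` column, if present, is ignored for identity: rows sharing
  a mature miRNA id are combined per the ``aggregate`` rule.
* Simplified Agilent feature-extraction export: a single table with a
  ``ProbeName`` (or ``probe_id``) column and one or more ``gProcessedSignal``
  columns (same single/multi-sample naming convention).  Multi-section
  vendor files are out of scope.
* Sample metadata: columns ``sample_id``, ``label``, ``replicate_group``,
  ``platforms`` (``+``-separated subset of ``ngs``/``microarray``).
* Canonical expression TSV: two comment header lines carrying the platform
  and scale tags, then a miRNA × sample table.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    ExpressionMatrix,
    FormatError,
    MatrixError,
    ProbeMap,
    SampleRecord,
    SampleTable,
)

__all__ = [
    "read_mirdeep2_counts",
    "read_agilent_signals",
    "read_sample_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_map",
    "write_probe_map",
    "write_sample_table",
]


def _read_table(path: str | os.PathLike, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        head = path.read_text().lstrip("﻿")
        first = head.splitlines()[0] if head.splitlines() else ""
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
    try:
        df = pd.read_csv(path, sep=delimiter, comment=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    return df


def _value_columns(df: pd.DataFrame, stem: str, base: str) -> tuple[list[str], list[str]]:
    """Find value columns named ``base`` or ``base_<sample>``.

    Returns (column names, sample ids)."""
    cols = [c for c in df.columns if c == base or c.startswith(base + "_")]
    if not cols:
        raise FormatError(f"missing {base} column")
    samples = [stem if c == base else c[len(base) + 1 :] for c in cols]
    return cols, samples


def read_mirdeep2_counts(
    path: str | os.PathLike,
    aggregate: str = "sum",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a miRDeep2-style expression table into a raw NGS matrix.

    Rows sharing a mature miRNA id (e.g. multiple precursors) are combined
    per ``aggregate``: ``"sum"`` adds their read counts (default, counts
    being additive evidence), ``"first"`` keeps the first occurrence.
    """
    if aggregate not in ("sum", "first"):
        raise ValueError(f"aggregate must be 'sum' or 'first', got {aggregate!r}")
    df = _read_table(path, delimiter)
    id_col = next((c for c in ("#miRNA", "miRNA", "mirna_id") if c in df.columns), df.columns[0])
    cols, samples = _value_columns(df, Path(path).stem, "read_count")

    values = df[cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise MatrixError(f"{path}: non-numeric read counts")
    if np.isnan(values).any():
        raise MatrixError(f"{path}: missing read counts")
    if (values < 0).any():
        raise MatrixError(f"{path}: negative read counts")

    ids: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for mirna, row in zip(df[id_col].astype(str), values):
        if mirna not in rows:
            ids.append(mirna)
            rows[mirna] = row.astype(float)
        elif aggregate == "sum":
            rows[mirna] = rows[mirna] + row
    return ExpressionMatrix(
        values=np.vstack([rows[m] for m in ids]),
        mirna_ids=ids,
        sample_ids=samples,
        platform="ngs",
        scale="raw",
    )


def read_agilent_signals(
    path: str | os.PathLike, delimiter: str | None = None
) -> ExpressionMatrix:
    """Read a simplified Agilent export into a probe-level raw matrix."""
    df = _read_table(path, delimiter)
    id_col = next((c for c in ("ProbeName", "probe_id", "probe") if c in df.columns), df.columns[0])
    cols, samples = _value_columns(df, Path(path).stem, "gProcessedSignal")
    probes = df[id_col].astype(str).tolist()
    dup = pd.Series(probes)[pd.Series(probes).duplicated()]
    if not dup.empty:
        raise MatrixError(f"{path}: duplicate probe id {dup.iloc[0]!r}")
    values = df[cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise MatrixError(f"{path}: missing signal values")
    return ExpressionMatrix(
        values=values,
        mirna_ids=probes,
        sample_ids=samples,
        platform="microarray",
        scale="raw",
    )


def read_sample_table(path: str | os.PathLike, delimiter: str | None = None) -> SampleTable:
    """Read sample metadata (labels, replicate groups, platforms)."""
    df = _read_table(path, delimiter)
    required = {"sample_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        platforms: frozenset[str] = frozenset()
        if "platforms" in df.columns and not pd.isna(row["platforms"]):
            raw = str(row["platforms"]).strip()
            if raw:
                platforms = frozenset(p.strip().lower() for p in raw.replace(";", "+").split("+") if p.strip())
        group = ""
        if "replicate_group" in df.columns and not pd.isna(row["replicate_group"]):
            group = str(row["replicate_group"])
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                label=str(row["label"]),
                replicate_group=group,
                platforms=platforms,
            )
        )
    return SampleTable(records)


def write_sample_table(table: SampleTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in table.records],
            "label": [r.label for r in table.records],
            "replicate_group": [r.replicate_group for r in table.records],
            "platforms": ["+".join(sorted(r.platforms)) for r in table.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# -- canonical expression TSV ------------------------------------------------


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write the canonical TSV: ``# platform=...`` / ``# scale=...`` headers
    followed by a miRNA × sample table (values at 12+ significant digits)."""
    if not isinstance(matrix, ExpressionMatrix):
        raise TypeError("expected an ExpressionMatrix")
    with open(path, "w") as fh:
        fh.write(f"# platform={matrix.platform}\n")
        fh.write(f"# scale={matrix.scale}\n")
        fh.write("mirna_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for mid, row in zip(matrix.mirna_ids, matrix.values):
            cells = "\t".join("NA" if np.isnan(v) else format(v, ".15g") for v in row)
            fh.write(f"{mid}\t{cells}\n")


def read_expression_matrix(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a matrix written by :func:`write_expression_matrix`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"], keep_default_na=False)
    if "platform" not in meta or "scale" not in meta:
        raise FormatError(f"{path}: missing platform/scale header lines")
    if df.columns[0] != "mirna_id":
        raise FormatError(f"{path}: first column must be 'mirna_id'")
    return ExpressionMatrix(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        mirna_ids=df["mirna_id"].astype(str).tolist(),
        sample_ids=[str(c) for c in df.columns[1:]],
        platform=meta["platform"],
        scale=meta["scale"],
    )


# -- probe map ---------------------------------------------------------------


def read_probe_map(path: str | os.PathLike, delimiter: str | None = None) -> ProbeMap:
    df = _read_table(path, delimiter)
    if not {"probe_id", "mirna_id"} <= set(df.columns):
        raise FormatError(f"{path}: need probe_id and mirna_id columns")
    probes = df["probe_id"].astype(str)
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise MatrixError(f"{path}: probe {dup!r} mapped more than once")
    return ProbeMap(dict(zip(probes, df["mirna_id"].astype(str))))


def write_probe_map(pmap: ProbeMap, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"probe_id": list(pmap.mapping), "mirna_id": list(pmap.mapping.values())}
    ).to_csv(path, sep="\t", index=False)
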