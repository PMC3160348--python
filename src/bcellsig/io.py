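"""Readers and writers for the pipeline's text formats.

Supported formats: GEO Series Matrix (the key-value + table dialect
used for deposited microarray series), a tab-delimited expression
matrix (probe id, optional gene symbol, then one column per sample),
tab-delimited sample annotations, ligand compendium and homolog-map
tables, GMT gene sets, and qPCR Ct tables.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CONTROL,
    PATIENT,
    ExpressionMatrix,
    FormatError,
    SampleAnnotation,
)
from .signature import HomologMap, LigandCompendium

SYMBOL_COLUMN = "gene_symbol"

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(
    path: str | Path,
    group_key: str = "disease state",
    control_pattern: str = r"control|healthy|normal",
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Parse a GEO Series Matrix file.

    Values in the data table are taken verbatim (they are assumed to be
    already normalized log2 intensities).  Sample titles and
    ``!Sample_characteristics_ch1`` lines are collected into the
    annotation; the group label is inferred from the characteristic
    whose key matches ``group_key`` (case-insensitive): values matching
    ``control_pattern`` become controls, everything else patients.
    """
    path = Path(path)
    header: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        low = line.strip().lower()
        if low == _TABLE_BEGIN:
            in_table, saw_begin = True, True
            continue
        if low == _TABLE_END:
            in_table, saw_end = False, True
            continue
        if in_table:
            if line.strip():
                table_lines.append(line)
        elif line.startswith("!"):
            key, *fields = line.split("\t")
            header.setdefault(key.lstrip("!").lower(), []).append(
                [f.strip().strip('"') for f in fields]
            )
    if not (saw_begin and saw_end):
        raise FormatError(f"{path.name}: missing series-matrix table markers")
    if not table_lines:
        raise FormatError(f"{path.name}: empty data table")

    cells = [l.split("\t") for l in table_lines]
    sample_ids = [c.strip().strip('"') for c in cells[0][1:]]
    probe_ids, rows = [], []
    for parts in cells[1:]:
        probe_ids.append(parts[0].strip().strip('"'))
        vals = parts[1:]
        if len(vals) != len(sample_ids):
            raise FormatError(f"{path.name}: ragged table row for {probe_ids[-1]}")
        row = []
        for v in vals:
            v = v.strip().strip('"')
            if v == "" or v.lower() in ("na", "nan", "null"):
                raise FormatError(
                    f"{path.name}: missing value for probe {probe_ids[-1]}"
                )
            row.append(float(v))
        rows.append(row)
    if len(set(probe_ids)) != len(probe_ids):
        raise FormatError(f"{path.name}: duplicate probe ids")

    matrix = ExpressionMatrix(
        pd.DataFrame(np.asarray(rows, dtype=float), index=probe_ids, columns=sample_ids)
    )

    ann = pd.DataFrame(index=sample_ids)
    titles = header.get("sample_title")
    if titles and len(titles[0]) == len(sample_ids):
        ann["title"] = titles[0]
    groups = pd.Series("", index=sample_ids, dtype=object)
    ctrl_re = re.compile(control_pattern, re.IGNORECASE)
    key_re = re.compile(re.escape(group_key), re.IGNORECASE)
    for char_fields in header.get("sample_characteristics_ch1", []):
        if len(char_fields) != len(sample_ids):
            continue
        for sid, entry in zip(sample_ids, char_fields):
            if ":" in entry:
                key, value = entry.split(":", 1)
            else:
                key, value = group_key, entry
            if key_re.search(key):
                groups[sid] = CONTROL if ctrl_re.search(value) else PATIENT
    if (groups == "").any():
        missing = groups.index[groups == ""].tolist()
        raise FormatError(
            f"{path.name}: no '{group_key}' characteristic for samples {missing[:5]}"
        )
    ann["group"] = groups
    return matrix, SampleAnnotation(ann)


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited matrix (probe id, optional gene symbol, samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    symbols = None
    if SYMBOL_COLUMN in df.columns:
        symbols = df.pop(SYMBOL_COLUMN).fillna("").astype(str)
    if df.isna().any().any():
        raise FormatError(f"{Path(path).name}: missing values in matrix")
    return ExpressionMatrix(df.astype(float), symbols)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    if (matrix.gene_symbols != "").any():
        out.insert(0, SYMBOL_COLUMN, matrix.gene_symbols)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    out = annotation.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_compendium(path: str | Path) -> LigandCompendium:
    """Tab-delimited ligand compendium: ligand, symbol, log2fc, timepoint_h."""
    df = pd.read_csv(path, sep="\t")
    return LigandCompendium(df)


def write_compendium(compendium: LigandCompendium, path: str | Path) -> None:
    compendium.table.to_csv(path, sep="\t", index=False)


def read_homolog_map(path: str | Path) -> HomologMap:
    """Two-column tab-delimited mouse-symbol / human-symbol pairs."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("homolog map needs two columns (mouse, human)")
    return HomologMap(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


def write_homolog_map(homolog_map: HomologMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(homolog_map.pairs.items()), columns=["mouse_symbol", "human_symbol"]
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: set name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line with fewer than 3 fields: {parts[0]!r}")
        name = parts[0]
        if name in sets:
            raise FormatError(f"duplicate gene set name: {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
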