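"""Readers and writers for every on-disk format the pipeline touches.

Canonical tabular dialect: UTF-8 TSV, no quoting, ``NA`` for missing cells.
Expression matrices put the feature id in the first column and sample ids in
the header. Gene sets go to GMT, perturbation libraries to GCT 1.2 (text,
dependency-free), and miRNA-target networks to SIF for network tools.

Readers are strict: duplicate identifiers, ragged rows, and non-numeric
cells raise :class:`FormatError` naming the offending id or line number
rather than being silently coerced.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    PerturbationLibrary,
    ValidationError,
    validate_annotation,
    validate_drug_response,
    validate_interactions,
)

__all__ = [
    "FormatError",
    "read_expression_table",
    "write_expression_table",
    "read_annotation",
    "write_annotation",
    "read_drug_response",
    "write_drug_response",
    "read_interactions",
    "write_interactions",
    "read_survival_table",
    "write_survival_table",
    "write_gct",
    "read_gct",
    "write_gmt",
    "read_gmt",
    "export_sif",
]

NA = "NA"


class FormatError(ValueError):
    """Malformed file content, with the location when determinable."""


def _check_rectangular(path: Path) -> list[list[str]]:
    """Split a TSV into cells, raising on ragged rows with the line number."""
    rows: list[list[str]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if lineno == 1 and not line:
                raise FormatError(f"{path}: empty header line")
            cells = line.split("\t")
            if rows and len(cells) != len(rows[0]):
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(cells)} fields, expected {len(rows[0])})"
                )
            rows.append(cells)
    if not rows:
        raise FormatError(f"{path}: empty file")
    return rows


def _parse_cell(cell: str, path: Path, lineno: int) -> float:
    if cell == NA or cell == "":
        return np.nan
    try:
        return float(cell)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric cell {cell!r} at line {lineno}"
        ) from None


def read_expression_table(
    path, probe_class_column: str | None = None
) -> ExpressionMatrix:
    """Read a features x samples TSV expression table.

    First column holds feature ids; the header row holds sample ids. If
    ``probe_class_column`` names a header token, that column is consumed as
    the per-feature probe class instead of a sample.
    """
    path = Path(path)
    rows = _check_rectangular(path)
    header = rows[0]
    sample_ids = header[1:]
    pc_idx = None
    if probe_class_column is not None:
        if probe_class_column not in sample_ids:
            raise FormatError(
                f"{path}: probe class column {probe_class_column!r} not in header"
            )
        pc_idx = sample_ids.index(probe_class_column)
        sample_ids = [s for i, s in enumerate(sample_ids) if i != pc_idx]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id {s!r}")
        seen.add(s)
    feature_ids: list[str] = []
    probe_classes: list[str] = []
    data: list[list[float]] = []
    seen_f: set[str] = set()
    for lineno, cells in enumerate(rows[1:], start=2):
        fid = cells[0]
        if fid in seen_f:
            raise FormatError(f"{path}: duplicate feature id {fid!r}")
        seen_f.add(fid)
        feature_ids.append(fid)
        values = cells[1:]
        if pc_idx is not None:
            probe_classes.append(values[pc_idx])
            values = [v for i, v in enumerate(values) if i != pc_idx]
        data.append([_parse_cell(v, path, lineno) for v in values])
    frame = pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype=float)
    pc = (
        pd.Series(probe_classes, index=feature_ids)
        if probe_class_column is not None
        else None
    )
    try:
        return ExpressionMatrix(frame, pc)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_table(matrix: ExpressionMatrix, path,
                           probe_class_column: str | None = None) -> None:
    path = Path(path)
    frame = matrix.values.copy()
    if probe_class_column is not None:
        if matrix.probe_class is None:
            raise FormatError("matrix carries no probe classes to write")
        frame.insert(0, probe_class_column, matrix.probe_class)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("feature_id\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        for fid, row in frame.iterrows():
            cells = [
                str(v) if isinstance(v, str) else (NA if pd.isna(v) else repr(float(v)))
                for v in row
            ]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def _read_long_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    rows = _check_rectangular(path)
    header = rows[0]
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    frame = pd.DataFrame(rows[1:], columns=header)
    return frame.replace({NA: np.nan, "": np.nan})


def read_annotation(path) -> pd.DataFrame:
    frame = _read_long_table(path, ("sample_id", "condition"))
    try:
        return validate_annotation(frame)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_drug_response(path) -> pd.DataFrame:
    frame = _read_long_table(
        path, ("cell_line", "drug", "source", "measure", "value")
    )
    frame["value"] = pd.to_numeric(frame["value"], errors="raise")
    try:
        return validate_drug_response(frame)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_drug_response(responses: pd.DataFrame, path) -> None:
    responses.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_interactions(path) -> pd.DataFrame:
    frame = _read_long_table(path, ("mirna_id", "target_gene"))
    try:
        return validate_interactions(frame)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_interactions(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_survival_table(path) -> pd.DataFrame:
    """Read a clinical follow-up table (subject_id, time, event)."""
    frame = _read_long_table(path, ("subject_id", "time", "event"))
    frame["time"] = pd.to_numeric(frame["time"], errors="raise")
    frame["event"] = pd.to_numeric(frame["event"], errors="raise").astype(int)
    return frame.set_index("subject_id")


def write_survival_table(clinical: pd.DataFrame, path) -> None:
    clinical.reset_index(names="subject_id").to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


# ---------------------------------------------------------------------------
# GCT 1.2


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write a GCT 1.2 text file (``#1.2`` header, NAME/Description columns)."""
    path = Path(path)
    n_rows, n_cols = matrix.shape
    if n_rows == 0 or n_cols == 0:
        raise FormatError("refusing to write an empty GCT matrix")
    for ident in list(matrix.feature_ids) + list(matrix.sample_ids):
        if "\t" in str(ident):
            raise FormatError(f"tab character in identifier {ident!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in matrix.values.iterrows():
            cells = [NA if pd.isna(v) else repr(float(v)) for v in row]
            fh.write(f"{fid}\t{NA}\t" + "\t".join(cells) + "\n")


def read_gct(path) -> ExpressionMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: not a GCT 1.2 file")
    try:
        n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise FormatError(f"{path}: malformed GCT dimension line") from None
    header = lines[2].split("\t")
    sample_ids = header[2:]
    if len(sample_ids) != n_cols:
        raise FormatError(
            f"{path}: header names {len(sample_ids)} samples, expected {n_cols}"
        )
    body = lines[3:]
    if len(body) != n_rows:
        raise FormatError(f"{path}: {len(body)} data rows, expected {n_rows}")
    feature_ids = []
    data = []
    for lineno, line in enumerate(body, start=4):
        cells = line.split("\t")
        if len(cells) != n_cols + 2:
            raise FormatError(f"{path}: ragged GCT row at line {lineno}")
        feature_ids.append(cells[0])
        data.append([_parse_cell(v, path, lineno) for v in cells[2:]])
    frame = pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype=float)
    try:
        return ExpressionMatrix(frame)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# GMT / SIF


def write_gmt(gene_sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    """Write named gene sets as GMT (name, description, members per line).

    Set names must be unique (dict input enforces that); an empty set is
    written as a memberless line.
    """
    path = Path(path)
    names = list(gene_sets)
    if len(set(names)) != len(names):
        raise FormatError("duplicate gene set names")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for name in names:
            desc = (descriptions or {}).get(name, NA)
            members = list(gene_sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise FormatError(f"{path}: malformed GMT line {lineno}")
            name = cells[0]
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set {name!r}")
            sets[name] = [c for c in cells[2:] if c]
    return sets


def export_sif(edges, path) -> None:
    """Write (source, relation, target) triples as SIF text."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for source, relation, target in edges:
            fh.write(f"{source}\t{relation}\t{target}\n")


# ---------------------------------------------------------------------------
# Perturbation library (GCT + metadata TSV)


def write_library(library: PerturbationLibrary, gct_path, meta_path,
                  responses_path=None) -> None:
    write_gct(ExpressionMatrix(library.scores), gct_path)
    library.meta.reset_index(names="perturbagen_id").to_csv(
        meta_path, sep="\t", index=False, na_rep=NA
    )
    if responses_path is not None and len(library.responses):
        library.responses.to_csv(responses_path, sep="\t", index=False, na_rep=NA)


def read_library(gct_path, meta_path, responses_path=None) -> PerturbationLibrary:
    scores = read_gct(gct_path).values
    meta = _read_long_table(meta_path, ("perturbagen_id",)).set_index(
        "perturbagen_id"
    )
    responses = pd.DataFrame()
    if responses_path is not None and Path(responses_path).exists():
        responses = _read_long_table(
            responses_path, ("perturbagen_id", "cell_line", "measure", "value")
        )
        responses["value"] = pd.to_numeric(responses["value"], errors="raise")
    return PerturbationLibrary(scores=scores, meta=meta, responses=responses)
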