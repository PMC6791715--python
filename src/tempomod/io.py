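"""Readers/writers for the canonical tabular artifacts.

All files are header-required, UTF-8, tab-separated, "." decimal point, no
thousands separators.  Gene identifiers (new-style locus tags, e.g.
``MXAN_RS20760``) are the primary keys throughout; old-style tags travel in
the optional ``alt_id`` column of the annotation.

Schemas
-------
annotation.tsv   gene_id, alt_id, length_bp, name, pathway
samples.tsv      sample_id, time_h, replicate, mapped_reads, rrna_reads
counts.tsv       gene_id + one integer column per sample_id
categories.tsv   gene_id, category  (optionally preceded by ``#labels: a,b``)
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

ANNOTATION_COLUMNS = ["gene_id", "alt_id", "length_bp", "name", "pathway"]
SAMPLE_COLUMNS = ["sample_id", "time_h", "replicate", "mapped_reads", "rrna_reads"]


def _read_rows(path) -> list[list[str]]:
    """Read a TSV into rows, raising ParseError on ragged lines."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ParseError(f"{path}: empty file, expected a header row")
    width = len(rows[0])
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
    return rows


def _to_int(value: str, what: str, *, minimum: int | None = None) -> int:
    try:
        out = int(value)
    except ValueError as exc:
        raise ValidationError(f"{what}: {value!r} is not an integer") from exc
    if minimum is not None and out < minimum:
        raise ValidationError(f"{what}: {out} < {minimum}")
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Gene annotation table: unique gene_id, ORF length in bp (>= 1)."""
    rows = _read_rows(path)
    if rows[0] != ANNOTATION_COLUMNS:
        raise SchemaError(f"{path}: header {rows[0]} != {ANNOTATION_COLUMNS}")
    df = pd.DataFrame(rows[1:], columns=ANNOTATION_COLUMNS)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r}")
    df["length_bp"] = [
        _to_int(v, f"{path}: length_bp of {g}", minimum=1)
        for g, v in zip(df["gene_id"], df["length_bp"])
    ]
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    rows = _read_rows(path)
    if rows[0] != SAMPLE_COLUMNS:
        raise SchemaError(f"{path}: header {rows[0]} != {SAMPLE_COLUMNS}")
    df = pd.DataFrame(rows[1:], columns=SAMPLE_COLUMNS)
    try:
        df["time_h"] = pd.to_numeric(df["time_h"])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric time_h") from exc
    for col, lo in [("replicate", 1), ("mapped_reads", 0), ("rrna_reads", 0)]:
        df[col] = [
            _to_int(v, f"{path}: {col} of {s}", minimum=lo)
            for s, v in zip(df["sample_id"], df[col])
        ]
    return validate_sample_sheet(df, origin=str(path))


def validate_sample_sheet(df: pd.DataFrame, origin: str = "sample sheet") -> pd.DataFrame:
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{origin}: duplicate sample_id")
    pairs = df[["time_h", "replicate"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise ValidationError(f"{origin}: duplicate (time_h, replicate) pair")
    bad = df["rrna_reads"] > df["mapped_reads"]
    if bad.any():
        sid = df.loc[bad, "sample_id"].iloc[0]
        raise ValidationError(f"{origin}: rrna_reads > mapped_reads for {sid}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    out = df.loc[:, SAMPLE_COLUMNS].copy()
    # canonical integer time where exact (0, 6, ... grid), else decimal
    out["time_h"] = [
        str(int(t)) if float(t) == int(t) else repr(float(t)) for t in out["time_h"]
    ]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def read_count_matrix(path, annotation: pd.DataFrame | None = None,
                      sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a genes x samples integer count matrix.

    First column is ``gene_id``; remaining column names are sample ids, which
    must all appear in *sheet* when one is given.  Genes absent from
    *annotation* (when given) are rejected, never silently dropped.
    """
    rows = _read_rows(path)
    header = rows[0]
    if not header or header[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be 'gene_id', got {header[:1]}")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise SchemaError(f"{path}: duplicated sample column")
    if sheet is not None:
        known = set(sheet["sample_id"])
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise SchemaError(f"{path}: samples not in sample sheet: {unknown}")
    genes, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        genes.append(row[0])
        data.append([
            _to_int(v, f"{path}: line {lineno} count", minimum=0) for v in row[1:]
        ])
    cm = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=samples)
    if cm.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id")
    if annotation is not None:
        missing = cm.index.difference(annotation["gene_id"])
        if len(missing):
            raise SchemaError(
                f"{path}: {len(missing)} genes absent from annotation "
                f"(first: {missing[0]!r})"
            )
    return cm


def write_count_matrix(cm: pd.DataFrame, path) -> None:
    cm.to_csv(path, sep="\t", index=True, index_label="gene_id")


# ---------------------------------------------------------------------------
# category table
# ---------------------------------------------------------------------------

def read_category_table(path, labels: set[str] | None = None) -> pd.DataFrame:
    """Two-column gene_id/category TSV.

    A leading ``#labels: a,b,c`` comment line declares the label set; an
    explicit *labels* argument overrides it.  With a declared label set,
    unknown labels raise; otherwise any string is accepted.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    declared = None
    skip = 0
    if first.startswith("#labels:"):
        declared = {s.strip() for s in first[len("#labels:"):].strip().split(",") if s.strip()}
        skip = 1
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))[skip:]
    if not rows or rows[0] != ["gene_id", "category"]:
        raise SchemaError(f"{path}: expected header gene_id<TAB>category")
    for lineno, row in enumerate(rows[1:], start=2 + skip):
        if len(row) != 2:
            raise ParseError(f"{path}: line {lineno} has {len(row)} fields, expected 2")
    df = pd.DataFrame(rows[1:], columns=["gene_id", "category"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene {dup!r}")
    label_set = labels if labels is not None else declared
    if label_set is not None:
        unknown = set(df["category"]) - set(label_set)
        if unknown:
            raise ValidationError(f"{path}: unknown category labels {sorted(unknown)}")
    df.attrs["labels"] = sorted(label_set) if label_set is not None else None
    return df


def write_category_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    labels = df.attrs.get("labels")
    with path.open("w", encoding="utf-8", newline="") as fh:
        if labels:
            fh.write("#labels: " + ",".join(labels) + "\n")
        df.loc[:, ["gene_id", "category"]].to_csv(fh, sep="\t", index=False)
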