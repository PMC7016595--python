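"""Readers and writers for the text formats the pipeline touches.

Expression matrices travel as GCT 1.2 or plain TSV (genes in rows, samples in
columns), gene sets as GMT, and sample annotations as TSV with a ``sample_id``
first column.  Gene and sample identifiers are opaque, case-sensitive strings;
no probe/symbol mapping is attempted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Scale = Literal["linear", "log2"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with a declared value scale.

    ``data`` is a pandas DataFrame indexed by gene id with sample ids as
    columns.  ``scale`` declares whether values are linear intensities or
    log2-transformed; rank-based scoring ignores it, but fold-change and
    mixing operations do not.
    """

    data: pd.DataFrame
    scale: Scale = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers after loading")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.data.shape[0] < 2 or self.data.shape[1] < 1:
            raise ValueError(
                f"need at least 2 genes and 1 sample, got shape {self.data.shape}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValueError(
                "expression values must be finite (no NaN/inf); "
                "use drop_missing_genes() upstream if needed"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (exponentiating declared-log2 values)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.data), scale="linear")

    def to_log2(self, pseudocount: float = 0.0) -> "ExpressionMatrix":
        """Return a log2-scale copy of declared-linear values."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.data + pseudocount), scale="log2")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], scale=self.scale)


@dataclass
class SampleAnnotation:
    """One sample's categorical labels (cell_type, group, treatment, ...).

    Missing cells are represented as ``None`` in ``labels``.
    """

    sample_id: str
    labels: dict[str, str | None] = field(default_factory=dict)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the row with the highest mean."""
    if not df.index.has_duplicates:
        return df
    dup_names = df.index[df.index.duplicated()].unique().tolist()
    means = df.mean(axis=1).to_numpy()
    # stable: among equal means the first occurrence wins
    keep = np.zeros(len(df), dtype=bool)
    order = pd.Series(np.arange(len(df)), index=df.index)
    for name in df.index.unique():
        pos = order.loc[[name]].to_numpy() if name in dup_names else None
        if pos is None:
            keep[order.loc[name]] = True
        else:
            keep[pos[np.argmax(means[pos])]] = True
    logger.info(
        "collapsed %d duplicate gene id(s) to highest-mean row: %s",
        len(dup_names),
        ", ".join(map(str, dup_names[:10])),
    )
    return df[keep]


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}; drop incomplete genes upstream"
        )
    return coerced.astype(float)


def read_expression(path, format: str = "tsv", scale: Scale = "linear") -> ExpressionMatrix:
    """Read an expression matrix from a GCT 1.2 or TSV file.

    Duplicate gene rows are collapsed to the highest-mean row (logged).
    """
    path = Path(path)
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT header '#1.2', got {version!r}")
            dims = fh.readline().strip().split("\t")
            if len(dims) < 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            try:
                n_genes, n_samples = int(dims[0]), int(dims[1])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer GCT dimensions {dims!r}") from exc
            body = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
        if "Description" in body.columns:
            body = body.drop(columns=["Description"])
        elif body.shape[1] == n_samples + 1:
            body = body.drop(columns=[body.columns[0]])
        if body.shape[0] != n_genes or body.shape[1] != n_samples:
            raise FormatError(
                f"{path}: GCT dimension line says {n_genes}x{n_samples} but body "
                f"is {body.shape[0]}x{body.shape[1]}"
            )
    elif format == "tsv":
        body = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    else:
        raise ValueError(f"unknown expression format {format!r}")
    body.index = body.index.astype(str)
    body.columns = body.columns.astype(str)
    body.index.name = None
    body.columns.name = None
    body = _check_numeric(body, path)
    body = _collapse_duplicate_genes(body)
    return ExpressionMatrix(body, scale=scale)


def write_expression(expr: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write an expression matrix as GCT 1.2 or TSV."""
    path = Path(path)
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            out = expr.data.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", lineterminator="\n")
    elif format == "tsv":
        out = expr.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", lineterminator="\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def drop_missing_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Optional pre-step: drop genes with any missing value (logged)."""
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        logger.info("dropping %d gene(s) with missing values", n_bad)
    return df.dropna(axis=0)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name<TAB>description<TAB>genes..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_annotations(path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV (header row; first column sample_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise FormatError(f"{path}: duplicated sample_id(s): {dups}")
    records = []
    for _, row in df.iterrows():
        labels = {
            col: (None if pd.isna(row[col]) else str(row[col]))
            for col in df.columns[1:]
        }
        records.append(SampleAnnotation(sample_id=str(row[id_col]), labels=labels))
    return records


def write_annotations(records: list[SampleAnnotation], path) -> None:
    keys: list[str] = []
    for rec in records:
        for k in rec.labels:
            if k not in keys:
                keys.append(k)
    rows = [
        {"sample_id": rec.sample_id, **{k: rec.labels.get(k) for k in keys}}
        for rec in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def annotation_series(records: list[SampleAnnotation], key: str) -> pd.Series:
    """Extract one annotation column as a Series indexed by sample id."""
    s = pd.Series(
        {rec.sample_id: rec.labels.get(key) for rec in records}, name=key, dtype=object
    )
    if s.notna().sum() == 0:
        raise ValueError(f"annotation column {key!r} has no non-missing values")
    return s


def validate_annotations(records: list[SampleAnnotation], expr: ExpressionMatrix) -> None:
    """Check every annotated sample exists in the companion matrix."""
    missing = [r.sample_id for r in records if r.sample_id not in expr.data.columns]
    if missing:
        raise ValueError(f"annotated sample(s) absent from expression matrix: {missing}")
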