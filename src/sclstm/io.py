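"""Reading and writing expression matrices, labels, and similarity matrices.

The canonical in-memory orientation is cells x genes; readers transpose
on-disk layouts as needed. Supported formats are delimited text (CSV/TSV,
dialect auto-detected from the header line) and Matrix Market triplets with
companion gene/barcode lists (10x convention: genes x cells on disk).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Input data violates an ExpressionMatrix/label invariant."""


class ParseError(ValueError):
    """File could not be parsed as the requested format."""


@dataclass
class ExpressionMatrix:
    """A cells x genes non-negative expression matrix with identifiers.

    Expression units (counts, CPM, TPM, FPKM, RPKM) are not interpreted.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression matrix must be 2-dimensional")
        n, m = self.values.shape
        if n < 2:
            raise ValidationError(
                "need at least 2 cells (pairwise similarity is undefined for n < 2)"
            )
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} rows"
            )
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != m:
            raise ValidationError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                "non-finite entries (missing values are not allowed; "
                "scRNA-seq zeros are zeros, not NA)"
            )
        if np.any(self.values < 0):
            raise ValidationError("negative expression entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusteringResult:
    """Per-cell integer cluster assignments plus provenance."""

    labels: np.ndarray
    k: int
    method: str = "AG"
    k_source: str = "given"
    seed: int | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        distinct = len(set(self.labels.tolist()))
        if distinct != self.k:
            raise ValidationError(
                f"result claims k={self.k} but has {distinct} distinct labels"
            )


def _detect_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_delimited(path: str) -> pd.DataFrame:
    sep = _detect_sep(path)
    with open(path) as fh:
        header_ids = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header_ids)) != len(header_ids):  # pandas silently renames dupes
        raise ValidationError(f"duplicate column ids in {path!r}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"cannot parse {path!r} as delimited matrix: {exc}") from exc
    if df.isna().any().any():
        bad = int(np.argmax(df.isna().any(axis=1).to_numpy())) + 2  # +header +1-based
        raise ValidationError(
            f"missing value around line {bad} of {path!r}; NA tokens are not allowed"
        )
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(
            f"non-numeric column(s) {non_numeric[:3]} in {path!r}"
        )
    return df


def _find_companion(path: str, names: Sequence[str]) -> str | None:
    d = os.path.dirname(os.path.abspath(path))
    for name in names:
        cand = os.path.join(d, name)
        if os.path.exists(cand):
            return cand
    return None


def _read_id_column(path: str) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            # 10x genes.tsv has two columns (id, symbol); take the first
            ids.append(line.split("\t")[0].split(",")[0])
    return ids


def read_expression_matrix(
    path: str,
    orientation: str | None = None,
    format: str | None = None,
    genes_path: str | None = None,
    barcodes_path: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix, returning it in cells x genes orientation.

    Parameters
    ----------
    path
        Delimited text file (first column = row ids, header = column ids)
        or a Matrix Market ``.mtx`` file.
    orientation
        ``"cells_by_genes"`` or ``"genes_by_cells"``, describing the on-disk
        layout. Defaults to ``cells_by_genes`` for delimited files and
        ``genes_by_cells`` for Matrix Market (the 10x convention).
    format
        ``"delimited"`` or ``"matrix_market"``; inferred from the extension
        when omitted.
    genes_path, barcodes_path
        Companion id files for Matrix Market input. When omitted, standard
        names (``genes.tsv``/``features.tsv``, ``barcodes.tsv``) are searched
        alongside the matrix.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "matrix_market" if path.endswith(".mtx") else "delimited"
    if format not in ("delimited", "matrix_market"):
        raise ValueError(f"unknown format {format!r}")

    if format == "delimited":
        orientation = orientation or "cells_by_genes"
        df = _read_delimited(path)
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    else:
        orientation = orientation or "genes_by_cells"
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ParseError(f"cannot parse {path!r} as Matrix Market: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        genes_path = genes_path or _find_companion(
            path, ("genes.tsv", "features.tsv", "genes.txt")
        )
        barcodes_path = barcodes_path or _find_companion(
            path, ("barcodes.tsv", "barcodes.txt")
        )
        if genes_path is None or barcodes_path is None:
            raise FileNotFoundError(
                "Matrix Market input requires companion gene and barcode id files"
            )
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(barcodes_path)
        if orientation == "genes_by_cells":
            row_ids, col_ids = gene_ids, cell_ids
        else:
            row_ids, col_ids = cell_ids, gene_ids

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")

    return ExpressionMatrix(values=values, cell_ids=row_ids, gene_ids=col_ids)


def filter_low_prevalence_genes(
    X: ExpressionMatrix, min_cells: int = 3
) -> ExpressionMatrix:
    """Keep genes expressed (value > 0) in at least ``min_cells`` cells.

    The default of 3 matches the common droplet-data preprocessing rule.
    Gene order is preserved; the cell set is unchanged.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    prevalence = np.count_nonzero(X.values > 0, axis=0)
    keep = prevalence >= min_cells
    if not keep.any():
        raise ValidationError(
            f"all {X.n_genes} genes expressed in fewer than {min_cells} cells; "
            "lower the threshold"
        )
    return ExpressionMatrix(
        values=X.values[:, keep],
        cell_ids=list(X.cell_ids),
        gene_ids=[g for g, k in zip(X.gene_ids, keep) if k],
    )


def read_labels(path: str) -> tuple[list[str] | None, list[str]]:
    """Read a label file: one column of labels, or (cell_id, label) pairs.

    Returns ``(cell_ids_or_None, labels)``. A header line is tolerated only
    for two-column files when the first field is literally ``cell_id``.
    """
    sep = _detect_sep(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                rows.append(line.split(sep))
    if not rows:
        raise ValidationError(f"empty label file {path!r}")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ParseError(f"ragged rows in label file {path!r}")
    if ncol == 1:
        return None, [r[0] for r in rows]
    if ncol == 2:
        if rows[0][0] == "cell_id":
            rows = rows[1:]
        return [r[0] for r in rows], [r[1] for r in rows]
    raise ParseError(f"label file {path!r} has {ncol} columns; expected 1 or 2")


def write_result(result: ClusteringResult, path: str) -> None:
    """Write assignments as two-column TSV: cell_id, cluster."""
    ids = result.cell_ids or [f"cell{i}" for i in range(len(result.labels))]
    with open(path, "w") as fh:
        fh.write("cell_id\tcluster\n")
        for cid, lab in zip(ids, result.labels):
            fh.write(f"{cid}\t{int(lab)}\n")


def read_result(path: str) -> ClusteringResult:
    ids, labels = read_labels(path)
    arr = np.asarray([int(v) for v in labels])
    return ClusteringResult(
        labels=arr, k=len(set(arr.tolist())), cell_ids=ids
    )


def write_matrix(M: np.ndarray, path: str, cell_ids: Sequence[str] | None = None) -> None:
    """Write a square cell x cell matrix as delimited text with id header."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("write_matrix expects a square matrix")
    ids = list(cell_ids) if cell_ids is not None else [f"cell{i}" for i in range(M.shape[0])]
    pd.DataFrame(M, index=ids, columns=ids).to_csv(path, float_format="%.17g")


def read_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    df = _read_delimited(path)
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path!r} is not square: {df.shape}")
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
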