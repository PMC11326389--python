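"""Readers and writers for count matrices and covariate tables.

Counts are accepted either as Matrix Market (``.mtx``) sparse triplets with
plain-text gene/barcode sidecar files, or as a dense CSV/TSV with gene ids
in the header row and cell ids in the first column.  Both MTX orientations
(genes x cells, the common 10x convention, and cells x genes) are accepted
and disambiguated by the sidecar lengths.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import CountMatrix, CovariateTable, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_covariates",
    "write_covariates",
]


def _read_ids(path: str) -> list:
    with open(path) as fh:
        # sidecars may be multi-column (10x genes.tsv has id + symbol); keep col 0
        return [line.split("\t")[0].split(",")[0].strip() for line in fh if line.strip()]


def _sidecar(path: str, stems: tuple) -> str:
    base = os.path.dirname(os.path.abspath(path))
    for stem in stems:
        cand = os.path.join(base, stem)
        if os.path.exists(cand):
            return cand
    raise ParseError(f"missing sidecar file (tried {', '.join(stems)}) next to {path}")


def read_count_matrix(
    path: str,
    format: str | None = None,
    cells_in_rows: bool | None = None,
) -> CountMatrix:
    """Read a count matrix from MTX (+ sidecars) or dense CSV/TSV.

    Parameters
    ----------
    path : str
        ``.mtx`` file, or delimited text with gene ids in the header row and
        cell ids in the first column.
    format : {"mtx", "csv"}, optional
        Inferred from the file extension when omitted.
    cells_in_rows : bool, optional
        For MTX only: orientation of the stored matrix.  By default it is
        inferred from the sidecar lengths; a square matrix with equal-length
        sidecars requires this flag.
    """
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "csv"
    if format == "mtx":
        return _read_mtx(path, cells_in_rows)
    if format == "csv":
        return _read_dense(path)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx(path: str, cells_in_rows: bool | None) -> CountMatrix:
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:  # malformed header / body
        raise ParseError(f"malformed MTX file {path}: {exc}") from exc
    mat = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    genes = _read_ids(_sidecar(path, ("genes.tsv", "features.tsv", "genes.txt")))
    cells = _read_ids(_sidecar(path, ("barcodes.tsv", "barcodes.txt")))
    nr, nc = mat.shape
    if cells_in_rows is None:
        if (nr, nc) == (len(cells), len(genes)) and (nr, nc) != (len(genes), len(cells)):
            cells_in_rows = True
        elif (nr, nc) == (len(genes), len(cells)) and (nr, nc) != (len(cells), len(genes)):
            cells_in_rows = False
        elif (nr, nc) == (len(cells), len(genes)) == (len(genes), len(cells)):
            raise ParseError(
                "square MTX with equal-length sidecars: pass cells_in_rows explicitly"
            )
        else:
            raise ParseError(
                f"MTX shape {nr}x{nc} matches neither sidecar orientation "
                f"({len(cells)} barcodes, {len(genes)} genes)"
            )
    if not cells_in_rows:
        mat = mat.T
    return CountMatrix(mat, cells, genes)


def _read_dense(path: str) -> CountMatrix:
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ParseError(f"malformed count file {path}: {exc}") from exc
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"non-numeric count for gene {col!r}, cell {bad.index[0]!r}: "
                f"{bad.iloc[0]!r}"
            )
    return CountMatrix(df.to_numpy(), list(df.index), list(df.columns))


def write_count_matrix(cm: CountMatrix, path: str, format: str | None = None) -> None:
    """Write counts as dense CSV/TSV or as MTX (cells x genes) with sidecars."""
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "csv"
    if format == "mtx":
        base = os.path.dirname(os.path.abspath(path))
        os.makedirs(base, exist_ok=True)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts))
        with open(os.path.join(base, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(cm.cell_ids) + "\n")
        with open(os.path.join(base, "genes.tsv"), "w") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
    else:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        cm.to_frame().to_csv(path, sep=sep)


def read_covariates(
    path: str,
    cell_matrix: CountMatrix | None = None,
    add_library_size: bool = True,
) -> CovariateTable:
    """Read a covariate table and align it to the count matrix cell order.

    The file needs a cell-id column (first column, or one named ``cell_id``
    / ``barcode``).  When ``cell_matrix`` is given, rows are reordered to its
    cell order and a ``library_size`` column (log total counts) is appended
    if absent and ``add_library_size`` is set.
    """
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    id_col = df.columns[0]
    for cand in ("cell_id", "barcode", "cell"):
        if cand in df.columns:
            id_col = cand
            break
    df = df.set_index(df[id_col].astype(str)).drop(columns=[id_col])
    if cell_matrix is not None:
        want, have = set(cell_matrix.cell_ids), set(df.index)
        missing = sorted(want - have)
        if missing:
            raise ParseError(f"covariates missing for cells: {', '.join(missing[:10])}")
        extra = sorted(have - want)
        if extra:
            raise ParseError(
                f"covariate cells absent from count matrix: {', '.join(extra[:10])}"
            )
        df = df.loc[cell_matrix.cell_ids]
        if add_library_size and "library_size" not in df.columns:
            df["library_size"] = np.log(np.maximum(cell_matrix.library_sizes(), 1))
    return CovariateTable(df)


def write_covariates(cov: CovariateTable, path: str) -> None:
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    out = cov.table.copy()
    out.index.name = "cell_id"
    out.to_csv(path, sep=sep)
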