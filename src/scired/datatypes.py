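"""Core data containers shared across the pipeline.

The pipeline passes three kinds of tabular objects around: raw counts
(cells x genes), per-cell covariates, and factor models (scores, loadings,
rotation).  They are small dataclasses over numpy arrays / pandas frames
with validation at construction, so downstream code can assume alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "CovariateTable",
    "FixtureConfig",
    "DesignMatrix",
    "FactorModel",
]


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


def _check_unique(ids, what: str) -> list:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ParseError(f"duplicate {what} identifier: {dup!r}")
    return ids


@dataclass
class CountMatrix:
    """Integer cell x gene count matrix with row/column identifiers.

    Parameters
    ----------
    counts : ndarray of shape (n_cells, n_genes)
        Non-negative integer-valued counts (dense).
    cell_ids, gene_ids : sequence of str
        Unique identifiers aligned to the rows / columns of ``counts``.
    """

    counts: np.ndarray
    cell_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ParseError("counts must be a 2-D matrix")
        n, g = self.counts.shape
        if n < 2 or g < 2:
            raise ParseError(f"need at least 2 cells and 2 genes, got {n} x {g}")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ParseError("counts must be numeric")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ParseError(
                f"negative count at cell {i}, gene {j}: {self.counts[i, j]}"
            )
        if not np.allclose(self.counts, np.round(self.counts)):
            i, j = np.argwhere(~np.isclose(self.counts, np.round(self.counts)))[0]
            raise ParseError(
                f"non-integer count at cell {i}, gene {j}: {self.counts[i, j]}"
            )
        self.counts = np.round(self.counts).astype(np.int64)
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(g)]
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if len(self.cell_ids) != n:
            raise ParseError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ParseError(f"{len(self.gene_ids)} gene ids for {g} columns")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total counts per cell."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.gene_ids)

    def filter_genes(self, min_cells: int = 3) -> "CountMatrix":
        """Drop genes expressed (count > 0) in fewer than ``min_cells`` cells."""
        keep = (self.counts > 0).sum(axis=0) >= min_cells
        if keep.sum() < 2:
            raise ValueError("fewer than 2 genes pass the expression filter")
        return CountMatrix(
            self.counts[:, keep],
            list(self.cell_ids),
            [g for g, k in zip(self.gene_ids, keep) if k],
        )


@dataclass
class CovariateTable:
    """Per-cell covariates aligned to a :class:`CountMatrix`.

    ``table`` holds one row per cell (index = cell ids, same order as the
    count matrix); each column is either categorical (object/category dtype)
    or numeric.
    """

    table: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)
        self.table.index = self.table.index.astype(str)
        if self.table.index.has_duplicates:
            raise ParseError("duplicate cell ids in covariate table")
        for col in self.table.columns:
            s = self.table[col]
            if pd.api.types.is_numeric_dtype(s):
                if not np.all(np.isfinite(s.to_numpy(dtype=float))):
                    raise ParseError(f"non-finite values in numeric covariate {col!r}")
            else:
                self.table[col] = s.astype(str)
                counts = self.table[col].value_counts()
                if not (counts >= 2).any():
                    # association scoring will drop such levels; keep the
                    # table usable for io round-trips and correlations
                    logging.getLogger(__name__).warning(
                        "categorical covariate %r has no level with >= 2 cells", col
                    )

    @property
    def cell_ids(self) -> list:
        return list(self.table.index)

    @property
    def columns(self) -> list:
        return list(self.table.columns)

    def is_categorical(self, name: str) -> bool:
        return not pd.api.types.is_numeric_dtype(self.table[name])

    def categorical_columns(self) -> list:
        return [c for c in self.columns if self.is_categorical(c)]

    def numeric_columns(self) -> list:
        return [c for c in self.columns if not self.is_categorical(c)]

    def levels(self, name: str) -> list:
        """Sorted levels of a categorical covariate."""
        return sorted(self.table[name].unique())

    def __getitem__(self, name: str) -> pd.Series:
        return self.table[name]


@dataclass
class FixtureConfig:
    """Parameters of the synthetic cell-line x protocol benchmark dataset.

    Emulates a cell-line mixture experiment: ``n_lines`` lines each carry a
    disjoint program of ``program_size`` genes upregulated ``program_effect``
    fold, and ``n_protocols`` library protocols differ in sequencing depth by
    the ``libsize_spread`` scale factors.
    """

    n_cells_per_group: int = 50
    n_genes: int = 300
    n_lines: int = 3
    n_protocols: int = 3
    program_size: int = 20
    program_effect: float = 3.0
    libsize_spread: tuple = (0.6, 1.0, 1.6)
    activity_jitter: float = 0.6
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    cell_log_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_cells_per_group < 1:
            raise ValueError("n_cells_per_group must be positive")
        if self.n_lines < 1 or self.n_protocols < 1:
            raise ValueError("need at least one line and one protocol")
        if self.program_effect < 1:
            raise ValueError("program_effect must be >= 1")
        if self.n_lines * self.program_size > self.n_genes:
            raise ValueError("line programs must be disjoint: too few genes")
        if len(self.libsize_spread) != self.n_protocols:
            raise ValueError("libsize_spread needs one scale per protocol")
        if self.activity_jitter < 0:
            raise ValueError("activity_jitter (log-sd of program activity) must be >= 0")


@dataclass
class DesignMatrix:
    """Encoded regression design: intercept + one-hot categoricals + scaled numerics."""

    matrix: np.ndarray
    column_names: list
    source_covariates: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design must be 2-D")
        if not np.allclose(self.matrix[:, 0], 1.0):
            raise ValueError("first design column must be the intercept")
        if len(self.column_names) != self.matrix.shape[1]:
            raise ValueError("column name count mismatch")

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FactorModel:
    """Scores (cells x k), loadings (genes x k) and the applied rotation.

    ``scores @ loadings.T`` approximates the centered residual matrix; for
    orthogonal rotations the product is invariant under rotation.
    """

    scores: np.ndarray
    loadings: np.ndarray
    rotation: np.ndarray
    explained_variance: np.ndarray
    rotation_kind: str = "none"
    cell_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        k = self.scores.shape[1]
        if self.loadings.shape[1] != k or self.rotation.shape != (k, k):
            raise ValueError("scores, loadings and rotation disagree on k")
        if self.rotation_kind not in {"none", "varimax", "promax"}:
            raise ValueError(f"unknown rotation kind {self.rotation_kind!r}")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.scores.shape[0])]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(self.loadings.shape[0])]

    @property
    def n_factors(self) -> int:
        return self.scores.shape[1]

    @property
    def factor_names(self) -> list:
        return [f"F{j + 1}" for j in range(self.n_factors)]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_ids, columns=self.factor_names)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=self.gene_ids, columns=self.factor_names
        )
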