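"""Ranked gene lists per factor and factor-covariate correlations.

Genes ordered by loading are the input to external enrichment tools;
Pearson correlation of factor scores with numeric technical covariates
(library size, genes detected, mitochondrial fraction, ...) flags factors
that are technically rather than biologically driven.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FactorModel

__all__ = [
    "RankedLoadings",
    "ranked_loadings",
    "top_genes",
    "factor_covariate_correlation",
    "export_ranked_list",
]

TECHNICAL_CORRELATION_THRESHOLD = 0.45


@dataclass
class RankedLoadings:
    factor_id: str
    genes: list
    loadings: list
    direction: str

    def __post_init__(self):
        if self.direction not in {"positive", "negative", "absolute"}:
            raise ValueError(f"unknown direction {self.direction!r}")
        if len(self.genes) != len(self.loadings):
            raise ValueError("genes/loadings length mismatch")


def _factor_column(model: FactorModel, factor_id) -> tuple[str, pd.Series]:
    frame = model.loadings_frame()
    if isinstance(factor_id, int):
        factor_id = frame.columns[factor_id]
    if factor_id not in frame.columns:
        raise KeyError(f"unknown factor {factor_id!r}")
    return factor_id, frame[factor_id]

def ranked_loadings(
    model: FactorModel, factor_id, direction: str = "positive"
) -> RankedLoadings:
    """All genes ordered by contribution to one factor.

    ``positive`` sorts by signed loading descending, ``negative`` ascending,
    ``absolute`` by |loading| descending; ties break by gene id (stable).
    """
    factor_id, col = _factor_column(model, factor_id)
    df = pd.DataFrame({"gene": col.index, "loading": col.to_numpy()})
    if direction == "positive":
        key, ascending = "loading", False
    elif direction == "negative":
        key, ascending = "loading", True
    elif direction == "absolute":
        df["_abs"] = df["loading"].abs()
        key, ascending = "_abs", False
    else:
        raise ValueError(f"unknown direction {direction!r}")
    df = df.sort_values(["gene"]).sort_values(key, ascending=ascending, kind="stable")
    return RankedLoadings(
        factor_id=factor_id,
        genes=list(df["gene"]),
        loadings=list(df["loading"]),
        direction=direction,
    )


def top_genes(
    model: FactorModel, factor_id, n: int = 200, direction: str = "positive"
) -> list:
    """First ``n`` genes of the ranked loading list (default 200)."""
    return ranked_loadings(model, factor_id, direction).genes[:n]


def factor_covariate_correlation(
    model: FactorModel,
    numeric_covariates,
    flag_threshold: float = TECHNICAL_CORRELATION_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of every factor with every numeric covariate.

    Returns ``(correlations, flagged)`` where ``flagged`` marks |r| above
    ``flag_threshold`` (factors likely driven by technical structure).
    """
    cov = pd.DataFrame(numeric_covariates)
    cov = cov.select_dtypes(include=[np.number])
    if cov.shape[1] == 0:
        raise ValueError("no numeric covariates given")
    scores = model.scores_frame()
    corr = pd.DataFrame(
        index=scores.columns, columns=cov.columns, dtype=float
    )
    for c in cov.columns:
        y = cov[c].to_numpy(dtype=float)
        for f in scores.columns:
            corr.loc[f, c] = float(np.corrcoef(scores[f].to_numpy(), y)[0, 1])
    return corr, (corr.abs() > flag_threshold)


def export_ranked_list(ranked: RankedLoadings, path: str) -> None:
    """Two-column TSV (gene, loading) preserving the ranking."""
    with open(path, "w") as fh:
        fh.write("gene\tloading\n")
        for g, l in zip(ranked.genes, ranked.loadings):
            fh.write(f"{g}\t{l:.10g}\n")
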