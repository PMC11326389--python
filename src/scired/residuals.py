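"""Removal of technical covariates with per-gene Poisson regression.

Each gene's counts are modeled as a Poisson GLM with log link on a shared
design matrix of technical covariates (library size, protocol, batch, ...).
The residuals of these fits — Pearson by default — form the matrix handed
to factorization: whatever structure the covariates explain is gone, and
the residual variance is approximately stabilized.

Residual conventions for observed y and fitted mean mu:

* Pearson:   (y - mu) / sqrt(mu)        (Poisson variance equals the mean)
* response:  y - mu
* deviance:  sign(y - mu) * sqrt(2 * (y*log(y/mu) - (y - mu))), 0*log 0 := 0
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import CountMatrix, CovariateTable, DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "build_design_matrix",
    "fit_poisson_glm",
    "pearson_residuals",
    "response_residuals",
    "deviance_residuals",
    "compute_residual_matrix",
    "PoissonResiduals",
    "GLMFitResult",
    "ResidualMatrix",
]

MU_FLOOR = 1e-10  # keeps Pearson residuals finite for all-zero genes
RESIDUAL_TYPES = ("pearson", "response", "deviance")


@dataclass
class GLMFitResult:
    coefficients: np.ndarray
    fitted_means: np.ndarray
    converged: bool

    def __post_init__(self):
        self.fitted_means = np.maximum(np.asarray(self.fitted_means, float), MU_FLOOR)


@dataclass
class ResidualMatrix:
    residuals: np.ndarray
    residual_type: str
    design_provenance: list
    cell_ids: list
    gene_ids: list

    def __post_init__(self):
        if self.residual_type not in RESIDUAL_TYPES:
            raise ValueError(f"unknown residual type {self.residual_type!r}")
        if not np.all(np.isfinite(self.residuals)):
            raise ValueError("residual matrix contains non-finite entries")


def build_design_matrix(
    covariates: CovariateTable, selected: list | None = None
) -> DesignMatrix:
    """Encode selected covariates as intercept + treatment-coded categoricals
    + standardized numerics, dropping collinear columns.

    The reference level of each categorical is the lexicographically first;
    numeric columns are centered and scaled to unit variance.  An empty
    selection yields the intercept-only design.
    """
    selected = list(selected or [])
    for name in selected:
        if name not in covariates.columns:
            raise KeyError(f"covariate {name!r} not in table")
    n = len(covariates.cell_ids)
    cols = [np.ones(n)]
    names = ["intercept"]
    for name in selected:
        s = covariates[name]
        if covariates.is_categorical(name):
            levels = covariates.levels(name)
            for lev in levels[1:]:  # first level is the reference
                cols.append((s == lev).to_numpy(float))
                names.append(f"{name}[{lev}]")
        else:
            x = s.to_numpy(float)
            sd = x.std()
            if sd == 0:
                logger.warning("constant numeric covariate %r dropped", name)
                continue
            cols.append((x - x.mean()) / sd)
            names.append(name)
    X = np.column_stack(cols)
    # rank-revealing QR: drop columns that add no rank (keep intercept first)
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            logger.warning("collinear design column %r dropped", names[j])
    if not selected:
        logger.info("empty covariate selection: intercept-only design")
    return DesignMatrix(X[:, keep], [names[j] for j in keep], selected)


def fit_poisson_glm(gene_counts: np.ndarray, design: DesignMatrix) -> GLMFitResult:
    """Maximum-likelihood Poisson fit (log link, IRLS) for one gene.

    All-zero genes short-circuit: the MLE mean is 0, returned floored at
    ``MU_FLOOR`` with ``converged=False`` rather than failing.
    """
    y = np.asarray(gene_counts, dtype=float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError("counts and design length mismatch")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if y.sum() == 0:
        return GLMFitResult(np.full(X.shape[1], -np.inf), np.full(len(y), MU_FLOOR), False)
    try:
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(maxiter=50, tol=1e-8)
        converged = bool(getattr(res, "converged", True))
        return GLMFitResult(res.params, res.mu, converged)
    except Exception as exc:  # pragma: no cover - degenerate numerical failure
        logger.warning("GLM fit failed (%s); falling back to intercept-only", exc)
        mean = max(y.mean(), MU_FLOOR)
        coef = np.full(X.shape[1], 0.0)
        coef[0] = np.log(mean)
        return GLMFitResult(coef, np.full(len(y), mean), False)


def pearson_residuals(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    y, mu = np.asarray(y, float), np.asarray(mu, float)
    if np.any(mu <= 0):
        raise ValueError("fitted means must be strictly positive")
    return (y - mu) / np.sqrt(mu)


def response_residuals(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return np.asarray(y, float) - np.asarray(mu, float)


def deviance_residuals(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    y, mu = np.asarray(y, float), np.asarray(mu, float)
    if np.any(mu <= 0):
        raise ValueError("fitted means must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        ylog = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    rad = 2.0 * (ylog - (y - mu))
    rad = np.maximum(rad, 0.0)  # clamp tiny negative rounding noise
    return np.sign(y - mu) * np.sqrt(rad)


_RESIDUAL_FN = {
    "pearson": pearson_residuals,
    "response": response_residuals,
    "deviance": deviance_residuals,
}


class PoissonResiduals(BaseEstimator, TransformerMixin):
    """Transformer: counts -> covariate-regressed Poisson GLM residuals.

    Parameters
    ----------
    residual_type : {"pearson", "response", "deviance"}, default "pearson"
        Residual flavor emitted by :meth:`transform`.

    Attributes
    ----------
    coefficients_ : ndarray of shape (n_genes, n_params)
    fitted_means_ : ndarray of shape (n_cells, n_genes)
    converged_ : boolean ndarray of shape (n_genes,)
    """

    def __init__(self, residual_type: str = "pearson"):
        self.residual_type = residual_type

    def fit(self, X: np.ndarray, design: DesignMatrix = None):
        if self.residual_type not in RESIDUAL_TYPES:
            raise ValueError(f"unknown residual type {self.residual_type!r}")
        X = np.asarray(X)
        if design is None:
            design = DesignMatrix(np.ones((X.shape[0], 1)), ["intercept"], [])
        self.design_ = design
        fits = [fit_poisson_glm(X[:, j], design) for j in range(X.shape[1])]
        self.coefficients_ = np.vstack([f.coefficients for f in fits])
        self.fitted_means_ = np.column_stack([f.fitted_means for f in fits])
        self.converged_ = np.array([f.converged for f in fits])
        n_bad = int((~self.converged_).sum())
        if n_bad:
            logger.info("%d genes flagged non-converged", n_bad)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape != self.fitted_means_.shape:
            raise ValueError("transform expects the matrix the model was fitted on")
        fn = _RESIDUAL_FN[self.residual_type]
        return fn(X, self.fitted_means_)

    def residuals(self, X: np.ndarray, residual_type: str | None = None) -> np.ndarray:
        """Residuals of a chosen flavor from the stored fit."""
        fn = _RESIDUAL_FN[residual_type or self.residual_type]
        return fn(np.asarray(X, float), self.fitted_means_)


def compute_residual_matrix(
    counts: CountMatrix,
    design: DesignMatrix,
    residual_type: str = "pearson",
) -> ResidualMatrix:
    """Per-gene Poisson fits on ``design`` followed by the chosen residual."""
    est = PoissonResiduals(residual_type=residual_type)
    est.fit(counts.counts, design)
    resid = est.transform(counts.counts)
    return ResidualMatrix(
        residuals=resid,
        residual_type=residual_type,
        design_provenance=list(design.source_covariates),
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
    )
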