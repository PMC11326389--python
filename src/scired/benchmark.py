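"""Permutation calibration of FCA scores and Gini sparsity summaries.

Shuffling a covariate's labels destroys any real factor association, so
re-scoring the FCA under many label permutations yields an empirical null
per (covariate level, factor) cell.  The empirical p-value is the fraction
of permuted scores at least as large as the observed one.  The Gini index
of a level's scores across factors summarizes how concentrated (sparse) its
associations are without committing to a p-value cutoff:

    G_k = (1 / (2 n^2 xbar)) * sum_i sum_j |x_i - x_j|,    G = mean_k G_k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import DEFAULT_CLASSIFIERS, EnsembleFCA, FCATable
from .datatypes import CovariateTable

logger = logging.getLogger(__name__)

__all__ = [
    "permute_labels",
    "empirical_pvalues",
    "count_significant",
    "gini_level",
    "global_gini",
    "run_permutation_benchmark",
    "PermutationResult",
    "GiniSummary",
]


@dataclass
class PermutationResult:
    n_perm: int
    pvalues: pd.DataFrame  # covariate-level x factor
    observed: FCATable
    alpha: float = 0.05
    seed: int = 0

    @property
    def n_significant_per_level(self) -> pd.Series:
        return count_significant(self.pvalues, self.alpha)[0]

    def format_pvalue(self, p: float) -> str:
        """Boundary p-values of 0 are reported as '< 1/n_perm'."""
        return f"< {1.0 / self.n_perm:g}" if p == 0 else f"{p:g}"


@dataclass
class GiniSummary:
    per_level: pd.Series
    global_gini: float


def permute_labels(covariates, covariate_name: str, seed: int = 0) -> np.ndarray:
    """Uniform random permutation of one covariate's level assignments."""
    if isinstance(covariates, CovariateTable):
        labels = covariates[covariate_name].to_numpy()
    else:
        labels = np.asarray(covariates[covariate_name])
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(len(labels))]


def empirical_pvalues(
    observed_fca: FCATable,
    permuted_fcas: list,
    pooled: bool = False,
    smoothed: bool = False,
) -> pd.DataFrame:
    """Per-cell empirical p-values against the permutation null.

    Default null is per (level, factor) cell: p = #(perm >= obs) / n_perm
    exactly as printed; ``smoothed`` applies the (r+1)/(n+1) correction and
    ``pooled`` compares each observed cell to the permuted values pooled
    across factors within its level.
    """
    if not permuted_fcas:
        raise ValueError("need at least one permutation")
    obs = observed_fca.values
    perms = np.stack([p.values.to_numpy() for p in permuted_fcas])  # (B, L, K)
    if perms.shape[1:] != obs.shape:
        raise ValueError("permuted and observed FCA shapes differ")
    B = perms.shape[0]
    o = obs.to_numpy()[None, :, :]
    if pooled:
        # compare each cell against all permuted values of its level
        counts = (perms[:, :, :, None] >= o[:, :, None, :]).sum(axis=(0, 2))
        denom = B * perms.shape[2]
    else:
        counts = (perms >= o).sum(axis=0)
        denom = B
    if smoothed:
        p = (counts + 1) / (denom + 1)
    else:
        p = counts / denom
    return pd.DataFrame(p, index=obs.index, columns=obs.columns)


def count_significant(pvalues: pd.DataFrame, alpha: float = 0.05):
    """Count p < alpha per covariate level; returns (counts, mean).

    A mean well above 1 suggests false positive associations (low
    specificity); zeros per level suggest false negatives (low sensitivity).
    """
    counts = (pvalues < alpha).sum(axis=1)
    return counts, float(counts.mean())


def _rectify(x: np.ndarray) -> np.ndarray:
    """Shift by the minimum so the Gini formula's mean is positive."""
    x = np.asarray(x, dtype=float)
    if x.min() < 0:
        logger.debug("shifting scores by %g for Gini non-negativity", -x.min())
        x = x - x.min()
    return x


def gini_level(values, rectify: bool = True) -> float:
    """Gini coefficient of one level's association scores across factors.

    Fast sorted form of the mean-absolute-difference double sum
    G = sum_i sum_j |x_i - x_j| / (2 n^2 xbar); 0 for identical values,
    (n-1)/n for a one-hot vector.
    """
    x = np.asarray(values, dtype=float)
    if rectify:
        x = _rectify(x)
    if np.any(x < 0):
        raise ValueError("Gini requires non-negative values")
    n = len(x)
    total = x.sum()
    if total == 0:
        return 0.0
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    # sum_i sum_j |x_i - x_j| = 2 * sum_i (2i - n - 1) x_(i)
    mad_sum = 2.0 * np.sum((2 * i - n - 1) * xs)
    g = mad_sum / (2.0 * n**2 * (total / n))
    if abs(g) < 1e-13:  # cancellation noise on (near-)constant input
        g = 0.0
    return float(g)


def global_gini(fca, rectify_globally: bool = True) -> GiniSummary:
    """Per-level Gini coefficients and their unweighted mean.

    Standardized FCA values can be negative; by default the whole table is
    shifted by its global minimum before the per-level formula.
    """
    values = fca.values if isinstance(fca, FCATable) else pd.DataFrame(fca)
    arr = values.to_numpy(dtype=float)
    if rectify_globally and arr.min() < 0:
        arr = arr - arr.min()
    per = pd.Series(
        [gini_level(arr[i], rectify=False) for i in range(arr.shape[0])],
        index=values.index,
    )
    return GiniSummary(per_level=per, global_gini=float(per.mean()))


def run_permutation_benchmark(
    model,
    covariates: CovariateTable,
    covariate_names: list | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    classifiers: tuple = DEFAULT_CLASSIFIERS,
    scaling: str = "standardize",
    mean: str = "arithmetic",
    pooled: bool = False,
    smoothed: bool = False,
) -> PermutationResult:
    """Full permutation test: recompute the ensemble FCA under ``n_perm``
    label shuffles of each tested covariate and derive empirical p-values.

    Each permutation re-runs the complete classifier ensemble on the
    shuffled labels (expensive but faithful to the calibration it checks).
    """
    names = covariate_names or covariates.categorical_columns()
    est = EnsembleFCA(
        classifiers=classifiers, scaling=scaling, mean=mean, random_state=seed
    )
    observed = est.fit_table(model, covariates, names)
    rng = np.random.default_rng(seed)
    permuted = []
    for b in range(n_perm):
        shuffled = covariates.table.copy()
        for cov in names:
            labels = shuffled[cov].to_numpy()
            shuffled[cov] = labels[rng.permutation(len(labels))]
        perm_cov = CovariateTable(shuffled)
        permuted.append(est.fit_table(model, perm_cov, names))
    pvals = empirical_pvalues(observed, permuted, pooled=pooled, smoothed=smoothed)
    result = PermutationResult(
        n_perm=n_perm, pvalues=pvals, observed=observed, alpha=alpha, seed=seed
    )
    result.permuted_fcas = permuted
    return result
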