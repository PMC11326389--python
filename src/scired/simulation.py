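"""Two-component Gaussian-mixture factor simulator and metric validation.

Synthetic factors are drawn from p*N(mu1, sigma1^2) + (1-p)*N(mu2, sigma2^2)
with component parameters sampled per factor (mu ~ U(0, 4), sigma ~
U(0.5, 1), p = 0.5 by default).  The ground-truth difficulty of each factor
is the overlap O of its two component densities,

    O = 1 - 1/2 [ erf((c - mu1)/(sqrt(2) sigma1)) - erf((c - mu2)/(sqrt(2) sigma2)) ]

evaluated at the density intersection point c (with mu1 < mu2).  Correlating
each interpretability metric with O across factors, over repeated rounds,
shows which metrics actually track separability: good separability metrics
correlate negatively with overlap, homogeneity positively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from . import interpretability as fis

__all__ = [
    "MixtureParams",
    "SimulatedFactors",
    "MetricOverlapReport",
    "simulate_mixture_factors",
    "gaussian_intersection",
    "gaussian_overlap",
    "metric_overlap_correlation",
]


@dataclass
class MixtureParams:
    """Sampling ranges and sizes for the mixture-factor simulator."""

    n_cells: int = 10000
    n_factors: int = 10
    n_rounds: int = 100
    p: float = 0.5
    mu_min: float = 0.0
    mu_max: float = 4.0
    sigma_min: float = 0.5
    sigma_max: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("mixture proportion must lie in (0, 1)")
        if self.sigma_min <= 0 or self.sigma_max < self.sigma_min:
            raise ValueError("sigma range must be positive and ordered")
        if self.mu_max < self.mu_min:
            raise ValueError("mu range must be ordered")


@dataclass
class SimulatedFactors:
    scores: np.ndarray  # n_cells x n_factors
    component_labels: np.ndarray  # n_cells x n_factors, values 1/2
    true_params: pd.DataFrame  # per factor: mu1, mu2, sigma1, sigma2, p
    true_overlap: np.ndarray  # per factor

    def __post_init__(self):
        if not np.all(np.isin(self.component_labels, (1, 2))):
            raise ValueError("component labels must be 1 or 2")
        if np.any((self.true_overlap < 0) | (self.true_overlap > 1)):
            raise ValueError("overlap must lie in [0, 1]")


@dataclass
class MetricOverlapReport:
    correlations: pd.DataFrame  # rounds x metrics
    summary: pd.DataFrame = field(init=False)  # metric: mean, sd, expected sign

    EXPECTED_SIGN = {
        "silhouette": -1,
        "bimodality_index": -1,
        "vrs": -1,
        "wvrs": -1,
        "davies_bouldin_scaled": -1,
        "dip": -1,
        "variance": 0,
        "simpson": -1,
        "asv_arithmetic": +1,
        "asv_geometric": +1,
    }

    def __post_init__(self):
        mean = self.correlations.mean()
        sd = self.correlations.std()
        self.summary = pd.DataFrame(
            {
                "mean_correlation": mean,
                "sd_correlation": sd,
                "expected_sign": [
                    self.EXPECTED_SIGN.get(m, 0) for m in self.correlations.columns
                ],
            }
        )


def simulate_mixture_factors(params: MixtureParams) -> SimulatedFactors:
    """Draw one round of mixture factors; pure function of ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n, k = params.n_cells, params.n_factors
    scores = np.empty((n, k))
    labels = np.empty((n, k), dtype=np.int64)
    rows = []
    overlaps = np.empty(k)
    for j in range(k):
        mu = rng.uniform(params.mu_min, params.mu_max, 2)
        sigma = rng.uniform(params.sigma_min, params.sigma_max, 2)
        comp = rng.random(n) < params.p  # True -> component 1
        x = np.where(
            comp,
            rng.normal(mu[0], sigma[0], n),
            rng.normal(mu[1], sigma[1], n),
        )
        scores[:, j] = x
        labels[:, j] = np.where(comp, 1, 2)
        rows.append(
            {"mu1": mu[0], "mu2": mu[1], "sigma1": sigma[0], "sigma2": sigma[1], "p": params.p}
        )
        overlaps[j] = gaussian_overlap(mu[0], sigma[0], mu[1], sigma[1])
    return SimulatedFactors(
        scores=scores,
        component_labels=labels,
        true_params=pd.DataFrame(rows, index=[f"F{j + 1}" for j in range(k)]),
        true_overlap=overlaps,
    )


def gaussian_intersection(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Intersection point c of two normal densities.

    Equal spreads give the midpoint (mu1+mu2)/2; unequal spreads solve the
    quadratic from equating log densities and return the root between the
    means (the one relevant to the shared mass).
    """
    if mu1 == mu2 and sigma1 == sigma2:
        raise ValueError("identical components have no unique intersection")
    if np.isclose(sigma1, sigma2):
        if mu1 == mu2:
            raise ValueError("identical means and spreads")
        return (mu1 + mu2) / 2.0
    a = 1.0 / sigma2**2 - 1.0 / sigma1**2
    b = 2.0 * (mu1 / sigma1**2 - mu2 / sigma2**2)
    c0 = mu2**2 / sigma2**2 - mu1**2 / sigma1**2 + 2.0 * np.log(sigma2 / sigma1)
    disc = b**2 - 4 * a * c0
    if disc < 0:
        raise ValueError("no real density intersection")
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    lo, hi = min(mu1, mu2), max(mu1, mu2)
    inside = roots[(roots >= lo) & (roots <= hi)]
    if len(inside):
        return float(inside[0])
    # same-mean case: either root; otherwise the closest to the interval
    return float(roots[np.argmin(np.abs(roots - (lo + hi) / 2))])


def gaussian_overlap(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Shared probability mass of two normal components via the erf formula
    at their density intersection (components ordered so mu1 <= mu2)."""
    if (mu2, sigma2) < (mu1, sigma1):
        mu1, sigma1, mu2, sigma2 = mu2, sigma2, mu1, sigma1
    if mu1 == mu2 and sigma1 == sigma2:
        return 1.0
    if np.isclose(mu1, mu2):
        # equal means: two symmetric intersections at mu +- d; the narrow
        # component is the minimum in the tails, the wide one in the middle
        sn, sw = sorted((sigma1, sigma2))
        d2 = 2.0 * np.log(sw / sn) / (1.0 / sn**2 - 1.0 / sw**2)
        d = np.sqrt(d2)
        o = (1.0 - erf(d / (np.sqrt(2.0) * sn))) + erf(d / (np.sqrt(2.0) * sw))
        return float(min(max(o, 0.0), 1.0))
    c = gaussian_intersection(mu1, sigma1, mu2, sigma2)
    o = 1.0 - 0.5 * (
        erf((c - mu1) / (np.sqrt(2.0) * sigma1))
        - erf((c - mu2) / (np.sqrt(2.0) * sigma2))
    )
    return float(min(max(o, 0.0), 1.0))


def metric_overlap_correlation(
    params: MixtureParams,
    metrics: tuple = (
        "silhouette",
        "bimodality_index",
        "dip",
        "variance",
        "asv_arithmetic",
        "asv_geometric",
    ),
) -> MetricOverlapReport:
    """Correlate interpretability metrics with true component overlap.

    Per round: simulate ``n_factors`` factors, compute each metric per
    factor (separability metrics label-free via the 2-means split;
    homogeneity from the true component labels as a 2-level covariate),
    then Pearson-correlate metric values with true overlaps across factors.
    ``simpson`` (specificity) is available but costs a full ensemble-FCA run
    per factor, with the factor's own component labels as the covariate.
    """
    rows = []
    for r in range(params.n_rounds):
        round_params = MixtureParams(**{**params.__dict__, "seed": params.seed + r})
        sim = simulate_mixture_factors(round_params)
        vals = {m: [] for m in metrics}
        for j in range(params.n_factors):
            x = sim.scores[:, j]
            comp = sim.component_labels[:, j]
            needs_split = {"silhouette", "vrs", "wvrs", "davies_bouldin_scaled"}
            labels = (
                fis.kmeans2_partition(x, seed=round_params.seed)
                if needs_split & set(metrics)
                else None
            )
            for m in metrics:
                if m == "silhouette":
                    vals[m].append(fis.silhouette_sep(x, labels))
                elif m == "vrs":
                    vals[m].append(fis.vrs(x, labels))
                elif m == "wvrs":
                    vals[m].append(fis.wvrs(x, labels))
                elif m == "davies_bouldin_scaled":
                    vals[m].append(fis.davies_bouldin_scaled(x, labels))
                elif m == "bimodality_index":
                    vals[m].append(fis.bimodality_index(x, seed=round_params.seed)[0])
                elif m == "dip":
                    vals[m].append(fis.dip_statistic(x))
                elif m == "variance":
                    vals[m].append(fis.effect_size_variance(x))
                elif m == "asv_arithmetic":
                    vals[m].append(fis.asv_homogeneity(x, comp, "arithmetic"))
                elif m == "asv_geometric":
                    vals[m].append(fis.asv_homogeneity(x, comp, "geometric"))
                elif m == "simpson":
                    vals[m].append(_simpson_from_fca(sim, j, round_params.seed))
                else:
                    raise ValueError(f"unknown metric {m!r}")
        corr = {
            m: float(np.corrcoef(vals[m], sim.true_overlap)[0, 1]) for m in metrics
        }
        rows.append(corr)
    return MetricOverlapReport(correlations=pd.DataFrame(rows))


def _simpson_from_fca(sim: SimulatedFactors, j: int, seed: int) -> float:
    """Specificity of factor j: Simpson index of its FCA column when its own
    component labels serve as a 2-level covariate."""
    from .association import ensemble_fca

    cov = pd.DataFrame(
        {"component": [f"c{int(v)}" for v in sim.component_labels[:, j]]},
        index=[f"cell_{i}" for i in range(sim.scores.shape[0])],
    )
    fca = ensemble_fca(sim.scores, cov, ["component"], seed=seed)
    return fis.simpson_index(fca.values.iloc[:, j])
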