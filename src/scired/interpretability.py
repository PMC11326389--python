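"""Factor interpretability scores (FIS).

Four families of metrics describe how interpretable a factor is:

* separability / bimodality (label-free): silhouette, variance-ratio score
  (between/within SS of a 2-means split), its sample-size-free variant,
  scaled inverse Davies-Bouldin, the bimodality index of a tied-variance
  two-component Gaussian mixture fit, and Hartigan's dip statistic;
* effect size: the variance of the factor scores;
* specificity (label-dependent): Simpson and Shannon diversity of a
  factor's association scores across covariate levels;
* homogeneity (label-dependent): scaled variance Var(x_L)/Var(x) per
  covariate level, averaged over levels (ASV).

Metrics are assembled into a metric x factor table; a row-wise min-max
scaled copy supports heatmap-style comparison between factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .association import FCATable

logger = logging.getLogger(__name__)

__all__ = [
    "kmeans2_partition",
    "vrs",
    "wvrs",
    "silhouette_sep",
    "davies_bouldin_scaled",
    "bimodality_index",
    "dip_statistic",
    "effect_size_variance",
    "simpson_index",
    "shannon_specificity",
    "scaled_variance",
    "asv_homogeneity",
    "build_fis_table",
    "GMMFit",
    "FISTable",
]


@dataclass
class GMMFit:
    mu1: float
    mu2: float
    sigma: float
    pi: float
    delta: float

    def __post_init__(self):
        if not 0 < self.pi < 1:
            raise ValueError("component proportion must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class FISTable:
    values: pd.DataFrame  # metric x factor
    row_scaled: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite FIS entries")

    def scaled(self) -> "FISTable":
        """Row-wise min-max scaled copy (each metric mapped to [0, 1])."""
        v = self.values.to_numpy(dtype=float)
        lo = v.min(axis=1, keepdims=True)
        rng = v.max(axis=1, keepdims=True) - lo
        rng[rng == 0] = 1.0
        out = pd.DataFrame(
            (v - lo) / rng, index=self.values.index, columns=self.values.columns
        )
        return FISTable(out, row_scaled=True)


# --------------------------------------------------------------------------
# separability


def kmeans2_partition(factor_scores: np.ndarray, seed: int = 0) -> np.ndarray:
    """Binary labels from 2-means on 1-D scores (best of 10 restarts)."""
    x = np.asarray(factor_scores, dtype=float).reshape(-1, 1)
    if np.ptp(x) == 0:
        raise ValueError("constant scores cannot be partitioned")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    return km.fit_predict(x)


def _cluster_stats(scores, labels):
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = [x[labels == c] for c in np.unique(labels)]
    if len(groups) != 2:
        raise ValueError("need exactly 2 clusters")
    return groups


def vrs(scores, labels) -> float:
    """Between- over within-cluster sum of squares of a binary split."""
    groups = _cluster_stats(scores, labels)
    x = np.asarray(scores, dtype=float)
    grand = x.mean()
    bss = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
    wss = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    if wss == 0:
        return np.inf
    return float(bss / wss)


def wvrs(scores, labels, alternative: bool = False) -> float:
    """Cluster-size-free variance ratio: squared mean gap over the mean of
    the per-cluster variances (``alternative``: mean of per-cluster SS)."""
    g1, g2 = _cluster_stats(scores, labels)
    gap2 = (g1.mean() - g2.mean()) ** 2
    if alternative:
        denom = 0.5 * (((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum())
    else:
        denom = 0.5 * (g1.var() + g2.var())
    if denom == 0:
        return np.inf
    return float(gap2 / denom)


def silhouette_sep(scores, labels) -> float:
    """Mean silhouette of a binary split of 1-D scores, in [-1, 1]."""
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    return float(silhouette_score(x, np.asarray(labels)))


def davies_bouldin_scaled(scores, labels, return_raw: bool = False):
    """Davies-Bouldin index mapped to (0, 1] via 1/(1+DBI); higher = better."""
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    dbi = float(davies_bouldin_score(x, np.asarray(labels)))
    scaled = 1.0 / (1.0 + dbi)
    return (scaled, dbi) if return_raw else scaled


def bimodality_index(
    scores, seed: int = 0, sqrt_proportions: bool = False
) -> tuple[float, GMMFit]:
    """Bimodality index of a tied-variance two-component Gaussian mixture.

    BI = pi*(1-pi)*delta with delta = |mu1 - mu2| / sigma; setting
    ``sqrt_proportions`` uses the classical sqrt(pi*(1-pi))*delta variant.
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    gmm = GaussianMixture(
        n_components=2, covariance_type="tied", random_state=seed, n_init=3
    )
    gmm.fit(x)
    mus = gmm.means_.ravel()
    order = np.argsort(mus)
    mu1, mu2 = mus[order]
    pi = float(gmm.weights_[order][0])
    sigma = float(np.sqrt(gmm.covariances_.ravel()[0]))
    floor = 1e-6 * max(np.ptp(x), 1e-12)
    if sigma < floor:
        logger.warning("degenerate tied variance; sigma floored")
        sigma = floor
    delta = abs(mu1 - mu2) / sigma
    w = np.sqrt(pi * (1 - pi)) if sqrt_proportions else pi * (1 - pi)
    return float(w * delta), GMMFit(mu1=mu1, mu2=mu2, sigma=sigma, pi=pi, delta=delta)


def dip_statistic(scores) -> float:
    """Hartigan's dip statistic: the maximum distance between the empirical
    distribution function and the closest unimodal distribution function.

    Classical greatest-convex-minorant / least-concave-majorant algorithm on
    the sorted sample; returns the statistic only (no p-value).
    """
    xs = np.sort(np.asarray(scores, dtype=float).ravel())
    n = len(xs)
    if n < 2:
        return 0.0
    x = np.empty(n + 1)  # 1-based indexing mirrors the published algorithm
    x[1:] = xs
    if x[n] == x[1]:
        return 1.0 / (2.0 * n)
    low, high = 1, n
    dip = 1.0  # in count units; divided by 2n at the end

    # mn[j]: previous touch point of the greatest convex minorant up to j
    mn = np.zeros(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    # mj[k]: next touch point of the least concave majorant from k up
    mj = np.zeros(n + 1, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    while True:
        gcm = [0, high]  # 1-based: gcm[1] = high, descending to low
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm) - 1
        ig = l_gcm
        ix = ig - 1
        lcm = [0, low]  # 1-based: lcm[1] = low, ascending to high
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm) - 1
        ih = l_lcm
        iv = 2

        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcm_ix, lcm_iv = gcm[ix], lcm[iv]
                if gcm_ix > lcm_iv:
                    gcm_i1 = gcm[ix + 1]
                    dx = (lcm_iv - gcm_i1 + 1) - (x[lcm_iv] - x[gcm_i1]) * (
                        gcm_ix - gcm_i1
                    ) / (x[gcm_ix] - x[gcm_i1])
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv - 1
                else:
                    lcm_iv1 = lcm[iv - 1]
                    dx = (x[gcm_ix] - x[lcm_iv1]) * (lcm_iv - lcm_iv1) / (
                        x[lcm_iv] - x[lcm_iv1]
                    ) - (gcm_ix - lcm_iv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # dip of the convex minorant fit on [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # dip of the concave majorant fit on [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return float(dip / (2.0 * n))


# --------------------------------------------------------------------------
# effect size, specificity, homogeneity


def effect_size_variance(scores) -> float:
    """Sample variance of the factor scores (ddof=1)."""
    x = np.asarray(scores, dtype=float)
    return float(x.var(ddof=1))


def _to_probabilities(fca_column) -> np.ndarray:
    """Rectify association scores at 0 and normalize to a probability vector."""
    p = np.maximum(np.asarray(fca_column, dtype=float), 0.0)
    total = p.sum()
    if total == 0:
        raise ValueError("all association scores non-positive; no probabilities")
    return p / total


def simpson_index(fca_column) -> float:
    """Simpson diversity D = sum p_i^2 of a factor's level-association
    probabilities; 1 = fully specific to one level, 1/N = uniform."""
    p = _to_probabilities(fca_column)
    return float((p**2).sum())


def shannon_specificity(fca_column, invert: bool = True) -> float:
    """Shannon entropy H = -sum p_i log p_i of the association probabilities.

    With ``invert`` (the FIS presentation) returns (log N - H)/log N so
    higher = more specific; otherwise the raw entropy in [0, log N].
    """
    p = _to_probabilities(fca_column)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if not invert:
        return h
    n = len(p)
    if n < 2:
        return 1.0
    return float((np.log(n) - h) / np.log(n))


def scaled_variance(scores, level_mask) -> float:
    """SV = Var(x_L)/Var(x): variance within one covariate level relative to
    the total variance."""
    x = np.asarray(scores, dtype=float)
    mask = np.asarray(level_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("level needs at least 2 cells")
    total = x.var()
    if total == 0:
        raise ValueError("zero total variance")
    return float(x[mask].var() / total)


def asv_homogeneity(scores, covariate_levels, mean_type: str = "arithmetic") -> float:
    """Average scaled variance across the levels of one covariate."""
    levels = pd.Series(covariate_levels).astype(str)
    svs = [
        scaled_variance(scores, (levels == lev).to_numpy())
        for lev in sorted(levels.unique())
        if (levels == lev).sum() >= 2
    ]
    if not svs:
        raise ValueError("no usable covariate levels")
    if mean_type == "arithmetic":
        return float(np.mean(svs))
    if mean_type == "geometric":
        return float(scipy.stats.gmean(np.maximum(svs, 1e-12)))
    raise ValueError(f"unknown mean type {mean_type!r}")


# --------------------------------------------------------------------------
# table assembly

DEFAULT_METRICS = ("silhouette", "bimodality_index", "variance", "simpson")
EXTRA_METRICS = ("vrs", "wvrs", "davies_bouldin_scaled", "dip", "shannon_inverted")


def build_fis_table(
    model,
    fca: FCATable | None,
    covariates=None,
    seed: int = 0,
    all_metrics: bool = False,
) -> FISTable:
    """Assemble the metric x factor interpretability table.

    Separability and effect size are computed from the score matrix alone;
    specificity needs the FCA table; homogeneity (one ASV row per
    categorical covariate) needs the covariate table.  The returned table is
    raw; use :meth:`FISTable.scaled` for the row-scaled presentation copy.
    """
    from .datatypes import CovariateTable, FactorModel

    if isinstance(model, FactorModel):
        scores = model.scores
        names = model.factor_names
    else:
        scores = np.asarray(model, dtype=float)
        names = [f"F{j + 1}" for j in range(scores.shape[1])]
    k = scores.shape[1]
    rows: dict[str, list] = {m: [] for m in DEFAULT_METRICS}
    if all_metrics:
        for m in EXTRA_METRICS:
            rows[m] = []
    def _specificity(fn, column):
        # a column with no positive association carries no specificity
        # signal; treat it as maximally diverse (uniform probabilities)
        try:
            return fn(column)
        except ValueError:
            n_lev = len(column)
            return fn(np.full(n_lev, 1.0 / n_lev))

    for j in range(k):
        xj = scores[:, j]
        labels = kmeans2_partition(xj, seed=seed)
        rows["silhouette"].append(silhouette_sep(xj, labels))
        rows["bimodality_index"].append(bimodality_index(xj, seed=seed)[0])
        rows["variance"].append(effect_size_variance(xj))
        if fca is not None:
            rows["simpson"].append(_specificity(simpson_index, fca.values.iloc[:, j]))
        else:
            rows["simpson"].append(np.nan)
        if all_metrics:
            rows["vrs"].append(vrs(xj, labels))
            rows["wvrs"].append(wvrs(xj, labels))
            rows["davies_bouldin_scaled"].append(davies_bouldin_scaled(xj, labels))
            rows["dip"].append(dip_statistic(xj))
            if fca is not None:
                rows["shannon_inverted"].append(
                    _specificity(shannon_specificity, fca.values.iloc[:, j])
                )
            else:
                rows["shannon_inverted"].append(np.nan)
    if fca is None:
        for key in ("simpson", "shannon_inverted"):
            rows.pop(key, None)
    if covariates is not None:
        if not isinstance(covariates, CovariateTable):
            covariates = CovariateTable(pd.DataFrame(covariates))
        for cov in covariates.categorical_columns():
            rows[f"asv_arithmetic[{cov}]"] = [
                asv_homogeneity(scores[:, j], covariates[cov]) for j in range(k)
            ]
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = names
    return FISTable(table, row_scaled=False)
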