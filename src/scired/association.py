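"""Factor-covariate association (FCA) scoring with a classifier ensemble.

For every level of every categorical covariate, a one-vs-rest label vector
is formed over cells and four classifiers are trained on the factor scores:
logistic regression (|coefficient| importance), a decision tree and
gradient-boosted trees (impurity-decrease importance), and a linear
threshold classifier whose importance is the ROC AUC computed from the
Mann-Whitney U statistic, AUC = U / (n0 * n1).  Each classifier's k-vector
of importances is scaled across factors (standardize / min-max / rank) and
the scaled vectors are averaged (arithmetic or geometric mean) into one row
of the FCA table.  The pooled FCA values are binarized by Otsu thresholding
into significant / non-significant associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .datatypes import CovariateTable, FactorModel

logger = logging.getLogger(__name__)

__all__ = [
    "importance_logistic",
    "importance_tree",
    "importance_auc",
    "scale_importances",
    "ensemble_fca",
    "otsu_threshold",
    "call_associations",
    "EnsembleFCA",
    "FCATable",
    "AssociationCalls",
    "DEFAULT_CLASSIFIERS",
]

DEFAULT_CLASSIFIERS = ("logistic", "decision_tree", "xgb", "auc")


@dataclass
class FCATable:
    """Covariate-level x factor association scores."""

    values: pd.DataFrame  # rows "covariate:level", columns factor names
    scaling_method: str = "standardize"
    mean_type: str = "arithmetic"
    classifier_set: tuple = DEFAULT_CLASSIFIERS

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite FCA scores")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate covariate-level rows")

    @property
    def n_factors(self) -> int:
        return self.values.shape[1]


@dataclass
class AssociationCalls:
    threshold: float
    significant: pd.DataFrame
    matched_factors: dict = field(default_factory=dict)
    unannotated_factors: list = field(default_factory=list)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return labels


def importance_logistic(scores: np.ndarray, labels) -> np.ndarray:
    """|coefficient| per factor of a joint logistic regression."""
    labels = _check_binary(labels)
    clf = LogisticRegression(max_iter=1000)
    clf.fit(np.asarray(scores, float), labels)
    return np.abs(clf.coef_.ravel())


def importance_tree(
    scores: np.ndarray, labels, model: str = "decision_tree", seed: int = 0
) -> np.ndarray:
    """Impurity-decrease importances from a tree or boosted ensemble."""
    labels = _check_binary(labels)
    X = np.asarray(scores, float)
    if model == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif model in {"xgb", "gradient_boosted_trees"}:
        from xgboost import XGBClassifier

        clf = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
        labels = (labels == labels.max()).astype(int)
    else:
        raise ValueError(f"unknown tree model {model!r}")
    clf.fit(X, labels)
    imp = np.asarray(clf.feature_importances_, dtype=float)
    return imp


def importance_auc(scores: np.ndarray, labels) -> np.ndarray:
    """Per-factor ROC AUC from the Mann-Whitney U statistic, rectified to
    max(AUC, 1-AUC) since factor signs are arbitrary."""
    labels = _check_binary(labels)
    X = np.asarray(scores, float)
    pos = labels == labels.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        u = scipy.stats.mannwhitneyu(X[pos, j], X[~pos, j], alternative="two-sided").statistic
        auc = u / (n0 * n1)
        out[j] = max(auc, 1.0 - auc)
    return out


def scale_importances(raw: np.ndarray, method: str = "standardize") -> np.ndarray:
    """Scale a k-vector of importances across factors."""
    x = np.asarray(raw, dtype=float)
    if method == "standardize":
        sd = x.std()
        if sd == 0:
            logger.warning("zero-variance importances; standardized to zeros")
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    if method == "minmax":
        rng = x.max() - x.min()
        if rng == 0:
            return np.zeros_like(x)
        return (x - x.min()) / rng
    if method == "rank":
        return scipy.stats.rankdata(x, method="average") / len(x)
    raise ValueError(f"unknown scaling method {method!r}")


def _combine(rows: np.ndarray, mean_type: str, scaling: str) -> np.ndarray:
    if mean_type == "arithmetic":
        return rows.mean(axis=0)
    if mean_type == "geometric":
        if scaling == "standardize":
            raise ValueError(
                "geometric mean is undefined on standardized (signed) scores; "
                "use minmax or rank scaling"
            )
        return scipy.stats.gmean(rows + 1e-12, axis=0)
    raise ValueError(f"unknown mean type {mean_type!r}")


class EnsembleFCA(BaseEstimator):
    """Ensemble factor-covariate association scorer.

    Parameters
    ----------
    classifiers : tuple of {"logistic", "decision_tree", "xgb", "auc"}
    scaling : {"standardize", "minmax", "rank"}, default "standardize"
    mean : {"arithmetic", "geometric"}, default "arithmetic"
    random_state : int, default 0
        Seed for tree-based classifiers.
    min_level_cells : int, default 2
        Covariate levels with fewer cells are dropped (logged).

    Attributes
    ----------
    fca_ : FCATable
    threshold_ : float          (Otsu threshold over all FCA entries)
    calls_ : AssociationCalls
    """

    def __init__(
        self,
        classifiers: tuple = DEFAULT_CLASSIFIERS,
        scaling: str = "standardize",
        mean: str = "arithmetic",
        random_state: int = 0,
        min_level_cells: int = 2,
    ):
        self.classifiers = classifiers
        self.scaling = scaling
        self.mean = mean
        self.random_state = random_state
        self.min_level_cells = min_level_cells

    def _importances(self, scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
        rows = []
        for name in self.classifiers:
            if name == "logistic":
                raw = importance_logistic(scores, labels)
            elif name == "decision_tree":
                raw = importance_tree(scores, labels, "decision_tree", self.random_state)
            elif name == "xgb":
                raw = importance_tree(scores, labels, "xgb", self.random_state)
            elif name == "auc":
                raw = importance_auc(scores, labels)
            else:
                raise ValueError(f"unknown classifier {name!r}")
            rows.append(scale_importances(raw, self.scaling))
        return _combine(np.vstack(rows), self.mean, self.scaling)

    def fit(self, scores, covariates, covariate_names: list | None = None):
        """Score factor-covariate-level associations.

        Parameters
        ----------
        scores : ndarray (n_cells, k) or FactorModel
        covariates : CovariateTable (or DataFrame)
        covariate_names : categorical covariates to include (default: all).
        """
        factor_names = None
        if isinstance(scores, FactorModel):
            factor_names = scores.factor_names
            scores = scores.scores
        scores = np.asarray(scores, dtype=float)
        if factor_names is None:
            factor_names = [f"F{j + 1}" for j in range(scores.shape[1])]
        if not isinstance(covariates, CovariateTable):
            covariates = CovariateTable(pd.DataFrame(covariates))
        names = covariate_names or covariates.categorical_columns()
        names = [c for c in names if covariates.is_categorical(c)]
        if not names:
            raise ValueError("no categorical covariates to associate")
        rows, labels_rows = {}, []
        for cov in names:
            s = covariates[cov]
            for lev in covariates.levels(cov):
                mask = (s == lev).to_numpy()
                if mask.sum() < self.min_level_cells or (~mask).sum() < self.min_level_cells:
                    logger.warning("level %s:%s too small; dropped", cov, lev)
                    continue
                rows[f"{cov}:{lev}"] = self._importances(scores, mask.astype(int))
                labels_rows.append((cov, lev))
        if not rows:
            raise ValueError("no usable covariate levels")
        values = pd.DataFrame.from_dict(rows, orient="index")
        values.columns = factor_names
        self.fca_ = FCATable(
            values=values,
            scaling_method=self.scaling,
            mean_type=self.mean,
            classifier_set=tuple(self.classifiers),
        )
        self.calls_ = call_associations(self.fca_)
        self.threshold_ = self.calls_.threshold
        return self

    def fit_table(self, scores, covariates, covariate_names=None) -> FCATable:
        self.fit(scores, covariates, covariate_names)
        return self.fca_


def ensemble_fca(
    model,
    covariates,
    covariate_names: list | None = None,
    classifiers: tuple = DEFAULT_CLASSIFIERS,
    scaling: str = "standardize",
    mean: str = "arithmetic",
    seed: int = 0,
) -> FCATable:
    """Functional wrapper over :class:`EnsembleFCA`."""
    est = EnsembleFCA(
        classifiers=classifiers, scaling=scaling, mean=mean, random_state=seed
    )
    return est.fit_table(model, covariates, covariate_names)


def otsu_threshold(values) -> float:
    """Exhaustive between-class-variance threshold over all candidate cuts.

    Candidates are the midpoints of consecutive sorted unique values; the
    returned threshold maximizes  w0*w1*(m0-m1)^2  where w are partition
    fractions and m partition means.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError("constant input: no threshold separates two classes")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(x)
    csum = np.cumsum(x)
    total = csum[-1]
    # number of points <= each midpoint
    n0 = np.searchsorted(x, mids, side="right")
    w0 = n0 / n
    w1 = 1 - w0
    m0 = csum[n0 - 1] / n0
    m1 = (total - csum[n0 - 1]) / (n - n0)
    between = w0 * w1 * (m0 - m1) ** 2
    return float(mids[int(np.argmax(between))])


def call_associations(fca: FCATable) -> AssociationCalls:
    """Binarize an FCA table at the pooled-Otsu threshold."""
    thr = otsu_threshold(fca.values.to_numpy())
    sig = fca.values > thr
    matched = {
        row: [f for f in fca.values.columns if sig.loc[row, f]] for row in sig.index
    }
    unannotated = [f for f in fca.values.columns if not sig[f].any()]
    return AssociationCalls(
        threshold=thr,
        significant=sig.astype(int),
        matched_factors=matched,
        unannotated_factors=unannotated,
    )
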