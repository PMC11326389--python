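"""SVD-based PCA of the residual matrix and interpretability rotations.

Factorization proceeds in two stages.  First, the gene-centered residual
matrix is decomposed by SVD: scores are the left singular vectors scaled by
the singular values, loadings the right singular vectors.  Second, the top-k
loadings are rotated — varimax (orthogonal, default) or promax (oblique) —
to concentrate each factor on few genes.

Varimax maximizes the Kaiser criterion

    v = sum_j { [ g * sum_i (l_ij^2/h_i^2)^2 - (sum_i l_ij^2/h_i^2)^2 ] / g^2 }

with communality h_i^2 = sum_j l_ij^2, via the classical iterative SVD
update (the base-R `varimax` algorithm): with B = L R,

    M = L^T (B∘B∘B − B · diag(colsum(B∘B))/g),   R ← U V^T from SVD of M,

stopping when the trace criterion (sum of singular values of M) stops
improving.  Promax powers the (row/column-normalized) varimax loadings to
build an idealized sparse pattern and least-squares fits an oblique
rotation to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import FactorModel
from .residuals import ResidualMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RotationSettings",
    "pca_svd",
    "kaiser_criterion",
    "varimax_rotate",
    "promax_rotate",
    "apply_rotation",
    "fix_signs",
    "RotatedFactorizer",
]


@dataclass
class RotationSettings:
    kaiser_normalize: bool = True
    tol: float = 1e-5
    max_iter: int = 1000
    promax_power: int = 3

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.promax_power < 2:
            raise ValueError("promax_power must be >= 2")


def _as_array(residuals) -> tuple[np.ndarray, list, list]:
    if isinstance(residuals, ResidualMatrix):
        return residuals.residuals, residuals.cell_ids, residuals.gene_ids
    arr = np.asarray(residuals, dtype=float)
    return arr, [], []


def fix_signs(scores: np.ndarray, loadings: np.ndarray):
    """Deterministic sign convention: the largest-|loading| gene of each
    factor gets a positive loading; scores flip in tandem."""
    flip = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            flip[j] = -1.0
    return scores * flip, loadings * flip, flip


def pca_svd(residuals, k: int, cell_ids=None, gene_ids=None) -> FactorModel:
    """PCA of the per-gene-centered residual matrix via SVD.

    Scores are U*S (cells x k), loadings are V (genes x k); the explained
    variance is s^2/(n-1) per factor.
    """
    X, cids, gids = _as_array(residuals)
    cell_ids = cell_ids or cids
    gene_ids = gene_ids or gids
    n, g = X.shape
    if not 1 <= k <= min(n, g):
        raise ValueError(f"k must lie in [1, {min(n, g)}], got {k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    scores, loadings, _ = fix_signs(scores, loadings)
    ev = (s[:k] ** 2) / max(n - 1, 1)
    model = FactorModel(
        scores=scores,
        loadings=loadings,
        rotation=np.eye(k),
        explained_variance=ev,
        rotation_kind="none",
        cell_ids=cell_ids,
        gene_ids=gene_ids,
    )
    model.total_variance = float((s**2).sum() / max(n - 1, 1))
    return model


def kaiser_criterion(loadings: np.ndarray) -> float:
    """Variance of communality-scaled squared loadings, summed over factors."""
    L = np.asarray(loadings, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    h2 = (L**2).sum(axis=1)
    keep = h2 > 0
    if not np.all(keep):
        logger.warning("%d zero-communality rows dropped", int((~keep).sum()))
        L, h2 = L[keep], h2[keep]
    g = L.shape[0]
    q = (L**2) / h2[:, None]
    v = (g * (q**2).sum(axis=0) - q.sum(axis=0) ** 2) / g**2
    return float(v.sum())


def _varimax_iterations(L: np.ndarray, tol: float, max_iter: int):
    """Core varimax SVD iteration on (possibly normalized) loadings."""
    g, k = L.shape
    R = np.eye(k)
    d = 0.0
    trace = []
    for _ in range(max_iter):
        B = L @ R
        M = L.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / g)
        U, s, Vt = scipy.linalg.svd(M)
        R = U @ Vt
        d_old, d = d, s.sum()
        trace.append(kaiser_criterion(L @ R))
        if d_old != 0 and d < d_old * (1 + tol):
            return R, trace, True
    return R, trace, False


def varimax_rotate(
    loadings: np.ndarray, settings: RotationSettings | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a g x k loading matrix.

    Returns ``(rotated_loadings, R)`` with R orthogonal.  With
    ``kaiser_normalize`` rows are scaled to unit communality during the
    iteration and unscaled afterwards.
    """
    settings = settings or RotationSettings()
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be 2-D")
    g, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    sc = np.ones(g)
    if settings.kaiser_normalize:
        sc = np.sqrt((L**2).sum(axis=1))
        sc[sc == 0] = 1.0
    Ln = L / sc[:, None]
    R, trace, converged = _varimax_iterations(Ln, settings.tol, settings.max_iter)
    if not converged:
        logger.warning("varimax did not converge in %d iterations", settings.max_iter)
    rotated = (Ln @ R) * sc[:, None]
    varimax_rotate.last_trace = trace  # per-iteration Kaiser criterion, for diagnostics
    return rotated, R


def promax_rotate(
    loadings: np.ndarray, settings: RotationSettings | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation (varimax first, then least-squares fit to a
    powered pattern matrix).

    The pattern is p_ij = |l_ij^(m+1)| / l_ij = sign(l_ij) |l_ij|^m (m =
    ``promax_power``) of the row- then column-normalized varimax loadings;
    R_promax = (L'L)^-1 L' P with columns scaled to unit sum of squares.
    Returns ``(rotated_loadings, R)`` where R = R_varimax @ R_promax maps the
    INPUT loadings to the promax solution (column norms stay 1 because the
    varimax part is orthogonal).
    """
    settings = settings or RotationSettings()
    L = np.asarray(loadings, dtype=float)
    g, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    Lrot, Rv = varimax_rotate(L, settings)
    # row (communality) then column normalization before powering
    h = np.sqrt((Lrot**2).sum(axis=1))
    h[h == 0] = 1.0
    N = Lrot / h[:, None]
    cn = np.sqrt((N**2).sum(axis=0))
    cn[cn == 0] = 1.0
    N = N / cn[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(N != 0, np.sign(N) * np.abs(N) ** settings.promax_power, 0.0)
    G = Lrot.T @ Lrot
    try:
        R = scipy.linalg.solve(G, Lrot.T @ P, assume_a="pos")
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("collinear varimax factors; promax undefined") from exc
    norms = np.sqrt((R**2).sum(axis=0))
    if np.any(norms == 0):
        raise ValueError("degenerate promax rotation column")
    R = R / norms[None, :]
    return Lrot @ R, Rv @ R


def apply_rotation(model: FactorModel, R: np.ndarray, kind: str = "varimax") -> FactorModel:
    """Rotate a factor model: scores <- scores R, loadings <- loadings R."""
    R = np.asarray(R, dtype=float)
    scores = model.scores @ R
    loadings = model.loadings @ R
    # deterministic presentation: order rotated factors by score variance
    order = np.argsort(-scores.var(axis=0, ddof=1), kind="stable")
    R = R[:, order]
    scores, loadings = scores[:, order], loadings[:, order]
    scores, loadings, flip = fix_signs(scores, loadings)
    ev = scores.var(axis=0, ddof=1)
    out = FactorModel(
        scores=scores,
        loadings=loadings,
        rotation=model.rotation @ (R * flip),
        explained_variance=ev,
        rotation_kind=kind,
        cell_ids=model.cell_ids,
        gene_ids=model.gene_ids,
    )
    if hasattr(model, "total_variance"):
        out.total_variance = model.total_variance
    return out


class RotatedFactorizer(BaseEstimator, TransformerMixin):
    """PCA + rotation of a residual matrix, sklearn-style.

    Parameters
    ----------
    n_factors : int, default 30
        Number of retained factors (k).
    rotation : {"varimax", "promax", "none"}, default "varimax"
    kaiser_normalize : bool, default True
    tol : float, default 1e-5
    max_iter : int, default 1000
    promax_power : int, default 3

    Attributes
    ----------
    model_ : FactorModel
        Scores/loadings/rotation of the fitted decomposition.
    loadings_ : ndarray (n_genes, k)
    rotation_ : ndarray (k, k)
    explained_variance_ : ndarray (k,)
    mean_ : per-gene centering offsets.
    """

    def __init__(
        self,
        n_factors: int = 30,
        rotation: str = "varimax",
        kaiser_normalize: bool = True,
        tol: float = 1e-5,
        max_iter: int = 1000,
        promax_power: int = 3,
    ):
        self.n_factors = n_factors
        self.rotation = rotation
        self.kaiser_normalize = kaiser_normalize
        self.tol = tol
        self.max_iter = max_iter
        self.promax_power = promax_power

    def _settings(self) -> RotationSettings:
        return RotationSettings(
            kaiser_normalize=self.kaiser_normalize,
            tol=self.tol,
            max_iter=self.max_iter,
            promax_power=self.promax_power,
        )

    def fit(self, X, y=None, cell_ids=None, gene_ids=None):
        if self.rotation not in {"varimax", "promax", "none"}:
            raise ValueError(f"unknown rotation {self.rotation!r}")
        arr, cids, gids = _as_array(X)
        self.mean_ = arr.mean(axis=0)
        base = pca_svd(X, self.n_factors, cell_ids=cell_ids or cids, gene_ids=gene_ids or gids)
        if self.rotation == "none" or self.n_factors == 1:
            model = base
        else:
            rotate = varimax_rotate if self.rotation == "varimax" else promax_rotate
            _, R = rotate(base.loadings, self._settings())
            model = apply_rotation(base, R, kind=self.rotation)
        self.model_ = model
        self.loadings_ = model.loadings
        self.rotation_ = model.rotation
        self.explained_variance_ = model.explained_variance
        return self

    def transform(self, X) -> np.ndarray:
        """Project a residual matrix onto the fitted (rotated) factor axes."""
        arr, _, _ = _as_array(X)
        return (arr - self.mean_) @ self.loadings_

    def fit_transform(self, X, y=None, **kw) -> np.ndarray:
        self.fit(X, **kw)
        return self.model_.scores
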