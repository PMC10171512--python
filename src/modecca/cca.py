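"""PCA reduction and canonical correlation analysis, from first principles.

Each block is reduced to the smallest number of principal components whose
cumulative explained variance reaches a target (default 80%), then the two
score matrices enter CCA.  The CCA itself is the numerically stable
QR/SVD construction: orthonormalise each centred block by economy QR and
take the singular value decomposition of the cross-product of the two
orthonormal bases — the singular values are the canonical correlations
and the back-transformed singular vectors the canonical weights.

Both decompositions are sign-indeterminate, so deterministic conventions
are applied: each PCA component has its largest-magnitude loading
positive, and each canonical variate pair is flipped so the x-variate
correlates non-negatively with the first usable reference variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["VarianceTargetPCA", "CCAResult", "PCACCA", "fit_pca", "fit_cca",
           "canonical_variate"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


class VarianceTargetPCA(BaseEstimator, TransformerMixin):
    """PCA retaining the smallest m components whose cumulative EVR >= target.

    Computed by SVD of the centred data matrix (stable for n >> p).
    Fitted attributes follow scikit-learn naming: ``components_`` is
    (n_components, n_features), ``explained_variance_ratio_`` covers all
    components, ``n_components_`` the retained count.
    """

    def __init__(self, variance_target: float = 0.80):
        self.variance_target = variance_target

    def fit(self, X, y=None):
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")
        x = _as_array(X)
        n = x.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        self.mean_ = x.mean(axis=0)
        xc = x - self.mean_
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        var = s**2
        total = var.sum()
        if total <= 0:
            raise ValueError("data has zero total variance")
        evr = var / total
        cum = np.cumsum(evr)
        m = int(np.searchsorted(cum, self.variance_target - 1e-12) + 1)
        m = min(m, len(evr))
        # sign convention: largest-|loading| entry of each component positive
        flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
        flip[flip == 0] = 1.0
        vt = vt * flip[:, None]
        self.components_ = vt[:m]
        self.explained_variance_ratio_ = evr
        self.n_components_ = m
        self.singular_values_ = s
        return self

    def transform(self, X):
        x = _as_array(X)
        return (x - self.mean_) @ self.components_.T


def fit_pca(table, variance_target: float = 0.80):
    """Fit a variance-target PCA; returns ``(model, scores)``."""
    model = VarianceTargetPCA(variance_target).fit(table)
    return model, model.transform(table)


@dataclass
class CCAResult:
    """Canonical correlations, weights and subject-level variates.

    ``correlations`` is non-increasing in [0, 1]; ``variates_x[:, i]`` and
    ``variates_y[:, i]`` are unit-variance subject scores whose Pearson
    correlation equals ``correlations[i]``.
    """

    correlations: np.ndarray
    weights_x: np.ndarray
    weights_y: np.ndarray
    variates_x: np.ndarray
    variates_y: np.ndarray

    @property
    def n_modes(self) -> int:
        return int(self.correlations.size)

    @property
    def n_subjects(self) -> int:
        return int(self.variates_x.shape[0])


def _qr_full_rank(xc: np.ndarray, label: str):
    q, r = np.linalg.qr(xc)
    diag = np.abs(np.diag(r))
    tol = max(xc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if diag.size == 0 or (diag <= tol).any():
        raise np.linalg.LinAlgError(
            f"{label} block is rank deficient; reduce it with PCA first"
        )
    return q, r


def fit_cca(scores_x, scores_y, sign_reference=None) -> CCAResult:
    """Canonical correlation analysis of two centred score blocks.

    ``sign_reference`` (defaults to ``scores_x``) supplies the columns used
    to fix the sign of each variate pair: the x-variate is flipped so its
    correlation with the first reference column of non-negligible
    correlation is positive.
    """
    x = _as_array(scores_x)
    y = _as_array(scores_y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must share subjects (same row count and order)")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    qx, rx = _qr_full_rank(xc, "x")
    qy, ry = _qr_full_rank(yc, "y")
    u, s, vt = np.linalg.svd(qx.T @ qy)
    m = min(x.shape[1], y.shape[1])
    corr = np.clip(s[:m], 0.0, 1.0)
    wx = linalg.solve_triangular(rx, u[:, :m])
    wy = linalg.solve_triangular(ry, vt.T[:, :m])
    uvar = xc @ wx
    vvar = yc @ wy

    # unit-variance variates (sample SD), weights rescaled to match
    su = uvar.std(axis=0, ddof=1)
    sv = vvar.std(axis=0, ddof=1)
    uvar /= su
    vvar /= sv
    wx = wx / su
    wy = wy / sv

    ref = _as_array(sign_reference) if sign_reference is not None else x
    refc = ref - ref.mean(axis=0)
    ref_sd = refc.std(axis=0, ddof=1)
    ref_sd[ref_sd == 0] = 1.0
    ref_corr = (refc / ref_sd).T @ uvar / (n - 1)  # ref-vars x modes
    for i in range(m):
        col = ref_corr[:, i]
        usable = np.flatnonzero(np.abs(col) > 1e-12)
        sign = np.sign(col[usable[0]]) if usable.size else 1.0
        if sign < 0:
            uvar[:, i] *= -1
            vvar[:, i] *= -1
            wx[:, i] *= -1
            wy[:, i] *= -1
    return CCAResult(corr, wx, wy, uvar, vvar)


def canonical_variate(result: CCAResult, mode: int):
    """Subject-level (u, v) variate pair for 1-based ``mode``."""
    if not 1 <= mode <= result.n_modes:
        raise IndexError(f"mode {mode} out of range 1..{result.n_modes}")
    return result.variates_x[:, mode - 1], result.variates_y[:, mode - 1]


class PCACCA(BaseEstimator):
    """Variance-target PCA on each block followed by CCA on the scores.

    Parameters
    ----------
    variance_target : float, default 0.80
        Cumulative explained-variance threshold applied to each block
        separately before the canonical analysis.

    After ``fit(X, Y)`` exposes ``pca_x_``, ``pca_y_``, ``cca_`` (a
    :class:`CCAResult`), plus ``correlations_`` as a shortcut.
    """

    def __init__(self, variance_target: float = 0.80):
        self.variance_target = variance_target

    def fit(self, X, Y):
        self.pca_x_ = VarianceTargetPCA(self.variance_target).fit(X)
        self.pca_y_ = VarianceTargetPCA(self.variance_target).fit(Y)
        scores_x = self.pca_x_.transform(X)
        scores_y = self.pca_y_.transform(Y)
        self.scores_x_ = scores_x
        self.scores_y_ = scores_y
        self.cca_ = fit_cca(scores_x, scores_y, sign_reference=X)
        self.correlations_ = self.cca_.correlations
        return self

    def transform(self, X, Y):
        """Canonical variate pair matrices for new (processed) data."""
        sx = self.pca_x_.transform(X)
        sy = self.pca_y_.transform(Y)
        u = (sx - self.scores_x_.mean(axis=0)) @ self.cca_.weights_x
        v = (sy - self.scores_y_.mean(axis=0)) @ self.cca_.weights_y
        return u, v
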