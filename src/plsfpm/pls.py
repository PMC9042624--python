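"""Univariate-response partial least squares (PLS1 / NIPALS).

Stage one of the two-stage survival procedure: orthogonal score vectors that
maximize covariance with the response are extracted from a collinear
covariate matrix.  Each iteration computes a unit-norm loading-weight vector
``w_a`` proportional to the covariance of the (deflated) covariates with the
(deflated) response, forms the score ``s_a = X_{a-1} w_a``, then deflates both
X and y by their regressions on ``s_a``.

The response here is typically the observed survival time (or its log); the
censoring indicator plays no role at this stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PLSDecomposition", "fit_pls", "transform", "back_project"]


@dataclass
class PLSDecomposition:
    """Fitted PLS1 decomposition.

    Attributes
    ----------
    weights : (p, A) array
        Loading weights; each column has unit Euclidean norm.
    scores : (n, A) array
        Training score vectors, mutually orthogonal.
    loadings : (p, A) array
        Deflation regressors p_a = X'_{a-1} s_a / (s_a's_a).
    y_loadings : (A,) array
        Response regressions q_a = s_a'y_{a-1} / (s_a's_a).
    centers, scales : (p,) arrays
        Column centering/scaling constants applied before extraction.
    response_center : float
    column_names : list of str
    x_norms : (A+1,) array
        Frobenius norm of the deflated X before each extraction (diagnostic).
    """

    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    response_center: float
    column_names: list
    x_norms: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def _validate_matrix(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape != (X.shape[0],):
        raise ValueError(f"y must have length {X.shape[0]}, got shape {y.shape}")
    bad = [j for j in range(X.shape[1]) if np.any(np.isnan(X[:, j]))]
    if bad:
        raise ValueError(f"NaN values in X columns (0-based): {bad}")
    if np.any(np.isnan(y)):
        raise ValueError("NaN values in y")
    return X, y


def fit_pls(
    X,
    y,
    n_components: int,
    *,
    standardize: bool = True,
    column_names=None,
) -> PLSDecomposition:
    """Extract ``n_components`` PLS1 components of ``y`` on ``X``.

    Covariates are centered and (by default) scaled to unit variance; the
    response is centered only.  Constant columns are dropped-in-place by
    assigning them zero weight, with a warning.  The sign of each weight
    vector is fixed so its largest-magnitude entry is positive.
    """
    X, y = _validate_matrix(X, y)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if column_names is None:
        column_names = [f"x{j + 1}" for j in range(p)]
    else:
        column_names = list(column_names)
        if len(column_names) != p:
            raise ValueError("column_names length mismatch")

    centers = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if n > 1 else np.ones(p)
    constant = sds == 0
    if np.any(constant):
        warnings.warn(
            f"constant columns receive zero weight: "
            f"{[column_names[j] for j in np.flatnonzero(constant)]}",
            UserWarning,
            stacklevel=2,
        )
    scales = np.where(constant, 1.0, sds) if standardize else np.ones(p)

    rank = np.linalg.matrix_rank(X - centers)
    max_a = min(rank, n - 1, p)
    if n_components > max_a:
        raise ValueError(
            f"n_components={n_components} exceeds attainable maximum {max_a} "
            f"(rank of centered X, capped at n-1)"
        )

    Xd = (X - centers) / scales
    Xd[:, constant] = 0.0
    y_center = float(y.mean())
    yd = y - y_center

    A = n_components
    W = np.zeros((p, A))
    S = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros(A)
    x_norms = np.zeros(A + 1)

    for a in range(A):
        x_norms[a] = np.linalg.norm(Xd)
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(
                f"response is orthogonal to the deflated covariates at "
                f"component {a + 1}; reduce n_components"
            )
        w = w / nw
        # reproducible sign: largest-magnitude entry positive
        k = int(np.argmax(np.abs(w)))
        if w[k] < 0:
            w = -w
        s = Xd @ w
        ss = float(s @ s)
        pa = Xd.T @ s / ss
        qa = float(s @ yd) / ss
        Xd = Xd - np.outer(s, pa)
        yd = yd - qa * s
        W[:, a], S[:, a], P[:, a], Q[a] = w, s, pa, qa
    x_norms[A] = np.linalg.norm(Xd)

    return PLSDecomposition(
        weights=W,
        scores=S,
        loadings=P,
        y_loadings=Q,
        centers=centers,
        scales=scales,
        response_center=y_center,
        column_names=column_names,
        x_norms=x_norms,
    )


def transform(decomp: PLSDecomposition, X_new) -> np.ndarray:
    """Project new rows onto the fitted components.

    Applies the stored centering/scaling, then the weight/loading deflation
    recursion; on the training matrix this reproduces the stored scores.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != decomp.n_features:
        raise ValueError(
            f"expected {decomp.n_features} columns, got {X_new.shape[1]}"
        )
    Xd = (X_new - decomp.centers) / decomp.scales
    A = decomp.n_components
    S = np.empty((X_new.shape[0], A))
    for a in range(A):
        s = Xd @ decomp.weights[:, a]
        Xd = Xd - np.outer(s, decomp.loadings[:, a])
        S[:, a] = s
    return S


def back_project(decomp: PLSDecomposition, component_coefs) -> np.ndarray:
    """Rotate component-space coefficients back to the covariate scale.

    Returns ``beta_X`` (on the original, unstandardized covariate scale) such
    that for any row ``x``, ``(x - centers) @ beta_X`` equals the linear
    predictor ``scores(x) @ component_coefs``.  Uses the standard rotation
    ``R = W (P'W)^{-1}``.
    """
    c = np.asarray(component_coefs, dtype=float)
    if c.shape != (decomp.n_components,):
        raise ValueError(
            f"component_coefs must have length {decomp.n_components}"
        )
    PtW = decomp.loadings.T @ decomp.weights
    rotation = decomp.weights @ np.linalg.inv(PtW)
    beta_std = rotation @ c
    return beta_std / decomp.scales
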