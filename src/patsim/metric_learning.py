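"""Mahalanobis metric learning for k-NN retrieval.

Three learners produce the square linear map L of a Mahalanobis distance:

- LMNN (large-margin nearest neighbor): pulls each point's k same-class
  target neighbors close while pushing differently-labeled impostors beyond
  a unit margin.
- NCA (neighborhood components analysis): maximizes the stochastic
  (softmax) leave-one-out k-NN score. Backed by scikit-learn's
  NeighborhoodComponentsAnalysis with identity initialization.
- MLKR (metric learning for kernel regression): minimizes the leave-one-out
  Nadaraya-Watson regression error; binary labels are treated as a {0, 1}
  regression target.

LMNN and MLKR are optimized with L-BFGS on analytic gradients, both
expressed through the weighted scatter identity
sum_ij C_ij (x_i-x_j)(x_i-x_j)^T = X^T (diag(r) + diag(c) - C - C^T) X.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.special import softmax
from sklearn.neighbors import NeighborhoodComponentsAnalysis

from .retrieval import MetricTransform

METHODS = ("lmnn", "nca", "mlkr")


def _weighted_scatter(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """sum_{i,j} C_ij (x_i - x_j)(x_i - x_j)^T without forming the pairs."""
    r = C.sum(axis=1)
    c = C.sum(axis=0)
    return (X.T * (r + c)) @ X - X.T @ (C @ X) - X.T @ (C.T @ X)


# ---------------------------------------------------------------------------
# Objectives (also used as independent contracts in tests)


def lmnn_objective(L: np.ndarray, X: np.ndarray, y: np.ndarray,
                   targets: np.ndarray, mu: float = 0.5, margin: float = 1.0,
                   with_grad: bool = False):
    n = X.shape[0]
    XL = X @ L.T
    D = cdist(XL, XL, "sqeuclidean")
    diff_class = y[:, None] != y[None, :]
    pull = 0.0
    push = 0.0
    C = np.zeros((n, n))
    for col in range(targets.shape[1]):
        j = targets[:, col]
        d_ij = D[np.arange(n), j]
        pull += d_ij.sum()
        C[np.arange(n), j] += (1.0 - mu)
        # impostors: l with y_l != y_i and d_il < margin + d_ij
        hinge = margin + d_ij[:, None] - D  # (i, l)
        active = diff_class & (hinge > 0)
        push += hinge[active].sum()
        rows = active.sum(axis=1).astype(float)
        C[np.arange(n), j] += mu * rows
        C -= mu * active
    value = (1.0 - mu) * pull + mu * push
    if not with_grad:
        return value
    grad = 2.0 * L @ _weighted_scatter(X, C)
    return value, grad


def nca_objective(L: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Expected leave-one-out softmax k-NN score (to be maximized)."""
    XL = X @ L.T
    D = cdist(XL, XL, "sqeuclidean")
    np.fill_diagonal(D, np.inf)
    P = softmax(-D, axis=1)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    return float((P * same).sum())


def mlkr_objective(L: np.ndarray, X: np.ndarray, y: np.ndarray,
                   with_grad: bool = False):
    """Leave-one-out kernel-regression squared error under the metric L."""
    y = np.asarray(y, dtype=float)
    XL = X @ L.T
    D = cdist(XL, XL, "sqeuclidean")
    np.fill_diagonal(D, np.inf)
    P = softmax(-D, axis=1)  # p_ij, j != i
    yhat = P @ y
    resid = yhat - y
    value = float((resid ** 2).sum())
    if not with_grad:
        return value
    # dvalue/d(d_ik^2) = -2 resid_i * p_ik * (y_k - yhat_i)
    W = -2.0 * resid[:, None] * P * (y[None, :] - yhat[:, None])
    grad = 2.0 * L @ _weighted_scatter(X, W)
    return value, grad


# ---------------------------------------------------------------------------
# Learners


def _target_neighbors(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """For each point, its k nearest same-class points (Euclidean, fixed)."""
    n = X.shape[0]
    D = cdist(X, X, "sqeuclidean")
    np.fill_diagonal(D, np.inf)
    D = D.copy()
    D[y[:, None] != y[None, :]] = np.inf
    order = np.argsort(D, axis=1, kind="stable")
    counts = (y[:, None] == y[None, :]).sum(axis=1) - 1
    if (counts < k).any():
        raise ValueError(
            f"every point needs at least k={k} same-class neighbors "
            f"(smallest class has {int(counts.min()) + 1} members)")
    return order[:, :k]


def _fit_lbfgs(fun, dim: int, maxiter: int) -> tuple[np.ndarray, float]:
    x0 = np.eye(dim).ravel()
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    msg = str(res.message).upper()
    # stopping at the iteration budget is expected; anything else is surfaced
    if not res.success and "MAXITER" not in msg and "ITERATIONS REACHED" not in msg:
        warnings.warn(f"metric optimization stopped early: {res.message}",
                      stacklevel=3)
    return res.x.reshape(dim, dim), float(res.fun)


def learn_metric(Z_train: np.ndarray, y_train: np.ndarray, method: str,
                 k: int = 5, seed: int = 0, maxiter: int = 60) -> MetricTransform:
    """Learn a square L for the named objective; the objective value at the
    returned L is never worse than at the identity initialization."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    X = np.atleast_2d(np.asarray(Z_train, dtype=float))
    y = np.asarray(y_train)
    dim = X.shape[1]
    eye = np.eye(dim)

    if method in ("lmnn", "nca") and np.unique(y).size < 2:
        raise ValueError(f"{method} requires at least two classes")

    if method == "lmnn":
        targets = _target_neighbors(X, y, k)

        def fun(flat):
            v, g = lmnn_objective(flat.reshape(dim, dim), X, y, targets,
                                  with_grad=True)
            return v, g.ravel()

        L, value = _fit_lbfgs(fun, dim, maxiter)
        if value > lmnn_objective(eye, X, y, targets):
            warnings.warn("LMNN did not improve on identity; returning I",
                          stacklevel=2)
            L, value = eye, lmnn_objective(eye, X, y, targets)
        return MetricTransform(L=L, method="lmnn", objective=value)

    if method == "mlkr":
        yf = y.astype(float)

        def fun(flat):
            v, g = mlkr_objective(flat.reshape(dim, dim), X, yf, with_grad=True)
            return v, g.ravel()

        L, value = _fit_lbfgs(fun, dim, maxiter)
        if value > mlkr_objective(eye, X, yf):
            warnings.warn("MLKR did not improve on identity; returning I",
                          stacklevel=2)
            L, value = eye, mlkr_objective(eye, X, yf)
        return MetricTransform(L=L, method="mlkr", objective=value)

    # NCA
    nca = NeighborhoodComponentsAnalysis(init="identity", random_state=seed,
                                         max_iter=maxiter)
    nca.fit(X, y)
    L = nca.components_
    value = nca_objective(L, X, y)
    if value < nca_objective(eye, X, y):
        warnings.warn("NCA did not improve on identity; returning I",
                      stacklevel=2)
        L, value = eye, nca_objective(eye, X, y)
    return MetricTransform(L=L, method="nca", objective=value)
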