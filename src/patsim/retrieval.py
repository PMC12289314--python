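"""Similar-patient retrieval: exact k-NN with Euclidean or Mahalanobis
distance and majority-vote label assignment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class MetricTransform:
    """A linear map L defining the Mahalanobis distance
    d(u, v) = ||L u - L v||_2. ``method`` records how L was obtained."""

    L: np.ndarray
    method: str = "identity"
    objective: float | None = None  # learner's objective value at L, if any

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2 or self.L.shape[0] != self.L.shape[1]:
            raise ValueError("L must be a square matrix")
        if not np.isfinite(self.L).all():
            raise ValueError("L must be finite")
        if self.method == "identity" and not np.allclose(self.L, np.eye(len(self.L))):
            raise ValueError("identity method requires L = I")

    @classmethod
    def identity(cls, dim: int) -> "MetricTransform":
        return cls(L=np.eye(dim), method="identity")

    def to_json_dict(self) -> dict:
        return {"method": self.method, "L": self.L.tolist(),
                "objective": self.objective}

    @classmethod
    def from_json_dict(cls, d: dict) -> "MetricTransform":
        return cls(L=np.array(d["L"]), method=d["method"],
                   objective=d.get("objective"))


@dataclass
class RetrievalResult:
    """Per-query neighbors: (q, k) index and distance arrays, the positive
    vote fraction, and the majority-vote prediction."""

    neighbor_indices: np.ndarray
    neighbor_distances: np.ndarray
    scores: np.ndarray       # fraction of positive neighbors, in [0, 1]
    predictions: np.ndarray  # 1 iff scores >= 0.5 (ties predict positive)

    @property
    def k(self) -> int:
        return self.neighbor_indices.shape[1]


def euclidean(u: np.ndarray, v: np.ndarray) -> float:
    u, v = np.asarray(u, float), np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(((u - v) ** 2).sum()))


def mahalanobis(u: np.ndarray, v: np.ndarray, T: MetricTransform) -> float:
    """Euclidean distance after the linear map L (square-root convention, so
    L = I reduces exactly to the Euclidean distance)."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    if T.L.shape[1] != u.shape[0]:
        raise ValueError("dimension mismatch between L and vectors")
    return euclidean(T.L @ u, T.L @ v)


def knn_query(Z_train: np.ndarray, y_train: np.ndarray, Z_query: np.ndarray,
              k: int, metric: MetricTransform | None = None,
              distance_fn=None, tie_positive: bool = True) -> RetrievalResult:
    """Exact k nearest training rows per query.

    Distance ties are broken by lower training-row index. The predicted
    label is 1 iff the positive vote fraction exceeds 0.5; an exact 0.5 tie
    predicts positive by default (``tie_positive``).
    """
    Z_train = np.atleast_2d(np.asarray(Z_train, float))
    Z_query = np.atleast_2d(np.asarray(Z_query, float))
    y_train = np.asarray(y_train)
    n = Z_train.shape[0]
    if not 0 < k <= n:
        raise ValueError(f"k={k} must lie in [1, n_train={n}]")
    if distance_fn is not None:
        D = np.array([[distance_fn(q, t) for t in Z_train] for q in Z_query])
    elif metric is not None:
        D = cdist(Z_query @ metric.L.T, Z_train @ metric.L.T)
    else:
        D = cdist(Z_query, Z_train)
    # stable argsort on distance => equal distances keep ascending row index
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    dists = np.take_along_axis(D, order, axis=1)
    votes = y_train[order].mean(axis=1)
    if tie_positive:
        preds = (votes >= 0.5).astype(int)
    else:
        preds = (votes > 0.5).astype(int)
    return RetrievalResult(neighbor_indices=order, neighbor_distances=dists,
                           scores=votes, predictions=preds)
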