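"""Supervised dimensionality reduction by partial least squares.

NIPALS-style PLS1 with the binary label as a single response column.  The
fitted model decomposes the (centered) training matrix as

    X = Xs . Xl^T + E

where Xs (samples x d) holds the component scores, Xl (features x d) the
loadings, and E the residual; scores are chosen to maximize covariance with
the label, in non-increasing order over components.  Determinism is pinned
by a fixed deflation scheme and a sign convention: each weight vector's
largest-magnitude entry is positive.

Out-of-sample projection uses only training-derived quantities (weights,
loadings, column means); it takes no labels, so using it inside a
cross-validation fold cannot leak test labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .table import FeatureTable

__all__ = ["PlsModel", "fit_pls", "transform"]


@dataclass
class PlsModel:
    n_components: int
    weights: np.ndarray       # m x d, unit-norm per component
    loadings: np.ndarray      # Xl, m x d
    scores: np.ndarray        # Xs, l x d (training scores)
    y_loadings: np.ndarray    # d
    residual: np.ndarray      # E, l x m
    x_mean: np.ndarray        # m
    y_mean: float
    feature_names: list[str]
    y_used: np.ndarray

    def transform_values(self, X: np.ndarray) -> np.ndarray:
        """Project rows of X into the d-dimensional score space."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"schema mismatch: model trained on {self.weights.shape[0]} "
                f"features, input has {X.shape[1]}"
            )
        Xc = X - self.x_mean
        T = np.empty((X.shape[0], self.n_components))
        for a in range(self.n_components):
            t = Xc @ self.weights[:, a]
            T[:, a] = t
            Xc = Xc - np.outer(t, self.loadings[:, a])
        return T

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "feature_names": self.feature_names,
        }


def fit_pls(table: FeatureTable, n_components: int) -> PlsModel:
    """Fit a PLS1 decomposition of the table against its binary labels.

    Requires an NA-free, normalized table and 1 <= d < min(m, l).
    """
    if table.na_mask.any():
        raise ValueError("fit_pls expects an NA-free table")
    if not table.normalized:
        raise ValueError("fit_pls expects a normalized table")
    X = np.asarray(table.values, dtype=float)
    y = np.asarray(table.labels, dtype=float)
    l, m = X.shape
    d = int(n_components)
    if not 1 <= d < m:
        raise ValueError(f"n_components must satisfy 1 <= d < m={m}")
    if d >= l:
        raise ValueError(f"n_components must be < number of samples ({l})")
    if np.ptp(y) == 0:
        raise ValueError("constant labels: PLS direction undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.empty((m, d))
    P = np.empty((m, d))
    T = np.empty((l, d))
    q = np.empty(d)
    for a in range(d):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError(
                f"residual covariance with labels vanished at component {a}: "
                "reduce n_components"
            )
        w /= nw
        # sign convention: largest-magnitude weight entry positive
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xc @ w
        tt = float(t @ t)
        p = Xc.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a], P[:, a], T[:, a] = w, p, t
        Xc = Xc - np.outer(t, p)
        yc = yc - q[a] * t

    E = (X - x_mean) - T @ P.T
    return PlsModel(
        n_components=d,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        residual=E,
        x_mean=x_mean,
        y_mean=y_mean,
        feature_names=list(table.feature_names),
        y_used=np.asarray(table.labels, dtype=int),
    )


def transform(model: PlsModel, table: FeatureTable) -> np.ndarray:
    """Project a table into the model's score space, checking the schema."""
    if list(table.feature_names) != list(model.feature_names):
        raise ValueError("feature names/order do not match the training table")
    return model.transform_values(table.values)
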