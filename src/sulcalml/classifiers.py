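"""The two classification models behind a common train/predict contract.

* :class:`LinearSeparator` — a soft-margin maximum-margin linear separator
  (linear-kernel SVM).  The decision value for a sample x is ``w.x - b``
  with prediction by sign.
* :class:`MlpClassifier` — a compact feedforward multilayer perceptron with
  two hidden layers, trained with Adam at batch size 1 under class-weighted
  cross-entropy for a fixed number of epochs (no early stopping).

Both models expose ``theta_norm_sq()`` — the squared Euclidean norm of the
flattened parameter vector (weights and biases) — which the PAC-Bayes
dropout bound consumes as its complexity term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = ["LinearSeparator", "fit_linear_svm", "MlpSpec", "MlpClassifier", "fit_mlp"]


# ---------------------------------------------------------------------------
# linear separator
# ---------------------------------------------------------------------------

@dataclass
class LinearSeparator:
    """Hyperplane ``w.x - b = 0`` with sign prediction."""

    C: float = 1.0
    class_weight: str | dict | None = "balanced"
    w: np.ndarray | None = None
    b: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSeparator":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("need samples from both classes")
        svc = SVC(kernel="linear", C=self.C, class_weight=self.class_weight)
        svc.fit(X, y)
        self.w = svc.coef_.ravel().copy()
        self.b = -float(svc.intercept_[0])
        return self

    def _check(self, X: np.ndarray) -> np.ndarray:
        if self.w is None:
            raise ValueError("model not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"dimension mismatch: model has {self.w.shape[0]} features, "
                f"input has {X.shape[1]}"
            )
        return X

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        return X @ self.w - self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_values(X) > 0).astype(int)

    def theta_norm_sq(self) -> float:
        """||Theta||^2 = sum of squared weights and the squared offset."""
        return float(np.sum(self.w**2) + self.b**2)

    def to_dict(self) -> dict:
        return {"kind": "linear", "C": self.C, "w": self.w.tolist(), "b": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSeparator":
        m = cls(C=d.get("C", 1.0))
        m.w = np.asarray(d["w"], dtype=float)
        m.b = float(d["b"])
        return m


def fit_linear_svm(X, y, C: float = 1.0, class_weight="balanced") -> LinearSeparator:
    return LinearSeparator(C=C, class_weight=class_weight).fit(X, y)


# ---------------------------------------------------------------------------
# multilayer perceptron
# ---------------------------------------------------------------------------

def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class MlpSpec:
    """Architecture and training recipe.

    Four layers: input, two ReLU hidden layers (defaults 32 and 16 units),
    and a 2-unit softmax output.  Training runs exactly ``epochs`` passes at
    batch size 1 with Adam (lr 0.001) on cross-entropy weighted by inverse
    class frequency; sample order is a seeded shuffle per epoch.
    """

    hidden: tuple[int, int] = (32, 16)
    epochs: int = 18
    batch_size: int = 1
    learning_rate: float = 0.001
    seed: int = 0


class MlpClassifier:
    """Feedforward network y_i^n = f(w_i^n . y^{n-1} + b_i^n), per layer."""

    def __init__(self, spec: MlpSpec | None = None):
        self.spec = spec or MlpSpec()
        self.weights: list[np.ndarray] | None = None
        self.biases: list[np.ndarray] | None = None

    # -- initialization -------------------------------------------------
    def _init_params(self, n_in: int) -> None:
        rng = np.random.default_rng(self.spec.seed)
        sizes = (n_in, *self.spec.hidden, 2)
        self.weights, self.biases = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / a)  # He init for ReLU hidden stack
            self.weights.append(rng.normal(0.0, scale, size=(a, b)))
            self.biases.append(np.zeros(b))

    # -- forward --------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [X]
        h = X
        for i, (W, c) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + c
            h = _softmax(z) if i == len(self.weights) - 1 else _relu(z)
            acts.append(h)
        return acts, h

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        return self._forward(X)[1]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Class-1 propensity minus 1/2, so sign thresholding matches predict."""
        return self.predict_proba(X)[:, 1] - 0.5

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def _check(self, X: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise ValueError("model not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.weights[0].shape[0]:
            raise ValueError("dimension mismatch")
        return X

    # -- training -------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MlpClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in input")
        self._init_params(X.shape[1])
        n = len(y)
        counts = np.bincount(y, minlength=2)
        if counts.min() == 0:
            raise ValueError("need samples from both classes")
        # inverse-frequency class weights, normalized to mean 1
        cw = n / (2.0 * counts)
        rng = np.random.default_rng(self.spec.seed + 1)
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        params = self.weights + self.biases
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        step = 0
        bs = self.spec.batch_size
        for _epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                grads = self._grad(X[idx], y[idx], cw)
                step += 1
                for p, g, m, v in zip(params, grads, m_t, v_t):
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    mhat = m / (1 - b1**step)
                    vhat = v / (1 - b2**step)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def _grad(self, Xb: np.ndarray, yb: np.ndarray, cw: np.ndarray) -> list[np.ndarray]:
        acts, probs = self._forward(Xb)
        k = len(yb)
        onehot = np.eye(2)[yb]
        w = cw[yb][:, None]
        delta = w * (probs - onehot) / k  # softmax + weighted CE
        gW, gb = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            gW.append(acts[layer].T @ delta)
            gb.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        return gW[::-1] + gb[::-1]

    # -- introspection --------------------------------------------------
    def theta_norm_sq(self) -> float:
        if self.weights is None:
            raise ValueError("model not fitted")
        return float(
            sum(np.sum(W**2) for W in self.weights)
            + sum(np.sum(c**2) for c in self.biases)
        )

    def forward_single(self, x: np.ndarray) -> np.ndarray:
        """Output of the network for one sample (class probabilities)."""
        return self.predict_proba(np.asarray(x, dtype=float)[None, :])[0]

    def to_dict(self) -> dict:
        return {
            "kind": "mlp",
            "spec": {
                "hidden": list(self.spec.hidden),
                "epochs": self.spec.epochs,
                "batch_size": self.spec.batch_size,
                "learning_rate": self.spec.learning_rate,
                "seed": self.spec.seed,
            },
            "weights": [W.tolist() for W in self.weights],
            "biases": [c.tolist() for c in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MlpClassifier":
        s = d["spec"]
        model = cls(MlpSpec(tuple(s["hidden"]), s["epochs"], s["batch_size"],
                            s["learning_rate"], s["seed"]))
        model.weights = [np.asarray(W, dtype=float) for W in d["weights"]]
        model.biases = [np.asarray(c, dtype=float) for c in d["biases"]]
        return model


def fit_mlp(X, y, spec: MlpSpec | None = None) -> MlpClassifier:
    return MlpClassifier(spec).fit(X, y)
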