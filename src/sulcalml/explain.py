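"""Model-agnostic explanation operators.

Three routes to per-feature attributions for a single prediction:

* :func:`explain_local` — a locality-weighted sparse linear surrogate in
  the spirit of LIME: perturb the sample, weight perturbations by a
  proximity kernel, and fit a penalized linear model whose coefficients
  are the explanation.
* :func:`exact_shapley` — full enumeration of the Shapley value

      phi_s = sum_{T subseteq S\\{s}} |T|! (|S|-|T|-1)! / |S|! * (f(T u {s}) - f(T))

  where f(T) evaluates the model with features outside T replaced by their
  background expectation.  Guarded to <= 12 features (2^12 coalitions).
* :func:`kernel_shap` — the weighted-least-squares approximation with the
  Shapley kernel (M-1) / (C(M,|z|) |z| (M-|z|)); with full coalition
  enumeration it reproduces the exact values.

All three satisfy (or approach) local accuracy: attributions plus the
baseline sum to the model output at the explained sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

__all__ = [
    "LocalSurrogateConfig",
    "ShapResult",
    "explain_local",
    "exact_shapley",
    "kernel_shap",
    "summarize_attributions",
]

_MAX_EXACT_FEATURES = 12


@dataclass
class LocalSurrogateConfig:
    n_perturbations: int = 500
    kernel_width: float = 2.0
    perturbation_sd: float = 1.0
    complexity_penalty: float = 0.01  # ridge penalty on surrogate coefficients
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perturbations < max(self.top_k, 2):
            raise ValueError("n_perturbations must be >= top_k (and >= 2)")


@dataclass
class ShapResult:
    feature_names: list[str]
    phi: np.ndarray
    baseline: float
    fx: float

    @property
    def additivity_residual(self) -> float:
        return abs(float(self.phi.sum()) + self.baseline - self.fx)


def explain_local(
    predict_fn, x: np.ndarray, config: LocalSurrogateConfig | None = None,
    feature_names: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Top-k signed surrogate weights around sample x.

    ``predict_fn`` maps an (n, m) array to a propensity vector.  A positive
    weight means increasing the feature increases the explained class's
    propensity near x.
    """
    config = LocalSurrogateConfig() if config is None else config
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    names = feature_names or [f"f{i}" for i in range(m)]
    rng = np.random.default_rng(config.seed)
    Z = x + config.perturbation_sd * rng.standard_normal((config.n_perturbations, m))
    Z[0] = x  # anchor the explained point
    dist = np.linalg.norm(Z - x, axis=1)
    if np.ptp(dist) == 0 and config.n_perturbations > 1:
        raise ValueError("degenerate perturbation spread")
    weights = np.exp(-(dist**2) / config.kernel_width**2)
    target = np.asarray(predict_fn(Z), dtype=float).ravel()
    reg = Ridge(alpha=config.complexity_penalty)
    reg.fit(Z - x, target, sample_weight=weights)
    coefs = reg.coef_
    order = np.argsort(-np.abs(coefs))[: config.top_k]
    return [(names[i], float(coefs[i])) for i in order]


def _coalition_outputs(predict_fn, x, background, masks):
    """Model outputs for synthetic points taking x on the mask, background off."""
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float).ravel()
    pts = np.where(masks, x, background)
    return np.asarray(predict_fn(pts), dtype=float).ravel()


def exact_shapley(
    predict_fn, x: np.ndarray, background: np.ndarray,
    feature_names: list[str] | None = None,
) -> ShapResult:
    """Shapley values by full coalition enumeration (<= 12 features).

    ``background`` is the reference point features revert to when excluded
    from a coalition — typically the training-sample mean.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = x.size
    if M > _MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration limited to {_MAX_EXACT_FEATURES} features, got {M}"
        )
    names = feature_names or [f"f{i}" for i in range(M)]
    n_coal = 1 << M
    masks = np.zeros((n_coal, M), dtype=bool)
    for c in range(n_coal):
        masks[c] = [(c >> i) & 1 for i in range(M)]
    vals = _coalition_outputs(predict_fn, x, background, masks)
    sizes = masks.sum(axis=1)
    # weight |T|! (M-|T|-1)! / M! indexed by coalition size |T|
    wt = np.array(
        [math.factorial(t) * math.factorial(M - t - 1) / math.factorial(M)
         for t in range(M)]
    )
    phi = np.zeros(M)
    for s in range(M):
        without = ~masks[:, s]
        tsize = sizes[without]
        f_t = vals[without]
        f_ts = vals[without.nonzero()[0] | (1 << s)]
        phi[s] = float(np.sum(wt[tsize] * (f_ts - f_t)))
    baseline = float(vals[0])
    fx = float(vals[-1])
    return ShapResult(list(names), phi, baseline, fx)


def _shapley_kernel_weight(M: int, z: int) -> float:
    if z == 0 or z == M:
        return 0.0
    return (M - 1) / (math.comb(M, z) * z * (M - z))


def kernel_shap(
    predict_fn, x: np.ndarray, background: np.ndarray,
    n_coalitions: int | None = None, seed: int = 0,
    feature_names: list[str] | None = None,
) -> ShapResult:
    """Kernel-weighted least-squares Shapley estimate.

    Solves a weighted regression over coalition indicator vectors with the
    Shapley kernel, under the local-accuracy constraint that attributions
    sum to f(x) - f(background).  With all 2^M - 2 proper coalitions
    enumerated the estimate equals the exact Shapley values.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = x.size
    names = feature_names or [f"f{i}" for i in range(M)]
    full = 2**M - 2 if M <= 24 else None  # proper, non-empty coalitions
    if full is not None and (n_coalitions is None or n_coalitions >= full):
        codes = np.arange(1, 2**M - 1)
        masks = ((codes[:, None] >> np.arange(M)) & 1).astype(bool)
        sizes = masks.sum(axis=1)
        w = np.array([_shapley_kernel_weight(M, int(z)) for z in sizes])
    else:
        if n_coalitions is None or n_coalitions < M + 2:
            raise ValueError("n_coalitions must be >= number of features + 2")
        # sample coalitions with probability proportional to the Shapley
        # kernel, then regress with uniform weights (sampling already
        # carries the kernel)
        rng = np.random.default_rng(seed)
        size_grid = np.arange(1, M)
        size_w = np.array([_shapley_kernel_weight(M, int(z)) * math.comb(M, z)
                           for z in size_grid], dtype=float)
        size_w /= size_w.sum()
        draw_sizes = rng.choice(size_grid, size=n_coalitions, p=size_w)
        masks = np.zeros((n_coalitions, M), dtype=bool)
        for i, z in enumerate(draw_sizes):
            masks[i, rng.choice(M, size=int(z), replace=False)] = True
        w = np.ones(len(masks))

    base = _coalition_outputs(predict_fn, x, background,
                              np.zeros((1, M), dtype=bool))[0]
    fx = _coalition_outputs(predict_fn, x, background,
                            np.ones((1, M), dtype=bool))[0]
    vals = _coalition_outputs(predict_fn, x, background, masks)

    # eliminate the constraint sum(phi) = fx - base by substituting the last
    # coefficient, as in the standard kernel-regression solution
    Zm = masks.astype(float)
    A = Zm[:, :-1] - Zm[:, [-1]]
    b = vals - base - Zm[:, -1] * (fx - base)
    Aw = A * w[:, None]
    try:
        phi_head = np.linalg.solve(A.T @ Aw, Aw.T @ b)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular coalition design; raise n_coalitions"
        ) from err
    phi = np.empty(M)
    phi[:-1] = phi_head
    phi[-1] = (fx - base) - phi_head.sum()
    return ShapResult(list(names), phi, float(base), float(fx))


def summarize_attributions(
    results: list[ShapResult],
    values: np.ndarray | None = None,
    top_k: int = 10,
) -> dict:
    """Rank features by mean |phi| across explained samples.

    Returns ``{"ranking": DataFrame, "dependence": {feature: (value, phi)
    DataFrame}}``; ``values`` (n_samples x m, in feature units) enables the
    dependence export.  All-zero attributions yield an empty ranking.
    """
    if not results:
        raise ValueError("no explanations to summarize")
    names = results[0].feature_names
    phi = np.vstack([r.phi for r in results])
    mean_abs = np.abs(phi).mean(axis=0)
    if np.all(mean_abs == 0):
        import warnings

        warnings.warn("all attributions are zero; nothing to rank")
        return {"ranking": pd.DataFrame(columns=["feature", "mean_abs_phi"]),
                "dependence": {}}
    order = np.argsort(-mean_abs)[:top_k]
    ranking = pd.DataFrame(
        {"feature": [names[i] for i in order], "mean_abs_phi": mean_abs[order]}
    )
    dependence = {}
    if values is not None:
        values = np.asarray(values, dtype=float)
        for i in order:
            dependence[names[i]] = pd.DataFrame(
                {"value": values[:, i], "phi": phi[:, i]}
            )
    return {"ranking": ranking, "dependence": dependence}
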