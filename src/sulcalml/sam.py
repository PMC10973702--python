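"""Classifier-based feature relevance via a proportion test.

Each feature is fed alone into a linear classifier under resubstitution
with upper-bound correction (d=1 concentration bound), averaged over many
balanced permutations of the cohort.  The per-feature mean accuracies
pi_hat are then ranked by a one-sided proportion test against their own
mean pi0:

    z = (pi_hat - pi0) / sigma0,    sigma0 = sqrt(pi0 * (1 - pi0) / l),

where l counts the accuracies above pi0, and the p-value is the standard
normal upper tail.  Features whose single-feature accuracy sits above the
pack are declared relevant, without any distributional assumption on the
features themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifiers import fit_linear_svm
from .table import FeatureTable
from .validation import (
    ConcentrationBoundSpec,
    balanced_subsample,
    compute_metrics,
    concentration_bound,
    confusion_from_predictions,
)

__all__ = [
    "SamConfig",
    "ProportionTestResult",
    "per_feature_accuracy",
    "proportion_test",
    "select_sam",
    "combine_selections",
    "run_sam",
]


@dataclass
class SamConfig:
    n_permutations: int = 1000
    eta: float = 0.05
    #: subtract the d=1 concentration bound from each permutation's accuracy
    apply_bound: bool = True
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ProportionTestResult:
    feature_name: str
    pi_hat: float
    pi0: float
    l: int
    sigma0: float
    z: float
    p_value: float


def per_feature_accuracy(
    table: FeatureTable, feature: str | int, config: SamConfig | None = None
) -> float:
    """Mean bound-corrected single-feature resubstitution accuracy.

    Each permutation draws a balanced subsample (equal class counts, size
    2*min class count) without replacement, trains a class-weight-balanced
    linear SVM on the single feature, and records resubstitution balanced
    accuracy minus the d=1 concentration bound at the subsample size.
    """
    config = SamConfig() if config is None else config
    j = table.feature_names.index(feature) if isinstance(feature, str) else int(feature)
    x = table.values[:, [j]]
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(config.seed)
    n_bal = 2 * int(np.bincount(y, minlength=2).min())
    mu = (
        concentration_bound(ConcentrationBoundSpec(n=n_bal, d=1, eta=config.eta))
        if config.apply_bound
        else 0.0
    )
    accs = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        idx = balanced_subsample(y, rng)
        model = fit_linear_svm(x[idx], y[idx], C=config.C)
        cm = confusion_from_predictions(y[idx], model.predict(x[idx]))
        accs[i] = compute_metrics(cm).balanced_accuracy - mu
    return float(accs.mean())


def proportion_test(
    accuracies: dict[str, float] | "np.ndarray", feature_names=None
) -> list[ProportionTestResult]:
    """Proportion test of every per-feature accuracy against their mean.

    pi0 is the mean of all accuracies, l the count strictly above pi0.
    Degenerate when no accuracy exceeds the mean (sigma0 undefined).
    """
    if isinstance(accuracies, dict):
        feature_names = list(accuracies)
        acc = np.array([accuracies[f] for f in feature_names], dtype=float)
    else:
        acc = np.asarray(accuracies, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(len(acc))]
    if len(acc) < 2:
        raise ValueError("need at least 2 features")
    pi0 = float(acc.mean())
    l = int((acc > pi0).sum())
    if l == 0:
        raise ValueError("no accuracy above the mean: sigma0 undefined")
    if not 0.0 < pi0 < 1.0:
        raise ValueError("pi0 outside (0, 1): proportion test undefined")
    sigma0 = float(np.sqrt(pi0 * (1.0 - pi0) / l))
    out = []
    for name, a in zip(feature_names, acc):
        z = (float(a) - pi0) / sigma0
        out.append(
            ProportionTestResult(
                feature_name=name,
                pi_hat=float(a),
                pi0=pi0,
                l=l,
                sigma0=sigma0,
                z=z,
                p_value=float(stats.norm.sf(z)),
            )
        )
    return out


def select_sam(
    results: list[ProportionTestResult], threshold: float = 0.05
) -> list[ProportionTestResult]:
    """Features with upper-tail p < threshold, descending z, ties by name."""
    if not results:
        raise ValueError("no results to select from")
    sig = [r for r in results if r.p_value < threshold]
    return sorted(sig, key=lambda r: (-r.z, r.feature_name))


def run_sam(table: FeatureTable, config: SamConfig | None = None) -> list[ProportionTestResult]:
    """Per-feature accuracies for every column, then the proportion test."""
    config = SamConfig() if config is None else config
    accs = {}
    for j, name in enumerate(table.feature_names):
        # fixed per-feature sub-seed so results do not depend on column order
        cfg = SamConfig(
            n_permutations=config.n_permutations,
            eta=config.eta,
            apply_bound=config.apply_bound,
            C=config.C,
            seed=config.seed + 7919 * j,
        )
        accs[name] = per_feature_accuracy(table, j, cfg)
    return proportion_test(accs)


@dataclass
class SelectionPartition:
    both: list[str] = field(default_factory=list)
    parametric_only: list[str] = field(default_factory=list)
    sam_only: list[str] = field(default_factory=list)

    @property
    def union(self) -> list[str]:
        return self.both + self.parametric_only + self.sam_only


def combine_selections(parametric_set, sam_set) -> SelectionPartition:
    """Partition two selected-feature sets into (both, parametric-only, sam-only)."""
    p, s = set(parametric_set), set(sam_set)
    return SelectionPartition(
        both=sorted(p & s),
        parametric_only=sorted(p - s),
        sam_only=sorted(s - p),
    )
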