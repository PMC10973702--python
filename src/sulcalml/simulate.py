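"""Seeded synthetic sulcal-morphometry tables.

The real cohort behind this kind of analysis (automated sulcus labelling of
structural MRI in a schizophrenia case-control study) is not publicly
depositable, so this module generates feature tables with the statistical
structure the downstream pipeline assumes:

* one ``length``/``meandepth``/``maxdepth`` triple per cortical region;
* mostly Gaussian columns with a configurable minority carrying a one-sided
  long-tailed (lognormal) contaminant, mimicking the skewed features seen in
  real sulcal measurements;
* the two depth measures of a region correlated through a shared latent
  factor (deeper sulci are deeper on both summaries), length independent;
* region-level misdetections — when the labelling pipeline misses a sulcus,
  all three of its measures are missing together;
* occasional gross outliers at 6-10 SD, so the exclusion rules downstream
  have positive cases to catch;
* small planted standardized group differences at chosen features.

Everything is driven by one integer seed; identical configs and seeds give
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .table import MEASURES, FeatureTable

__all__ = ["SimulationConfig", "simulate_table", "simulate_demographics"]

# fixed offsets deriving per-stage RNG streams from the master seed
_STAGE_OFFSETS = {
    "base": 0,
    "heavy": 1,
    "misdetect": 2,
    "outlier": 3,
}

# lognormal contaminant shape: additive skew strong enough that a normality
# test rejects essentially always at n ~ 100
_HEAVY_SIGMA = 0.9
_HEAVY_SCALE = 0.8


@dataclass
class SimulationConfig:
    """Generator settings for one synthetic cohort.

    Defaults mirror the study conditions the pipeline targets: two groups of
    ~57 subjects, 49 usable regions x 3 measures = 147 features, ~15% of
    features long-tailed, depth measures correlated ~0.7 within region.
    """

    n_per_class: int = 57
    n_regions: int = 49
    measures: Sequence[str] = MEASURES
    effect_features: Sequence[tuple[int, float]] = field(default_factory=list)
    heavy_tail_fraction: float = 0.15
    depth_correlation: float = 0.7
    misdetect_prob: float = 0.0
    outlier_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        for name, v in (
            ("heavy_tail_fraction", self.heavy_tail_fraction),
            ("misdetect_prob", self.misdetect_prob),
            ("outlier_prob", self.outlier_prob),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.depth_correlation <= 1.0:
            raise ValueError("depth_correlation must be in [-1, 1]")
        m = self.n_regions * len(self.measures)
        for idx, _delta in self.effect_features:
            if not 0 <= idx < m:
                raise ValueError(f"effect feature index {idx} out of range [0, {m})")

    @property
    def n_features(self) -> int:
        return self.n_regions * len(self.measures)

    def to_dict(self) -> dict:
        return {
            "n_per_class": self.n_per_class,
            "n_regions": self.n_regions,
            "measures": list(self.measures),
            "effect_features": [[int(i), float(d)] for i, d in self.effect_features],
            "heavy_tail_fraction": self.heavy_tail_fraction,
            "depth_correlation": self.depth_correlation,
            "misdetect_prob": self.misdetect_prob,
            "outlier_prob": self.outlier_prob,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["effect_features"] = [tuple(e) for e in d.get("effect_features", [])]
        return cls(**d)


def _heavy_sd() -> float:
    """Theoretical SD of N(0,1) + scale * lognormal(0, sigma) (independent)."""
    s2 = _HEAVY_SIGMA**2
    var_ln = (np.exp(s2) - 1.0) * np.exp(s2)
    return float(np.sqrt(1.0 + _HEAVY_SCALE**2 * var_ln))


def simulate_table(config: SimulationConfig) -> FeatureTable:
    """Draw one cohort table from the configured generative model.

    Rows are ``n_per_class`` controls (label 0) followed by ``n_per_class``
    cases (label 1).  Planted effects shift the case group mean by
    ``delta`` in units of the column's theoretical SD.
    """
    n = 2 * config.n_per_class
    n_feat = config.n_features
    measures = list(config.measures)
    n_meas = len(measures)

    rng_base = np.random.default_rng(config.seed + _STAGE_OFFSETS["base"])
    rng_heavy = np.random.default_rng(config.seed + _STAGE_OFFSETS["heavy"])
    rng_miss = np.random.default_rng(config.seed + _STAGE_OFFSETS["misdetect"])
    rng_out = np.random.default_rng(config.seed + _STAGE_OFFSETS["outlier"])

    values = np.empty((n, n_feat))
    col_sd = np.ones(n_feat)

    # shared latent factor per region couples the two depth measures;
    # corr(meandepth, maxdepth) = depth_correlation, each column marginal N(0,1)
    rho = config.depth_correlation
    a = np.sqrt(abs(rho))
    b = np.sqrt(1.0 - abs(rho))
    sign = 1.0 if rho >= 0 else -1.0
    depth_idx = {m: i for i, m in enumerate(measures) if "depth" in m}
    for r in range(config.n_regions):
        latent = rng_base.standard_normal(n)
        for j, meas in enumerate(measures):
            col = r * n_meas + j
            eps = rng_base.standard_normal(n)
            if meas in depth_idx and len(depth_idx) == 2:
                # first depth column takes +latent, second takes sign*latent
                s = 1.0 if list(depth_idx).index(meas) == 0 else sign
                values[:, col] = s * a * latent + b * eps
            else:
                values[:, col] = eps

    # long-tailed columns: additive one-sided lognormal contaminant
    n_heavy = int(round(config.heavy_tail_fraction * n_feat))
    heavy_cols = rng_heavy.choice(n_feat, size=n_heavy, replace=False) if n_heavy else np.array([], dtype=int)
    if n_heavy:
        contam = _HEAVY_SCALE * rng_heavy.lognormal(0.0, _HEAVY_SIGMA, size=(n, n_heavy))
        contam -= contam.mean(axis=0)  # keep column means comparable
        values[:, heavy_cols] += contam
        col_sd[heavy_cols] = _heavy_sd()

    labels = np.repeat([0, 1], config.n_per_class)

    # planted standardized group shifts
    for idx, delta in config.effect_features:
        values[labels == 1, idx] += delta * col_sd[idx]

    # region-level misdetections: all measures of the region missing together
    na_mask = np.zeros((n, n_feat), dtype=bool)
    if config.misdetect_prob > 0:
        miss = rng_miss.random((n, config.n_regions)) < config.misdetect_prob
        na_mask = np.repeat(miss, n_meas, axis=1)

    # gross outliers at 6-10 SD, only in observed cells
    if config.outlier_prob > 0:
        hit = (rng_out.random((n, n_feat)) < config.outlier_prob) & ~na_mask
        if hit.any():
            k = int(hit.sum())
            mag = rng_out.uniform(6.0, 10.0, size=k)
            sgn = rng_out.choice([-1.0, 1.0], size=k)
            values[hit] = sgn * mag * col_sd[np.nonzero(hit)[1]]

    values[na_mask] = np.nan

    feature_names = [
        f"region{r + 1:03d}_{meas}"
        for r in range(config.n_regions)
        for meas in measures
    ]
    subject_ids = [f"ctl{i + 1:03d}" for i in range(config.n_per_class)] + [
        f"scz{i + 1:03d}" for i in range(config.n_per_class)
    ]
    return FeatureTable(
        subject_ids=subject_ids,
        labels=labels,
        values=values,
        feature_names=feature_names,
        na_mask=na_mask,
        normalized=False,
    )


#: default demographic covariates: (case mean, case sd, control mean, control sd)
DEFAULT_COVARIATES = {
    "age": (22.95, 5.64, 24.79, 7.36),
    "iq": (93.18, 18.40, 116.41, 14.38),
    "education_years": (12.41, 2.91, 13.40, 2.54),
}


def simulate_demographics(
    n_case: int,
    n_control: int,
    seed: int = 0,
    covariates: dict[str, tuple[float, float, float, float]] | None = None,
) -> pd.DataFrame:
    """Per-subject covariate table with exact group moments.

    Each covariate is drawn as standard normal within group, then affinely
    rescaled so that the realized sample mean and SD (ddof=1) equal the
    targets exactly.  This makes summary-statistic worked examples (group
    t-tests on age, IQ, years of education) reproducible to rounding.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group for exact moments")
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    rng = np.random.default_rng(seed)
    out = {
        "subject_id": [f"scz{i + 1:03d}" for i in range(n_case)]
        + [f"ctl{i + 1:03d}" for i in range(n_control)],
        "group": ["case"] * n_case + ["control"] * n_control,
    }
    for name, (m1, s1, m0, s0) in covariates.items():
        vals = np.empty(n_case + n_control)
        for sl, mu, sd in (
            (slice(0, n_case), m1, s1),
            (slice(n_case, None), m0, s0),
        ):
            z = rng.standard_normal(sl.stop - sl.start if sl.stop else len(vals) - sl.start)
            z = (z - z.mean()) / z.std(ddof=1)
            vals[sl] = mu + sd * z
        out[name] = vals
    return pd.DataFrame(out)
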