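"""Exclusion and normalization rules for raw feature tables.

The cascade mirrors how automated sulcus-labelling studies clean their
tables, in a fixed canonical order:

1. drop subjects whose count of misdetected regions is strictly greater
   than a threshold (default 18, ~15% of a 123-region atlas);
2. drop regions excluded by name (default: left/right insula, whose shape
   makes automated detection unreliable);
3. drop any region that still has at least one misdetection among the
   remaining subjects;
4. z-score every remaining column (sample SD by default);
5. drop subjects with any standardized value beyond ``outlier_sd`` (default
   6 SD).

Normalization statistics come from the subjects surviving steps 1-3; the
outlier removal in step 5 does not trigger re-standardization, so the
">6 SD" rule keeps a single, well-defined meaning.  The order matters —
swapping steps 4 and 5 changes which subjects survive — and is fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import FeatureTable, region_of

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "EmptyCohortError",
    "EmptyFeatureSetError",
    "DegenerateFeatureError",
    "apply_exclusions",
    "renormalize",
]


class EmptyCohortError(ValueError):
    """All subjects were removed by the exclusion cascade."""


class EmptyFeatureSetError(ValueError):
    """All regions were removed by the exclusion cascade."""


class DegenerateFeatureError(ValueError):
    """A column has zero variance and cannot be z-scored."""


@dataclass
class PreprocessConfig:
    max_misdetections_per_subject: int = 18
    excluded_regions: tuple[str, ...] = ("insula_left", "insula_right")
    outlier_sd: float = 6.0
    #: use sample (n-1) SD when z-scoring; population (n) SD if False
    sample_sd: bool = True

    def __post_init__(self) -> None:
        if self.max_misdetections_per_subject < 0:
            raise ValueError("max_misdetections_per_subject must be >= 0")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


@dataclass
class PreprocessReport:
    """Which rule removed what.  Every removal is attributed to exactly one rule."""

    subjects_removed_misdetection: list[str] = field(default_factory=list)
    regions_removed_named: list[str] = field(default_factory=list)
    regions_removed_residual_na: list[str] = field(default_factory=list)
    subjects_removed_outlier: list[str] = field(default_factory=list)
    final_shape: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        return {
            "subjects_removed_misdetection": self.subjects_removed_misdetection,
            "regions_removed_named": self.regions_removed_named,
            "regions_removed_residual_na": self.regions_removed_residual_na,
            "subjects_removed_outlier": self.subjects_removed_outlier,
            "final_shape": list(self.final_shape),
        }


def _region_na(table: FeatureTable) -> tuple[list[str], np.ndarray]:
    """(region names, subjects x regions boolean misdetection matrix).

    A region counts as misdetected for a subject if any of its measures is NA.
    """
    regions = table.regions
    col_region = np.array([region_of(n) for n in table.feature_names])
    mat = np.zeros((table.n_subjects, len(regions)), dtype=bool)
    for k, r in enumerate(regions):
        mat[:, k] = table.na_mask[:, col_region == r].any(axis=1)
    return regions, mat


def apply_exclusions(
    table: FeatureTable, config: PreprocessConfig | None = None
) -> tuple[FeatureTable, PreprocessReport]:
    """Run the five-step exclusion cascade; returns the clean table and a report."""
    if table.normalized:
        raise ValueError("apply_exclusions expects a raw (unnormalized) table")
    config = PreprocessConfig() if config is None else config
    report = PreprocessReport()

    # step 1: subjects with too many misdetected regions (strictly greater than)
    regions, miss = _region_na(table)
    n_miss = miss.sum(axis=1)
    keep_rows = n_miss <= config.max_misdetections_per_subject
    report.subjects_removed_misdetection = [
        table.subject_ids[i] for i in np.nonzero(~keep_rows)[0]
    ]
    if not keep_rows.any():
        raise EmptyCohortError("every subject exceeds the misdetection threshold")
    table = table.subset(rows=np.nonzero(keep_rows)[0])

    # step 2: named region exclusions
    excluded = set(config.excluded_regions)
    col_region = np.array([region_of(n) for n in table.feature_names])
    keep_cols = ~np.isin(col_region, list(excluded))
    report.regions_removed_named = [r for r in table.regions if r in excluded]
    if not keep_cols.any():
        raise EmptyFeatureSetError("all regions excluded by name")
    table = table.subset(cols=np.nonzero(keep_cols)[0])

    # step 3: regions with any residual misdetection
    regions, miss = _region_na(table)
    bad_regions = {r for r, any_na in zip(regions, miss.any(axis=0)) if any_na}
    report.regions_removed_residual_na = sorted(bad_regions)
    col_region = np.array([region_of(n) for n in table.feature_names])
    keep_cols = ~np.isin(col_region, list(bad_regions))
    if not keep_cols.any():
        raise EmptyFeatureSetError("every region has a residual misdetection")
    table = table.subset(cols=np.nonzero(keep_cols)[0])
    assert not table.na_mask.any(), "cascade steps 1-3 must leave an NA-free table"

    # step 4: z-score each column on the surviving subjects
    table = renormalize(table, sample_sd=config.sample_sd)

    # step 5: outlier subjects; no re-standardization afterwards
    out_rows = (np.abs(table.values) > config.outlier_sd).any(axis=1)
    report.subjects_removed_outlier = [
        table.subject_ids[i] for i in np.nonzero(out_rows)[0]
    ]
    if out_rows.all():
        raise EmptyCohortError("every subject carries a >outlier_sd value")
    table = table.subset(rows=np.nonzero(~out_rows)[0])

    report.final_shape = (table.n_subjects, table.n_features)
    return table, report


def renormalize(table: FeatureTable, sample_sd: bool = True) -> FeatureTable:
    """Z-score every column to mean 0, SD 1.  Idempotent to 1e-8.

    Raises :class:`DegenerateFeatureError` naming the first constant column.
    """
    if table.na_mask.any():
        raise ValueError("renormalize expects an NA-free table")
    ddof = 1 if sample_sd else 0
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=ddof)
    # constant columns can carry O(eps) spread from the mean's rounding
    zero = np.nonzero(sd <= 1e-12 * (1.0 + np.abs(mean)))[0]
    if zero.size:
        raise DegenerateFeatureError(
            f"zero-variance column: {table.feature_names[zero[0]]}"
        )
    out = table.subset()
    out.values = (table.values - mean) / sd
    out.normalized = True
    return out
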