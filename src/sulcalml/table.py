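"""Subject-by-feature container for sulcal morphometry tables.

A :class:`FeatureTable` holds one row per subject and one column per
``<region>_<measure>`` pair, together with the binary diagnosis label
(1 = case, 0 = control), a missingness mask for misdetected sulci, and a
flag recording whether columns have been z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "MEASURES", "region_of", "measure_of"]

#: canonical measure names, in column order within a region
MEASURES = ("length", "meandepth", "maxdepth")


def region_of(feature_name: str) -> str:
    """Region part of a ``<region>_<measure>`` feature name."""
    return feature_name.rsplit("_", 1)[0]


def measure_of(feature_name: str) -> str:
    """Measure part of a ``<region>_<measure>`` feature name."""
    return feature_name.rsplit("_", 1)[1]


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and NA bookkeeping.

    Parameters
    ----------
    subject_ids
        One identifier per row.
    labels
        Binary vector, 1 for cases and 0 for controls.
    values
        Real matrix of shape ``(n_subjects, n_features)``; entries under
        ``na_mask`` are NaN.
    feature_names
        ``<region>_<measure>`` strings, one per column.
    na_mask
        Boolean matrix marking misdetected (missing) entries.
    normalized
        True once columns have been z-scored.
    """

    subject_ids: list[str]
    labels: np.ndarray
    values: np.ndarray
    feature_names: list[str]
    na_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.na_mask is None:
            self.na_mask = np.isnan(self.values)
        self.na_mask = np.asarray(self.na_mask, dtype=bool)
        n, m = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError(
                f"{len(self.subject_ids)} subject ids for {n} rows"
            )
        if len(self.feature_names) != m:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {m} columns"
            )
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal number of subjects")
        if self.na_mask.shape != self.values.shape:
            raise ValueError("na_mask shape must match values")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = control, 1 = case)")

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def regions(self) -> list[str]:
        """Unique region names in column order."""
        seen: dict[str, None] = {}
        for name in self.feature_names:
            seen.setdefault(region_of(name), None)
        return list(seen)

    def subset(self, rows=None, cols=None) -> "FeatureTable":
        """Return a copy restricted to the given row/column index arrays."""
        rows = np.arange(self.n_subjects) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_features) if cols is None else np.asarray(cols)
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in rows],
            labels=self.labels[rows],
            values=self.values[np.ix_(rows, cols)].copy(),
            feature_names=[self.feature_names[j] for j in cols],
            na_mask=self.na_mask[np.ix_(rows, cols)].copy(),
        )

    # -- round trips ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.where(self.na_mask, np.nan, self.values),
            columns=self.feature_names,
        )
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        """Write ``subject_id,label,<region>_<measure>...`` with empty NA cells."""
        self.to_dataframe().to_csv(path, index=False, na_rep="")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, normalized: bool = False) -> "FeatureTable":
        feature_names = [c for c in df.columns if c not in ("subject_id", "label")]
        values = df[feature_names].to_numpy(dtype=float)
        return cls(
            subject_ids=[str(s) for s in df["subject_id"]],
            labels=df["label"].to_numpy(dtype=int),
            values=values,
            feature_names=feature_names,
            na_mask=np.isnan(values),
            normalized=normalized,
        )

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path), normalized=normalized)
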