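"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import FeatureGeometry

GROUPS = ("NC", "pureADD", "pureSVaD", "mixed")

COHORT_COLUMNS = ("subject_id", "group", "age", "sex", "education")


@dataclass
class FeatureMatrix:
    """Subjects x features measurements for one modality.

    ``values`` is a DataFrame indexed by subject id with feature ids as
    columns; ``geometry`` (optional) attaches the spatial layout of the
    columns; ``modality`` is a free-form tag such as ``"thickness"`` or
    ``"FA"``.
    """

    values: pd.DataFrame
    modality: str = ""
    geometry: FeatureGeometry | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate subject id: {dup!r}")
        if self.geometry is not None and \
                self.geometry.n_features != self.values.shape[1]:
            raise ValidationError(
                f"geometry has {self.geometry.n_features} features but "
                f"matrix has {self.values.shape[1]} columns")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check a covariate table: required columns, unique ids, sane ranges."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject id: {dup!r}")
    unknown = set(cohort["group"]) - set(GROUPS)
    if unknown:
        raise ValidationError(f"unknown group labels: {sorted(unknown)}")
    if (cohort["age"] <= 0).any():
        raise ValidationError("ages must be positive")
    if (cohort["education"] < 0).any():
        raise ValidationError("education (years) must be non-negative")
    if not cohort["sex"].isin([0, 1]).all():
        raise ValidationError("sex must be coded 0/1")
    return cohort


def as_matrix(x) -> np.ndarray:
    """Coerce FeatureMatrix / WScoreMatrix / DataFrame / ndarray to 2D floats."""
    if isinstance(x, FeatureMatrix):
        return x.to_numpy()
    if hasattr(x, "values") and isinstance(x.values, pd.DataFrame):
        return x.values.to_numpy(dtype=float)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise ValidationError("expected a 2D subjects x features matrix")
    return a
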