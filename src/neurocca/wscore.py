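"""W-score normative mapping.

A W-score is a covariate-adjusted Z-like score: per feature (surface vertex
or skeleton voxel), an ordinary-least-squares model of the raw value on
age, sex and education is fitted on the control group only, and any
subject's measurement is then expressed as

    W = (raw value - value expected for that subject's covariates)
        / (SD of the control-group residuals)

so that controls have mean 0 and SD 1 per feature, W = +1.65 / -1.65 sit
at roughly the 95th / 5th percentiles under Gaussian noise, and the score
is dimensionless and comparable across features and modalities.  Positive
W always means a *larger* raw value (larger thickness, larger FA/DA/DR).

The residual SD uses the unbiased denominator (n - k), where k counts the
regression parameters including the intercept; with the same denominator
used when checking the control calibration, SD(W) in controls is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "education")

#: relative tolerance below which a residual SD is treated as exactly zero
_DEGENERATE_RTOL = 1e-10


@dataclass
class NormativeModel:
    """Per-feature control-group regression: coefficients and residual SD.

    ``coef`` has one column per feature and one row per design column
    (intercept first, then the covariates in ``covariate_names``).
    ``degenerate`` flags features whose control residual SD is (numerically)
    zero — a perfect fit or a constant feature; these carry no normative
    information and are excluded from downstream sparse CCA input.
    """

    feature_ids: pd.Index
    covariate_names: tuple[str, ...]
    coef: np.ndarray            # (k, p)
    residual_sd: np.ndarray     # (p,)
    n_controls: int
    degenerate: np.ndarray      # (p,) bool

    @property
    def valid_features(self) -> pd.Index:
        return self.feature_ids[~self.degenerate]

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        d = _design(covariates, self.covariate_names)
        return d @ self.coef

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a coefficient table (one row per feature)."""
        cols = {"intercept": self.coef[0]}
        for j, name in enumerate(self.covariate_names, start=1):
            cols[f"slope_{name}"] = self.coef[j]
        cols["residual_sd"] = self.residual_sd
        cols["n_controls"] = np.full(len(self.feature_ids), self.n_controls)
        return pd.DataFrame(cols, index=self.feature_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NormativeModel":
        slope_cols = [c for c in frame.columns if c.startswith("slope_")]
        names = tuple(c[len("slope_"):] for c in slope_cols)
        coef = np.vstack([frame["intercept"].to_numpy()]
                         + [frame[c].to_numpy() for c in slope_cols])
        sd = frame["residual_sd"].to_numpy(dtype=float)
        return cls(feature_ids=frame.index, covariate_names=names, coef=coef,
                   residual_sd=sd,
                   n_controls=int(frame["n_controls"].iloc[0]),
                   degenerate=sd == 0.0)


@dataclass
class WScoreMatrix:
    """Subjects x features of dimensionless W-scores.

    ``sign_convention`` records that positive values always indicate a
    larger raw measurement.
    """

    values: pd.DataFrame
    modality: str = ""
    sign_convention: str = "positive = larger raw value"

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _design(covariates: pd.DataFrame, names) -> np.ndarray:
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise ValidationError(f"covariate table missing columns: {missing}")
    d = np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[c].to_numpy(dtype=float) for c in names])
    return d


def fit_normative_model(
        controls: FeatureMatrix | pd.DataFrame,
        covariates: pd.DataFrame,
        covariate_names=DEFAULT_COVARIATES,
) -> NormativeModel:
    """Fit per-feature OLS of the control measurements on the covariates.

    Requires at least 5 controls, more controls than regression parameters,
    and a full-rank design; a constant covariate (e.g. all-male controls)
    is reported by name.  Row order of the controls is irrelevant.
    """
    values = controls.values if isinstance(controls, FeatureMatrix) else controls
    y = values.to_numpy(dtype=float)
    cov = covariates.set_index("subject_id").loc[values.index].reset_index() \
        if "subject_id" in covariates.columns and \
        not covariates.index.equals(values.index) else covariates
    if len(cov) != len(values):
        raise ValidationError("covariate rows do not match control rows")
    n, p = y.shape
    if n < 5:
        raise ValidationError(f"need at least 5 controls, got {n}")
    d = _design(cov, covariate_names)
    k = d.shape[1]
    if n <= k:
        raise ValidationError(
            f"{n} controls cannot identify {k} regression parameters")
    for j, name in enumerate(covariate_names, start=1):
        if np.ptp(d[:, j]) == 0:
            raise ValidationError(
                f"covariate {name!r} is constant in the controls; "
                "the normative design is rank deficient")
    if np.linalg.matrix_rank(d) < k:
        raise ValidationError("normative design matrix is rank deficient")

    coef, *_ = np.linalg.lstsq(d, y, rcond=None)
    resid = y - d @ coef
    sd = np.sqrt(np.sum(resid ** 2, axis=0) / (n - k))
    scale = np.maximum(np.abs(y).max(axis=0), 1.0)
    degenerate = sd <= _DEGENERATE_RTOL * scale
    sd = np.where(degenerate, 0.0, sd)
    if degenerate.any():
        log.warning("normative model: %d feature(s) with zero residual SD "
                    "flagged as degenerate", int(degenerate.sum()))
    return NormativeModel(
        feature_ids=values.columns, covariate_names=tuple(covariate_names),
        coef=coef, residual_sd=sd, n_controls=n, degenerate=degenerate)


def compute_wscores(
        model: NormativeModel,
        subjects: FeatureMatrix | pd.DataFrame,
        covariates: pd.DataFrame,
) -> WScoreMatrix:
    """Score any cohort (including the controls themselves) against a model.

    Features with zero control residual SD yield NaN (logged), never an
    infinite score.
    """
    values = subjects.values if isinstance(subjects, FeatureMatrix) else subjects
    modality = subjects.modality if isinstance(subjects, FeatureMatrix) else ""
    if not values.columns.equals(model.feature_ids):
        raise ValidationError("feature ids do not match the normative model")
    cov = covariates.set_index("subject_id").loc[values.index].reset_index() \
        if "subject_id" in covariates.columns and \
        not covariates.index.equals(values.index) else covariates
    if len(cov) != len(values):
        raise ValidationError("covariates missing for some subjects")
    pred = model.predict(cov)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (values.to_numpy(dtype=float) - pred) / model.residual_sd
    if model.degenerate.any():
        w[:, model.degenerate] = np.nan
        log.warning("W-scores: %d degenerate feature(s) set to NaN",
                    int(model.degenerate.sum()))
    return WScoreMatrix(
        pd.DataFrame(w, index=values.index, columns=values.columns),
        modality=modality)
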