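"""Readers and writers: tab-delimited matrices, tables and YAML configs.

All matrices travel as TSV with subject ids in the first column and
feature ids in the header; floats are written with shortest round-trip
repr, so a write/read cycle is lossless.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureMatrix, validate_cohort
from .errors import ValidationError
from .geometry import FeatureGeometry
from .wscore import NormativeModel, WScoreMatrix


def read_feature_matrix(path, geometry: FeatureGeometry | None = None,
                        modality: str = "") -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ValidationError(f"empty file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty file: {path}")
    except pd.errors.ParserError as e:
        raise ValidationError(f"malformed (ragged?) matrix in {path}: {e}")
    if df.shape[1] == 0:
        raise ValidationError(f"no feature columns in {path}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate subject id {dup!r} in {path}")
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValidationError(
            f"non-numeric cell in {path} at row {row!r}, column {col!r}")
    return FeatureMatrix(df.astype(float), modality=modality,
                         geometry=geometry)


def write_feature_matrix(matrix: FeatureMatrix | WScoreMatrix, path) -> None:
    _mkparent(path)
    matrix.values.to_csv(path, sep="\t", index_label="subject_id")


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    _mkparent(path)
    cohort.to_csv(path, sep="\t", index=False)


def write_normative_model(model: NormativeModel, path) -> None:
    _mkparent(path)
    model.to_frame().to_csv(path, sep="\t", index_label="feature")


def read_normative_model(path) -> NormativeModel:
    frame = pd.read_csv(path, sep="\t", index_col="feature")
    return NormativeModel.from_frame(frame)


def write_weights(result, view: str, path, header: dict | None = None) -> None:
    """Weight vector as a (feature id, weight) table, run parameters echoed
    as '#'-prefixed header lines."""
    _mkparent(path)
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        result.weights_frame(view).to_csv(fh, sep="\t", index=False)


def write_statmap(statmap, path) -> None:
    _mkparent(path)
    statmap.to_frame().to_csv(path, sep="\t", index=False)


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such config file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} is not a key-value mapping")
    return data


def dump_yaml(data: dict, path) -> None:
    _mkparent(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def export_skeleton_volume(values: np.ndarray, geometry: FeatureGeometry,
                           path) -> None:
    """Optional NIfTI export of a per-voxel map on a skeleton grid.

    Requires nibabel; the grid is written as a single-slice volume with
    unit affine — format adherence, not anatomy.
    """
    try:
        import nibabel as nib
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ValidationError("NIfTI export requires nibabel") from e
    if geometry.grid_shape is None:
        raise ValidationError("volume export needs a skeleton grid geometry")
    vol = np.asarray(values, dtype=float).reshape(*geometry.grid_shape, 1)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), os.fspath(path))


def _mkparent(path) -> None:
    parent = Path(path).parent
    if parent and not parent.exists():
        parent.mkdir(parents=True, exist_ok=True)
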