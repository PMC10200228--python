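"""NIfTI, sidecar-JSON, CSV, and YAML readers/writers.

Volumes travel as NIfTI-1 (`.nii.gz`) with the voxel size in the header
affine; segmentations carry a sidecar JSON (same stem, `.json`) mapping parcel
names to integer ids.  Volumes are assumed RAS-like with axial as the third
axis; files that fail the assumption are reoriented to closest-canonical on
load and the reorientation logged.  Cohort tables are plain CSV with the
column schema of :mod:`tauread.synthetic`.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .volumes import LabelVolume, PetVolume

logger = logging.getLogger("tauread")

MANDATORY_COHORT_COLUMNS = ("participant_id", "visual_read", "suvr", "centiloid", "ptau181", "abeta42_40_ratio")
_KNOWN_COHORT_COLUMNS = MANDATORY_COHORT_COLUMNS + ("disease_state", "baseline_dx")
_NUMERIC_COHORT_COLUMNS = ("suvr", "centiloid", "ptau181", "abeta42_40_ratio")


class SidecarError(FileNotFoundError):
    """A segmentation NIfTI has no sidecar JSON label map."""


class MalformedCellError(ValueError):
    """A numeric cohort column contains unparseable cells."""


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag([*voxel_size, 1.0])
    return aff


def write_pet(vol: PetVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol.voxel_size)), str(path))
    return path


def write_segmentation(vol: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.data.astype(np.int16), _affine(vol.voxel_size)), str(path))
    sidecar_path(path).write_text(json.dumps(vol.label_map, indent=2, sort_keys=True))
    return path


def _load_canonical(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    canonical = nib.as_closest_canonical(img)
    if canonical.affine.tolist() != img.affine.tolist():
        logger.info("reoriented %s to closest canonical (RAS) orientation", path)
    zooms = tuple(float(z) for z in canonical.header.get_zooms()[:3])
    return np.asanyarray(canonical.dataobj), zooms


def read_pet(path: str | Path) -> PetVolume:
    data, zooms = _load_canonical(Path(path))
    return PetVolume(data=np.asarray(data, dtype=np.float64), voxel_size=zooms)


def read_segmentation(path: str | Path) -> LabelVolume:
    path = Path(path)
    sidecar = sidecar_path(path)
    if not sidecar.exists():
        raise SidecarError(f"segmentation {path} has no sidecar label map {sidecar}")
    label_map = {str(k): int(v) for k, v in json.loads(sidecar.read_text()).items()}
    data, zooms = _load_canonical(path)
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise ValueError(f"segmentation {path} holds non-integer label values")
        data = rounded.astype(np.int32)
    return LabelVolume(data=data, voxel_size=zooms, label_map=label_map)


def read_volume(path: str | Path) -> PetVolume | LabelVolume:
    """Load a NIfTI volume; the presence of a sidecar label map selects
    segmentation semantics, otherwise the file is read as PET activity."""
    return read_segmentation(path) if sidecar_path(path).exists() else read_pet(path)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; typed columns, missing values preserved as NaN.

    Unknown columns produce a warning; absent mandatory columns and
    unparseable numeric cells raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} lacks mandatory columns {missing}")
    unknown = [
        c
        for c in df.columns
        if c not in _KNOWN_COHORT_COLUMNS and not c.startswith("dx_year_") and not c.endswith("_status")
    ]
    if unknown:
        warnings.warn(f"cohort table {path} has unrecognized columns {unknown}", stacklevel=2)
    for col in _NUMERIC_COHORT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & coerced.isna()].tolist()
        if bad:
            raise MalformedCellError(f"cohort table {path}, column {col!r}: malformed numeric cells in rows {bad}")
        df[col] = coerced
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) configuration mapping."""
    content = Path(path).read_text()
    config = yaml.safe_load(content)
    if config is None:
        return {}
    if not isinstance(config, dict):
        raise ValueError(f"configuration {path} must be a mapping")
    return config


def write_report(report: dict, path: str | Path | None) -> str:
    """Serialize a report deterministically (sorted keys); write when given a path."""
    text = json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
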