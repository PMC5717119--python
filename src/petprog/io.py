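"""Image and table I/O.

Volumes and masks travel as NIfTI-1 files; cohort and feature tables as
RFC-4180 CSV with a mandatory header.  Voxel coordinates are 0-based array
indices; the physical position of index (i,j,k) is ``origin + index*spacing``.
No orientation resampling is performed: grids are assumed axis-aligned, and a
mask is only usable with a volume whose grid it matches exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import (
    DimensionalityError,
    GridMismatchError,
    ValidationError,
)

#: Cohort CSV columns that must always be present, in canonical order.
COHORT_COLUMNS = ("id", "age", "stage_group", "treatment", "os_months", "event")

#: Canonical names of the 16 PET metrics, in reporting order.
FEATURE_COLUMNS = (
    "suv_max",
    "suv_mean",
    "mtv_ml",
    "tlg",
    "hist_sd",
    "hist_entropy",
    "hist_energy",
    "hist_skewness",
    "hist_kurtosis",
    "glcm_homogeneity",
    "glcm_entropy",
    "glcm_dissimilarity",
    "ngtdm_coarseness",
    "glszm_intensity_variability",
    "glszm_large_area_emphasis",
    "glszm_zone_percentage",
)


@dataclass(frozen=True)
class PETVolume:
    """A 3D grid of body-weight SUV values.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        SUV per voxel; finite and non-negative.
    spacing : tuple of 3 float
        Voxel edge length per axis, millimetres, strictly positive.
    origin : tuple of 3 float
        Physical coordinate (mm) of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or min(v.shape) < 1:
            raise DimensionalityError(
                f"volume must be 3D with non-empty axes, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("volume contains non-finite SUV values")
        n_neg = int(np.sum(v < 0))
        if n_neg:
            raise ValidationError(f"volume contains {n_neg} negative SUV values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive on all axes: {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (spacing product in mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} voxel set on the same grid as its paired :class:`PETVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise DimensionalityError(
                f"mask must be 3D with non-empty axes, got shape {v.shape}"
            )
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask voxels must be 0/1, found values {uniq[:5]}")
        object.__setattr__(self, "voxels", v.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_ml(self) -> float:
        """Foreground volume in ml: voxel count x voxel volume, exactly."""
        return self.n_foreground * self.voxel_volume_ml


def check_grid_congruence(volume: PETVolume, mask: BinaryMask) -> None:
    """Raise :class:`GridMismatchError` unless mask and volume share a grid."""
    if volume.shape != mask.shape:
        raise GridMismatchError(f"shape mismatch: {volume.shape} vs {mask.shape}")
    if not np.allclose(volume.spacing, mask.spacing):
        raise GridMismatchError(f"spacing mismatch: {volume.spacing} vs {mask.spacing}")
    if not np.allclose(volume.origin, mask.origin):
        raise GridMismatchError(f"origin mismatch: {volume.origin} vs {mask.origin}")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load_3d(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D image, got {data.ndim} dimensions"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path) -> PETVolume:
    """Read a 3D SUV volume from a NIfTI-1 file."""
    data, spacing, origin = _load_3d(path)
    return PETVolume(data.astype(float), spacing, origin)


def write_volume(volume: PETVolume, path) -> None:
    img = nib.Nifti1Image(
        volume.voxels.astype(np.float32), _affine(volume.spacing, volume.origin)
    )
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    data, spacing, origin = _load_3d(path)
    return BinaryMask(np.rint(data).astype(np.uint8), spacing, origin)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


def _validate_cohort(df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate patient ids: {dup}")

    def bad_ids(cond) -> list:
        return df.loc[cond, "id"].tolist()

    checks = [
        (~df["stage_group"].isin([1, 2, 3, 4]), "stage_group not in {1,2,3,4}"),
        (~df["treatment"].isin([1, 2]), "treatment not in {1 curative, 2 palliative}"),
        (~(df["os_months"] > 0) | ~np.isfinite(df["os_months"]), "os_months not finite positive"),
        (~df["event"].isin([0, 1]), "event not in {0,1}"),
    ]
    problems = []
    for cond, msg in checks:
        ids = bad_ids(cond)
        if ids:
            problems.append(f"{msg}: rows {ids}")
    if problems:
        raise ValidationError("; ".join(problems))


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a patient cohort CSV.

    Required columns: id, age, stage_group, treatment (1 curative / 2
    palliative), os_months, event.  Feature columns, if present, ride along
    unchanged.
    """
    df = pd.read_csv(path)
    _validate_cohort(df)
    df["stage_group"] = df["stage_group"].astype(int)
    df["treatment"] = df["treatment"].astype(int)
    df["event"] = df["event"].astype(int)
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    _validate_cohort(df)
    df.to_csv(path, index=False)


def write_feature_table(rows: pd.DataFrame, path) -> None:
    """Write a per-case feature table (id + the 16 metric columns)."""
    cols = ["id"] + [c for c in FEATURE_COLUMNS if c in rows.columns]
    extra = [c for c in rows.columns if c not in cols]
    rows[cols + extra].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
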