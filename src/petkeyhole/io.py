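"""Volume and table I/O.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based. The world coordinate (mm) of the *center* of
  voxel ``(i, j, k)`` is ``origin + index * spacing`` along each axis; the
  NIfTI affine written by :func:`write_volume` is the corresponding diagonal
  affine. All ROI placements and lesion centroids are expressed in these
  world coordinates.
* SUV values are taken as given — the input volume is assumed to already be
  normalized to standardized uptake values (dose/weight normalization happens
  upstream on the scanner console).
* Voxel volume in mL is ``prod(spacing_mm) / 1000``.
* Tables are CSV (RFC-4180, UTF-8, '.' decimal). Floats are written with
  :func:`repr`-style shortest round-trip formatting, so a write/read cycle
  preserves values exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import LesionTableError, VolumeFormatError

__all__ = [
    "PETVolume",
    "read_volume",
    "write_volume",
    "read_lesion_table",
    "write_lesion_table",
    "validate_lesion_table",
    "read_roi_json",
    "write_roi_json",
    "LESION_TABLE_COLUMNS",
]

LESION_TABLE_COLUMNS = [
    "patient_id",
    "timepoint",
    "lesion_id",
    "suvmax",
    "volume_ml",
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
]

_TIMEPOINTS = ("baseline", "followup")


@dataclass(frozen=True)
class PETVolume:
    """A single-timepoint PET volume in SUV units.

    Parameters
    ----------
    values
        3D array of SUV values (dimensionless, non-negative).
    spacing
        Voxel spacing in mm per axis, matching the array axis order.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise VolumeFormatError(
                f"PET volume must be 3D, got {values.ndim} dimensions"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise VolumeFormatError(f"spacing must be 3 positive values, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        n_negative = int(np.count_nonzero(values < 0))
        if n_negative:
            raise VolumeFormatError(
                f"SUV values must be non-negative; {n_negative} negative voxel(s) found"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacings are mm, 1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world-mm bounds of the voxel-center lattice."""
        low = np.asarray(self.origin, dtype=float)
        high = low + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return low, high

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World-mm coordinate(s) of voxel index/indices (center convention)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )


def read_volume(path: str | Path, *, on_negative: str = "reject") -> PETVolume:
    """Read a 3D NIfTI volume of SUV values.

    A trailing degenerate 4th dimension (size 1) is squeezed with a warning.
    Negative voxels are rejected by default; pass ``on_negative='clamp'`` to
    clip them to 0 instead.
    """
    if on_negative not in ("reject", "clamp"):
        raise ValueError("on_negative must be 'reject' or 'clamp'")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        warnings.warn(
            f"{path}: squeezing degenerate 4th dimension of size 1", stacklevel=2
        )
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: invalid voxel spacing {zooms}")
    n_negative = int(np.count_nonzero(data < 0))
    if n_negative:
        if on_negative == "reject":
            raise VolumeFormatError(
                f"{path}: {n_negative} negative voxel(s); SUV must be non-negative "
                "(pass on_negative='clamp' to clip)"
            )
        data = np.clip(data, 0.0, None)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return PETVolume(values=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def write_volume(volume: PETVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine carrying the spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_label_map(labels: np.ndarray, reference: PETVolume, path: str | Path) -> None:
    """Write an integer lesion label map aligned to ``reference``."""
    affine = np.diag(list(reference.spacing) + [1.0])
    affine[:3, 3] = reference.origin
    nib.save(nib.Nifti1Image(labels.astype(np.int32), affine), str(path))


def validate_lesion_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the lesion-table schema; returns the (unmodified) table."""
    missing = [c for c in LESION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise LesionTableError(f"lesion table missing columns: {missing}")
    bad_tp = set(table["timepoint"].unique()) - set(_TIMEPOINTS)
    if bad_tp:
        raise LesionTableError(
            f"timepoint must be one of {_TIMEPOINTS}, found {sorted(bad_tp)}"
        )
    key = ["patient_id", "timepoint", "lesion_id"]
    dup = table.duplicated(subset=key)
    if dup.any():
        rows = table.loc[dup, key].to_records(index=False).tolist()
        raise LesionTableError(f"duplicate (patient, timepoint, lesion_id) keys: {rows}")
    if len(table) and (table["volume_ml"] <= 0).any():
        raise LesionTableError("volume_ml must be positive for every lesion")
    return table


def write_lesion_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_lesion_table(table)
    table.to_csv(path, index=False)


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        dtype={"patient_id": str, "timepoint": str},
    )
    if len(table) == 0:
        # header-only file: enforce schema, coerce dtypes
        table = table.reindex(columns=LESION_TABLE_COLUMNS)
    return validate_lesion_table(table)


def write_roi_json(rois: dict, path: str | Path) -> None:
    """Write reference-ROI placements as JSON.

    ``rois`` maps ROI kind ('liver'/'aorta') to a dict with ``center_mm`` and
    the geometric parameters used by :class:`~petkeyhole.segmentation.ReferenceROISpec`.
    """
    Path(path).write_text(json.dumps(rois, indent=2, sort_keys=True))


def read_roi_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
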