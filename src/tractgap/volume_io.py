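"""Volumetric data model and coordinate plumbing.

Everything downstream lives on a :class:`Volume3D`: a 3D scalar grid plus a
4x4 voxel-index -> world-mm affine (RAS+ convention, as encoded in NIfTI
headers).  All distances in this package are computed in world millimetres,
never voxel units, so anisotropic grids are handled uniformly.

Conventions fixed here and relied upon everywhere else:

* voxel indices are 0-based; index ``(i, j, k)`` maps to the *center* of that
  voxel in world space;
* the "axial slice" of a point is the set of voxels sharing its third (k)
  index;
* :func:`nearest_voxel` rounds half-integer coordinates toward the lower
  index, so results are platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "WorldPoint",
    "Volume3D",
    "ContactRecord",
    "as_point",
    "voxel_to_world",
    "world_to_voxel",
    "nearest_voxel",
    "read_nifti",
    "write_nifti",
    "read_contacts_csv",
    "write_contacts_csv",
]

CONTACTS_CSV_COLUMNS = ["patient_id", "hemisphere", "contact_index", "x_mm", "y_mm", "z_mm"]

HEMISPHERES = ("left", "right")


class WorldPoint(NamedTuple):
    """A point in world space (RAS+ millimetres)."""

    x: float
    y: float
    z: float

    def to_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


PointLike = Union[WorldPoint, Sequence[float], np.ndarray]


def as_point(p: PointLike) -> np.ndarray:
    """Coerce a point-like object to a finite float array of shape (3,)."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"point has non-finite coordinates: {arr}")
    return arr


@dataclass
class Volume3D:
    """A 3D scalar image with a voxel-to-world affine.

    Parameters
    ----------
    data
        3D array of scalar intensities (e.g. streamline counts).
    affine
        4x4 matrix mapping homogeneous voxel indices to world mm (RAS+).

    Attributes
    ----------
    spacing
        Per-axis voxel size in mm, derived from the norms of the affine's
        first three columns.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must have exactly 3 axes, got {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all extents must be >= 1, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (N, 3) of the given integer or fractional indices (N, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def voxel_to_world(volume: Volume3D, index: PointLike) -> WorldPoint:
    """Map a (possibly fractional, possibly out-of-grid) voxel index to world mm."""
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise ValueError(f"index must be a 3-vector, got shape {idx.shape}")
    xyz = volume.affine[:3, :3] @ idx + volume.affine[:3, 3]
    return WorldPoint(*xyz)


def world_to_voxel(volume: Volume3D, point: PointLike) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns a continuous (unrounded) index."""
    p = as_point(point)
    inv = np.linalg.inv(volume.affine)
    return inv[:3, :3] @ p + inv[:3, 3]


def nearest_voxel(volume: Volume3D, point: PointLike) -> tuple[np.ndarray, bool]:
    """Nearest integer voxel index of a world point, plus an in-bounds flag.

    Componentwise rounding; fractions of exactly 0.5 round toward the lower
    index (``ceil(v - 0.5)``), a fixed tie-break so measurements do not depend
    on the platform's rounding mode.
    """
    cont = world_to_voxel(volume, point)
    idx = np.ceil(cont - 0.5).astype(int)
    in_bounds = bool(np.all(idx >= 0) and np.all(idx < np.array(volume.shape)))
    return idx, in_bounds


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path: Union[str, Path]) -> Volume3D:
    """Load a NIfTI-1 volume (.nii / .nii.gz) as a :class:`Volume3D`."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim} axes")
    return Volume3D(data=data, affine=np.asarray(img.affine, dtype=float))


def write_nifti(volume: Volume3D, path: Union[str, Path]) -> None:
    """Write a :class:`Volume3D` to NIfTI-1, preserving data values exactly."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Contact records


@dataclass(frozen=True)
class ContactRecord:
    """One DBS electrode pole with its exported world coordinate."""

    patient_id: str
    hemisphere: str
    contact_index: int
    position: WorldPoint

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}")
        if self.contact_index < 0:
            raise ValueError(f"contact_index must be >= 0, got {self.contact_index}")


def _check_unique(contacts: Iterable[ContactRecord]) -> None:
    seen: set[tuple[str, str, int]] = set()
    for c in contacts:
        key = (c.patient_id, c.hemisphere, c.contact_index)
        if key in seen:
            raise ValueError(f"duplicate contact {key} in cohort file")
        seen.add(key)


def read_contacts_csv(path: Union[str, Path]) -> list[ContactRecord]:
    """Read a cohort contacts CSV (``patient_id,hemisphere,contact_index,x_mm,y_mm,z_mm``)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(CONTACTS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing contact columns {sorted(missing)}")
    contacts = [
        ContactRecord(
            patient_id=str(row.patient_id),
            hemisphere=str(row.hemisphere),
            contact_index=int(row.contact_index),
            position=WorldPoint(float(row.x_mm), float(row.y_mm), float(row.z_mm)),
        )
        for row in df.itertuples()
    ]
    _check_unique(contacts)
    return contacts


def write_contacts_csv(contacts: Sequence[ContactRecord], path: Union[str, Path]) -> None:
    _check_unique(contacts)
    df = pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "hemisphere": c.hemisphere,
                "contact_index": c.contact_index,
                "x_mm": c.position.x,
                "y_mm": c.position.y,
                "z_mm": c.position.z,
            }
            for c in contacts
        ],
        columns=CONTACTS_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)
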