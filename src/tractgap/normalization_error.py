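"""Normalization-induced landmark-distance error.

Normalizing patient data into a standard space (MNI) perturbs spatial
relations.  The protocol quantified here measures one scalar per patient:
the distance from the electrode tip to the red-nucleus landmark, once in
native space and once after normalization (transformed tip vs. atlas
landmark); the error is the absolute difference of the two distances.

The normalization itself is modelled as a :class:`SpatialTransform` — a 4x4
affine plus an optional smooth sinusoidal residual field standing in for the
imperfect non-rigid part of a real registration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .volume_io import PointLike, WorldPoint, as_point

__all__ = [
    "WarpField",
    "SpatialTransform",
    "LandmarkMeasurement",
    "apply_transform",
    "landmark_error",
    "exclude_outliers",
    "write_landmark_csv",
    "read_landmark_csv",
]

NORMERROR_CSV_COLUMNS = ["patient_id", "d_native_mm", "d_norm_mm", "error_mm", "excluded"]


@dataclass(frozen=True)
class WarpField:
    """Smooth residual deformation: a sum of three sinusoidal vector fields.

    Component ``i`` of the displacement at world point ``x`` is

        w_i(x) = sum_j (A[j, i] / 3) * sin(2*pi * x_j / wavelength + phi[j, i])

    with per-axis amplitudes ``A[j, i]`` in mm and phases ``phi`` in radians.
    The 1/3 normalization bounds each component by the largest amplitude, so a
    field drawn with amplitudes in [0, a] displaces no point by more than
    ``sqrt(3) * a`` mm.
    """

    amplitudes: tuple  # 3x3 nested tuples, [field j][component i], mm
    wavelength_mm: float
    phases: tuple  # 3x3 nested tuples, radians

    def __post_init__(self) -> None:
        A = np.asarray(self.amplitudes, dtype=float)
        P = np.asarray(self.phases, dtype=float)
        if A.shape != (3, 3) or P.shape != (3, 3):
            raise ValueError("amplitudes and phases must be 3x3")
        if np.any(A < 0):
            raise ValueError("amplitudes must be >= 0")
        if self.wavelength_mm <= 0:
            raise ValueError("wavelength must be > 0")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Displacement vectors (N, 3) at world points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        A = np.asarray(self.amplitudes, dtype=float)
        P = np.asarray(self.phases, dtype=float)
        w = np.zeros_like(pts)
        for j in range(3):  # field j varies along world axis j
            phase = 2.0 * np.pi * pts[:, j : j + 1] / self.wavelength_mm + P[j]
            w += (A[j] / 3.0) * np.sin(phase)
        return w


@dataclass
class SpatialTransform:
    """Affine normalization with an optional smooth residual error field."""

    affine: np.ndarray
    warp: Optional[WarpField] = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    def apply(self, point: PointLike) -> WorldPoint:
        p = as_point(point)
        out = self.affine[:3, :3] @ p + self.affine[:3, 3]
        if self.warp is not None:
            out = out + self.warp.displacement(p[None, :])[0]
        return WorldPoint(*out)

    def apply_many(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.affine[:3, :3].T + self.affine[:3, 3]
        if self.warp is not None:
            out = out + self.warp.displacement(pts)
        return out

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"affine": self.affine.tolist(), "warp": None}
        if self.warp is not None:
            d["warp"] = {
                "amplitudes_mm": np.asarray(self.warp.amplitudes).tolist(),
                "wavelength_mm": self.warp.wavelength_mm,
                "phases_rad": np.asarray(self.warp.phases).tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpatialTransform":
        warp = None
        if d.get("warp") is not None:
            w = d["warp"]
            warp = WarpField(
                amplitudes=tuple(map(tuple, w["amplitudes_mm"])),
                wavelength_mm=float(w["wavelength_mm"]),
                phases=tuple(map(tuple, w["phases_rad"])),
            )
        return cls(affine=np.asarray(d["affine"], dtype=float), warp=warp)

    def save_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load_json(cls, path: Union[str, Path]) -> "SpatialTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def apply_transform(t: SpatialTransform, point: PointLike) -> WorldPoint:
    """Functional form of :meth:`SpatialTransform.apply`."""
    return t.apply(point)


@dataclass
class LandmarkMeasurement:
    """Tip-to-landmark distance in native vs. normalized space for one patient."""

    patient_id: str
    d_native: float
    d_norm: float
    error: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.d_native < 0 or self.d_norm < 0:
            raise ValueError("distances must be >= 0")


def landmark_error(
    tip_native: PointLike,
    rn_native: PointLike,
    t: SpatialTransform,
    rn_atlas: PointLike,
    patient_id: str = "",
) -> LandmarkMeasurement:
    """Error of a normalized tip-to-red-nucleus distance vs. native space.

    ``d_native = ||tip - rn||`` in native space; ``d_norm`` is the distance
    between the *transformed* tip and the atlas landmark; the reported error
    is ``|d_norm - d_native|`` — a difference of scalar distances, not a point
    displacement, mirroring how the two spaces are actually compared.
    """
    tip = as_point(tip_native)
    rn = as_point(rn_native)
    atlas = as_point(rn_atlas)
    d_native = float(np.linalg.norm(tip - rn))
    d_norm = float(np.linalg.norm(t.apply(tip).to_array() - atlas))
    return LandmarkMeasurement(
        patient_id=patient_id, d_native=d_native, d_norm=d_norm, error=abs(d_norm - d_native)
    )


def exclude_outliers(
    measurements: Sequence[LandmarkMeasurement], cutoff_mm: float = 5.0
) -> tuple[list[LandmarkMeasurement], list[LandmarkMeasurement]]:
    """Split measurements into (retained, excluded) at an error cutoff.

    Errors strictly above ``cutoff_mm`` are flagged as assumed coordinate
    misrepresentation after normalization and excluded from the summary; both
    output lists preserve input order.
    """
    if cutoff_mm <= 0:
        raise ValueError("cutoff_mm must be > 0")
    retained: list[LandmarkMeasurement] = []
    excluded: list[LandmarkMeasurement] = []
    for m in measurements:
        if m.error > cutoff_mm:
            excluded.append(dataclasses.replace(m, excluded=True))
        else:
            retained.append(dataclasses.replace(m, excluded=False))
    return retained, excluded


def write_landmark_csv(
    measurements: Sequence[LandmarkMeasurement], path: Union[str, Path]
) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "d_native_mm": m.d_native,
                "d_norm_mm": m.d_norm,
                "error_mm": m.error,
                "excluded": m.excluded,
            }
            for m in measurements
        ],
        columns=NORMERROR_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_landmark_csv(path: Union[str, Path]) -> list[LandmarkMeasurement]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return [
        LandmarkMeasurement(
            patient_id=str(r.patient_id),
            d_native=float(r.d_native_mm),
            d_norm=float(r.d_norm_mm),
            error=float(r.error_mm),
            excluded=bool(r.excluded),
        )
        for r in df.itertuples()
    ]
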