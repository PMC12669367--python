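"""Contact-to-tract distance measurement: 3D distance maps vs. axial manual reading.

Two measurement techniques are compared throughout the package:

* **automated** — an exact Euclidean distance transform of the binarized
  tract (in world mm, honoring anisotropic voxel spacing) sampled at the
  electrode pole coordinate's nearest voxel;
* **manual (emulated)** — the distance from the pole coordinate to the
  nearest tract voxel *restricted to the pole's axial slice*, emulating a
  human reading distances off a single transverse image.  When the tract does
  not appear on that slice the distance is not measurable, which is exactly
  the exclusion mechanism that removes measurements from the cohort
  bookkeeping.

All distances are measured to mask voxel centers, consistently across the
automated path, the manual emulation and the brute-force oracle, so the
comparisons between techniques are internally coherent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .thresholding import BinaryMask, binarize_thrp, robust_range, step_down
from .volume_io import PointLike, Volume3D, ContactRecord, as_point, nearest_voxel

__all__ = [
    "DistanceMap",
    "MeasurementRecord",
    "TractMasks",
    "compute_distance_map",
    "distance_at_point",
    "oracle_point_to_mask",
    "manual_axial_distance",
    "measure_contact",
    "records_to_frame",
    "write_measurements_csv",
    "read_measurements_frame",
]

MEASUREMENTS_CSV_COLUMNS = [
    "patient_id",
    "hemisphere",
    "tract",
    "contact_index",
    "p_initial",
    "p_final",
    "stepped_down",
    "d_auto_mm",
    "d_manual_mm",
    "manual_measurable",
]


@dataclass
class DistanceMap:
    """Per-voxel shortest distance (mm) to a binarized tract."""

    data: np.ndarray
    affine: np.ndarray
    source_id: str = ""

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def _mask_volume_view(mask: BinaryMask) -> Volume3D:
    return Volume3D(data=mask.data.astype(float), affine=mask.affine)


def compute_distance_map(mask: BinaryMask) -> DistanceMap:
    """Exact Euclidean distance transform of a tract mask, in world mm.

    Every mask voxel maps to 0; every other voxel to the distance from its
    center to the nearest mask-voxel center, with anisotropic voxel spacing
    taken as the per-axis sampling.  Raises on an empty mask — an empty
    binarization has no distances and must be handled by the caller (the
    flagged-empty path of the thresholding stage).
    """
    if mask.is_empty:
        raise ValueError("cannot compute a distance map from an empty mask")
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)
    return DistanceMap(data=np.asarray(dist, dtype=float), affine=mask.affine, source_id=mask.source_id)


def distance_at_point(
    dmap: DistanceMap, point: PointLike, interpolate: bool = False
) -> float:
    """Sample a distance map at a world coordinate.

    Nearest-neighbor by default — the exported pole coordinate is assigned to
    its voxel and that voxel's stored distance is read off, mirroring a
    per-coordinate export from a distance image.  ``interpolate=True``
    switches to trilinear sampling for sensitivity analysis.
    """
    vol = Volume3D(data=dmap.data, affine=dmap.affine)
    if interpolate:
        from .volume_io import world_to_voxel

        cont = world_to_voxel(vol, point)
        if np.any(cont < 0) or np.any(cont > np.array(vol.shape) - 1):
            raise ValueError(f"point {tuple(as_point(point))} outside distance map grid")
        return float(ndimage.map_coordinates(dmap.data, cont.reshape(3, 1), order=1)[0])
    idx, ok = nearest_voxel(vol, point)
    if not ok:
        raise ValueError(f"point {tuple(as_point(point))} outside distance map grid")
    return float(dmap.data[tuple(idx)])


def oracle_point_to_mask(mask: BinaryMask, point: PointLike) -> float:
    """Brute-force shortest distance from a world point to any mask voxel center.

    Independent of the distance-transform path (no precomputation): the
    minimum over all mask voxels of the Euclidean world distance.  Used as the
    verification oracle for the automated measurements.
    """
    if mask.is_empty:
        raise ValueError("mask is empty")
    p = as_point(point)
    coords = mask.voxel_coords_mm()
    return float(np.min(np.linalg.norm(coords - p, axis=1)))


def manual_axial_distance(
    mask: BinaryMask,
    point: PointLike,
    jitter_mm: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    in_plane: bool = False,
) -> Optional[float]:
    """Emulated manual measurement on the contact's axial slice.

    The mask is restricted to the axial slice containing the point's nearest
    voxel (the transverse image a human would measure on).  If no tract voxel
    lies in that slice the measurement is *not possible* and ``None`` is
    returned.  Otherwise the Euclidean distance from the pole coordinate to
    the nearest in-slice mask voxel center is returned, optionally perturbed
    by zero-mean uniform jitter of half-width ``jitter_mm`` (a crude reading
    -error emulation; default off) and floored at 0.

    ``in_plane=True`` instead projects the pole onto the slice plane and
    measures purely 2D, i.e. ignores the pole's offset from the slice center;
    the default keeps the pole's true 3D coordinate, so a manual measurement
    can never undercut the true 3D shortest distance.
    """
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be >= 0")
    p = as_point(point)
    vol = _mask_volume_view(mask)
    idx, ok = nearest_voxel(vol, p)
    if not ok:
        raise ValueError(f"point {tuple(p)} outside mask grid")
    k = int(idx[2])
    slice_idx = np.argwhere(mask.data[:, :, k])
    if slice_idx.size == 0:
        return None  # tract not evident on this axial slice
    ij = np.column_stack([slice_idx, np.full(len(slice_idx), k)])
    coords = ij.astype(float) @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    if in_plane:
        d = float(np.min(np.linalg.norm(coords[:, :2] - p[:2], axis=1)))
    else:
        d = float(np.min(np.linalg.norm(coords - p, axis=1)))
    if jitter_mm > 0:
        if rng is None:
            rng = np.random.default_rng()
        d += float(rng.uniform(-jitter_mm, jitter_mm))
    return max(d, 0.0)


class TractMasks:
    """Cached binarizations and distance maps of one probability volume.

    The robust range is computed once; masks and distance maps per candidate
    percentage are built lazily and memoized, since the measurement stage and
    the threshold-sensitivity sweep revisit the same thresholds.
    """

    def __init__(
        self,
        volume: Volume3D,
        candidates: Sequence[float],
        source_id: str = "",
        nonzero_only: bool = False,
    ) -> None:
        self.volume = volume
        self.candidates = sorted(float(p) for p in candidates)
        self.source_id = source_id
        self.robust_range = robust_range(volume, nonzero_only=nonzero_only)
        self._masks: dict[float, BinaryMask] = {}
        self._dmaps: dict[float, Optional[DistanceMap]] = {}

    def mask(self, percent: float) -> BinaryMask:
        p = float(percent)
        if p not in self._masks:
            self._masks[p] = binarize_thrp(
                self.volume, p, rr=self.robust_range, source_id=self.source_id
            )
        return self._masks[p]

    def dmap(self, percent: float) -> Optional[DistanceMap]:
        """Distance map at a threshold, or None when the mask is empty."""
        p = float(percent)
        if p not in self._dmaps:
            m = self.mask(p)
            self._dmaps[p] = None if m.is_empty else compute_distance_map(m)
        return self._dmaps[p]

    def auto_distance(self, percent: float, point: PointLike) -> Optional[float]:
        dm = self.dmap(percent)
        return None if dm is None else distance_at_point(dm, point)


@dataclass
class MeasurementRecord:
    """One contact x tract distance measurement with threshold provenance."""

    patient_id: str
    hemisphere: str
    tract: str
    contact_index: int
    p_initial: float
    p_final: float
    stepped_down: bool
    d_auto: float  # mm; NaN when the mask at p_final was empty
    d_manual: Optional[float]  # mm; None when the tract was absent on the axial slice

    def __post_init__(self) -> None:
        if self.stepped_down and not self.p_final < self.p_initial:
            raise ValueError("stepped_down requires p_final < p_initial")
        if self.d_manual is not None and self.d_manual < 0:
            raise ValueError("manual distance must be >= 0")

    @property
    def manual_measurable(self) -> bool:
        return self.d_manual is not None

    @property
    def auto_measurable(self) -> bool:
        return math.isfinite(self.d_auto)


def measure_contact(
    tract_masks: Mapping[str, TractMasks],
    contact: ContactRecord,
    p_selected: float,
    candidates: Sequence[float],
    cutoff_mm: float = 10.0,
    jitter_mm: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[MeasurementRecord]:
    """Measure one contact against each tract, applying the step-down rule.

    The automated distance is read from the distance map at the selected
    threshold.  If it strictly exceeds ``cutoff_mm`` (or the mask at the
    selected threshold is empty) and a lower candidate exists, that tract is
    re-binarized exactly one step lower and re-measured once — the relaxation
    applied when a tract at the working threshold gives an implausibly distant
    (or vanished) representation.  The step is per tract; the other tract's
    threshold is untouched.  The manual emulation is then read on the mask at
    the final threshold.
    """
    records: list[MeasurementRecord] = []
    for tract, tm in tract_masks.items():
        p_final = float(p_selected)
        stepped = False
        d_auto = tm.auto_distance(p_final, contact.position)
        needs_step = d_auto is None or d_auto > cutoff_mm
        if needs_step:
            lower = step_down(p_final, candidates)
            if lower is not None:
                p_final = lower
                stepped = True
                d_auto = tm.auto_distance(p_final, contact.position)
        mask_final = tm.mask(p_final)
        if d_auto is None:
            d_manual = None
        else:
            d_manual = manual_axial_distance(
                mask_final, contact.position, jitter_mm=jitter_mm, rng=rng
            )
        records.append(
            MeasurementRecord(
                patient_id=contact.patient_id,
                hemisphere=contact.hemisphere,
                tract=tract,
                contact_index=contact.contact_index,
                p_initial=float(p_selected),
                p_final=p_final,
                stepped_down=stepped,
                d_auto=float("nan") if d_auto is None else d_auto,
                d_manual=d_manual,
            )
        )
    return records


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "hemisphere": r.hemisphere,
            "tract": r.tract,
            "contact_index": r.contact_index,
            "p_initial": r.p_initial,
            "p_final": r.p_final,
            "stepped_down": r.stepped_down,
            "d_auto_mm": r.d_auto,
            "d_manual_mm": float("nan") if r.d_manual is None else r.d_manual,
            "manual_measurable": r.manual_measurable,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MEASUREMENTS_CSV_COLUMNS)


def write_measurements_csv(records: Sequence[MeasurementRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_measurements_frame(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(MEASUREMENTS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing measurement columns {sorted(missing)}")
    return df
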