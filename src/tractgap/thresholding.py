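"""Robust-range thresholding of tract probability maps.

Streamline-count images from probabilistic tractography are heavy-tailed:
most voxels are zero, a thin core carries counts up to the number of seeded
samples.  Binarization cutoffs are therefore expressed as a *percentage of
the robust range* — the intensity span between the 2nd and 98th percentile of
the histogram, which ignores the extreme tail.  Because the robust range sits
far below the global maximum, meaningful percentages are far above 100%
(400–1000% by default).

The module also provides an explicit, reproducible stand-in for visual
threshold selection (minimum Dice overlap between the crossing and
non-decussating tract masks, whole-brain, both hemispheres) and the one-step
threshold relaxation rule applied when a measured distance is implausibly
large.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .volume_io import Volume3D

__all__ = [
    "RobustRange",
    "BinaryMask",
    "robust_range",
    "threshold_value",
    "binarize_thrp",
    "dice",
    "ThresholdSelection",
    "select_discrimination_threshold",
    "step_down",
]


@dataclass(frozen=True)
class RobustRange:
    """Intensity range between the 2nd and 98th percentile of an image."""

    rmin: float
    rmax: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rmin) and np.isfinite(self.rmax)):
            raise ValueError("robust range must be finite")
        if self.rmin > self.rmax:
            raise ValueError(f"rmin {self.rmin} > rmax {self.rmax}")


@dataclass
class BinaryMask:
    """A binarized tract with its provenance.

    ``threshold_value`` records the absolute intensity cutoff
    ``rmin + (percent/100) * (rmax - rmin)`` that produced the mask, so a mask
    can always be traced back to its source volume and threshold percentage.
    """

    data: np.ndarray
    affine: np.ndarray
    source_id: str = ""
    percent: float = float("nan")
    threshold_value: float = float("nan")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def voxel_coords_mm(self) -> np.ndarray:
        """World coordinates (N, 3) of the centers of all mask voxels."""
        idx = np.argwhere(self.data).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def robust_range(volume: Volume3D, nonzero_only: bool = False) -> RobustRange:
    """2nd/98th percentile intensity range of a volume.

    Percentiles use linear interpolation between order statistics and are
    taken over *all* voxels, zeros included.  ``nonzero_only=True`` restricts
    the histogram to nonzero voxels, a variant some binarization tools apply;
    the default follows the plain histogram definition.
    """
    values = np.asarray(volume.data, dtype=float).ravel()
    if nonzero_only:
        values = values[values != 0]
        if values.size == 0:
            raise ValueError("volume has no nonzero voxels")
    if np.all(np.isnan(values)):
        raise ValueError("volume is all-NaN")
    lo, hi = np.nanpercentile(values, [2.0, 98.0])
    return RobustRange(rmin=float(lo), rmax=float(hi))


def threshold_value(rr: RobustRange, percent: float) -> float:
    """Absolute intensity cutoff at ``percent`` % of the robust range."""
    if percent <= 0:
        raise ValueError(f"threshold percent must be > 0, got {percent}")
    return rr.rmin + (percent / 100.0) * (rr.rmax - rr.rmin)


def binarize_thrp(
    volume: Volume3D,
    percent: float,
    rr: Optional[RobustRange] = None,
    source_id: str = "",
    nonzero_only: bool = False,
) -> BinaryMask:
    """Binarize a probability map at ``percent`` % of its robust range.

    Voxels with value >= the cutoff are kept (the comparison is inclusive, so
    a degenerate constant volume yields a full mask at any percentage).
    Empty masks are legal; callers check :attr:`BinaryMask.is_empty`.
    """
    if rr is None:
        rr = robust_range(volume, nonzero_only=nonzero_only)
    thr = threshold_value(rr, percent)
    return BinaryMask(
        data=np.asarray(volume.data) >= thr,
        affine=volume.affine,
        source_id=source_id,
        percent=float(percent),
        threshold_value=thr,
    )


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0.0 when both masks are empty."""
    if a.data.shape != b.data.shape:
        raise ValueError("masks have different shapes")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 0.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


@dataclass
class ThresholdSelection:
    """Outcome of whole-brain discrimination-threshold selection."""

    percent: float
    feasible: bool
    mean_dice: dict = field(default_factory=dict)  # candidate -> mean c/nd Dice
    nonempty: dict = field(default_factory=dict)  # candidate -> all four masks non-empty


def select_discrimination_threshold(
    c_left: Volume3D,
    c_right: Volume3D,
    nd_left: Volume3D,
    nd_right: Volume3D,
    candidates: Sequence[float],
    nonzero_only: bool = False,
) -> ThresholdSelection:
    """Pick the one threshold (whole brain, both hemispheres) that best
    separates the crossing from the non-decussating tract.

    For each candidate percentage all four masks (c/nd x left/right) are
    built; candidates for which any mask is empty are infeasible.  Among
    feasible candidates the one minimizing the mean of the two per-hemisphere
    Dice overlaps between c- and nd-masks is selected (smaller overlap =
    better discrimination); ties resolve to the lowest percentage.  If no
    candidate is feasible the lowest percentage is returned with
    ``feasible=False``.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    cands = sorted(float(p) for p in candidates)
    vols = {"c_left": c_left, "c_right": c_right, "nd_left": nd_left, "nd_right": nd_right}
    ranges = {k: robust_range(v, nonzero_only=nonzero_only) for k, v in vols.items()}

    sel = ThresholdSelection(percent=cands[0], feasible=False)
    best: Optional[float] = None
    for p in cands:
        masks = {k: binarize_thrp(v, p, rr=ranges[k], source_id=k) for k, v in vols.items()}
        ok = all(not m.is_empty for m in masks.values())
        sel.nonempty[p] = ok
        d = 0.5 * (
            dice(masks["c_left"], masks["nd_left"]) + dice(masks["c_right"], masks["nd_right"])
        )
        sel.mean_dice[p] = d
        if ok and (best is None or d < best):  # strict < : ties keep the lowest p
            best = d
            sel.percent = p
            sel.feasible = True
    return sel


def step_down(p: float, candidates: Sequence[float]) -> Optional[float]:
    """The next lower candidate threshold, or None if ``p`` is already lowest."""
    cands = sorted(float(c) for c in candidates)
    p = float(p)
    if p not in cands:
        raise ValueError(f"threshold {p} not among candidates {cands}")
    i = cands.index(p)
    return cands[i - 1] if i > 0 else None


def threshold_sidecar(rr: RobustRange, percent: float, mask: BinaryMask) -> dict:
    """JSON-serializable provenance for one binarization (CLI sidecar)."""
    return {
        "percent": float(percent),
        "rmin": rr.rmin,
        "rmax": rr.rmax,
        "threshold_value": mask.threshold_value,
        "non_empty": not mask.is_empty,
        "n_voxels": mask.n_voxels,
    }
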