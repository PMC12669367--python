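"""Phantom cohorts for exercising the error-assessment pipeline.

No patient data ships with the package; instead every downstream stage is
validated on synthetic cohorts that reproduce the *statistical structure* the
analysis assumes:

* tube-like tract "probability maps" with heavy-tailed streamline-count
  histograms (almost all voxels zero, a thin high-count core, a sprinkle of
  low-count background noise so the robust range is non-degenerate);
* two tracts per hemisphere — a crossing and a non-decussating bundle —
  whose centerlines converge toward the thalamic end, so the choice of
  binarization threshold genuinely changes how separable they are;
* bilateral multi-contact electrode trajectories placed near the crossing
  tract;
* a red-nucleus-like landmark between the two bundles;
* per-patient normalization transforms (small rigid + scale affine plus a
  smooth sinusoidal residual), with an optional fraction of grossly
  misnormalized patients.

All generators are pure functions of (parameters, seed): the same inputs
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import RunConfig
from .normalization_error import SpatialTransform, WarpField
from .volume_io import (
    ContactRecord,
    Volume3D,
    WorldPoint,
    as_point,
    write_contacts_csv,
    write_nifti,
    read_nifti,
    read_contacts_csv,
)

__all__ = [
    "TractSpec",
    "LeadSpec",
    "PhantomPatient",
    "PhantomCohort",
    "TRACT_LABELS",
    "make_grid",
    "generate_tract_probability_map",
    "generate_lead_contacts",
    "generate_normalization_transform",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

TRACT_LABELS = ("c-DRTT", "nd-DRTT")

LANDMARKS_CSV_COLUMNS = [
    "patient_id",
    "hemisphere",
    "structure",
    "space",
    "x_mm",
    "y_mm",
    "z_mm",
]


@dataclass
class TractSpec:
    """Geometry and intensity model of one synthetic tract.

    The intensity at a voxel center at shortest world distance ``r`` from the
    piecewise-linear centerline is ``round(n_samples * exp(-r^2 / (2 sigma^2)))``
    (values below 1 set to 0), emulating the monotone transverse decay of a
    streamline-count image with peak ``n_samples`` (default 5000 samples per
    seed voxel, the conventional probabilistic-tracking setting).
    """

    label: str
    hemisphere: str
    centerline: Sequence  # ordered control points, world mm
    sigma_mm: float = 3.0
    n_samples: int = 5000
    noise_fraction: float = 0.05

    def __post_init__(self) -> None:
        pts = np.asarray([as_point(p) for p in self.centerline], dtype=float)
        if pts.shape[0] < 2:
            raise ValueError("centerline needs >= 2 control points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive centerline control points must be distinct")
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be > 0")
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must be in [0, 1)")
        self.centerline = pts


@dataclass
class LeadSpec:
    """One electrode trajectory: deepest contact (tip) plus a direction."""

    tip: WorldPoint
    direction: Sequence
    n_contacts: int = 4
    contact_spacing_mm: float = 2.0

    def __post_init__(self) -> None:
        d = as_point(self.direction)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must have unit norm (within 1e-9)")
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        if self.contact_spacing_mm <= 0:
            raise ValueError("contact_spacing_mm must be > 0")
        self.direction = d


@dataclass
class PhantomPatient:
    patient_id: str
    volumes: dict  # (hemisphere, label) -> Volume3D
    contacts: list  # ContactRecord, both hemispheres
    rn_native: dict  # hemisphere -> WorldPoint
    rn_atlas: dict  # hemisphere -> WorldPoint
    transform: SpatialTransform


@dataclass
class PhantomCohort:
    patients: list
    grid_affine: np.ndarray
    grid_shape: tuple
    config: Optional[RunConfig] = None

    def contacts(self) -> list:
        return [c for p in self.patients for c in p.contacts]


def make_grid(
    shape: Sequence[int] = (96, 96, 96), spacing: Sequence[float] = (2.0, 2.0, 2.0)
) -> Volume3D:
    """An empty, world-centered RAS+ grid (origin at the volume center)."""
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(np.asarray(shape) - 1) * spacing / 2.0
    return Volume3D(data=np.zeros(shape, dtype=float), affine=affine)


def _polyline_min_distance(points: np.ndarray, centerline: np.ndarray) -> np.ndarray:
    """Shortest world distance from each point (N,3) to a piecewise-linear path."""
    d2 = np.full(points.shape[0], np.inf)
    for a, b in zip(centerline[:-1], centerline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.minimum(d2, np.einsum("ij,ij->i", points - proj, points - proj))
    return np.sqrt(d2)


def _as_rng(seed: Union[int, np.random.Generator, Sequence[int]]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_tract_probability_map(
    spec: TractSpec, grid: Volume3D, seed: Union[int, np.random.Generator]
) -> Volume3D:
    """Synthesize a streamline-count image around a centerline.

    See :class:`TractSpec` for the intensity model.  After the deterministic
    tube is laid down, ``noise_fraction`` of the remaining zero voxels receive
    spurious counts drawn uniformly from ``{1, ..., max(1, n_samples // 100)}``,
    yielding the heavy-tailed histogram (mostly zeros, rare high counts) that
    makes robust-range thresholds at several-hundred percent meaningful.
    """
    rng = _as_rng(seed)
    cl = np.asarray(spec.centerline, dtype=float)

    # the centerline must intersect the grid somewhere
    seg_len = np.linalg.norm(np.diff(cl, axis=0), axis=1).sum()
    n_probe = max(int(seg_len), len(cl)) * 2
    ts = np.linspace(0, 1, n_probe)
    probe = np.concatenate(
        [a + ts[:, None] * (b - a) for a, b in zip(cl[:-1], cl[1:])], axis=0
    )
    inv = np.linalg.inv(grid.affine)
    vox = probe @ inv[:3, :3].T + inv[:3, 3]
    inside = np.all((vox > -0.5) & (vox < np.asarray(grid.shape) - 0.5), axis=1)
    if not inside.any():
        raise ValueError("centerline lies entirely outside the grid")

    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    centers = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    r = _polyline_min_distance(centers, cl)
    vals = np.rint(spec.n_samples * np.exp(-(r**2) / (2.0 * spec.sigma_mm**2)))
    vals[vals < 1] = 0.0

    if spec.noise_fraction > 0:
        zeros = np.flatnonzero(vals == 0)
        n_noise = int(round(spec.noise_fraction * zeros.size))
        if n_noise > 0:
            chosen = rng.choice(zeros.size, size=n_noise, replace=False)
            hi = max(1, spec.n_samples // 100)
            vals[zeros[chosen]] = rng.integers(1, hi + 1, size=n_noise)

    return Volume3D(data=vals.reshape(grid.shape), affine=grid.affine.copy())


def generate_lead_contacts(spec: LeadSpec) -> list:
    """Contact positions along a lead; index 0 is the deepest contact (tip)."""
    tip = as_point(spec.tip)
    d = as_point(spec.direction)
    return [
        WorldPoint(*(tip + c * spec.contact_spacing_mm * d)) for c in range(spec.n_contacts)
    ]


def generate_normalization_transform(
    seed: Union[int, np.random.Generator],
    affine_part: Optional[np.ndarray] = None,
    warp_amplitude_mm: float = 0.0,
    warp_wavelength_mm: float = 50.0,
) -> SpatialTransform:
    """An affine normalization plus a seeded smooth residual error field.

    The residual is a sum of three sinusoidal vector fields with per-axis
    amplitudes drawn uniformly in ``[0, warp_amplitude_mm]`` and common
    spatial wavelength; amplitude 0 gives a pure affine.
    """
    if warp_amplitude_mm < 0:
        raise ValueError("warp_amplitude_mm must be >= 0")
    rng = _as_rng(seed)
    affine = np.eye(4) if affine_part is None else np.asarray(affine_part, dtype=float)
    warp = None
    if warp_amplitude_mm > 0:
        amplitudes = rng.uniform(0.0, warp_amplitude_mm, size=(3, 3))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(3, 3))
        warp = WarpField(
            amplitudes=tuple(map(tuple, amplitudes)),
            wavelength_mm=float(warp_wavelength_mm),
            phases=tuple(map(tuple, phases)),
        )
    return SpatialTransform(affine=affine, warp=warp)


# ---------------------------------------------------------------------------
# Cohort assembly


def _hemisphere_centerlines(sign: float, rng: np.random.Generator) -> dict:
    """Converging c/nd centerlines for one hemisphere, with per-patient jitter.

    Both bundles ascend from the cerebellar to the thalamic end; their lateral
    separation shrinks from ~12 mm inferiorly to ~3 mm superiorly, so low
    thresholds (wide masks) merge them while high thresholds keep them apart.
    """
    c_base = np.array(
        [[14.0, -28.0, -34.0], [10.0, -18.0, -12.0], [8.0, -12.0, 2.0], [7.0, -8.0, 14.0]]
    )
    nd_base = np.array(
        [[26.0, -30.0, -34.0], [20.0, -18.0, -12.0], [13.0, -12.0, 2.0], [10.0, -8.0, 14.0]]
    )
    out = {}
    for label, base in (("c-DRTT", c_base), ("nd-DRTT", nd_base)):
        shift = rng.uniform(-1.5, 1.5, size=3)  # rigid per-tract jitter keeps convergence
        cl = base.copy()
        cl[:, 0] *= sign
        cl += shift
        out[label] = cl
    return out


def _random_rigid_scale_affine(rng: np.random.Generator) -> np.ndarray:
    """Small rotation + isotropic scale + translation, emulating an affine
    normalization into a template space."""
    ax, ay, az = np.deg2rad(rng.uniform(-3.0, 3.0, size=3))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    s = rng.uniform(0.96, 1.04)
    A = np.eye(4)
    A[:3, :3] = s * (Rz @ Ry @ Rx)
    A[:3, 3] = rng.uniform(-5.0, 5.0, size=3)
    return A


def generate_cohort(config: RunConfig, seed: Optional[int] = None) -> PhantomCohort:
    """Build a full phantom cohort, deterministically from (config, seed).

    Each patient consumes an independent RNG stream derived from the master
    seed and the patient index, so enlarging the cohort never perturbs
    existing patients.  For the last ``n_misnormalized`` patients the stored
    (applied) transform is the true one corrupted by a gross translation —
    the atlas landmark was placed with the *true* transform, so their
    normalized coordinates are misrepresented, emulating a failed
    normalization.
    """
    master = int(config.seed if seed is None else seed)
    grid = make_grid(config.grid_shape, config.grid_spacing_mm)
    patients: list[PhantomPatient] = []
    for pidx in range(config.n_patients):
        rng = np.random.default_rng([master, pidx])
        pid = f"p{pidx:03d}"
        volumes: dict = {}
        contacts: list[ContactRecord] = []
        rn_native: dict = {}
        rn_atlas: dict = {}

        misnorm = pidx >= config.n_patients - config.n_misnormalized
        true_transform = generate_normalization_transform(
            rng,
            affine_part=_random_rigid_scale_affine(rng),
            warp_amplitude_mm=config.warp_amplitude_mm,
            warp_wavelength_mm=config.warp_wavelength_mm,
        )
        transform = true_transform
        if misnorm:
            shift_dir = rng.normal(size=3)
            shift_dir /= np.linalg.norm(shift_dir)
            shift = rng.uniform(
                config.misnormalized_shift_min_mm, config.misnormalized_shift_max_mm
            )
            bad_affine = true_transform.affine.copy()
            bad_affine[:3, 3] += shift * shift_dir
            transform = SpatialTransform(affine=bad_affine, warp=true_transform.warp)

        for hemi, sign in (("left", -1.0), ("right", 1.0)):
            lines = _hemisphere_centerlines(sign, rng)
            for label, cl in lines.items():
                spec = TractSpec(
                    label=label,
                    hemisphere=hemi,
                    centerline=cl,
                    sigma_mm=config.tract_sigma_mm,
                    n_samples=config.n_samples,
                    noise_fraction=config.noise_fraction,
                )
                volumes[(hemi, label)] = generate_tract_probability_map(spec, grid, rng)

            # lead: aimed at the crossing tract's thalamic segment, jittered
            # 0-8 mm laterally off the centerline
            target = lines["c-DRTT"][2].copy()
            theta = rng.uniform(0.0, 2.0 * np.pi)
            radius = rng.uniform(0.0, 8.0)
            target[0] += radius * np.cos(theta)
            target[1] += radius * np.sin(theta)
            direction = np.array(
                [0.15 * sign + rng.uniform(-0.1, 0.1), 0.1 + rng.uniform(-0.1, 0.1), 1.0]
            )
            direction /= np.linalg.norm(direction)
            tip = target - 4.0 * direction
            lead = LeadSpec(
                tip=WorldPoint(*tip),
                direction=direction,
                n_contacts=config.n_contacts,
                contact_spacing_mm=config.contact_spacing_mm,
            )
            for ci, pos in enumerate(generate_lead_contacts(lead)):
                contacts.append(
                    ContactRecord(
                        patient_id=pid, hemisphere=hemi, contact_index=ci, position=pos
                    )
                )

            # red-nucleus-like landmark between the two bundles
            rn = 0.5 * (lines["c-DRTT"][2] + lines["nd-DRTT"][2]) + rng.uniform(
                -1.0, 1.0, size=3
            )
            rn_native[hemi] = WorldPoint(*rn)
            atlas = true_transform.apply(rn).to_array()
            if config.atlas_rn_offset_mm > 0:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                atlas = atlas + config.atlas_rn_offset_mm * u
            rn_atlas[hemi] = WorldPoint(*atlas)

        patients.append(
            PhantomPatient(
                patient_id=pid,
                volumes=volumes,
                contacts=contacts,
                rn_native=rn_native,
                rn_atlas=rn_atlas,
                transform=transform,
            )
        )
    return PhantomCohort(
        patients=patients, grid_affine=grid.affine, grid_shape=grid.shape, config=config
    )


# ---------------------------------------------------------------------------
# Cohort directory I/O


def write_cohort(cohort: PhantomCohort, out_dir: Union[str, Path]) -> None:
    """Write a cohort as NIfTI volumes + contacts/landmarks CSVs + transform JSONs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landmark_rows = []
    for p in cohort.patients:
        for (hemi, label), vol in sorted(p.volumes.items()):
            write_nifti(vol, out / f"{p.patient_id}_{hemi}_{label}.nii.gz")
        p.transform.save_json(out / f"transform_{p.patient_id}.json")
        for hemi in ("left", "right"):
            for space, point in (("native", p.rn_native[hemi]), ("atlas", p.rn_atlas[hemi])):
                landmark_rows.append(
                    {
                        "patient_id": p.patient_id,
                        "hemisphere": hemi,
                        "structure": "RN",
                        "space": space,
                        "x_mm": point.x,
                        "y_mm": point.y,
                        "z_mm": point.z,
                    }
                )
    write_contacts_csv(cohort.contacts(), out / "contacts.csv")
    pd.DataFrame(landmark_rows, columns=LANDMARKS_CSV_COLUMNS).to_csv(
        out / "landmarks.csv", index=False
    )


def load_cohort(cohort_dir: Union[str, Path]) -> PhantomCohort:
    """Read back a cohort directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    contacts = read_contacts_csv(d / "contacts.csv")
    lm = pd.read_csv(d / "landmarks.csv", dtype={"patient_id": str})
    pids = sorted({c.patient_id for c in contacts})
    patients = []
    grid_affine = None
    grid_shape = None
    for pid in pids:
        volumes = {}
        for hemi in ("left", "right"):
            for label in TRACT_LABELS:
                vol = read_nifti(d / f"{pid}_{hemi}_{label}.nii.gz")
                volumes[(hemi, label)] = vol
                grid_affine, grid_shape = vol.affine, vol.shape
        transform = SpatialTransform.load_json(d / f"transform_{pid}.json")
        rn_native = {}
        rn_atlas = {}
        sub = lm[lm.patient_id == pid]
        for hemi in ("left", "right"):
            for space, store in (("native", rn_native), ("atlas", rn_atlas)):
                row = sub[(sub.hemisphere == hemi) & (sub.space == space)]
                if len(row) != 1:
                    raise ValueError(
                        f"{cohort_dir}: expected one {space} RN landmark for {pid}/{hemi}"
                    )
                store[hemi] = WorldPoint(
                    float(row.x_mm.iloc[0]), float(row.y_mm.iloc[0]), float(row.z_mm.iloc[0])
                )
        patients.append(
            PhantomPatient(
                patient_id=pid,
                volumes=volumes,
                contacts=[c for c in contacts if c.patient_id == pid],
                rn_native=rn_native,
                rn_atlas=rn_atlas,
                transform=transform,
            )
        )
    return PhantomCohort(patients=patients, grid_affine=grid_affine, grid_shape=grid_shape)
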