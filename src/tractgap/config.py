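"""Run configuration: every tunable of the phantom pipeline in one validated record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run configuration is invalid; message lists offending keys."""


@dataclass
class RunConfig:
    """Parameters of a full phantom run.

    Cohort / grid
        ``n_patients`` phantom patients on a ``grid_shape`` grid with
        ``grid_spacing_mm`` voxels (isotropic 2 mm by default, the resolution
        diffusion acquisitions for this application typically use).
    Tracts
        Gaussian transverse profile of width ``tract_sigma_mm`` around a
        piecewise-linear centerline, peak streamline count ``n_samples``
        (5000, the conventional per-voxel sample count of probabilistic
        tracking), and ``noise_fraction`` of background voxels carrying small
        spurious counts so the robust range is non-degenerate.
    Thresholding / measurement
        ``candidate_percents`` of the robust range; distances above
        ``step_down_cutoff_mm`` trigger a one-step threshold relaxation;
        ``jitter_mm`` adds uniform reading error to the manual emulation.
    Normalization
        Per-patient affine (small rigid + scale) plus a sinusoidal residual of
        amplitude ``warp_amplitude_mm`` / wavelength ``warp_wavelength_mm``;
        ``n_misnormalized`` patients have their applied transform corrupted
        by a gross translation (magnitude uniform in
        ``[misnormalized_shift_min_mm, misnormalized_shift_max_mm]``),
        emulating coordinate misrepresentation after a failed normalization;
        measurements with error above ``outlier_cutoff_mm`` are excluded from
        the summary.
    """

    n_patients: int = 10
    grid_shape: tuple = (96, 96, 96)
    grid_spacing_mm: tuple = (2.0, 2.0, 2.0)
    n_contacts: int = 4
    contact_spacing_mm: float = 2.0
    tract_sigma_mm: float = 3.0
    n_samples: int = 5000
    noise_fraction: float = 0.05
    candidate_percents: tuple = (400.0, 600.0, 800.0, 1000.0)
    step_down_cutoff_mm: float = 10.0
    jitter_mm: float = 0.0
    warp_amplitude_mm: float = 1.0
    warp_wavelength_mm: float = 50.0
    n_misnormalized: int = 1
    misnormalized_shift_min_mm: float = 8.0
    misnormalized_shift_max_mm: float = 25.0
    atlas_rn_offset_mm: float = 0.0
    outlier_cutoff_mm: float = 5.0
    robust_range_nonzero_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.grid_spacing_mm = tuple(float(v) for v in self.grid_spacing_mm)
        self.candidate_percents = tuple(float(v) for v in self.candidate_percents)
        self.validate()

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_patients < 1:
            bad.append(f"n_patients must be >= 1 (got {self.n_patients})")
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            bad.append(f"grid_shape must be 3 extents >= 8 (got {self.grid_shape})")
        if len(self.grid_spacing_mm) != 3 or any(s <= 0 for s in self.grid_spacing_mm):
            bad.append(f"grid_spacing_mm must be 3 positive values (got {self.grid_spacing_mm})")
        if self.n_contacts < 1:
            bad.append(f"n_contacts must be >= 1 (got {self.n_contacts})")
        if self.contact_spacing_mm <= 0:
            bad.append(f"contact_spacing_mm must be > 0 (got {self.contact_spacing_mm})")
        if self.tract_sigma_mm <= 0:
            bad.append(f"tract_sigma_mm must be > 0 (got {self.tract_sigma_mm})")
        if self.n_samples < 1:
            bad.append(f"n_samples must be >= 1 (got {self.n_samples})")
        if not (0 <= self.noise_fraction < 1):
            bad.append(f"noise_fraction must be in [0, 1) (got {self.noise_fraction})")
        pc = self.candidate_percents
        if len(pc) < 1 or any(p <= 0 for p in pc) or any(a >= b for a, b in zip(pc, pc[1:])):
            bad.append(
                f"candidate_percents must be strictly increasing positives (got {pc})"
            )
        if self.step_down_cutoff_mm <= 0:
            bad.append(f"step_down_cutoff_mm must be > 0 (got {self.step_down_cutoff_mm})")
        if self.jitter_mm < 0:
            bad.append(f"jitter_mm must be >= 0 (got {self.jitter_mm})")
        if self.warp_amplitude_mm < 0:
            bad.append(f"warp_amplitude_mm must be >= 0 (got {self.warp_amplitude_mm})")
        if self.warp_wavelength_mm <= 0:
            bad.append(f"warp_wavelength_mm must be > 0 (got {self.warp_wavelength_mm})")
        if not (0 <= self.n_misnormalized <= self.n_patients):
            bad.append(
                f"n_misnormalized must be in [0, n_patients] (got {self.n_misnormalized})"
            )
        if not (0 <= self.misnormalized_shift_min_mm <= self.misnormalized_shift_max_mm):
            bad.append(
                "misnormalized_shift_min_mm/max_mm must satisfy 0 <= min <= max "
                f"(got {self.misnormalized_shift_min_mm}, {self.misnormalized_shift_max_mm})"
            )
        if self.atlas_rn_offset_mm < 0:
            bad.append(f"atlas_rn_offset_mm must be >= 0 (got {self.atlas_rn_offset_mm})")
        if self.outlier_cutoff_mm <= 0:
            bad.append(f"outlier_cutoff_mm must be > 0 (got {self.outlier_cutoff_mm})")
        if not (0 <= int(self.seed) < 2**31):
            bad.append(f"seed must be in [0, 2^31) (got {self.seed})")
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))

    # -- serialization -----------------------------------------------------

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = sorted(set(mapping) - cls.field_names())
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping of keys to values")
        return cls.from_mapping(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["grid_spacing_mm"] = list(self.grid_spacing_mm)
        d["candidate_percents"] = list(self.candidate_percents)
        return d

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def sha256(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
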