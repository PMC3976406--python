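"""Shared containers for the resting-state ICA pipeline.

Volumetric data live on a :class:`VolumeGrid`; per-scan time series are
stored masked, as a ``T x V`` matrix whose column order is the C-order scan
of the brain mask. Keeping the mask and voxel size together with every scan
makes mm-space cluster reports and NIfTI round-trips unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DAYS = ("FD", "WD")
TIMEPOINTS = ("T1", "T2", "T3")
#: The five scans each subject contributes: baseline morning on both days,
#: evening on both days, plus the intermediate working-day scan.
CONDITIONS = ("FD-T1", "FD-T3", "WD-T1", "WD-T2", "WD-T3")


@dataclass(frozen=True)
class VolumeGrid:
    """A common 3-D sampling grid with an isotropic voxel size and brain mask."""

    dims: tuple[int, int, int]
    voxel_size_mm: float
    brain_mask: np.ndarray  # boolean, shape == dims

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 4 for d in self.dims):
            raise ValueError(f"grid dims must be a triple of integers >= 4, got {self.dims}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        mask = np.asarray(self.brain_mask, dtype=bool)
        if mask.shape != tuple(self.dims):
            raise ValueError(f"brain_mask shape {mask.shape} != dims {self.dims}")
        if not mask.any():
            raise ValueError("brain_mask is empty")
        object.__setattr__(self, "brain_mask", mask)

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (the V of every masked matrix)."""
        return int(self.brain_mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked V-vector back onto the 3-D grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError(f"expected {self.n_voxels} masked values, got {values.shape[-1]}")
        vol = np.full(self.dims, fill, dtype=float)
        vol[self.brain_mask] = values
        return vol

    def from_volume(self, volume: np.ndarray) -> np.ndarray:
        """Extract the masked V-vector from a full 3-D volume."""
        volume = np.asarray(volume)
        if volume.shape[:3] != tuple(self.dims):
            raise ValueError(f"volume shape {volume.shape} != dims {self.dims}")
        return volume[self.brain_mask]


def make_ellipsoid_mask(dims: tuple[int, int, int], margin: float = 1.0) -> np.ndarray:
    """Brain-like ellipsoid mask inscribed in the grid, `margin` voxels in."""
    nx, ny, nz = dims
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = cx - margin, cy - margin, cz - margin
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


@dataclass
class Scan:
    """One subject-session 4-D time series, masked to ``T x V``."""

    subject: str
    day: str
    timepoint: str
    tr_s: float
    data: np.ndarray  # (T, V) float
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("scan data must be a T x V matrix")
        if self.n_timepoints < 32:
            raise ValueError(f"scan needs >= 32 time points, got {self.n_timepoints}")
        if self.data.shape[1] != self.grid.n_voxels:
            raise ValueError(
                f"scan has {self.data.shape[1]} voxels but mask has {self.grid.n_voxels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("scan data contain non-finite values")
        if self.day not in DAYS or self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown design labels {self.day}-{self.timepoint}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def condition(self) -> str:
        return f"{self.day}-{self.timepoint}"

    def replace_data(self, data: np.ndarray) -> "Scan":
        return Scan(self.subject, self.day, self.timepoint, self.tr_s, data, self.grid)


@dataclass
class ConfoundSet:
    """Per-scan nuisance series: motion parameters and physiological phases."""

    motion: np.ndarray  # (T, 6): 3 translations mm, 3 rotations deg
    cardiac_phase: np.ndarray  # (T,) radians in [0, 2*pi)
    resp_phase: np.ndarray  # (T,) radians in [0, 2*pi)
    extra: np.ndarray | None = None  # (T, m), e.g. respiration volume per time

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
        self.cardiac_phase = np.mod(np.asarray(self.cardiac_phase, dtype=float), 2 * np.pi)
        self.resp_phase = np.mod(np.asarray(self.resp_phase, dtype=float), 2 * np.pi)
        t = self.motion.shape[0]
        if self.motion.shape != (t, 6):
            raise ValueError("motion must be T x 6")
        if self.cardiac_phase.shape != (t,) or self.resp_phase.shape != (t,):
            raise ValueError("phase series length must match motion length")
        if self.extra is not None:
            self.extra = np.atleast_2d(np.asarray(self.extra, dtype=float))
            if self.extra.shape[0] != t:
                raise ValueError("extra confounds length must match motion length")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]


@dataclass
class StatMap:
    """A voxelwise statistic map (t values) on the masked grid."""

    values: np.ndarray  # (V,)
    df: int
    grid: VolumeGrid
    tail: str = "two"  # {"one", "two"}
    capped: bool = field(default=False)  # any zero-variance voxel hit the t cap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_voxels,):
            raise ValueError("stat map length must equal mask voxel count")
        if not np.isfinite(self.values).all():
            raise ValueError("stat map must be finite (cap zero-variance voxels)")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")
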