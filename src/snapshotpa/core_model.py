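"""Domain types shared across the imaging pipeline.

Conventions used everywhere in this package:

* voxel indices are 0-based and linearized with X fastest-varying,
  ``i = ix + nx * (iy + ny * iz)``;
* physical constants are SI internally; grid coordinates and voxel
  pitches are expressed in millimetres at the interfaces, matching how
  scan geometries are normally quoted;
* the acoustic relay (prism + cylindrical pipe) couples sound into the
  detector through a circular entrance aperture whose centre sits at
  the coordinate origin ``(0, 0, 0) mm``, with the pipe axis along +Z.
  Imaged voxels therefore live at z > 0, in water, in front of that
  entrance plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcousticParams",
    "VolumeGrid",
    "VolumeImage",
    "MeasuredSignal",
    "make_grid",
    "linear_index",
    "delinearize",
    "voxel_center",
]

# Tolerant endpoint inclusion: extent/inc like 6/0.3 is 19.999...96 in
# binary floating point and must still count 21 planes.
_COUNT_EPS = 1e-6


@dataclass(frozen=True)
class AcousticParams:
    """Physical constants of the detection chain.

    Parameters
    ----------
    v_water, v_pipe:
        Sound speeds (m/s) in the coupling water and in the fused-silica
        relay pipe. Total internal reflection requires ``v_water < v_pipe``.
    f_c:
        Transducer centre frequency (Hz).
    frac_bw_6db:
        Fractional -6 dB bandwidth of the transducer (dimensionless).
    pipe_length, pipe_radius:
        Relay pipe geometry (m).
    fs:
        Sampling rate of the digitizer (Hz).
    n_samples:
        Record length of one single-shot acquisition (samples).
    """

    v_water: float = 1500.0
    v_pipe: float = 5900.0
    f_c: float = 1e6
    frac_bw_6db: float = 0.8466
    pipe_length: float = 0.30
    pipe_radius: float = 0.015
    fs: float = 20e6
    n_samples: int = 4096

    def __post_init__(self) -> None:
        if not (0.0 < self.v_water < self.v_pipe):
            raise ValueError(
                f"need 0 < v_water < v_pipe, got {self.v_water}, {self.v_pipe}"
            )
        if not (0.0 < self.frac_bw_6db < 2.0):
            raise ValueError(f"frac_bw_6db out of (0, 2): {self.frac_bw_6db}")
        nyquist_needed = 2.0 * self.f_c * (1.0 + self.frac_bw_6db / 2.0)
        if self.fs <= nyquist_needed:
            raise ValueError(
                f"fs={self.fs:g} Hz below Nyquist for the pulse band "
                f"(need > {nyquist_needed:g} Hz)"
            )
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def wavelength_water(self) -> float:
        """Acoustic wavelength in water at the centre frequency (m)."""
        return self.v_water / self.f_c

    @property
    def wavelength_pipe(self) -> float:
        """Acoustic wavelength in the relay pipe at the centre frequency (m)."""
        return self.v_pipe / self.f_c


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3D voxel lattice covering the calibrated volume.

    ``counts[a] = floor(extent[a]/inc[a]) + 1``: both endpoints of each
    axis are scanned, so the stated extent is covered completely.
    """

    extent_mm: tuple[float, float, float]
    inc_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    counts: tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_mm):
            raise ValueError(f"extents must be positive: {self.extent_mm}")
        if any(d <= 0 for d in self.inc_mm):
            raise ValueError(f"increments must be positive: {self.inc_mm}")
        counts = tuple(
            int(math.floor(e / d + _COUNT_EPS)) + 1
            for e, d in zip(self.extent_mm, self.inc_mm)
        )
        object.__setattr__(self, "counts", counts)

    @property
    def nx(self) -> int:
        return self.counts[0]

    @property
    def ny(self) -> int:
        return self.counts[1]

    @property
    def nz(self) -> int:
        return self.counts[2]

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    # -- index plumbing -------------------------------------------------

    def linear_index(self, idx: tuple[int, int, int]) -> int:
        ix, iy, iz = idx
        if not (0 <= ix < self.nx and 0 <= iy < self.ny and 0 <= iz < self.nz):
            raise IndexError(f"voxel index {idx} outside counts {self.counts}")
        return ix + self.nx * (iy + self.ny * iz)

    def delinearize(self, i: int) -> tuple[int, int, int]:
        if not 0 <= i < self.n_voxels:
            raise IndexError(f"linear index {i} outside [0, {self.n_voxels})")
        ix = i % self.nx
        iy = (i // self.nx) % self.ny
        iz = i // (self.nx * self.ny)
        return ix, iy, iz

    def voxel_center(self, i: int) -> tuple[float, float, float]:
        ix, iy, iz = self.delinearize(i)
        ox, oy, oz = self.origin_mm
        dx, dy, dz = self.inc_mm
        return (ox + ix * dx, oy + iy * dy, oz + iz * dz)

    def voxel_centers(self) -> np.ndarray:
        """All voxel centres, shape (N, 3), mm, in linear-index order."""
        dx, dy, dz = self.inc_mm
        xs = self.origin_mm[0] + dx * np.arange(self.nx)
        ys = self.origin_mm[1] + dy * np.arange(self.ny)
        zs = self.origin_mm[2] + dz * np.arange(self.nz)
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (0=X, 1=Y, 2=Z), mm."""
        return self.origin_mm[axis] + self.inc_mm[axis] * np.arange(self.counts[axis])

    def contains_point(self, coord_mm) -> bool:
        """Whether a physical point lies inside the lattice bounding box."""
        for a in range(3):
            lo = self.origin_mm[a]
            hi = lo + self.inc_mm[a] * (self.counts[a] - 1)
            if not (lo - 1e-9 <= coord_mm[a] <= hi + 1e-9):
                return False
        return True

    def nearest_voxel(self, coord_mm) -> tuple[int, int, int]:
        """Nearest voxel to a point; exact midpoints break toward the lower index."""
        idx = []
        for a in range(3):
            q = (coord_mm[a] - self.origin_mm[a]) / self.inc_mm[a]
            k = int(math.ceil(q - 0.5))  # ties to the lower index
            idx.append(min(max(k, 0), self.counts[a] - 1))
        return tuple(idx)


def make_grid(extent_mm, inc_mm, origin_mm=(0.0, 0.0, 0.0)) -> VolumeGrid:
    """Build the voxel lattice for a scanned volume.

    ``extent_mm`` is the physical scan range per axis and ``inc_mm`` the
    scan increment; both endpoints are included, so e.g. a 15 x 15 x 6 mm
    volume at 0.5 / 0.5 / 0.3 mm pitch has 31 x 31 x 21 voxels.
    """
    return VolumeGrid(tuple(float(e) for e in extent_mm),
                      tuple(float(d) for d in inc_mm),
                      tuple(float(o) for o in origin_mm))


def centered_grid(extent_mm, inc_mm, standoff_mm: float = 10.0) -> VolumeGrid:
    """Grid centred laterally on the relay-pipe axis, starting ``standoff_mm``
    in front of the entrance plane (the usual imaging geometry)."""
    ex, ey, _ = extent_mm
    return make_grid(extent_mm, inc_mm, origin_mm=(-ex / 2.0, -ey / 2.0, standoff_mm))


def linear_index(grid: VolumeGrid, idx: tuple[int, int, int]) -> int:
    return grid.linear_index(idx)


def delinearize(grid: VolumeGrid, i: int) -> tuple[int, int, int]:
    return grid.delinearize(i)


def voxel_center(grid: VolumeGrid, i: int) -> tuple[float, float, float]:
    return grid.voxel_center(i)


@dataclass
class VolumeImage:
    """Nonnegative voxel intensities over a :class:`VolumeGrid`.

    ``values`` is the flat length-N vector in linear-index order; the 3-D
    view ``as_array()`` has shape ``(nz, ny, nx)`` so that voxel
    ``(ix, iy, iz)`` sits at ``[iz, iy, ix]``.
    """

    values: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_voxels:
            raise ValueError(
                f"image length {self.values.size} != grid voxel count "
                f"{self.grid.n_voxels}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    def as_array(self) -> np.ndarray:
        g = self.grid
        return self.values.reshape(g.nz, g.ny, g.nx)

    @classmethod
    def from_array(cls, arr: np.ndarray, grid: VolumeGrid) -> "VolumeImage":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (grid.nz, grid.ny, grid.nx):
            raise ValueError(
                f"array shape {arr.shape} != (nz, ny, nx) = "
                f"{(grid.nz, grid.ny, grid.nx)}"
            )
        return cls(arr.ravel(), grid)

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "VolumeImage":
        return cls(np.zeros(grid.n_voxels), grid)


@dataclass
class MeasuredSignal:
    """A single-shot detector trace with its sampling metadata."""

    samples: np.ndarray
    fs: float
    pulse_energy: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs
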