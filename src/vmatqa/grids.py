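"""Dose containers and the portable text grid formats.

``DosePlane`` holds a 2D dose array indexed ``values[row, col]`` where columns
run along x (origin ``x0``, spacing ``dx``) and rows along y (origin ``y0``,
spacing ``dy``).  ``DoseGrid`` holds a 3D array indexed ``values[ix, iy, iz]``
with x lateral, y superior-inferior and z anterior-posterior; ``StructureMask``
is a boolean array on the same lattice.

Planes serialise to CSV with a single header row ``x0,y0,dx,dy,rows,cols``
followed by ``rows`` data lines; 3D grids to a JSON header line followed by
one CSV line per (ix, iy) row.  Both formats are plain text and lossless to
float64 repr precision.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DosePlane", "DoseGrid", "StructureMask",
           "read_plane_csv", "write_plane_csv",
           "read_grid_txt", "write_grid_txt",
           "read_mask_txt", "write_mask_txt"]


@dataclass
class DosePlane:
    """A 2D dose distribution in Gy on a regular lattice."""

    values: np.ndarray
    spacing: tuple[float, float]  # (dx, dy) mm
    origin: tuple[float, float] = (0.0, 0.0)  # (x0, y0) mm of values[0, 0]
    detector_mask: np.ndarray | None = None  # optional sparse sampling sites

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("dose plane must be 2D")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("plane spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.detector_mask is not None:
            self.detector_mask = np.asarray(self.detector_mask, bool)
            if self.detector_mask.shape != self.values.shape:
                raise ValueError("detector mask shape must match values")

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.values.shape[0])

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of lattice points, mm."""
        return (self.x[0], self.x[-1], self.y[0], self.y[-1])

    def shifted(self, dx: float, dy: float) -> "DosePlane":
        return DosePlane(self.values, self.spacing,
                         (self.origin[0] + dx, self.origin[1] + dy),
                         self.detector_mask)

    def sample(self, x: np.ndarray, y: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Bilinear interpolation at physical coordinates; ``fill`` outside."""
        from scipy.ndimage import map_coordinates

        col = (np.asarray(x, float) - self.origin[0]) / self.spacing[0]
        row = (np.asarray(y, float) - self.origin[1]) / self.spacing[1]
        out = map_coordinates(self.values, np.vstack([row.ravel(), col.ravel()]),
                              order=1, mode="constant", cval=np.nan)
        ny, nx = self.values.shape
        outside = (col.ravel() < 0) | (col.ravel() > nx - 1) | \
                  (row.ravel() < 0) | (row.ravel() > ny - 1)
        out[outside] = fill
        return out.reshape(np.shape(x))


@dataclass
class DoseGrid:
    """A 3D dose distribution in Gy; axes (x, y, z) with y superior-inferior."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("dose grid must be 3D")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.voxel_size[axis] * np.arange(self.values.shape[axis])

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.values * factor, self.voxel_size, self.origin)


@dataclass
class StructureMask:
    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 3:
            raise ValueError("structure mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Text I/O


def write_plane_csv(plane: DosePlane, path: str | Path) -> None:
    rows, cols = plane.values.shape
    with open(path, "w") as fh:
        fh.write(f"{plane.origin[0]!r},{plane.origin[1]!r},"
                 f"{plane.spacing[0]!r},{plane.spacing[1]!r},{rows},{cols}\n")
        np.savetxt(fh, plane.values, delimiter=",", fmt="%.10g")


def read_plane_csv(path: str | Path) -> DosePlane:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if len(header) != 6:
            raise ValueError(f"{path}: expected header x0,y0,dx,dy,rows,cols")
        x0, y0, dx, dy = map(float, header[:4])
        rows, cols = int(header[4]), int(header[5])
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    if values.shape != (rows, cols):
        raise ValueError(f"{path}: data shape {values.shape} != header ({rows}, {cols})")
    return DosePlane(values, (dx, dy), (x0, y0))


def write_grid_txt(grid: DoseGrid, path: str | Path) -> None:
    nx, ny, nz = grid.values.shape
    with open(path, "w") as fh:
        fh.write(json.dumps({"shape": [nx, ny, nz],
                             "voxel_size": list(grid.voxel_size),
                             "origin": list(grid.origin)}) + "\n")
        np.savetxt(fh, grid.values.reshape(nx * ny, nz), delimiter=",", fmt="%.10g")


def read_grid_txt(path: str | Path) -> DoseGrid:
    with open(path) as fh:
        header = json.loads(fh.readline())
        nx, ny, nz = header["shape"]
        values = np.loadtxt(fh, delimiter=",", ndmin=2).reshape(nx, ny, nz)
    return DoseGrid(values, tuple(header["voxel_size"]), tuple(header["origin"]))


def write_mask_txt(mask: StructureMask, voxel_size, origin, path: str | Path) -> None:
    nx, ny, nz = mask.mask.shape
    with open(path, "w") as fh:
        fh.write(json.dumps({"name": mask.name, "shape": [nx, ny, nz],
                             "voxel_size": list(voxel_size), "origin": list(origin)}) + "\n")
        np.savetxt(fh, mask.mask.reshape(nx * ny, nz), delimiter=",", fmt="%d")


def read_mask_txt(path: str | Path) -> tuple[StructureMask, tuple, tuple]:
    with open(path) as fh:
        header = json.loads(fh.readline())
        nx, ny, nz = header["shape"]
        values = np.loadtxt(fh, delimiter=",", ndmin=2).reshape(nx, ny, nz)
    return (StructureMask(header["name"], values > 0.5),
            tuple(header["voxel_size"]), tuple(header["origin"]))
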