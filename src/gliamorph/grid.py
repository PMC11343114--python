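"""Voxel-grid geometry and regions of interest.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` everywhere (arrays, shapes, voxel sizes,
  physical coordinates);
* voxel indices are 0-based; the physical position of voxel ``(k, j, i)``
  is its *center*, ``((k + 0.5) dz, (j + 0.5) dy, (i + 0.5) dx)`` in µm;
* every physical length is in µm, every volume in µm³.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "ROI", "roi_volume"]


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and physical voxel size of a 3D image stack.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts ``(nz, ny, nx)``.
    voxel_size : tuple of float
        Physical voxel edge lengths ``(dz, dy, dx)`` in µm, all strictly
        positive.  Anisotropy (``dz != dy``) is permitted and handled by
        every downstream distance computation.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or len(vs) != 3:
            raise ValueError("VoxelGrid is 3D: shape and voxel_size need 3 entries")
        if any(n <= 0 for n in shape):
            raise ValueError(f"non-positive shape {shape}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"non-positive voxel size {vs}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Physical size of the whole grid per axis, in µm."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def index_to_um(self, idx: np.ndarray) -> np.ndarray:
        """Physical coordinates (µm) of voxel indices (centers), shape (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return (idx + 0.5) * np.asarray(self.voxel_size)

    def um_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical positions (µm), shape (..., 3)."""
        pos = np.asarray(pos, dtype=float)
        return pos / np.asarray(self.voxel_size) - 0.5

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)


@dataclass
class ROI:
    """A region of interest: axis-aligned bounds or an explicit mask.

    ``bounds`` are per-axis ``(start, stop)`` voxel ranges, inclusive start
    and exclusive stop, in ``(z, y, x)`` order.  Exactly one of ``bounds``
    and ``mask`` must be given.
    """

    label: str = "roi"
    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.bounds is None) == (self.mask is None):
            raise ValueError("ROI needs exactly one of bounds or mask")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.bounds is not None:
            self.bounds = tuple(
                (int(a), int(b)) for a, b in self.bounds
            )  # type: ignore[assignment]
            for a, b in self.bounds:
                if b < a or a < 0:
                    raise ValueError(f"bad ROI bounds {self.bounds}")

    @classmethod
    def full(cls, grid: VoxelGrid, label: str = "full") -> "ROI":
        return cls(label=label, bounds=tuple((0, n) for n in grid.shape))

    def validate(self, grid: VoxelGrid) -> None:
        if self.mask is not None:
            if self.mask.shape != grid.shape:
                raise ValueError(
                    f"ROI mask shape {self.mask.shape} != grid shape {grid.shape}"
                )
        else:
            for (a, b), n in zip(self.bounds, grid.shape):
                if b > n:
                    raise ValueError(f"ROI bounds {self.bounds} exceed grid {grid.shape}")

    def as_mask(self, grid: VoxelGrid) -> np.ndarray:
        """Boolean voxel mask of the ROI on ``grid``."""
        self.validate(grid)
        if self.mask is not None:
            return self.mask
        m = np.zeros(grid.shape, dtype=bool)
        (z0, z1), (y0, y1), (x0, x1) = self.bounds
        m[z0:z1, y0:y1, x0:x1] = True
        return m

    def voxel_count(self, grid: VoxelGrid) -> int:
        self.validate(grid)
        if self.mask is not None:
            return int(self.mask.sum())
        return int(np.prod([b - a for a, b in self.bounds]))

    def contains_um(self, pos: np.ndarray, grid: VoxelGrid) -> np.ndarray:
        """Whether physical points (µm, shape (..., 3)) fall inside the ROI.

        A point belongs to the ROI iff the voxel containing it does.
        """
        self.validate(grid)
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        idx = np.floor(pos / np.asarray(grid.voxel_size)).astype(int)
        inside_grid = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=-1)
        out = np.zeros(len(idx), dtype=bool)
        if self.mask is not None:
            ok = inside_grid
            out[ok] = self.mask[tuple(idx[ok].T)]
        else:
            lo = np.array([a for a, _ in self.bounds])
            hi = np.array([b for _, b in self.bounds])
            out = inside_grid & np.all((idx >= lo) & (idx < hi), axis=-1)
        return out


def roi_volume(roi: ROI, grid: VoxelGrid) -> float:
    """Physical ROI volume in µm³ (voxel count × voxel volume)."""
    n = roi.voxel_count(grid)
    if n == 0:
        warnings.warn(f"ROI {roi.label!r} contains no voxels", stacklevel=2)
    return n * grid.voxel_volume
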