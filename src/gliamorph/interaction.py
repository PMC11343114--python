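"""Spot–cell interaction: signed distances, contact/engulfment, CD68.

Each detected spot is classified against the nearest microglial surface
by its centroid's signed Euclidean distance d (positive outside the cell,
negative inside):

* engulfed — ``-engulf_shell < d <= 0`` (default "shell" reading of the
  0.5 µm internal-surface rule) or ``d <= 0`` ("full_interior" reading);
* contact  — not engulfed and ``|d| <= contact_max`` (default 1 µm);
* free     — otherwise.

Spots deeper inside than the shell are always flagged ``deep_interior``
so both readings of the engulfment rule stay reportable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ROI, VoxelGrid, roi_volume
from .morphometry import CellMask
from .spots import SpotSet, kmeans_threshold

__all__ = [
    "SignedDistanceField",
    "signed_distance",
    "classify_spots",
    "cd68_volume",
    "engulfment_summary",
    "CONTACT_MAX_UM",
    "ENGULF_SHELL_UM",
]

#: spots at no more than this distance from the cell surface are contacts
CONTACT_MAX_UM = 1.0
#: spots less than this far inside the surface are engulfed (shell mode)
ENGULF_SHELL_UM = 0.5


@dataclass
class SignedDistanceField:
    """Per-voxel signed Euclidean distance (µm) to the nearest cell surface.

    ``field`` is positive outside the union of cell masks and negative
    inside; ``nearest_cell`` holds the id of the nearest cell per voxel.
    Distances at arbitrary physical points are obtained by trilinear
    interpolation (:meth:`distance_at`).
    """

    field: np.ndarray
    nearest_cell: np.ndarray
    grid: VoxelGrid

    def distance_at(self, pos_um: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos_um, dtype=float))
        coords = self.grid.um_to_index(pos).T
        return ndimage.map_coordinates(self.field, coords, order=1, mode="nearest")

    def nearest_cell_at(self, pos_um: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos_um, dtype=float))
        idx = np.clip(np.round(self.grid.um_to_index(pos)).astype(int), 0,
                      np.asarray(self.grid.shape) - 1)
        return self.nearest_cell[tuple(idx.T)]


def signed_distance(cells: list[CellMask], grid: VoxelGrid) -> SignedDistanceField:
    """Anisotropy-aware signed EDT to the cell-surface voxel layer.

    The surface is the set of mask voxels with a 6-neighbour outside the
    mask (the image border itself is not a surface: a cell clipped by the
    stack edge has no boundary there).  Field values are the Euclidean
    distance to the nearest surface voxel center — zero on surface
    voxels, positive outside the mask, negative inside.
    """
    if not cells:
        raise ValueError("no cell masks")
    union = np.zeros(grid.shape, dtype=bool)
    labels = np.zeros(grid.shape, dtype=np.int32)
    for c in cells:
        if c.mask.shape != grid.shape:
            raise ValueError("cell mask shape differs from grid")
        union |= c.mask
        labels[c.mask] = c.cell_id
    cross = ndimage.generate_binary_structure(3, 1)
    boundary = union & ~ndimage.binary_erosion(union, structure=cross, border_value=1)
    if not boundary.any():  # mask fills the whole grid: no surface anywhere
        raise ValueError("cell masks have no surface within the grid")
    dist, indices = ndimage.distance_transform_edt(
        ~boundary, sampling=grid.voxel_size, return_indices=True
    )
    field = np.where(union, -dist, dist).astype(np.float32)
    nearest = labels[tuple(indices)]
    nearest[union] = labels[union]
    return SignedDistanceField(field=field, nearest_cell=nearest, grid=grid)


def classify_point_distances(
    d: np.ndarray,
    contact_max: float = CONTACT_MAX_UM,
    engulf_shell: float = ENGULF_SHELL_UM,
    mode: str = "shell",
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the distance rules to signed distances; returns (class, deep flag).

    This single function defines the free/contact/engulfed partition for
    the whole package — the synthetic generator's ground truth and the
    measurement pipeline both call it.
    """
    d = np.asarray(d, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("NaN signed distance")
    if mode not in ("shell", "full_interior"):
        raise ValueError(f"unknown engulfment mode {mode!r}")
    deep = d <= -engulf_shell
    if mode == "shell":
        engulfed = (d > -engulf_shell) & (d <= 0)
    else:
        engulfed = d <= 0
    contact = ~engulfed & (np.abs(d) <= contact_max)
    cls = np.where(engulfed, "engulfed", np.where(contact, "contact", "free"))
    return cls, deep


def classify_spots(
    spots: SpotSet | np.ndarray,
    field: SignedDistanceField,
    contact_max: float = CONTACT_MAX_UM,
    engulf_shell: float = ENGULF_SHELL_UM,
    mode: str = "shell",
) -> pd.DataFrame:
    """Classify spot centroids as free / contact / engulfed.

    ``spots`` may be a :class:`~gliamorph.spots.SpotSet` (retained spots
    are used) or an (n, 3) array of centroid positions in µm.  Returns a
    table with spot id, nearest cell id, signed distance, class, mode and
    the deep-interior flag; every spot gets exactly one class.
    """
    pos = spots.centroids_um() if isinstance(spots, SpotSet) else np.atleast_2d(np.asarray(spots, float))
    if pos.size == 0:
        return pd.DataFrame(columns=["spot_id", "cell_id", "distance_um", "class",
                                     "mode", "deep_interior"])
    d = field.distance_at(pos)
    cls, deep = classify_point_distances(d, contact_max, engulf_shell, mode)
    return pd.DataFrame(
        {
            "spot_id": np.arange(len(pos)),
            "cell_id": field.nearest_cell_at(pos),
            "distance_um": d,
            "class": cls,
            "mode": mode,
            "deep_interior": deep,
        }
    )


def cd68_volume(
    cd68: np.ndarray,
    cells: list[CellMask],
    grid: VoxelGrid,
    threshold: float | None = None,
) -> pd.DataFrame:
    """CD68⁺ volume (µm³) inside each cell mask.

    Within the union of cell masks, CD68 is thresholded by the exact
    two-means split of the in-mask intensities (or a manual threshold);
    the CD68⁺ volume per cell is the suprathreshold voxel count times the
    voxel volume.  Returns one row per cell plus a ``total`` row.
    """
    if not cells:
        raise ValueError("no cells")
    cd68 = np.asarray(cd68, dtype=np.float32)
    union = np.zeros(grid.shape, dtype=bool)
    for c in cells:
        union |= c.mask
    if threshold is None:
        try:
            threshold = kmeans_threshold(cd68[union])
        except ValueError:
            threshold = np.inf  # flat in-mask signal: nothing suprathreshold
    supra = (cd68 > threshold) & union
    rows = []
    for c in cells:
        vol = float(np.sum(supra & c.mask)) * grid.voxel_volume
        rows.append({"cell_id": c.cell_id, "cd68_volume_um3": vol,
                     "cell_volume_um3": float(c.mask.sum()) * grid.voxel_volume})
    df = pd.DataFrame(rows)
    df.attrs["total_cd68_um3"] = float(df["cd68_volume_um3"].sum())
    df.attrs["threshold"] = float(threshold)
    return df


def engulfment_summary(records: pd.DataFrame, roi: ROI, grid: VoxelGrid) -> dict:
    """Per-ROI engulfment summary from a classification table.

    Returns engulfed count, engulfed density per 10³ µm³, and the engulfed
    fraction of retained spots (NaN, with a warning, when no spots).
    """
    n_spots = len(records)
    n_engulfed = int((records["class"] == "engulfed").sum()) if n_spots else 0
    n_contact = int((records["class"] == "contact").sum()) if n_spots else 0
    vol = roi_volume(roi, grid)
    if n_spots == 0:
        warnings.warn("no spots: engulfed fraction undefined")
        frac = float("nan")
    else:
        frac = n_engulfed / n_spots
    return {
        "n_spots": n_spots,
        "n_contact": n_contact,
        "n_engulfed": n_engulfed,
        "engulfed_density_per_1e3um3": n_engulfed / vol * 1e3 if vol > 0 else float("nan"),
        "engulfed_fraction": frac,
    }
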