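"""Terminal ("spot") detection in a punctate fluorescence channel.

The detection chain mirrors the classic Imaris-style spot workflow:
background subtraction and Gaussian pre-filtering, a scale-normalised 3D
Mexican-hat (Laplacian-of-Gaussian) filter at a fixed physical spot size,
26-connected local-maxima candidates, and an automatic threshold computed
by exact two-cluster k-means on the candidate responses.

All scales are physical (µm) and converted per axis to voxels, so
anisotropic stacks are handled transparently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ROI, VoxelGrid

__all__ = [
    "DetectionParams",
    "SpotSet",
    "kmeans_threshold",
    "preprocess_channel",
    "detect_spots",
    "spot_density",
]


def kmeans_threshold(values) -> float:
    """Exact 1-D two-means threshold.

    The optimal 2-means partition of scalars is contiguous in sorted
    order, so the global optimum is found by scanning every split point of
    the sorted sample and minimising the total within-cluster sum of
    squares (prefix-sum arithmetic, no iterative heuristic).  The returned
    threshold is the midpoint of the two cluster means.

    Raises
    ------
    ValueError
        If fewer than two distinct values are supplied (degenerate
        distribution, no two-cluster structure exists).
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise ValueError("degenerate distribution: need >= 2 distinct values")
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)  # split: left = x[:k], right = x[k:]
    sse_left = csq[k - 1] - csum[k - 1] ** 2 / k
    sse_right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
    # ties broken toward the smallest split -> deterministic
    best = int(np.argmin(sse_left + sse_right))
    kb = best + 1
    mean_left = csum[kb - 1] / kb
    mean_right = (csum[-1] - csum[kb - 1]) / (n - kb)
    return float((mean_left + mean_right) / 2.0)


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the spot-detection chain (physical units, µm).

    Attributes
    ----------
    spot_diameter : float
        Physical diameter of the spot model (default 0.8 µm).
    background_sigma : float or None
        Gaussian sd of the large-scale background estimate; default
        ``5 × spot_diameter``.
    prefilter_sigma : float or None
        Gaussian pre-smoothing sd; default ``spot_radius / 2``.
    threshold_mode : {"kmeans", "manual"}
    manual_threshold : float
        Response threshold used when ``threshold_mode == "manual"``.
    exclude_border : bool
        Drop maxima closer than one spot radius to the stack border
        (they remain in the table, flagged, but are not retained).
    """

    spot_diameter: float = 0.8
    background_sigma: float | None = None
    prefilter_sigma: float | None = None
    threshold_mode: str = "kmeans"
    manual_threshold: float = 0.0
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.spot_diameter <= 0:
            raise ValueError("spot diameter must be > 0")
        for name in ("background_sigma", "prefilter_sigma"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.threshold_mode not in ("kmeans", "manual"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")

    @property
    def spot_radius(self) -> float:
        return self.spot_diameter / 2.0

    @property
    def bg_sigma(self) -> float:
        return self.background_sigma if self.background_sigma is not None else 5.0 * self.spot_diameter

    @property
    def pre_sigma(self) -> float:
        return self.prefilter_sigma if self.prefilter_sigma is not None else self.spot_radius / 2.0

    @property
    def log_sigma(self) -> float:
        # 3D blob-optimal LoG scale for a ball of the stated radius
        return self.spot_radius / np.sqrt(3.0)


@dataclass
class SpotSet:
    """Detected spots with their responses and retention flags.

    ``table`` columns: ``z, y, x`` (centroid, µm), ``response`` (filter
    response at the maximum), ``intensity`` (raw channel value at the
    maximum voxel), ``retained`` (above threshold, inside ROI, not at the
    border), ``edge`` (within one spot radius of the stack border).
    """

    table: pd.DataFrame
    spot_diameter: float = 0.8
    channel_name: str = "agrp"
    roi_label: str = "full"
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        cols = {"z", "y", "x", "response", "intensity", "retained", "edge"}
        missing = cols - set(self.table.columns)
        if missing:
            raise ValueError(f"spot table missing columns {sorted(missing)}")

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    @property
    def count(self) -> int:
        return int(self.table["retained"].sum())

    def centroids_um(self, retained_only: bool = True) -> np.ndarray:
        t = self.retained if retained_only else self.table
        return t[["z", "y", "x"]].to_numpy(dtype=float)


def _sigma_vox(sigma_um: float, grid: VoxelGrid) -> tuple[float, float, float]:
    return tuple(sigma_um / v for v in grid.voxel_size)


def preprocess_channel(
    channel: np.ndarray, grid: VoxelGrid, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Background subtraction followed by Gaussian smoothing.

    The background is a large-scale Gaussian blur of the channel; the
    difference is clipped at zero and then smoothed at roughly half the
    spot radius.  Output is non-negative.
    """
    channel = np.asarray(channel, dtype=np.float32)
    if np.any(channel < 0):
        raise ValueError("channel must be non-negative")
    bg = ndimage.gaussian_filter(channel, sigma=_sigma_vox(params.bg_sigma, grid))
    out = np.clip(channel - bg, 0.0, None)
    return ndimage.gaussian_filter(out, sigma=_sigma_vox(params.pre_sigma, grid))


def _local_maxima(resp: np.ndarray) -> np.ndarray:
    """26-connected local maxima; plateau ties keep the lexicographically
    smallest voxel index.  Returns an (n, 3) int index array."""
    footprint = np.ones((3, 3, 3), dtype=bool)
    maxf = ndimage.maximum_filter(resp, footprint=footprint, mode="constant", cval=-np.inf)
    cand = (resp >= maxf) & (resp > 0)
    if not cand.any():
        return np.empty((0, 3), dtype=int)
    # collapse plateaus: label connected equal-valued candidate regions
    lbl, nlbl = ndimage.label(cand, structure=footprint)
    idx = np.argwhere(cand)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    idx = idx[order]
    labels = lbl[tuple(idx.T)]
    _, first = np.unique(labels, return_index=True)
    return idx[np.sort(first)]


def detect_spots(
    channel: np.ndarray,
    grid: VoxelGrid,
    roi: ROI | None = None,
    params: DetectionParams = DetectionParams(),
    preprocessed: bool = False,
    channel_name: str = "agrp",
) -> SpotSet:
    """Detect fixed-diameter spots with a Mexican-hat (LoG) filter.

    The response is the scale-normalised negative Laplacian of Gaussian at
    σ = spot_radius/√3 (per-axis, anisotropy-aware).  Candidates are
    26-connected local maxima of the response; retained spots are the
    candidates at or above the automatic (exact two-means over candidate
    responses) or manual threshold.  Centroids are refined by an
    intensity-weighted mean over the spot-radius neighbourhood.
    """
    if roi is None:
        roi = ROI.full(grid)
    roi.validate(grid)
    if min(grid.physical_extent) < params.spot_diameter:
        raise ValueError("ROI/stack smaller than one spot diameter")

    pre = np.asarray(channel, dtype=np.float32) if preprocessed else preprocess_channel(channel, grid, params)
    sig = params.log_sigma
    resp = -(sig**2) * ndimage.gaussian_laplace(pre, sigma=_sigma_vox(sig, grid))

    idx = _local_maxima(resp)
    cols = ["z", "y", "x", "response", "intensity", "retained", "edge"]
    if len(idx) == 0:
        return SpotSet(
            pd.DataFrame(columns=cols).astype(
                {"z": float, "y": float, "x": float, "response": float,
                 "intensity": float, "retained": bool, "edge": bool}),
            spot_diameter=params.spot_diameter, channel_name=channel_name,
            roi_label=roi.label)

    pos = grid.index_to_um(idx)
    in_roi = roi.contains_um(pos, grid)
    idx, pos = idx[in_roi], pos[in_roi]

    responses = resp[tuple(idx.T)]
    extent = np.asarray(grid.physical_extent)
    r = params.spot_radius
    edge = np.any((pos < r) | (pos > extent - r), axis=1) if params.exclude_border else np.zeros(len(pos), bool)

    if params.threshold_mode == "manual":
        thr = float(params.manual_threshold)
    else:
        pool = responses[~edge]
        try:
            thr = kmeans_threshold(pool)
            lo, hi = pool[pool < thr], pool[pool >= thr]
            if lo.size == 0 or lo.mean() > 0.5 * hi.mean():
                # candidate responses are effectively unimodal (no noise
                # population to reject): keep every candidate
                thr = -np.inf
        except ValueError:
            thr = -np.inf  # too few candidates to split: keep all
    retained = (responses >= thr) & ~edge

    # intensity-weighted centroid refinement within one spot radius
    rad_vox = np.maximum(np.round(r / np.asarray(grid.voxel_size)).astype(int), 1)
    refined = pos.copy()
    channel_f = np.asarray(channel, dtype=np.float32)
    for s, (k, j, i) in enumerate(idx):
        if not retained[s]:
            continue
        sl = tuple(
            slice(max(c - w, 0), min(c + w + 1, n))
            for c, w, n in zip((k, j, i), rad_vox, grid.shape)
        )
        w = channel_f[sl]
        # weighted mean of voxel centers
        grids = np.meshgrid(*[np.arange(a.start, a.stop) for a in sl], indexing="ij")
        tot = float(w.sum())
        if tot > 0:
            com = np.array([float((g * w).sum()) / tot for g in grids])
            refined[s] = (com + 0.5) * np.asarray(grid.voxel_size)

    table = pd.DataFrame(
        {
            "z": refined[:, 0], "y": refined[:, 1], "x": refined[:, 2],
            "response": responses.astype(float),
            "intensity": channel_f[tuple(idx.T)].astype(float),
            "retained": retained, "edge": edge,
        }
    )
    table = table.sort_values(["z", "y", "x"], kind="mergesort").reset_index(drop=True)
    return SpotSet(table, spot_diameter=params.spot_diameter,
                   channel_name=channel_name, roi_label=roi.label, threshold=thr)


def spot_density(spots: SpotSet, roi: ROI, grid: VoxelGrid) -> tuple[int, float]:
    """Retained-spot count and density per 10³ µm³ of the ROI."""
    from .grid import roi_volume

    vol = roi_volume(roi, grid)
    n = spots.count
    return n, (n / vol * 1e3 if vol > 0 else float("nan"))
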