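"""Slow, independent reference implementations used for validation.

Each function here recomputes a quantity by a different route than the
production code (dense sampling, exhaustive enumeration, direct search)
and is deliberately kept free of the modules it checks.  They are meant
for small inputs only.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sholl_counts_sampled",
    "hull_volume_facet_enumeration",
    "two_means_split_enumeration",
    "signed_distance_boundary_search",
]


def sholl_counts_sampled(
    positions: np.ndarray, edges: np.ndarray, root: int, radii, samples: int = 2001
) -> np.ndarray:
    """Sphere-crossing counts by dense sampling along each edge segment.

    For every edge the distance-to-root profile is sampled at ``samples``
    points; a crossing of radius r is a sign change of (distance − r)
    between consecutive samples.  Exact except for radii tangent to an
    edge or crossing within less than the sampling step (measure-zero for
    random geometry).
    """
    positions = np.asarray(positions, float)
    c = positions[root]
    t = np.linspace(0.0, 1.0, samples)
    counts = np.zeros(len(radii), dtype=int)
    for a, b in np.asarray(edges, int):
        pts = positions[a][None, :] + t[:, None] * (positions[b] - positions[a])[None, :]
        d = np.linalg.norm(pts - c, axis=1)
        for k, r in enumerate(radii):
            s = np.sign(d - r)
            counts[k] += int(np.sum(s[:-1] * s[1:] < 0))
    return counts


def hull_volume_facet_enumeration(points: np.ndarray) -> float:
    """Convex-hull volume by brute-force facet enumeration.

    Every triple of points is tested as a supporting plane (all other
    points on one side); the volume of the enclosed polytope is then
    accumulated with the divergence theorem, V = Σ (1/3) (c·n̂) A over
    outward-oriented facets.  O(n³·n); for small n only.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 4:
        raise ValueError("need >= 4 points")
    interior = pts.mean(axis=0)
    scale = max(1.0, float(np.abs(pts).max()))
    tol = 1e-9 * scale
    from itertools import combinations

    # collect unique supporting planes (outward-oriented), then compute the
    # polygon area of each planar face so coplanar faces are counted once
    planes: dict[tuple, np.ndarray] = {}
    for i, j, k in combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        nrm = np.cross(b - a, c - a)
        nn = np.linalg.norm(nrm)
        if nn < 1e-12 * scale * scale:
            continue
        nrm = nrm / nn
        s = (pts - a) @ nrm
        if not (np.all(s <= tol) or np.all(s >= -tol)):
            continue
        if (interior - a) @ nrm > 0:
            nrm = -nrm
        key = tuple(np.round(np.append(nrm, (a @ nrm) / scale), 7))
        planes.setdefault(key, (nrm.copy(), a.copy()))

    vol = 0.0
    for nrm, a in planes.values():
        offset = float(a @ nrm)
        on_face = pts[np.abs((pts - a) @ nrm) <= 1e-6 * scale]
        # orthonormal in-plane basis
        e1 = np.cross(nrm, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(nrm, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        p2 = np.c_[on_face @ e1, on_face @ e2]
        area = _convex_polygon_area(p2)
        vol += offset * area / 3.0
    return float(vol)


def _convex_polygon_area(p2: np.ndarray) -> float:
    """Area of the convex hull of 2D points via hand-rolled monotone chain."""
    pts = sorted(map(tuple, p2))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    poly = lower[:-1] + upper[:-1]
    area = 0.0
    for a, b in zip(poly, poly[1:] + poly[:1]):
        area += a[0] * b[1] - b[0] * a[1]
    return abs(area) / 2.0


def two_means_split_enumeration(values) -> float:
    """Two-means threshold by naive enumeration of all sorted splits.

    Means and within-cluster sums of squares are computed directly per
    split with no shared arithmetic with the production implementation.
    """
    x = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        raise ValueError("degenerate distribution")
    best_sse, best_k = None, None
    for k in range(1, n):
        left, right = x[:k], x[k:]
        ml = sum(left) / len(left)
        mr = sum(right) / len(right)
        sse = sum((v - ml) ** 2 for v in left) + sum((v - mr) ** 2 for v in right)
        if best_sse is None or sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    left, right = x[:best_k], x[best_k:]
    return (sum(left) / len(left) + sum(right) / len(right)) / 2.0


def signed_distance_boundary_search(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Signed distance by direct search over boundary voxel centers.

    Boundary voxels are mask voxels with at least one 6-neighbour outside
    the mask; the image edge is not treated as a surface (a cell clipped
    by the stack border has no boundary there).  Every voxel's unsigned
    distance is the minimum Euclidean distance to any boundary voxel
    center, signed negative inside the mask.  For grids up to ~32³.
    """
    mask = np.asarray(mask, bool)
    vs = np.asarray(voxel_size, float)
    nz, ny, nx = mask.shape
    padded = np.pad(mask, 1, mode="edge")
    boundary = np.zeros_like(mask)
    for ax in range(3):
        for sh in (-1, 1):
            sl = [slice(1, 1 + n) for n in (nz, ny, nx)]
            sl[ax] = slice(1 + sh, 1 + sh + mask.shape[ax])
            boundary |= mask & ~padded[tuple(sl)]
    bpos = np.argwhere(boundary) * vs
    allpos = np.argwhere(np.ones_like(mask)) * vs
    if len(bpos) == 0:
        return np.full(mask.shape, np.inf)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(bpos).query(allpos)
    field = d.reshape(mask.shape)
    field[mask] *= -1.0
    return field
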