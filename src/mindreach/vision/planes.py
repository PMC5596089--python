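"""Horizontal-plane extraction by region growing over near-vertical normals.

A pixel is a plane candidate when its normal is within ``angle_tol`` of the
configured vertical axis (either sign).  Growing joins 4-neighboring
candidates whose 3D points are within ``d_threshold`` of each other; grown
regions with at least ``n_c`` pixels are accepted.  The closure of this
queue-based growth is exactly the set of connected components of the
candidate graph, which is how it is computed here (and why the accepted set
is independent of seed order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .cloud import OrganizedCloud

__all__ = ["PlaneSet", "extract_planes", "neighbor_edges"]

DEFAULT_ANGLE_TOL = 10.0      # degrees
DEFAULT_D_THRESHOLD = 0.02    # meters
DEFAULT_MIN_PLANE = 500       # pixels (n_C)
VERTICAL = (0.0, 0.0, 1.0)    # top-down camera: gravity along the optical axis


@dataclass
class PlaneSet:
    """Accepted plane regions and their union, the merged horizontal plane.

    ``planes`` holds the grown regions proper (every member passed the
    normal-angle test); ``boundary`` holds plane-height pixels absorbed by
    the closing pass along region borders, where the 4-neighbor cross
    product is corrupted by depth discontinuities or undefined (image
    border, neighbors of invalid pixels).  The merged plane is the union.
    """

    shape: tuple[int, int]
    planes: list[np.ndarray]
    boundary: np.ndarray | None = None     # flat indices

    @property
    def mask(self) -> np.ndarray:
        """H x W boolean mask of the merged horizontal plane."""
        m = np.zeros(self.shape, dtype=bool)
        for idx in self.planes:
            m.flat[idx] = True
        if self.boundary is not None:
            m.flat[self.boundary] = True
        return m

    @property
    def n_pixels(self) -> int:
        n = int(sum(idx.size for idx in self.planes))
        if self.boundary is not None:
            n += int(self.boundary.size)
        return n


def neighbor_edges(
    nodes: np.ndarray,
    points: np.ndarray,
    d_threshold: float,
    eight_connected: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Qualifying adjacency among ``nodes`` (H x W bool): grid neighbors that
    are both nodes and within ``d_threshold`` in 3D.  Returns flat index
    pairs (i, j), one direction each."""
    h, w = nodes.shape
    flat = np.arange(h * w).reshape(h, w)
    shifts = [(0, 1), (1, 0)]
    if eight_connected:
        shifts += [(1, 1), (1, -1)]
    src_all, dst_all = [], []
    for di, dj in shifts:
        i0, i1 = max(0, -di), min(h, h - di)
        j0, j1 = max(0, -dj), min(w, w - dj)
        a = np.s_[i0:i1, j0:j1]
        b = np.s_[i0 + di:i1 + di, j0 + dj:j1 + dj]
        both = nodes[a] & nodes[b]
        dist = np.linalg.norm(points[a] - points[b], axis=2)
        ok = both & (dist <= d_threshold)
        src_all.append(flat[a][ok])
        dst_all.append(flat[b][ok])
    return np.concatenate(src_all), np.concatenate(dst_all)


def extract_planes(
    cloud: OrganizedCloud,
    normal_field: np.ndarray,
    angle_tol: float = DEFAULT_ANGLE_TOL,
    d_threshold: float = DEFAULT_D_THRESHOLD,
    n_c: int = DEFAULT_MIN_PLANE,
    vertical: tuple[float, float, float] = VERTICAL,
    eight_connected: bool = False,
    close_boundary: bool = True,
    surface_tol: float | None = None,
) -> PlaneSet:
    """Grow and accept horizontal-plane regions.

    ``normal_field`` is the H x W x 3 output of :func:`~mindreach.vision.cloud.normals`
    (NaN rows are never candidates).  With ``close_boundary`` the merged
    plane additionally absorbs adjacent plane-height pixels whose normals
    are undefined or discontinuity-corrupted (kept separate in
    ``PlaneSet.boundary``).
    """
    v = np.asarray(vertical, dtype=float)
    v = v / np.linalg.norm(v)
    cos_tol = np.cos(np.deg2rad(angle_tol))
    with np.errstate(invalid="ignore"):
        cand = cloud.valid & (np.abs(normal_field @ v) >= cos_tol)

    h, w = cloud.shape
    if not cand.any():
        return PlaneSet(shape=(h, w), planes=[])

    src, dst = neighbor_edges(cand, cloud.points, d_threshold, eight_connected)
    n = h * w
    graph = coo_matrix(
        (np.ones(src.size, dtype=np.int8), (src, dst)), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)

    cand_flat = np.flatnonzero(cand.ravel())
    comp_of_cand = comp[cand_flat]
    planes: list[np.ndarray] = []
    for comp_id in np.unique(comp_of_cand):
        members = cand_flat[comp_of_cand == comp_id]
        if members.size >= n_c:
            planes.append(members)
    planes.sort(key=lambda idx: -idx.size)
    result = PlaneSet(shape=(h, w), planes=planes)
    if close_boundary and planes:
        if surface_tol is None:
            surface_tol = d_threshold / 2.0
        result.boundary = _absorb_boundary(cloud, result, d_threshold, surface_tol, v)
    return result


def _absorb_boundary(
    cloud: OrganizedCloud,
    plane_set: PlaneSet,
    d_threshold: float,
    surface_tol: float,
    vertical: np.ndarray,
) -> np.ndarray:
    """Close the merged plane over pixels whose normals are unusable.

    A valid non-member pixel joins when it (a) is 4-adjacent to a member
    within ``d_threshold`` in 3D and (b) lies within ``surface_tol`` of the
    plane's surface along the vertical axis; iterated to closure.  This
    recovers the image-border ring and the one-pixel halo around object
    silhouettes, where the neighborhood cross product spans two surfaces.
    """
    height = cloud.points @ vertical
    pts = cloud.points.reshape(-1, 3)
    member_idx = np.concatenate(plane_set.planes)
    level = float(np.mean(height.reshape(-1)[member_idx]))
    eligible = cloud.valid & (np.abs(height - level) <= surface_tol)

    member = np.zeros(plane_set.shape, dtype=bool)
    member.flat[member_idx] = True
    frontier = member.copy()
    h, w = plane_set.shape
    shifts = ((0, 1), (0, -1), (1, 0), (-1, 0))
    absorbed = np.zeros_like(member)
    while frontier.any():
        new = np.zeros_like(member)
        for di, dj in shifts:
            i0, i1 = max(0, -di), min(h, h - di)
            j0, j1 = max(0, -dj), min(w, w - dj)
            a = np.s_[i0:i1, j0:j1]
            b = np.s_[i0 + di:i1 + di, j0 + dj:j1 + dj]
            dist = np.linalg.norm(cloud.points[a] - cloud.points[b], axis=2)
            ok = frontier[a] & eligible[b] & ~member[b] & (dist <= d_threshold)
            tgt = np.zeros_like(member)
            tgt[b] = ok
            new |= tgt & ~member
        member |= new
        absorbed |= new
        frontier = new
    return np.flatnonzero(absorbed.ravel())
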