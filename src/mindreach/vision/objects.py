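"""Candidate convex hulls, two-pass region-growing segmentation, and
object localization.

Pass 1 grows object regions from every non-plane point inside a candidate
convex hull (distance rule on 4-neighbors) and keeps regions of at least
``n_c_prime`` pixels.  Pass 2 re-grows from the region pixels that sit on
the hull boundary, this time allowed to recruit qualifying points *outside*
the hull, iterating to closure, so that object parts protruding past the
hull are recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint

from .cloud import OrganizedCloud
from .planes import DEFAULT_D_THRESHOLD, PlaneSet, neighbor_edges, VERTICAL

__all__ = [
    "ObjectSet",
    "object_hulls",
    "segment_objects",
    "locate",
]

DEFAULT_MIN_OBJECT = 50       # pixels (n'_C)

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ObjectSet:
    """Accepted object regions as disjoint flat pixel-index arrays."""

    shape: tuple[int, int]
    objects: list[np.ndarray]

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for idx in self.objects:
            m.flat[idx] = True
        return m

    @property
    def total(self) -> np.ndarray:
        """The merged set O of all object pixels (flat indices)."""
        if not self.objects:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(self.objects))


def _plane_height(cloud: OrganizedCloud, plane_set: PlaneSet, vertical: np.ndarray) -> float:
    pts = cloud.points.reshape(-1, 3)
    idx = np.concatenate(plane_set.planes)
    return float(np.mean(pts[idx] @ vertical))


def _off_plane_mask(
    cloud: OrganizedCloud,
    plane_set: PlaneSet,
    plane_margin: float,
    vertical: tuple[float, float, float],
) -> np.ndarray:
    """Valid pixels that are not in the plane set and (when a margin is
    given) clear the plane surface by more than ``plane_margin`` along the
    vertical axis.  The margin suppresses the thin halo of
    discontinuity-corrupted normals that hugs each object's base at plane
    height."""
    mask = cloud.valid & ~plane_set.mask
    if plane_margin > 0 and plane_set.planes:
        v = np.asarray(vertical, dtype=float)
        v = v / np.linalg.norm(v)
        height = cloud.points @ v
        mask &= np.abs(height - _plane_height(cloud, plane_set, v)) > plane_margin
    return mask


def _cover_mask(hull, shape: tuple[int, int]) -> np.ndarray:
    """Pixels covered by the hull polygon (boundary counts as inside)."""
    h, w = shape
    minx, miny, maxx, maxy = hull.bounds
    i0, i1 = max(0, int(np.floor(minx))), min(h - 1, int(np.ceil(maxx)))
    j0, j1 = max(0, int(np.floor(miny))), min(w - 1, int(np.ceil(maxy)))
    out = np.zeros(shape, dtype=bool)
    if i1 < i0 or j1 < j0:
        return out
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij")
    pts = shapely.points(ii.ravel().astype(float), jj.ravel().astype(float))
    out[ii.ravel(), jj.ravel()] = shapely.covers(hull, pts)
    return out


def object_hulls(
    plane_set: PlaneSet,
    cloud: OrganizedCloud,
    plane_margin: float = 0.0,
    vertical: tuple[float, float, float] = VERTICAL,
):
    """Convex hull (pixel space, (row, col) coordinates) of every connected
    component of off-plane pixels enclosed by the plane's footprint.

    Returns a list of shapely geometries (polygons; degenerate components
    give lines or points).
    """
    if not plane_set.planes:
        raise ValueError("empty plane set: extract the plane first")
    candidates = _off_plane_mask(cloud, plane_set, plane_margin, vertical)

    plane_pixels = np.argwhere(plane_set.mask)
    footprint = MultiPoint(plane_pixels[:, :2].astype(float)).convex_hull

    labels, n_comp = ndimage.label(candidates, structure=_FOUR_CONNECTED)
    hulls = []
    for comp_id in range(1, n_comp + 1):
        coords = np.argwhere(labels == comp_id).astype(float)
        geom = MultiPoint(coords).convex_hull
        if footprint.covers(geom):
            hulls.append(geom)
    return hulls


def _grow_outward(
    member: np.ndarray,
    seeds: np.ndarray,
    allowed: np.ndarray,
    points: np.ndarray,
    d_threshold: float,
) -> np.ndarray:
    """Frontier BFS from ``seeds``: recruit 4-neighbors in ``allowed`` within
    the distance threshold, iterating until no qualifying neighbor remains."""
    h, w = member.shape
    member = member.copy()
    frontier = seeds.copy()
    shifts = ((0, 1), (0, -1), (1, 0), (-1, 0))
    while frontier.any():
        new = np.zeros_like(member)
        for di, dj in shifts:
            i0, i1 = max(0, -di), min(h, h - di)
            j0, j1 = max(0, -dj), min(w, w - dj)
            a = np.s_[i0:i1, j0:j1]               # source pixel
            b = np.s_[i0 + di:i1 + di, j0 + dj:j1 + dj]   # its neighbor
            cand = frontier[a] & allowed[b] & ~member[b]
            dist = np.linalg.norm(points[a] - points[b], axis=2)
            ok = cand & (dist <= d_threshold)
            tgt = np.zeros_like(member)
            tgt[b] = ok
            new |= tgt & ~member
        member |= new
        frontier = new
    return member


def segment_objects(
    cloud: OrganizedCloud,
    plane_set: PlaneSet,
    hulls,
    d_threshold: float = DEFAULT_D_THRESHOLD,
    n_c_prime: int = DEFAULT_MIN_OBJECT,
    plane_margin: float = 0.0,
    vertical: tuple[float, float, float] = VERTICAL,
) -> ObjectSet:
    """Two-pass region growing inside (then past) each candidate hull.

    ``plane_margin`` optionally drops candidates within that height of the
    plane surface; with boundary closing in plane extraction the default of
    0 is appropriate.
    """
    off_plane = _off_plane_mask(cloud, plane_set, plane_margin, vertical)
    h, w = cloud.shape
    claimed = np.zeros((h, w), dtype=bool)
    objects: list[np.ndarray] = []

    for hull in hulls:
        inside = _cover_mask(hull, (h, w))
        nodes = inside & off_plane & ~claimed
        if not nodes.any():
            continue

        # pass 1: components of interior points under the distance rule
        src, dst = neighbor_edges(nodes, cloud.points, d_threshold)
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        graph = coo_matrix(
            (np.ones(src.size, dtype=np.int8), (src, dst)), shape=(h * w, h * w)
        )
        _, comp = connected_components(graph, directed=False)
        node_flat = np.flatnonzero(nodes.ravel())
        for comp_id in np.unique(comp[node_flat]):
            members_flat = node_flat[comp[node_flat] == comp_id]
            if members_flat.size < n_c_prime:
                continue
            member = np.zeros((h, w), dtype=bool)
            member.flat[members_flat] = True

            # pass 2: seeds on the hull boundary (a 4-neighbor leaves the
            # hull), growth may cross outside the hull
            outside = ~inside
            boundary = member & (
                np.roll(outside, 1, 0) | np.roll(outside, -1, 0)
                | np.roll(outside, 1, 1) | np.roll(outside, -1, 1)
            )
            if boundary.any():
                allowed = off_plane & ~claimed
                member = _grow_outward(
                    member, boundary, allowed, cloud.points, d_threshold
                )
            objects.append(np.flatnonzero(member.ravel()))
            claimed |= member

    objects.sort(key=lambda idx: -idx.size)
    return ObjectSet(shape=(h, w), objects=objects)


def locate(object_pixels: np.ndarray, cloud: OrganizedCloud) -> np.ndarray:
    """Camera-frame centroid: coordinate-wise mean of the member points."""
    idx = np.asarray(object_pixels)
    if idx.size == 0:
        raise ValueError("cannot locate an empty object point set")
    return cloud.points.reshape(-1, 3)[idx.ravel()].mean(axis=0)
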