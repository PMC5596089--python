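"""Synthetic tabletop scenes rendered by per-pixel ray casting.

Stands in for a depth camera: a pinhole model looks down at a horizontal
plane carrying cylinder- and box-shaped solids.  Every pixel's ray is
intersected with the plane and all solids; the nearest hit gives the 3D
point and the ground-truth label (``0`` plane, ``1..n`` the i-th object,
``-1`` no hit / invalid pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import OrganizedCloud

__all__ = ["CameraModel", "SceneObject", "SceneSpec", "synth_scene"]

_OBJECT_COLORS = (
    (0.85, 0.25, 0.2), (0.2, 0.45, 0.85), (0.95, 0.75, 0.1),
    (0.3, 0.7, 0.3), (0.6, 0.3, 0.7),
)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera on a (H, W) grid; +z is the optical axis."""

    height: int = 120
    width: int = 160
    f: float = 120.0                       # focal length in pixels
    cx: float | None = None                # principal point col (default center)
    cy: float | None = None                # principal point row

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2 or self.f <= 0:
            raise ValueError("degenerate camera: need H, W >= 2 and f > 0")

    def ray_dirs(self) -> np.ndarray:
        """H x W x 3 unnormalized ray directions with unit z component."""
        cx = (self.width - 1) / 2.0 if self.cx is None else self.cx
        cy = (self.height - 1) / 2.0 if self.cy is None else self.cy
        jj, ii = np.meshgrid(np.arange(self.width), np.arange(self.height))
        return np.dstack([(jj - cx) / self.f, (ii - cy) / self.f, np.ones_like(jj, float)])


@dataclass(frozen=True)
class SceneObject:
    """A solid resting on the plane.

    ``shape`` is ``cylinder`` (radius) or ``box`` (size = (sx, sy)); the
    object occupies depths ``plane_depth - height .. plane_depth`` along the
    camera z axis (it rises toward the camera).
    """

    shape: str
    center: tuple[float, float]            # (x, y) on the plane, camera frame
    height: float
    radius: float = 0.0
    size: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "box"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.height <= 0:
            raise ValueError("object height must be positive")
        if self.shape == "cylinder" and self.radius <= 0:
            raise ValueError("cylinder needs a positive radius")
        if self.shape == "box" and min(self.size) <= 0:
            raise ValueError("box needs positive side lengths")


@dataclass(frozen=True)
class SceneSpec:
    plane_depth: float = 1.0               # camera-to-table distance, m
    plane_extent: tuple[float, float] = (0.6, 0.45)   # half-sizes in x, y
    objects: tuple[SceneObject, ...] = ()
    noise_sd: float = 0.0                  # depth noise along the ray, m
    seed: int = 0
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        if self.plane_depth <= 0 or self.noise_sd < 0:
            raise ValueError("plane_depth must be > 0 and noise_sd >= 0")
        ex, ey = self.plane_extent
        for obj in self.objects:
            x, y = obj.center
            if abs(x) > ex or abs(y) > ey:
                raise ValueError(f"object at {obj.center} lies outside the plane extent")
            if obj.height >= self.plane_depth:
                raise ValueError("object taller than the camera distance")


def _hit_plane(dirs: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Ray parameter t (= depth, unit-z rays) of the plane hit, NaN if the
    hit lands outside the table extent."""
    t = np.full(dirs.shape[:2], spec.plane_depth)
    x = t * dirs[..., 0]
    y = t * dirs[..., 1]
    ex, ey = spec.plane_extent
    t[(np.abs(x) > ex) | (np.abs(y) > ey)] = np.nan
    return t


def _hit_cylinder(dirs: np.ndarray, obj: SceneObject, z0: float) -> np.ndarray:
    cx, cy = obj.center
    z_top, z_bot = z0 - obj.height, z0
    dx, dy = dirs[..., 0], dirs[..., 1]
    t = np.full(dirs.shape[:2], np.nan)

    # top cap
    t_cap = np.full_like(t, z_top)
    hit = (t_cap * dx - cx) ** 2 + (t_cap * dy - cy) ** 2 <= obj.radius**2
    t[hit] = z_top

    # lateral surface: |(t dx - cx, t dy - cy)| = r, smallest valid root
    a = dx**2 + dy**2
    b = -2.0 * (dx * cx + dy * cy)
    c = cx**2 + cy**2 - obj.radius**2
    disc = b**2 - 4 * a * c
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        for root in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
            ok = np.isfinite(root) & (root >= z_top) & (root <= z_bot)
            t = np.where(ok & (~np.isfinite(t) | (root < t)), root, t)
    return t


def _hit_box(dirs: np.ndarray, obj: SceneObject, z0: float) -> np.ndarray:
    cx, cy = obj.center
    sx, sy = obj.size
    lo = np.array([cx - sx / 2, cy - sy / 2, z0 - obj.height])
    hi = np.array([cx + sx / 2, cy + sy / 2, z0])
    t_near = np.zeros(dirs.shape[:2])
    t_far = np.full(dirs.shape[:2], np.inf)
    for axis in range(3):
        d = dirs[..., axis]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(d != 0, lo[axis] / d, np.where(lo[axis] <= 0, -np.inf, np.inf))
            t2 = np.where(d != 0, hi[axis] / d, np.where(hi[axis] >= 0, np.inf, -np.inf))
        t_near = np.maximum(t_near, np.minimum(t1, t2))
        t_far = np.minimum(t_far, np.maximum(t1, t2))
    t = np.where(t_near <= t_far, t_near, np.nan)
    return t


def synth_scene(spec: SceneSpec) -> tuple[OrganizedCloud, np.ndarray]:
    """Render the scene.

    Returns the organized cloud and the H x W ground-truth label grid
    (``-1`` invalid, ``0`` plane, ``i`` the i-th object, 1-based).
    Depth noise perturbs the ray parameter, so points move along their
    viewing ray; labels are from the noiseless geometry.
    """
    rng = np.random.default_rng(spec.seed)
    dirs = spec.camera.ray_dirs()
    h, w = dirs.shape[:2]

    t_best = _hit_plane(dirs, spec)
    labels = np.where(np.isfinite(t_best), 0, -1)
    for idx, obj in enumerate(spec.objects, start=1):
        t_obj = (_hit_cylinder if obj.shape == "cylinder" else _hit_box)(
            dirs, obj, spec.plane_depth
        )
        closer = np.isfinite(t_obj) & (~np.isfinite(t_best) | (t_obj < t_best))
        t_best = np.where(closer, t_obj, t_best)
        labels = np.where(closer, idx, labels)

    if spec.noise_sd > 0:
        t_best = t_best + rng.normal(0.0, spec.noise_sd, t_best.shape)

    valid = np.isfinite(t_best)
    points = np.where(valid[..., None], t_best[..., None] * dirs, 0.0)

    rgb = np.full((h, w, 3), 0.55)
    for idx in range(1, len(spec.objects) + 1):
        rgb[labels == idx] = _OBJECT_COLORS[(idx - 1) % len(_OBJECT_COLORS)]
    rgb[~valid] = 0.0

    return OrganizedCloud(points=points, valid=valid, rgb=rgb), labels
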