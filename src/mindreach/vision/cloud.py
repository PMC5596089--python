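"""Organized point clouds and per-pixel normal estimation.

Conventions (used throughout the vision stack):

* pixel coordinates are ``(row, col)``, 0-based;
* 3D points are in the camera frame, meters, with +z pointing away from the
  camera along the optical axis;
* the scene "vertical" (gravity) axis is a configuration item; with the
  default top-down camera it is the camera z axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["OrganizedCloud", "normals"]


@dataclass
class OrganizedCloud:
    """H x W grid of camera-frame 3D points with a validity mask.

    The grid preserves the pixel <-> point correspondence of the depth
    sensor: ``points[i, j]`` is the 3D point seen by pixel ``(i, j)``.
    """

    points: np.ndarray                  # H x W x 3, float
    valid: np.ndarray                   # H x W bool
    rgb: np.ndarray | None = None       # H x W x 3, float in [0, 1]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must be an H x W x 3 array")
        if self.valid.shape != self.points.shape[:2]:
            raise ValueError("validity mask shape must match the point grid")
        if self.rgb is not None and self.rgb.shape[:2] != self.points.shape[:2]:
            raise ValueError("rgb shape must match the point grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.points.shape[:2]

    def point(self, pixel: tuple[int, int]) -> np.ndarray:
        return self.points[pixel[0], pixel[1]]

    # -- raw text I/O: H x W x 3 grid + mask, diff-able -------------------

    def write(self, base: str | Path) -> Path:
        base = Path(base)
        base.parent.mkdir(parents=True, exist_ok=True)
        h, w = self.shape
        with open(base, "w") as fh:
            fh.write(f"# organized-cloud {h} {w}\n")
            flat = np.column_stack(
                [self.points.reshape(-1, 3), self.valid.reshape(-1, 1)]
            )
            np.savetxt(fh, flat, fmt="%.17g", delimiter="\t")
        return base

    @classmethod
    def read(cls, base: str | Path) -> "OrganizedCloud":
        base = Path(base)
        with open(base) as fh:
            header = fh.readline().split()
            if header[:1] != ["#"] or header[1] != "organized-cloud":
                raise ValueError(f"{base}: not an organized-cloud file")
            h, w = int(header[2]), int(header[3])
            flat = np.loadtxt(fh, delimiter="\t", ndmin=2)
        if flat.shape != (h * w, 4):
            raise ValueError(f"{base}: expected {h * w} rows of 4 columns")
        return cls(
            points=flat[:, :3].reshape(h, w, 3),
            valid=flat[:, 3].reshape(h, w).astype(bool),
        )


def normals(cloud: OrganizedCloud, depth_jump: float | None = None) -> np.ndarray:
    """Per-pixel unit normals from the 4-neighborhood cross product.

    For pixel P at (i, j) with grid neighbors P1=(i, j-1), P2=(i+1, j),
    P3=(i, j+1), P4=(i-1, j):

        v = (P1 - P3) x (P2 - P4),  normalized to unit length.

    Border pixels, pixels with an invalid neighbor, and (optionally) pixels
    whose neighborhood spans a depth discontinuity larger than
    ``depth_jump`` meters get NaN normals.
    """
    pts = cloud.points
    h, w = cloud.shape
    out = np.full((h, w, 3), np.nan)
    if h < 3 or w < 3:
        return out

    p1 = pts[1:-1, :-2]    # (i, j-1)
    p2 = pts[2:, 1:-1]     # (i+1, j)
    p3 = pts[1:-1, 2:]     # (i, j+1)
    p4 = pts[:-2, 1:-1]    # (i-1, j)
    v = np.cross(p1 - p3, p2 - p4)
    norm = np.linalg.norm(v, axis=2)

    ok = (
        cloud.valid[1:-1, 1:-1]
        & cloud.valid[1:-1, :-2] & cloud.valid[2:, 1:-1]
        & cloud.valid[1:-1, 2:] & cloud.valid[:-2, 1:-1]
        & (norm > 0)
    )
    if depth_jump is not None:
        z = pts[..., 2]
        zc = z[1:-1, 1:-1]
        for zn in (z[1:-1, :-2], z[2:, 1:-1], z[1:-1, 2:], z[:-2, 1:-1]):
            ok &= np.abs(zn - zc) <= depth_jump

    with np.errstate(invalid="ignore"):
        unit = v / norm[..., None]
    out[1:-1, 1:-1][ok] = unit[ok]
    return out
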