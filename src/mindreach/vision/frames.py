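"""Rigid coordinate transforms between camera, calibration-board and robot
frames, applied homogeneously: p' = R p + T.

A calibration file is a JSON object with an ``edges`` list; each edge names
its ``from`` and ``to`` frames and carries a row-major rotation ``R`` and a
translation ``T``.  Transforms between any two frames connected in the edge
graph are found by composing (and inverting) edges along the path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RigidTransform", "load_calibration", "FrameGraph"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    R: np.ndarray                 # 3x3 rotation
    T: np.ndarray                 # 3-vector translation
    from_frame: str = ""
    to_frame: str = ""

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        T = np.asarray(self.T, dtype=float).ravel()
        if R.shape != (3, 3) or T.shape != (3,):
            raise ValueError("R must be 3x3 and T a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("R is not orthonormal (R^T R != I)")
        if np.linalg.det(R) < 0:
            raise ValueError("R is a reflection (det R = -1), not a rotation")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)

    @classmethod
    def identity(cls, frame: str = "") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), frame, frame)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point (3,) or a stack (N, 3) into the target frame."""
        p = np.asarray(points, dtype=float)
        if p.shape == (3,):
            return self.R @ p + self.T
        if p.ndim == 2 and p.shape[1] == 3:
            return p @ self.R.T + self.T
        raise ValueError("expected a 3-vector or an N x 3 array")

    def invert(self) -> "RigidTransform":
        """The inverse mapping p = R^T (p' - T)."""
        return RigidTransform(
            self.R.T, -self.R.T @ self.T, self.to_frame, self.from_frame
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``
        (matrix-product order), checking frame labels when both are set."""
        if self.from_frame and other.to_frame and self.from_frame != other.to_frame:
            raise ValueError(
                f"cannot chain {other.from_frame}->{other.to_frame} into "
                f"{self.from_frame}->{self.to_frame}"
            )
        return RigidTransform(
            self.R @ other.R,
            self.R @ other.T + self.T,
            other.from_frame,
            self.to_frame,
        )

    def as_matrix(self) -> np.ndarray:
        """The homogeneous 4x4 matrix [[R, T], [0, 1]]."""
        H = np.eye(4)
        H[:3, :3] = self.R
        H[:3, 3] = self.T
        return H

    @classmethod
    def from_matrix(
        cls, H: np.ndarray, from_frame: str = "", to_frame: str = ""
    ) -> "RigidTransform":
        H = np.asarray(H, dtype=float)
        if H.shape != (4, 4) or not np.allclose(H[3], [0, 0, 0, 1], atol=_ORTHO_TOL):
            raise ValueError("expected a homogeneous 4x4 rigid matrix")
        return cls(H[:3, :3], H[:3, 3], from_frame, to_frame)


class FrameGraph:
    """Named frames connected by calibrated rigid transforms."""

    def __init__(self, edges: list[RigidTransform]):
        self._adj: dict[str, list[RigidTransform]] = {}
        for e in edges:
            if not e.from_frame or not e.to_frame:
                raise ValueError("graph edges need frame labels")
            self._adj.setdefault(e.from_frame, []).append(e)
            self._adj.setdefault(e.to_frame, []).append(e.invert())

    @property
    def frames(self) -> list[str]:
        return sorted(self._adj)

    def transform(self, from_frame: str, to_frame: str) -> RigidTransform:
        """Composed transform along the (BFS) path between two frames."""
        if from_frame not in self._adj or to_frame not in self._adj:
            missing = from_frame if from_frame not in self._adj else to_frame
            raise KeyError(f"unknown frame {missing!r}; have {self.frames}")
        if from_frame == to_frame:
            return RigidTransform.identity(from_frame)
        queue = [(from_frame, RigidTransform.identity(from_frame))]
        seen = {from_frame}
        while queue:
            frame, acc = queue.pop(0)
            for edge in self._adj[frame]:
                if edge.from_frame != frame or edge.to_frame in seen:
                    continue
                nxt = edge.compose(acc)
                if edge.to_frame == to_frame:
                    return nxt
                seen.add(edge.to_frame)
                queue.append((edge.to_frame, nxt))
        raise KeyError(f"frames {from_frame!r} and {to_frame!r} are not connected")


def load_calibration(path: str | Path) -> FrameGraph:
    with open(path) as fh:
        doc = json.load(fh)
    edges = [
        RigidTransform(
            np.asarray(e["R"], dtype=float),
            np.asarray(e["T"], dtype=float),
            e["from"],
            e["to"],
        )
        for e in doc["edges"]
    ]
    return FrameGraph(edges)
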