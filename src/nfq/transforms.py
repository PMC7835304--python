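"""World-space rigid and affine transforms between modality frames.

Conventions: transforms map source-world mm to destination-world mm and are
stored as a linear part plus translation. Rigid transforms keep a proper
rotation (R^T R = I, det R = +1) to machine precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "AffineTransform", "random_rigid", "load_transform"]

_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has det < 0 (reflection)")
        # re-orthonormalize so repeated composition cannot drift
        u, _, vt = np.linalg.svd(self.rotation)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        self.rotation = r

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler_deg(
        cls, angles_deg=(0.0, 0.0, 0.0), translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Intrinsic x-y-z Euler rotation (degrees) plus translation (mm)."""
        ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(rotation=rz @ ry @ rx, translation=np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other — apply ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(rotation=m[:3, :3], translation=m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (degrees) via the trace identity."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path) -> None:
        _dump_matrix(self.as_matrix(), "rigid", path)


@dataclass
class AffineTransform:
    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(
            matrix=self.matrix @ other.matrix,
            translation=self.matrix @ other.translation + self.translation,
        )

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(matrix=inv, translation=-inv @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.matrix
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, dtype=float)
        return cls(matrix=m[:3, :3], translation=m[:3, 3])

    def to_json(self, path) -> None:
        _dump_matrix(self.as_matrix(), "affine", path)


def random_rigid(
    rng: np.random.Generator, max_rotation_deg: float = 10.0, max_translation_mm: float = 2.0
) -> RigidTransform:
    """Uniform random rotation axis, bounded angle and translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(rotation=rot, translation=t)


def _dump_matrix(m: np.ndarray, kind: str, path) -> None:
    with open(path, "w") as fh:
        json.dump({"kind": kind, "matrix": m.tolist()}, fh, indent=2)


def load_transform(path) -> RigidTransform | AffineTransform:
    with open(path) as fh:
        payload = json.load(fh)
    m = np.asarray(payload["matrix"], dtype=float)
    if payload.get("kind") == "rigid":
        return RigidTransform.from_matrix(m)
    return AffineTransform.from_matrix(m)
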