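"""Landmark-based co-registration and resampling.

The MRI-to-PET/CT step is a fiducial-landmark rigid fit: six paired skull
landmarks (eyes, mandibular condyles, cochleae) are identified in both
frames and the rigid transform minimizing the RMS distance between the
paired points is computed in closed form (Kabsch: centroid alignment + SVD
of the cross-covariance, with a reflection guard). Normalization of each
animal to the atlas frame uses the same landmarks with a 12-parameter
least-squares affine. Volumes are then resampled onto a reference grid with
trilinear (images) or nearest-neighbour (labels) interpolation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateGeometryError
from .transforms import AffineTransform, RigidTransform
from .volume import Volume3D

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet",
    "estimate_rigid",
    "estimate_affine",
    "resample",
]

#: Canonical fiducial set: paired eyes, mandibular condyles and cochleae.
LANDMARK_NAMES = (
    "eye_L",
    "eye_R",
    "condyle_L",
    "condyle_R",
    "cochlea_L",
    "cochlea_R",
)


@dataclass
class LandmarkSet:
    """Named fiducial points in world mm."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.points = {
            str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()
        }
        if len(self.points) == 0:
            raise ValueError("LandmarkSet requires at least one point")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.points.keys())

    def as_array(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        order = order if order is not None else self.names
        return np.stack([self.points[n] for n in order])

    def transformed(self, transform) -> "LandmarkSet":
        return LandmarkSet({n: transform.apply(p) for n, p in self.points.items()})

    def jittered(self, rng: np.random.Generator, sd_mm: float) -> "LandmarkSet":
        return LandmarkSet(
            {n: p + rng.normal(0.0, sd_mm, size=3) for n, p in self.points.items()}
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x", "y", "z"])
            for n, p in self.points.items():
                w.writerow([n, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        pts: dict[str, np.ndarray] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                pts[row["name"]] = np.array(
                    [float(row["x"]), float(row["y"]), float(row["z"])]
                )
        return cls(pts)


def _paired_arrays(src: LandmarkSet, dst: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    if set(src.names) != set(dst.names):
        missing = set(src.names).symmetric_difference(dst.names)
        raise ValueError(f"landmark names do not match between sets: {sorted(missing)}")
    order = tuple(sorted(src.names))
    return src.as_array(order), dst.as_array(order)


def estimate_rigid(src: LandmarkSet, dst: LandmarkSet) -> tuple[RigidTransform, float]:
    """Closed-form least-RMS rigid fit mapping ``src`` points onto ``dst``.

    Returns the transform and the post-fit residual RMS in mm. The SVD
    solution is the unique minimizer of the RMS point distance over proper
    rotations; a reflection guard flips the smallest singular vector when
    the raw solution has negative determinant.
    """
    a, b = _paired_arrays(src, dst)
    if len(a) < 3:
        raise DegenerateGeometryError("rigid fit requires at least 3 paired landmarks")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    # rank < 2 after centering: points (nearly) collinear, rotation about the
    # line is unconstrained
    scale = max(np.linalg.norm(a0), 1.0)
    if np.sum(s > 1e-9 * scale) < 2:
        raise DegenerateGeometryError("landmarks are collinear; rigid fit is degenerate")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = cb - rot @ ca
    xfm = RigidTransform(rotation=rot, translation=t)
    resid = xfm.apply(a) - b
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return xfm, rms


def estimate_affine(src: LandmarkSet, dst: LandmarkSet) -> tuple[AffineTransform, float]:
    """Ordinary least-squares 12-parameter affine fit (exact when ``dst`` is
    an affine image of ``src``). Requires >= 4 non-coplanar points."""
    a, b = _paired_arrays(src, dst)
    if len(a) < 4:
        raise DegenerateGeometryError("affine fit requires at least 4 landmarks")
    design = np.hstack([a, np.ones((len(a), 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(np.abs(a).max(), 1.0)) < 4:
        raise DegenerateGeometryError("landmarks are coplanar; affine fit is rank-deficient")
    coef, *_ = np.linalg.lstsq(design, b, rcond=None)
    xfm = AffineTransform(matrix=coef[:3].T, translation=coef[3])
    resid = xfm.apply(a) - b
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return xfm, rms


def resample(
    volume: Volume3D,
    transform,
    reference: Volume3D,
    interpolation: str = "trilinear",
    cval: float = 0.0,
) -> Volume3D:
    """Resample ``volume`` onto the grid of ``reference``.

    ``transform`` maps source-volume world coordinates into the reference
    world frame. Out-of-field voxels are filled with ``cval`` (0 =
    background). ``nearest`` must be used for label volumes so the label set
    is preserved.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError("interpolation must be 'trilinear' or 'nearest'")
    order = 1 if interpolation == "trilinear" else 0
    # reference voxel -> reference world -> source world -> source voxel
    m = (
        np.linalg.inv(volume.affine)
        @ np.linalg.inv(transform.as_matrix())
        @ reference.affine
    )
    # 1e-12 voxel is far below registration precision; rounding keeps
    # near-identity maps from pushing border voxels out of the grid
    m = np.round(m, 12)
    out = ndimage.affine_transform(
        volume.data.astype(float) if order else volume.data,
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=cval,
        prefilter=False,
    )
    if order == 0:
        out = out.astype(volume.data.dtype)
    return Volume3D(data=out, affine=reference.affine.copy(), units=volume.units)
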