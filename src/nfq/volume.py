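"""Volumetric image container.

A :class:`Volume3D` is a plain voxel grid plus a 4x4 voxel-to-world affine
(RAS, mm — the NIfTI convention) and a free-text unit tag. nibabel handles
all on-disk NIfTI-1 I/O; this class only carries the in-memory pairing of
data and geometry that every pipeline stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "DynamicPET"]


@dataclass
class Volume3D:
    """3D voxel grid with world geometry.

    Parameters
    ----------
    data:
        3D array of voxel values.
    affine:
        4x4 voxel-index -> world-mm mapping (RAS).
    units:
        Free-text unit tag, e.g. ``"MBq/cm3"`` or ``"a.u."``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel indices to (N,3) world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def copy(self, data: np.ndarray | None = None) -> "Volume3D":
        return Volume3D(
            data=self.data.copy() if data is None else np.asarray(data),
            affine=self.affine.copy(),
            units=self.units,
        )

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data), self.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, units: str = "") -> "Volume3D":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.dataobj), affine=img.affine, units=units)


@dataclass
class DynamicPET:
    """Ordered, timed PET frames with the metadata needed for SUV conversion.

    Frames are activity-concentration volumes (MBq/cm^3) on a shared grid;
    ``frame_times`` are (start, end) minutes post-injection, non-overlapping
    and increasing.
    """

    frames: list[Volume3D]
    frame_times: list[tuple[float, float]]
    dose_MBq: float
    weight_g: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("DynamicPET requires at least one frame")
        if len(self.frames) != len(self.frame_times):
            raise ValueError("one (start, end) interval required per frame")
        if self.dose_MBq <= 0 or self.weight_g <= 0:
            raise ValueError("dose_MBq and weight_g must be positive")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != ref.shape or not np.allclose(f.affine, ref.affine):
                raise ValueError("all frames must share grid and affine")
        prev_end = -np.inf
        for t0, t1 in self.frame_times:
            if t1 <= t0:
                raise ValueError(f"frame interval ({t0}, {t1}) is not increasing")
            if t0 < prev_end:
                raise ValueError("frame intervals overlap")
            prev_end = t1

    @property
    def affine(self) -> np.ndarray:
        return self.frames[0].affine

    @property
    def acquisition_window_min(self) -> tuple[float, float]:
        return self.frame_times[0][0], self.frame_times[-1][1]

    def as_4d(self) -> np.ndarray:
        return np.stack([f.data for f in self.frames], axis=-1)

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.as_4d(), self.affine)
        nib.save(img, str(path))
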