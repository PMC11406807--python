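"""Core value types shared across the pipeline.

Axis convention (fixed for the whole package): arrays are indexed ``(z, y, x)``
with ``z`` the rostrocaudal stack axis; the physical coordinate of a voxel is
``index * voxel_size_mm`` (isotropic voxels, 0-based indices).  Point clouds
derived from masks therefore carry ``(z, y, x)`` coordinates in mm.  Landmark
configurations read from fiducial files keep the file's ``(x, y, z)`` column
order; shape analysis is order-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "PointCloud",
    "LandmarkConfiguration",
    "RigidTransform",
    "MorphometryReport",
]


@dataclass
class VolumeImage:
    """A 3D grayscale grid with isotropic physical voxel size.

    Parameters
    ----------
    voxels : ndarray, shape (Z, Y, X)
        Intensity values (arbitrary units).  Stored as floating point.
    voxel_size_mm : float
        Physical edge length of one voxel, in mm.  Must be positive.
    """

    voxels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.voxels.shape}")
        if not (self.voxel_size_mm > 0):
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        if not np.issubdtype(self.voxels.dtype, np.floating):
            self.voxels = self.voxels.astype(np.float64)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryMask:
    """A 3D boolean grid sharing the geometry of a :class:`VolumeImage`."""

    voxels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if not (self.voxel_size_mm > 0):
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        if self.voxels.dtype != bool:
            self.voxels = self.voxels.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(np.count_nonzero(self.voxels))

    def same_geometry(self, other: "BinaryMask | VolumeImage") -> bool:
        return self.shape == other.shape and np.isclose(
            self.voxel_size_mm, other.voxel_size_mm
        )


@dataclass
class PointCloud:
    """An ordered set of 3D points in physical ``(z, y, x)`` mm coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class LandmarkConfiguration:
    """Ordered, labeled landmark points for one sample.

    ``points`` is a ``(K, 3)`` array in mm; the row order is the anatomical
    correspondence across samples and must not be permuted.
    """

    points: np.ndarray
    label: str = ""
    point_labels: Optional[list[str]] = None
    coordinate_system: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (K, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("a landmark configuration needs at least 1 point")
        # shape analysis additionally requires K >= 3; enforced by the gpa module
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.point_labels is not None and len(self.point_labels) != len(self):
            raise ValueError("point_labels length must match number of points")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t`` in mm coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal (R^T R = I within 1e-8)")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1 within 1e-8)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# Column order is the on-disk CSV contract of write_report().
@dataclass
class MorphometryReport:
    """The per-sample morphometric criterion panel."""

    sample: str = ""
    volume_mm3: float = float("nan")
    surface_area_mm2: float = float("nan")
    outgrowth_angle_deg: float = float("nan")
    ventricle_volume_mm3: float = float("nan")
    proportion: float = float("nan")
    rostral_volume_mm3: float = float("nan")
    caudal_volume_mm3: float = float("nan")
    left_length_mm: float = float("nan")
    right_length_mm: float = float("nan")
    left_angle_deg: float = float("nan")
    right_angle_deg: float = float("nan")
    central_length_mm: float = float("nan")
    total_length_mm: float = float("nan")
    ventricle_length_mm: float = float("nan")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]
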