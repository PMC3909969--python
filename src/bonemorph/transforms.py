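"""Spatial transforms: rigid, affine, and dense displacement fields.

Transforms act on world-mm points (``apply``), compose (``compose``:
``a.compose(b)`` applies ``b`` first, then ``a``), and serialise as
plain-text 4x4 homogeneous matrices.  A :class:`DisplacementField` stores a
per-voxel world-mm vector on the geometry of a fixed image; evaluating it
at an arbitrary world point uses trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import ImageGrid, world_to_voxel

__all__ = ["RigidTransform", "AffineTransform", "DisplacementField"]


@dataclass
class AffineTransform:
    """x -> linear @ x + translation, with invertible linear part."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("singular linear part")

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.linear.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform applying ``other`` first, then ``self``."""
        cls = type(self) if type(self) is type(other) else AffineTransform
        return cls(self.linear @ other.linear,
                   self.linear @ other.translation + self.translation)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return type(self)(inv, -inv @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "AffineTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def save(self, path) -> str:
        np.savetxt(path, self.matrix, fmt="%.17g")
        return str(path)

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls.from_matrix(np.loadtxt(path))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


class RigidTransform(AffineTransform):
    """Rotation (orthonormal, det +1) plus translation."""

    def __post_init__(self):
        super().__post_init__()
        if not np.allclose(self.linear @ self.linear.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.linear) < 0:
            raise ValueError("rotation must have determinant +1 (no reflection)")

    @property
    def rotation(self) -> np.ndarray:
        return self.linear

    @classmethod
    def from_euler(cls, angles_deg, translation=(0.0, 0.0, 0.0),
                   center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation from extrinsic x-y-z Euler angles (degrees) about
        ``center``, then translation: x -> R (x - c) + c + t."""
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", np.asarray(angles_deg, float),
                                  degrees=True).as_matrix()
        c = np.asarray(center, float)
        t = np.asarray(translation, float) + c - rot @ c
        return cls(rot, t)


@dataclass
class DisplacementField:
    """Dense per-voxel world-mm displacement vectors on a fixed-image grid.

    ``vectors`` has shape ``(nx, ny, nz, 3)``.  The field maps fixed-space
    world points into moving space: ``T(x) = x + u(x)``.
    """

    geometry: ImageGrid  # geometry carrier; intensities ignored
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.geometry.shape + (3,):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match grid "
                f"shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")

    def interpolate(self, points, outside_tol_voxels: float = 1.0) -> np.ndarray:
        """Trilinearly interpolate the field at world-mm ``points``.

        Points outside the lattice by more than ``outside_tol_voxels``
        raise; points in the tolerance band are clamped to the border.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        idx = world_to_voxel(self.geometry, points)
        upper = np.array(self.geometry.shape) - 1
        outside = np.any((idx < -outside_tol_voxels)
                         | (idx > upper + outside_tol_voxels), axis=1)
        if np.any(outside):
            raise ValueError(
                f"{int(outside.sum())} point(s) lie more than "
                f"{outside_tol_voxels} voxel(s) outside the field support"
            )
        idx = np.clip(idx, 0.0, upper)
        coords = idx.T  # (3, n)
        out = np.empty((points.shape[0], 3))
        for c in range(3):
            out[:, c] = map_coordinates(self.vectors[..., c], coords,
                                        order=1, mode="nearest")
        return out

    def apply(self, points) -> np.ndarray:
        """Forward map fixed-space points into moving space."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points + self.interpolate(points)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)
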