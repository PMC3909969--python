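"""Volumetric image data model, NIfTI/NRRD I/O, and coordinate conventions.

An :class:`ImageGrid` is a dense 3-D scalar lattice together with the
geometry that places it in world space: voxel spacing (mm per axis), the
world position of voxel index ``(0, 0, 0)`` (the origin), and a 3x3
orthonormal direction matrix whose columns are the world directions of the
three index axes.  Indices are 0-based and node-centred: the world position
of an (possibly fractional) index ``i`` is exactly

    world = origin + direction @ (spacing * i)

so the index-to-world map is affine.  All world coordinates are in mm.
Arrays are indexed ``[i, j, k]`` along the x/y/z index axes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageGrid",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
    "resample",
]

MM3_PER_CM3 = 1000.0


def _as_geometry(spacing, origin, direction):
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    direction = np.asarray(direction, dtype=float).reshape(3, 3)
    return spacing, origin, direction


@dataclass
class ImageGrid:
    """A 3-D scalar lattice with world-space geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units, indexed ``[i, j, k]``.
    spacing : (3,) float
        Voxel spacing in mm per index axis; strictly positive.
    origin : (3,) float
        World coordinate (mm) of voxel index (0, 0, 0).
    direction : (3, 3) float
        Orthonormal matrix, determinant +1; columns are the world
        directions of the index axes.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"ImageGrid requires a 3-D lattice, got {self.data.ndim}-D"
            )
        if min(self.data.shape) < 1:
            raise ValueError("lattice must have at least 1 voxel per axis")
        self.spacing, self.origin, self.direction = _as_geometry(
            self.spacing, self.origin, self.direction
        )
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-8):
            raise ValueError("direction matrix must be orthonormal")
        if np.linalg.det(self.direction) < 0:
            raise ValueError("direction matrix must have determinant +1")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "ImageGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "ImageGrid":
        """New grid with identical geometry and replaced intensities."""
        return replace(self, data=np.asarray(data))


class BinaryMask(ImageGrid):
    """A boolean lattice sharing the geometry of its source :class:`ImageGrid`."""

    def __post_init__(self):
        super().__post_init__()
        self.data = self.data.astype(bool)

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(
            np.asarray(data), self.spacing.copy(), self.origin.copy(),
            self.direction.copy(),
        )


# ---------------------------------------------------------------------------
# coordinate mapping

def voxel_to_world(grid: ImageGrid, index) -> np.ndarray:
    """Map (fractional, possibly out-of-bounds) voxel indices to world mm.

    Accepts a single 3-vector or an (n, 3) array.
    """
    index = np.asarray(index, dtype=float)
    return grid.origin + (index * grid.spacing) @ grid.direction.T


def world_to_voxel(grid: ImageGrid, world) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`."""
    world = np.asarray(world, dtype=float)
    return ((world - grid.origin) @ grid.direction) / grid.spacing


# ---------------------------------------------------------------------------
# SimpleITK bridge (internal)

def to_sitk(grid: ImageGrid) -> sitk.Image:
    # sitk arrays are indexed [z, y, x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    img.SetDirection(tuple(grid.direction.flatten()))
    return img


def from_sitk(img: sitk.Image, cls=ImageGrid) -> ImageGrid:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return cls(
        data,
        np.array(img.GetSpacing()),
        np.array(img.GetOrigin()),
        np.array(img.GetDirection()).reshape(3, 3),
    )


_FORMAT_EXT = {"nifti": (".nii", ".nii.gz"), "nrrd": (".nrrd",)}


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        return "nifti"
    if p.endswith(".nrrd"):
        return "nrrd"
    raise ValueError(f"cannot infer volume format from path {path!r}")


def read_volume(path, format: str | None = None) -> ImageGrid:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume.

    Geometry metadata (spacing, origin, direction) is preserved losslessly
    and intensities are returned unchanged.  Raises ``FileNotFoundError``
    for a missing file and ``ValueError`` for non-3-D images.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMAT_EXT:
        raise ValueError(f"unsupported format {fmt!r}; expected 'nifti' or 'nrrd'")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # malformed header
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(
            f"expected a 3-D volume, got {img.GetDimension()}-D: {path}"
        )
    return from_sitk(img)


def write_volume(grid: ImageGrid, path, format: str | None = None) -> str:
    """Write a volume as NIfTI or NRRD; round-trips through
    :func:`read_volume` bit-compatibly for integer types."""
    fmt = format or _infer_format(path)
    if fmt not in _FORMAT_EXT:
        raise ValueError(f"unsupported format {fmt!r}; expected 'nifti' or 'nrrd'")
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
        grid = ImageGrid(data, grid.spacing, grid.origin, grid.direction)
    sitk.WriteImage(to_sitk(grid), str(path))
    return str(path)


# ---------------------------------------------------------------------------
# resampling

_INTERP = {"nearest": sitk.sitkNearestNeighbor, "linear": sitk.sitkLinear}


def resample(
    grid: ImageGrid,
    shape,
    spacing,
    origin=None,
    direction=None,
    interpolation: str = "linear",
    default_value: float = 0.0,
) -> ImageGrid:
    """Resample onto a target geometry by world-space interpolation.

    The output carries the target geometry exactly; intensities are
    interpolated in world space (``nearest`` or ``linear``).  A
    :class:`BinaryMask` resampled with ``nearest`` stays boolean.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise ValueError(f"target spacing must be positive, got {spacing}")
    shape = tuple(int(s) for s in shape)
    if min(shape) < 1:
        raise ValueError(f"degenerate target shape {shape}")
    origin = grid.origin if origin is None else np.asarray(origin, float)
    direction = grid.direction if direction is None else np.asarray(direction, float)
    if interpolation not in _INTERP:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    is_mask = isinstance(grid, BinaryMask)
    src = to_sitk(grid if not is_mask else ImageGrid(
        grid.data.astype(np.uint8), grid.spacing, grid.origin, grid.direction))
    out = sitk.Resample(
        src,
        size=[shape[0], shape[1], shape[2]],
        transform=sitk.Transform(),
        interpolator=_INTERP[interpolation],
        outputOrigin=tuple(origin),
        outputSpacing=tuple(spacing),
        outputDirection=tuple(np.asarray(direction).flatten()),
        defaultPixelValue=default_value,
    )
    result = from_sitk(out)
    if is_mask and interpolation == "nearest":
        return BinaryMask(result.data.astype(bool), result.spacing,
                          result.origin, result.direction)
    return result
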