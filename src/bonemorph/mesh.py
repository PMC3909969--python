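"""Isosurface extraction and triangle-mesh geometry.

Surfaces are extracted with the marching-cubes isosurface algorithm
(Lorensen-Cline family) and carried as a :class:`TriangleMesh` in world mm
with consistent outward orientation.  Volume is computed by the divergence
theorem on the closed mesh (signed tetrahedra to the origin) and reported
in cm^3.  Binary masks are Gaussian-smoothed before extraction to remove
the voxel staircase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from skimage import measure

from .grid import MM3_PER_CM3, BinaryMask, ImageGrid, voxel_to_world
from .transforms import AffineTransform

__all__ = [
    "TriangleMesh",
    "extract_surface",
    "mesh_volume",
    "vertex_normals",
    "transform_mesh",
    "read_mesh",
    "write_mesh",
]


@dataclass
class TriangleMesh:
    """Triangle surface in world mm with optional per-vertex scalars."""

    vertices: np.ndarray  # (nv, 3) float, mm
    faces: np.ndarray  # (nf, 3) int, consistent winding
    scalars: dict = field(default_factory=dict)  # name -> (nv,) float

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        for name, vals in self.scalars.items():
            vals = np.asarray(vals, dtype=float).reshape(-1)
            if vals.shape[0] != len(self.vertices):
                raise ValueError(f"scalar {name!r} length mismatch")
            self.scalars[name] = vals

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces))

    def triangles(self) -> np.ndarray:
        """(nf, 3, 3) triangle corner array."""
        return self.vertices[self.faces]

    def boundary_edge_count(self) -> int:
        """Edges referenced by exactly one face (0 for a closed mesh)."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts == 1))

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0

    def flipped(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy(),
                            dict(self.scalars))

    def with_scalars(self, **scalars) -> "TriangleMesh":
        merged = dict(self.scalars)
        merged.update(scalars)
        return TriangleMesh(self.vertices, self.faces, merged)


# ---------------------------------------------------------------------------

def extract_surface(
    grid: ImageGrid,
    iso_level: float | None = None,
    smooth_sigma_mm: float | None = None,
) -> TriangleMesh:
    """Extract the marching-cubes isosurface of a volume or mask.

    Binary masks are converted to float and Gaussian-smoothed (default
    sigma 0.5 voxel) before extraction at level 0.5.  Vertices are mapped
    to world mm; the mesh is oriented outward (positive signed volume).
    """
    is_mask = isinstance(grid, BinaryMask) or grid.data.dtype == bool
    data = np.asarray(grid.data, dtype=float)
    if is_mask:
        sigma_vox = (0.5 * np.ones(3) if smooth_sigma_mm is None
                     else smooth_sigma_mm / grid.spacing)
        if np.any(sigma_vox > 0):
            data = gaussian_filter(data, sigma_vox)
        if iso_level is None:
            iso_level = 0.5
    elif smooth_sigma_mm is not None and smooth_sigma_mm > 0:
        data = gaussian_filter(data, smooth_sigma_mm / grid.spacing)
    if iso_level is None:
        raise ValueError("iso_level required for grayscale input")
    lo, hi = float(data.min()), float(data.max())
    if not (lo < iso_level < hi):
        raise ValueError(
            f"iso_level {iso_level} outside intensity range ({lo}, {hi})"
        )
    # pad with background so objects clipped by the field of view are
    # capped at the boundary and the mesh stays closed
    padded = np.pad(data, 1, mode="constant", constant_values=lo)
    verts_idx, faces, _, _ = measure.marching_cubes(padded, level=iso_level)
    verts = voxel_to_world(grid, verts_idx - 1.0)
    mesh = TriangleMesh(verts, faces)
    # orient outward: signed volume must be positive for closed meshes
    if mesh.is_closed():
        tm = mesh.to_trimesh()
        if tm.volume < 0:
            mesh = mesh.flipped()
    return mesh


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in cm^3 via the divergence theorem.

    Sums signed tetrahedra (origin, v0, v1, v2) over all faces; requires a
    closed, consistently oriented mesh (invariant under rigid motion).
    """
    nb = mesh.boundary_edge_count()
    if nb:
        raise ValueError(f"mesh is not closed: {nb} boundary edges")
    tri = mesh.triangles()
    signed = np.einsum(
        "ij,ij->i", tri[:, 0],
        np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    return float(abs(signed)) / MM3_PER_CM3


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted average of incident face normals, unit length.

    Outward for closed outward-oriented meshes.  Isolated vertices get a
    zero vector with a warning.
    """
    tri = mesh.triangles()
    face_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area*n
    normals = np.zeros_like(mesh.vertices)
    for c in range(3):
        np.add.at(normals, mesh.faces[:, c], face_n)
    norm = np.linalg.norm(normals, axis=1)
    zero = norm < 1e-300
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} isolated/degenerate vertex normals")
        norm[zero] = 1.0
    return normals / norm[:, None]


def transform_mesh(mesh: TriangleMesh, transform: AffineTransform) -> TriangleMesh:
    """Map vertices through a rigid/affine transform; faces unchanged."""
    return TriangleMesh(transform.apply(mesh.vertices), mesh.faces.copy(),
                        dict(mesh.scalars))


# ---------------------------------------------------------------------------
# mesh file I/O: PLY via trimesh, legacy ASCII VTK PolyData in-house

def write_mesh(mesh: TriangleMesh, path, colors: np.ndarray | None = None) -> str:
    p = str(path)
    if p.lower().endswith(".ply"):
        tm = mesh.to_trimesh()
        if colors is not None:
            tm.visual.vertex_colors = colors
        tm.export(p)
        return p
    if p.lower().endswith(".vtk"):
        return _write_vtk(mesh, p, colors)
    raise ValueError(f"unsupported mesh format: {p}")


def read_mesh(path) -> TriangleMesh:
    p = str(path)
    if p.lower().endswith(".ply"):
        tm = trimesh.load(p, process=False)
        return TriangleMesh.from_trimesh(tm)
    if p.lower().endswith(".vtk"):
        return _read_vtk(p)
    raise ValueError(f"unsupported mesh format: {p}")


def _write_vtk(mesh: TriangleMesh, path: str, colors=None) -> str:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbonemorph surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        np.savetxt(fh, mesh.vertices, fmt="%.9g")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(mesh.n_faces, 3), mesh.faces]), fmt="%d")
        wrote_pd = False
        for name, vals in mesh.scalars.items():
            if not wrote_pd:
                fh.write(f"POINT_DATA {mesh.n_vertices}\n")
                wrote_pd = True
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, vals, fmt="%.9g")
        if colors is not None:
            if not wrote_pd:
                fh.write(f"POINT_DATA {mesh.n_vertices}\n")
                wrote_pd = True
            fh.write("COLOR_SCALARS rgb 3\n")
            np.savetxt(fh, np.asarray(colors, float)[:, :3], fmt="%.6g")
    return path


def _read_vtk(path: str) -> TriangleMesh:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    verts = faces = None
    scalars = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        parts = line.split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            flat = []
            i += 1
            while len(flat) < 3 * n:
                flat.extend(float(x) for x in tokens[i].split())
                i += 1
            verts = np.array(flat).reshape(n, 3)
            continue
        if key == "POLYGONS":
            n = int(parts[1])
            rows = []
            i += 1
            while len(rows) < n:
                vals = [int(x) for x in tokens[i].split()]
                if vals:
                    if vals[0] != 3:
                        raise ValueError("only triangle polygons supported")
                    rows.append(vals[1:4])
                i += 1
            faces = np.array(rows, dtype=np.int64)
            continue
        if key == "SCALARS":
            name = parts[1]
            i += 2  # skip LOOKUP_TABLE line
            flat = []
            while len(flat) < len(verts):
                flat.extend(float(x) for x in tokens[i].split())
                i += 1
            scalars[name] = np.array(flat)
            continue
        if key == "COLOR_SCALARS":
            ncomp = int(parts[2])
            need = ncomp * len(verts)
            flat = []
            i += 1
            while len(flat) < need:
                flat.extend(float(x) for x in tokens[i].split())
                i += 1
            continue
        i += 1
    if verts is None or faces is None:
        raise ValueError(f"not a triangle PolyData file: {path}")
    return TriangleMesh(verts, faces, scalars)
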