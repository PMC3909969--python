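"""Bone segmentation and spherical-fiducial detection.

Fiducials here are small radio-opaque spheres (1 mm tantalum by default)
implanted in bone as stable landmarks for serial-scan superimposition.
They are far brighter than bone, so detection thresholds above the bone
class, filters connected components by volume (the analytic sphere volume
(pi/6)*d^3 within a tolerance) and by sphericity, and reports each marker's
intensity-weighted centroid in world mm — the intensity weighting reads the
partial-volume shell and yields sub-voxel accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grid import BinaryMask, ImageGrid, voxel_to_world, world_to_voxel

__all__ = [
    "Fiducial",
    "FiducialSet",
    "DistanceTable",
    "threshold_bone",
    "detect_fiducials",
    "mask_out_fiducials",
    "pairwise_distances",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass(frozen=True)
class Fiducial:
    label: str
    position: np.ndarray  # world mm
    voxel_count: int
    mean_intensity: float


@dataclass
class FiducialSet:
    """Ordered, uniquely-labelled implant centroids in world mm."""

    markers: list = field(default_factory=list)

    def __post_init__(self):
        labels = [m.label for m in self.markers]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate fiducial labels: {labels}")
        for m in self.markers:
            if not np.all(np.isfinite(m.position)):
                raise ValueError(f"non-finite position for marker {m.label}")
            if m.voxel_count < 1:
                raise ValueError(f"marker {m.label} has voxel_count < 1")

    def __len__(self):
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def labels(self) -> list:
        return [m.label for m in self.markers]

    @property
    def positions(self) -> np.ndarray:
        if not self.markers:
            return np.zeros((0, 3))
        return np.array([m.position for m in self.markers], dtype=float)

    def get(self, label: str) -> Fiducial:
        for m in self.markers:
            if m.label == label:
                return m
        raise KeyError(label)

    def reordered(self, labels) -> "FiducialSet":
        return FiducialSet([self.get(l) for l in labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": m.label,
                    "x_mm": m.position[0],
                    "y_mm": m.position[1],
                    "z_mm": m.position[2],
                    "voxels": m.voxel_count,
                    "mean_intensity": m.mean_intensity,
                }
                for m in self.markers
            ],
            columns=["label", "x_mm", "y_mm", "z_mm", "voxels", "mean_intensity"],
        )

    def save_csv(self, path) -> str:
        self.to_frame().to_csv(path, index=False)
        return str(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FiducialSet":
        markers = [
            Fiducial(str(r.label), np.array([r.x_mm, r.y_mm, r.z_mm], float),
                     int(r.voxels), float(r.mean_intensity))
            for r in df.itertuples()
        ]
        return cls(markers)

    @classmethod
    def load_csv(cls, path) -> "FiducialSet":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class DistanceTable:
    """Unordered-pair Euclidean distances between labelled markers, with
    optional change columns against a second time point."""

    table: pd.DataFrame  # label_a, label_b, distance_mm [, distance_b_mm, delta_mm, percent]

    def __post_init__(self):
        if len(self.table) and (self.table["distance_mm"] < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self):
        return len(self.table)

    def distance(self, a: str, b: str) -> float:
        t = self.table
        row = t[((t.label_a == a) & (t.label_b == b))
                | ((t.label_a == b) & (t.label_b == a))]
        if row.empty:
            raise KeyError((a, b))
        return float(row.iloc[0].distance_mm)

    def save_csv(self, path) -> str:
        self.table.to_csv(path, index=False)
        return str(path)


# ---------------------------------------------------------------------------

def threshold_bone(
    grid: ImageGrid,
    method: str = "otsu",
    fixed_low: float | None = None,
    min_component_mm3: float = 1.0,
    keep_largest: bool = False,
) -> BinaryMask:
    """Segment the bone (bright) class from a grayscale volume.

    ``otsu`` picks the threshold maximising between-class variance;
    ``fixed`` uses ``fixed_low``.  Components smaller than
    ``min_component_mm3`` are removed; ``keep_largest`` retains only the
    largest connected component (the mandible body).  A threshold above the
    lattice maximum yields an empty mask with a warning rather than an
    error.
    """
    data = np.asarray(grid.data, dtype=float)
    if method == "otsu":
        low = float(threshold_otsu(data))
    elif method == "fixed":
        if fixed_low is None:
            raise ValueError("method='fixed' requires fixed_low")
        low = float(fixed_low)
    else:
        raise ValueError(f"unknown method {method!r}")

    fg = data >= low
    if not fg.any():
        warnings.warn("threshold exceeds maximum intensity; empty mask")
        return BinaryMask(fg, grid.spacing, grid.origin, grid.direction)

    labels, n = ndimage.label(fg, structure=_STRUCT26)
    if n:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        min_vox = max(1, int(round(min_component_mm3 / grid.voxel_volume_mm3)))
        if keep_largest:
            keep = np.zeros(n + 1, dtype=bool)
            keep[int(np.argmax(counts))] = True
        else:
            keep = counts >= min_vox
            keep[0] = False
        fg = keep[labels]
    return BinaryMask(fg, grid.spacing, grid.origin, grid.direction)


def _component_surface_area_mm2(comp: np.ndarray, spacing) -> float:
    """Exposed-face surface area of a voxelised component."""
    area = 0.0
    face = (spacing[1] * spacing[2], spacing[0] * spacing[2],
            spacing[0] * spacing[1])
    for ax in range(3):
        d = np.diff(comp.astype(np.int8), axis=ax)
        n_faces = np.count_nonzero(d)
        # boundary faces of the array
        first = np.take(comp, 0, axis=ax).sum()
        last = np.take(comp, -1, axis=ax).sum()
        area += face[ax] * (n_faces + first + last)
    return float(area)


def _sphericity(volume_mm3: float, area_mm2: float) -> float:
    # pi^(1/3) * (6V)^(2/3) / A : 1 for a perfect sphere
    return float(np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / area_mm2)


def default_metal_threshold(grid: ImageGrid, bone_mask: BinaryMask | None = None,
                            fraction: float = 0.5) -> float:
    """Threshold separating metal markers from bone.

    Tantalum markers are the brightest material present; the default sits
    midway between the bone level (class median, which resists the
    partial-volume shell) and the lattice maximum — far above bone noise,
    yet low enough to catch small spheres whose peak is depressed by blur.
    """
    data = np.asarray(grid.data, dtype=float)
    if bone_mask is not None and bone_mask.data.any():
        bone = bone_mask.data
    else:
        bone = data >= threshold_otsu(data)
    # median resists the partial-volume shell that drags the mean down
    bone_level = float(np.median(data[bone]))
    return bone_level + fraction * (float(data.max()) - bone_level)


def detect_fiducials(
    grid: ImageGrid,
    metal_threshold: float | None = None,
    diameter_mm: float = 1.0,
    diameter_tol: float = 0.6,
    min_sphericity: float = 0.6,
    expected_count: int | None = None,
) -> FiducialSet:
    """Detect bright spherical implant markers and localise their centroids.

    Connected components (26-connectivity) above ``metal_threshold`` are
    filtered to a volume within ``(1 +/- diameter_tol)^3`` of the analytic
    sphere volume ``(pi/6) * diameter_mm^3`` and to sphericity at least
    ``min_sphericity``.  Surviving components are reported with their
    intensity-weighted centroid in world mm, labelled ``m1..mN``
    deterministically by sorted world coordinates (z, then y, then x).
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    if metal_threshold is None:
        metal_threshold = default_metal_threshold(grid)
    data = np.asarray(grid.data, dtype=float)
    fg = data >= metal_threshold
    markers = []
    if fg.any():
        labels, n = ndimage.label(fg, structure=_STRUCT26)
        sphere_vol = (np.pi / 6.0) * diameter_mm**3
        lo = sphere_vol * (1.0 - diameter_tol) ** 3
        hi = sphere_vol * (1.0 + diameter_tol) ** 3
        vox_vol = grid.voxel_volume_mm3
        objects = ndimage.find_objects(labels)
        for lab, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            comp = labels[sl] == lab
            nv = int(comp.sum())
            vol = nv * vox_vol
            # single voxels cannot be validated as spheres (noise speckle)
            if nv < 2 or not (lo <= vol <= hi):
                continue
            area = _component_surface_area_mm2(comp, grid.spacing)
            if _sphericity(vol, area) < min_sphericity:
                continue
            ii, jj, kk = np.nonzero(comp)
            idx = np.column_stack([
                ii + sl[0].start, jj + sl[1].start, kk + sl[2].start,
            ]).astype(float)
            vals = data[idx[:, 0].astype(int), idx[:, 1].astype(int),
                        idx[:, 2].astype(int)]
            # weight by squared intensity above threshold: reads the
            # partial-volume shell while emphasising the peak over the
            # truncation-sensitive rim of the thresholded blob
            w = np.maximum(vals - metal_threshold, 0.0) ** 2 + 1e-12
            centroid_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
            pos = voxel_to_world(grid, centroid_idx)
            markers.append((pos, nv, float(vals.mean())))

    order = sorted(range(len(markers)),
                   key=lambda i: tuple(markers[i][0][::-1]))  # z, y, x
    fids = FiducialSet([
        Fiducial(f"m{rank + 1}", markers[i][0], markers[i][1], markers[i][2])
        for rank, i in enumerate(order)
    ])
    if expected_count is not None and len(fids) < expected_count:
        warnings.warn(
            f"detected {len(fids)} fiducials, expected {expected_count}"
        )
    return fids


def mask_out_fiducials(
    mask: BinaryMask, fids: FiducialSet, exclusion_radius: float
) -> BinaryMask:
    """Clear mask voxels within ``exclusion_radius`` mm of any marker
    centroid, so metal blobs do not contaminate the bone surface mesh."""
    if len(fids) == 0 or exclusion_radius <= 0:
        return mask.with_data(mask.data.copy())
    out = mask.data.copy()
    r_vox = np.ceil(exclusion_radius / mask.spacing).astype(int)
    for m in fids:
        c = world_to_voxel(mask, m.position)
        lo = np.maximum(np.floor(c - r_vox - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + r_vox + 2).astype(int),
                        np.array(mask.shape))
        if np.any(lo >= hi):
            continue
        sub = np.stack(np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        world = voxel_to_world(mask, sub.astype(float))
        inside = np.linalg.norm(world - m.position, axis=1) <= exclusion_radius
        s = sub[inside]
        out[s[:, 0], s[:, 1], s[:, 2]] = False
    return mask.with_data(out)


def pairwise_distances(
    fids_a: FiducialSet, fids_b: FiducialSet | None = None
) -> DistanceTable:
    """All unordered-pair inter-implant distances (mm) within ``fids_a``;
    with ``fids_b``, per-pair change (delta mm and percent of baseline)."""
    if fids_b is not None:
        if sorted(fids_a.labels) != sorted(fids_b.labels):
            raise ValueError(
                f"label mismatch: {fids_a.labels} vs {fids_b.labels}"
            )
        fids_b = fids_b.reordered(fids_a.labels)
    rows = []
    markers = list(fids_a)
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            a, b = markers[i], markers[j]
            d = float(np.linalg.norm(a.position - b.position))
            row = {"label_a": a.label, "label_b": b.label, "distance_mm": d}
            if fids_b is not None:
                db = float(np.linalg.norm(
                    fids_b.get(a.label).position - fids_b.get(b.label).position))
                row["distance_b_mm"] = db
                row["delta_mm"] = db - d
                row["percent"] = 100.0 * (db - d) / d if d > 0 else np.nan
            rows.append(row)
    cols = ["label_a", "label_b", "distance_mm"]
    if fids_b is not None:
        cols += ["distance_b_mm", "delta_mm", "percent"]
    return DistanceTable(pd.DataFrame(rows, columns=cols))
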