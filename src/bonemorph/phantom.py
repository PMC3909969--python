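"""Synthetic serial-scan phantom with complete ground truth.

The phantom emulates a small-animal mandible imaged twice with a CT-like
protocol: a mandible-like solid (an elongated superellipsoid body, a
vertical posterior ramus slab, and a condylar knob) at bone intensity on a
dark background, with very bright 1.0 mm spherical fiducial implants
seated in the stable lower-body ("molar") and symphysis regions.  Volumes
default to 96^3 voxels at 0.3 mm isotropic spacing with Gaussian blur
(sigma 0.3 mm) and additive Gaussian noise (sigma 50 on a 0/1000/3000
background/bone/metal intensity scale).

The follow-up time point is produced by a *known* growth displacement
field plus a *known* rigid pose change, so every downstream stage can be
checked against exact truth.  Growth is modelled analytically as two
monotone smoothstep stretches — vertical expansion ramping up the ramus to
the condyle, and posterior expansion ramping backwards across the ramus —
which keeps the stable molar region displacement identically zero, the
field divergence non-negative (pure expansion), and the truth in closed
form.  One marker may additionally be displaced by a configured offset to
emulate implant failure during growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import BinaryMask, ImageGrid, voxel_to_world
from .segment import Fiducial, FiducialSet
from .transforms import DisplacementField, RigidTransform

__all__ = ["PhantomScenario", "PhantomTruth", "make_phantom", "apply_growth",
           "GrowthParams"]


@dataclass
class GrowthParams:
    """Analytic growth-field amplitudes and ramp supports (mm).

    ``condylar_mm`` is the maximal vertical displacement, reached at and
    above ``z_full``; ``posterior_mm`` the maximal backwards displacement,
    reached behind ``y_full``.  Ramps start at ``z_start``/``y_start`` and
    are exactly zero before them, so the molar region (low z, mid y) is a
    true stable zone.
    """

    condylar_mm: float = 2.0
    posterior_mm: float = 1.5
    z_start: float = 12.0
    z_full: float = 20.0
    y_start: float = 14.0
    y_full: float = 19.0

    def __post_init__(self):
        if self.condylar_mm < 0 or self.posterior_mm < 0:
            raise ValueError("growth amplitudes must be non-negative")
        if self.z_full <= self.z_start or self.y_full <= self.y_start:
            raise ValueError("ramp end must exceed ramp start")


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass
class PhantomScenario:
    """Full description of the synthetic subject and imaging protocol."""

    shape: tuple = (96, 96, 96)
    spacing: float = 0.3
    # mandible-like solid (all mm, world frame)
    body_center: tuple = (14.4, 10.0, 8.0)
    body_semiaxes: tuple = (5.0, 8.0, 3.5)
    body_exponent: float = 2.5
    ramus_center: tuple = (14.4, 16.5, 13.0)
    ramus_semiaxes: tuple = (2.2, 2.5, 7.0)
    ramus_exponent: float = 3.0
    condyle_center: tuple = (14.4, 16.5, 20.5)
    condyle_radius: float = 2.2
    # imaging
    background: float = 0.0
    bone: float = 1000.0
    metal: float = 3000.0
    blur_sigma_mm: float = 0.3
    noise_sigma: float = 50.0
    # fiducials
    fiducial_diameter_mm: float = 1.0
    n_fiducials: int = 5

    def fiducial_sites(self) -> np.ndarray:
        """Implant centres (mm): symphysis, molar region, body; all in the
        growth-stable zone, ordered by world z then y then x."""
        sites = np.array([
            (14.4, 3.5, 8.0),   # symphysis
            (11.5, 9.0, 6.5),   # molar region, lateral
            (17.3, 11.0, 6.5),  # molar region, contralateral
            (14.4, 13.0, 6.2),  # molar region, posterior
            (13.5, 6.5, 10.0),  # upper body
            (16.0, 8.0, 9.5),   # upper body, contralateral
            (14.4, 14.5, 9.0),  # lower ramus
        ])
        if not 3 <= self.n_fiducials <= len(sites):
            raise ValueError(
                f"n_fiducials must be in [3, {len(sites)}], got {self.n_fiducials}")
        chosen = sites[: self.n_fiducials]
        order = np.lexsort((chosen[:, 0], chosen[:, 1], chosen[:, 2]))
        return chosen[order]

    # -- analytic implicit solid -------------------------------------------
    def _super(self, pts, center, semi, exponent):
        q = np.abs((pts - np.asarray(center)) / np.asarray(semi))
        return (q ** exponent).sum(axis=-1)

    def inside_bone(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        body = self._super(pts, self.body_center, self.body_semiaxes,
                           self.body_exponent) <= 1.0
        ramus = self._super(pts, self.ramus_center, self.ramus_semiaxes,
                            self.ramus_exponent) <= 1.0
        condyle = np.linalg.norm(pts - np.asarray(self.condyle_center),
                                 axis=-1) <= self.condyle_radius
        return body | ramus | condyle

    def growth_displacement(self, pts: np.ndarray,
                            growth: GrowthParams) -> np.ndarray:
        """Analytic truth displacement u(p) at baseline points (mm)."""
        pts = np.asarray(pts, float)
        u = np.zeros_like(pts)
        u[..., 2] = growth.condylar_mm * _smoothstep(
            (pts[..., 2] - growth.z_start) / (growth.z_full - growth.z_start))
        u[..., 1] = growth.posterior_mm * _smoothstep(
            (pts[..., 1] - growth.y_start) / (growth.y_full - growth.y_start))
        return u

    def _invert_growth(self, pts: np.ndarray, growth: GrowthParams,
                       iters: int = 25) -> np.ndarray:
        """Solve p + u(p) = x for p by fixed-point iteration."""
        if growth.condylar_mm == 0 and growth.posterior_mm == 0:
            return np.asarray(pts, float)
        p = np.asarray(pts, float).copy()
        for _ in range(iters):
            p = pts - self.growth_displacement(p, growth)
        return p

    def world_points(self) -> np.ndarray:
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in self.shape],
                            indexing="ij")
        idx = np.stack(grids, axis=-1)
        return idx * self.spacing  # identity direction, origin 0

    def _render(self, solid: np.ndarray, marker_centers: np.ndarray,
                pts: np.ndarray, rng: np.random.Generator):
        data = np.where(solid, self.bone, self.background).astype(float)
        r = self.fiducial_diameter_mm / 2.0
        for c in marker_centers:
            lo = np.maximum(((c - r - 1) / self.spacing).astype(int), 0)
            hi = np.minimum(((c + r + 2) / self.spacing).astype(int),
                            np.array(self.shape))
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            local = pts[sl]
            inside = np.linalg.norm(local - c, axis=-1) <= r
            sub = data[sl]
            sub[inside] = self.metal
            data[sl] = sub
        if self.blur_sigma_mm > 0:
            data = gaussian_filter(data, self.blur_sigma_mm / self.spacing)
        if self.noise_sigma > 0:
            data = data + rng.normal(0.0, self.noise_sigma, size=data.shape)
        return data


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume."""

    bone_mask: BinaryMask
    fiducial_truth: FiducialSet
    pose_change: RigidTransform
    growth_field: DisplacementField
    displaced_marker: tuple | None = None  # (label, offset 3-vector mm)
    scenario: PhantomScenario | None = None
    growth: GrowthParams | None = None


def _truth_fiducials(centers: np.ndarray, scenario: PhantomScenario) -> FiducialSet:
    vox = round((np.pi / 6.0) * scenario.fiducial_diameter_mm**3
                / scenario.spacing**3)
    return FiducialSet([
        Fiducial(f"m{i + 1}", np.asarray(c, float), max(int(vox), 1),
                 scenario.metal)
        for i, c in enumerate(centers)
    ])


def make_phantom(
    scenario: PhantomScenario | None = None, seed: int = 0, **overrides
) -> tuple:
    """Generate the baseline scan and its ground truth.

    Any :class:`PhantomScenario` field may be overridden by keyword.
    Identical seeds produce bit-identical volumes.
    """
    scenario = replace(scenario or PhantomScenario(), **overrides)
    rng = np.random.default_rng(seed)
    pts = scenario.world_points()
    solid = scenario.inside_bone(pts)
    centers = scenario.fiducial_sites()
    margin = scenario.fiducial_diameter_mm / 2.0
    for c in centers:
        # the whole marker sphere must sit inside the bone solid
        probe = c + margin * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
             [0, 0, 1], [0, 0, -1], [0, 0, 0]], float)
        if not scenario.inside_bone(probe).all():
            raise ValueError(f"fiducial at {c} lies outside the bone solid")
    data = scenario._render(solid, centers, pts, rng)
    spacing = np.full(3, scenario.spacing)
    grid = ImageGrid(data, spacing)
    mask = BinaryMask(solid, spacing)
    zero_field = DisplacementField(
        grid.with_data(np.zeros(scenario.shape, dtype=np.int8)),
        np.zeros(scenario.shape + (3,)))
    truth = PhantomTruth(mask, _truth_fiducials(centers, scenario),
                         RigidTransform.identity(), zero_field,
                         None, scenario, GrowthParams(0, 0))
    return grid, truth


def apply_growth(
    baseline_truth: PhantomTruth,
    growth: GrowthParams | None = None,
    pose: RigidTransform | None = None,
    displace_marker: tuple | None = None,
    seed: int = 1,
) -> tuple:
    """Generate the follow-up scan from a baseline phantom's truth.

    The baseline solid is carried through the analytic growth map
    ``phi(p) = p + u(p)`` and then the rigid ``pose``; fiducials follow the
    same map, except an optional single marker additionally offset by
    ``displace_marker = (label, offset_mm)`` to emulate implant failure.
    A fresh noise realisation is drawn from ``seed``.  Raises if the
    growth map folds (non-positive Jacobian determinant anywhere).
    """
    scenario = baseline_truth.scenario
    if scenario is None:
        raise ValueError("baseline truth lacks its scenario description")
    growth = growth or GrowthParams()
    pose = pose or RigidTransform.identity()
    rng = np.random.default_rng(seed)
    pts = scenario.world_points()

    # fold check: the Jacobian is diagonal (each ramp depends only on its
    # own coordinate), det J = (1 + A_y S'/dy)(1 + A_z S'/dz) with
    # min S' = 0; folding needs a diagonal term <= -1
    for amp, lo, hi in [(growth.posterior_mm, growth.y_start, growth.y_full),
                        (growth.condylar_mm, growth.z_start, growth.z_full)]:
        if 1.0 + min(0.0, amp) * 1.5 / (hi - lo) <= 0:
            raise ValueError("growth parameters fold the displacement field")

    # follow-up solid: x inside iff phi^-1(pose^-1(x)) inside baseline
    pre_pose = pose.inverse().apply(pts.reshape(-1, 3))
    base_pts = scenario._invert_growth(pre_pose, growth)
    solid = scenario.inside_bone(base_pts).reshape(scenario.shape)

    centers = baseline_truth.fiducial_truth.positions
    labels = baseline_truth.fiducial_truth.labels
    moved = centers + scenario.growth_displacement(centers, growth)
    if displace_marker is not None:
        label, offset = displace_marker
        offset = np.asarray(offset, float).reshape(3)
        moved[labels.index(label)] += offset
    moved = pose.apply(moved)

    data = scenario._render(solid, moved, pts, rng)
    spacing = np.full(3, scenario.spacing)
    grid = ImageGrid(data, spacing)
    mask = BinaryMask(solid, spacing)

    u = scenario.growth_displacement(pts, growth)
    field = DisplacementField(
        grid.with_data(np.zeros(scenario.shape, dtype=np.int8)), u)
    fids = FiducialSet([
        Fiducial(lbl, pos, m.voxel_count, m.mean_intensity)
        for lbl, pos, m in zip(labels, moved, baseline_truth.fiducial_truth)
    ])
    truth = PhantomTruth(mask, fids, pose, field,
                         displace_marker, scenario, growth)
    return grid, truth
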