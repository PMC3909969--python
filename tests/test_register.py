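"""Rigid fiducial superimposition, stability diagnostics, and
intensity-based affine/deformable registration."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from bonemorph.grid import ImageGrid
from bonemorph.mesh import TriangleMesh
from bonemorph.phantom import make_phantom
from bonemorph.register import (AffineConfig, DemonsConfig, fit_rigid,
                                leave_one_out_stability, match_fiducials,
                                register_affine, register_nonrigid, warp_mesh)
from bonemorph.segment import Fiducial, FiducialSet
from bonemorph.transforms import DisplacementField, RigidTransform

from conftest import icosphere_mesh


def fidset(positions, labels=None):
    positions = np.atleast_2d(positions)
    labels = labels or [f"m{i+1}" for i in range(len(positions))]
    return FiducialSet([Fiducial(l, np.asarray(p, float), 1, 1.0)
                        for l, p in zip(labels, positions)])


def random_rigid(rng):
    return RigidTransform.from_euler(rng.uniform(-180, 180, 3),
                                     rng.uniform(-10, 10, 3))


class TestFitRigid:
    def test_identical_points_give_identity(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        t, rep = fit_rigid(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)
        assert rep.fre_rms < 1e-12

    def test_exact_recovery_of_constructed_transform(self):
        rot90 = RigidTransform.from_euler((0, 0, 90), (1, 2, 3))
        a = np.array([(0., 0, 0), (1, 0, 0), (0, 1, 0), (0.3, 0.2, 0.9)])
        t, rep = fit_rigid(a, rot90.apply(a))
        assert np.abs(t.rotation - rot90.rotation).max() < 1e-12
        assert np.abs(t.translation - rot90.translation).max() < 1e-12
        assert rep.fre_rms < 1e-9

    def test_optimal_vs_random_transform_oracle(self, rng):
        a = rng.uniform(-5, 5, size=(4, 3))
        truth = random_rigid(rng)
        b = truth.apply(a) + rng.normal(0, 0.1, size=a.shape)
        _, rep = fit_rigid(a, b)
        for _ in range(1000):
            cand = random_rigid(rng)
            resid = np.sqrt(np.mean(np.sum((cand.apply(a) - b) ** 2, axis=1)))
            assert rep.fre_rms <= resid + 1e-12

    def test_forward_and_reverse_fits_are_inverses(self, rng):
        a = rng.uniform(-5, 5, size=(6, 3))
        b = random_rigid(rng).apply(a)
        t_ab, _ = fit_rigid(a, b)
        t_ba, _ = fit_rigid(b, a)
        comp = t_ab.compose(t_ba)
        assert np.abs(comp.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(comp.translation).max() < 1e-9

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="3 point"):
            fit_rigid([(0, 0, 0), (1, 0, 0)], [(0, 0, 0), (1, 0, 0)])
        line = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid(line, line)

    def test_reflection_never_returned(self, rng):
        # near-planar configurations tempt the SVD into a reflection
        a = rng.uniform(-5, 5, size=(5, 3))
        a[:, 2] *= 1e-3
        b = random_rigid(rng).apply(a) + rng.normal(0, 0.5, a.shape)
        t, _ = fit_rigid(a, b)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)


class TestFitRigidProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    angles = st.floats(-180.0, 180.0, allow_nan=False)
    coords = st.floats(-20.0, 20.0, allow_nan=False)

    @given(ax=angles, ay=angles, az=angles, tx=coords, ty=coords, tz=coords)
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_any_rigid_transform_recovered_exactly(self, ax, ay, az,
                                                   tx, ty, tz):
        truth = RigidTransform.from_euler((ax, ay, az), (tx, ty, tz))
        pts = np.array([(0., 0, 0), (7, 0, 0), (0, 5, 0), (2, 3, 6),
                        (-4, 1, 2)])
        t, rep = fit_rigid(pts, truth.apply(pts))
        assert rep.fre_rms < 1e-8
        assert np.abs(t.matrix - truth.matrix).max() < 1e-8


class TestMatchFiducials:
    def test_identical_sets_identity_permutation(self):
        s = fidset([(0, 0, 0), (4, 0, 0), (0, 5, 0), (1, 1, 3)])
        assert match_fiducials(s, s) == [0, 1, 2, 3]

    def test_recovers_shuffle_under_rigid_motion(self, rng):
        a_pts = rng.uniform(-8, 8, size=(5, 3))
        truth = random_rigid(rng)
        shuffle = rng.permutation(5)
        b = fidset(truth.apply(a_pts)[shuffle])
        perm = match_fiducials(fidset(a_pts), b)
        # permutation must map marker i of a to its true counterpart
        assert np.array_equal(np.argsort(shuffle), perm)
        _, rep = fit_rigid(a_pts, b.positions[perm])
        assert rep.fre_rms < 1e-9

    def test_single_marker_trivial(self):
        assert match_fiducials(fidset([(1, 2, 3)]), fidset([(9, 9, 9)])) == [0]

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            match_fiducials(fidset([(0, 0, 0)]),
                            fidset([(0, 0, 0), (1, 1, 1)]))


class TestStability:
    def test_consistent_markers_unflagged(self, rng):
        a = rng.uniform(-8, 8, size=(5, 3))
        t = random_rigid(rng)
        rep = leave_one_out_stability(fidset(a), fidset(t.apply(a)))
        assert rep.flags == []
        assert rep.estimated_displacements.max() < 1e-9

    def test_single_displaced_marker_flagged_with_magnitude(self, rng):
        a = np.array([(14.4, 3.5, 8.0), (11.5, 9.0, 6.5), (17.3, 11.0, 6.5),
                      (14.4, 13.0, 6.2), (13.5, 6.5, 10.0)])
        t = random_rigid(rng)
        b = t.apply(a)
        b[1] += t.rotation @ np.array([0.0, 0.0, 1.6])  # tangential slip
        rep = leave_one_out_stability(fidset(a), fidset(b), flag_threshold=1.0)
        assert [l for l, _ in rep.flags] == ["m2"]
        assert rep.estimated_displacements[1] == pytest.approx(1.6, abs=0.1)
        others = np.delete(rep.estimated_displacements, 1)
        assert others.max() < 0.1

    def test_two_of_six_displaced_both_flagged(self, rng):
        a = rng.uniform(-8, 8, size=(6, 3))
        t = random_rigid(rng)
        b = t.apply(a)
        b[0] += 2.0 * np.array([1.0, 0, 0])
        b[3] += 2.0 * np.array([0, 0.6, 0.8])
        rep = leave_one_out_stability(fidset(a), fidset(b), flag_threshold=1.0)
        assert sorted(l for l, _ in rep.flags) == ["m1", "m4"]

    def test_three_markers_fall_back_to_full_fit(self, rng):
        a = rng.uniform(-8, 8, size=(3, 3))
        with pytest.warns(UserWarning, match="fewer than 4"):
            rep = leave_one_out_stability(fidset(a), fidset(a))
        assert rep.flags == []


@pytest.fixture(scope="module")
def reg_phantom():
    """Study-condition image for intensity registration (28.8 mm scene)."""
    grid, _ = make_phantom(seed=3, shape=(48, 48, 48), spacing=0.6,
                           blur_sigma_mm=0.6)
    return grid


class TestRegisterAffine:
    def test_self_registration_is_identity(self, reg_phantom):
        t = register_affine(reg_phantom, reg_phantom)
        assert np.abs(t.linear - np.eye(3)).max() < 1e-3
        assert np.abs(t.translation).max() < 0.1 * 0.6

    def test_known_translation_recovered(self, reg_phantom):
        g = reg_phantom
        moved = ImageGrid(ndi.shift(g.data, (1.5, 0, 0), order=1,
                                    mode="nearest"), g.spacing)
        t = register_affine(g, moved)
        # content moved +1.5 voxels; moving->fixed carries it back
        expected = np.array([-1.5 * 0.6, 0.0, 0.0])
        center = (np.array(g.shape) - 1) / 2 * g.spacing
        err = np.linalg.norm(t.apply(center) - (center + expected))
        assert err < 0.25 * 0.6

    def test_known_scaling_recovered(self, reg_phantom):
        g = reg_phantom
        c = (np.array(g.shape) - 1) / 2.0
        coords = np.meshgrid(*[np.arange(s, dtype=float) for s in g.shape],
                             indexing="ij")
        coords = [(x - ci) / 1.05 + ci for x, ci in zip(coords, c)]
        moved = ImageGrid(ndi.map_coordinates(g.data, coords, order=1,
                                              mode="nearest"), g.spacing)
        t = register_affine(g, moved)
        # moving shows the content magnified 1.05x; inverse shrinks it back
        assert np.allclose(np.diag(t.linear), 1 / 1.05, atol=0.01)

    def test_non_overlapping_volumes_rejected(self, reg_phantom):
        g = reg_phantom
        far = ImageGrid(g.data, g.spacing, g.origin + 1000.0, g.direction)
        with pytest.raises(ValueError, match="overlap"):
            register_affine(g, far)


class TestRegisterNonrigid:
    def test_self_registration_field_near_zero(self, reg_phantom):
        field = register_nonrigid(reg_phantom, reg_phantom)
        assert field.magnitude().mean() < 0.05 * 0.6

    def test_known_translation_field(self, reg_phantom):
        g = reg_phantom
        moved = ImageGrid(ndi.shift(g.data, (1.5, 0, 0), order=1,
                                    mode="nearest"), g.spacing)
        field = register_nonrigid(g, moved)
        err = np.linalg.norm(field.vectors - np.array([0.9, 0, 0]), axis=-1)
        assert err.mean() < 0.5 * 0.6

    def test_gaussian_bump_field(self, reg_phantom):
        g = reg_phantom
        c = np.array([14.4, 16.5, 13.0])
        s = 4.0
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in g.shape],
                            indexing="ij")
        x = np.stack(grids, -1) * 0.6
        peak = 2 * 0.6  # 2 voxels
        p = x.copy()
        for _ in range(25):
            r2 = ((p - c) ** 2).sum(-1)
            p[..., 2] = x[..., 2] - peak * np.exp(-r2 / (2 * s * s))
        moved = ImageGrid(ndi.map_coordinates(
            g.data, [p[..., 0] / 0.6, p[..., 1] / 0.6, p[..., 2] / 0.6],
            order=1, mode="nearest"), g.spacing)
        field = register_nonrigid(g, moved)
        truth = np.zeros(field.vectors.shape)
        truth[..., 2] = peak * np.exp(-((x - c) ** 2).sum(-1) / (2 * s * s))
        err = np.linalg.norm(field.vectors - truth, axis=-1)
        inside = g.data > 500
        assert err[inside].mean() < 0.75 * 0.6

    def test_accepted_iterations_decrease_metric(self, reg_phantom):
        # the per-level driver accepts an update only on strict decrease
        from bonemorph.register import _demons_level

        g = reg_phantom
        moved = ndi.shift(g.data, (1.0, 0, 0), order=1, mode="nearest")
        f = g.data / g.data.max()
        m = moved / g.data.max()
        cfg = DemonsConfig()
        disp0 = np.zeros(f.shape + (3,))

        def metric(d):
            from bonemorph.register import _warp_index
            return float(np.mean((_warp_index(m, d) - f) ** 2))

        out = _demons_level(f, m, disp0, cfg, 15)
        assert metric(out) < metric(disp0)


class TestWarpMesh:
    def make_field(self, vectors_fn, shape=(20, 20, 20), spacing=1.0):
        geom = ImageGrid(np.zeros(shape, dtype=np.int8),
                         spacing=(spacing,) * 3)
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                            indexing="ij")
        x = np.stack(grids, -1) * spacing
        return DisplacementField(geom, vectors_fn(x))

    def test_zero_field_identity(self):
        field = self.make_field(lambda x: np.zeros_like(x))
        mesh = icosphere_mesh(5.0, 2, center=(10, 10, 10))
        out = warp_mesh(mesh, field)
        assert np.allclose(out.vertices, mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)

    def test_uniform_field_forward(self):
        field = self.make_field(
            lambda x: np.broadcast_to([1.0, 0, 0], x.shape).copy())
        mesh = icosphere_mesh(5.0, 2, center=(10, 10, 10))
        out = warp_mesh(mesh, field, "forward")
        assert np.allclose(out.vertices - mesh.vertices, [1, 0, 0])

    def test_forward_inverse_roundtrip_under_smooth_bump(self):
        c = np.array([10.0, 10.0, 10.0])

        def bump(x):
            v = np.zeros_like(x)
            v[..., 2] = 0.8 * np.exp(-((x - c) ** 2).sum(-1) / (2 * 9.0))
            return v

        field = self.make_field(bump)
        mesh = icosphere_mesh(4.0, 3, center=(10, 10, 10))
        roundtrip = warp_mesh(warp_mesh(mesh, field, "forward"),
                              field, "inverse")
        err = np.linalg.norm(roundtrip.vertices - mesh.vertices, axis=1)
        assert err.max() < 0.05

    def test_vertices_outside_support_rejected(self):
        field = self.make_field(lambda x: np.zeros_like(x))
        mesh = icosphere_mesh(5.0, 1, center=(100, 100, 100))
        with pytest.raises(ValueError, match="outside"):
            warp_mesh(mesh, field)
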