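"""Surface-distance metrics, Procrustes alignment, volume change, and
colour-mapped export."""

import numpy as np
import pytest
import trimesh.triangles

from bonemorph.mesh import TriangleMesh, read_mesh
from bonemorph.morpho import (SurfaceScalarField, export_colormap, hausdorff,
                              mean_min_report, min_distances, procrustes_align,
                              signed_distances, volume_change)
from bonemorph.transforms import RigidTransform

from conftest import icosphere_mesh


def brute_force_min_distances(source, target):
    tri = target.triangles()
    out = np.empty(source.n_vertices)
    for i, p in enumerate(source.vertices):
        cp = trimesh.triangles.closest_point(
            tri, np.repeat(p[None], len(tri), axis=0))
        out[i] = np.linalg.norm(cp - p, axis=1).min()
    return out


def random_mesh(rng, n=50):
    pts = rng.uniform(-5, 5, size=(n, 3))
    hull = trimesh.Trimesh(pts).convex_hull
    return TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces))


def square(z=0.0):
    return TriangleMesh([[0, 0, z], [1, 0, z], [1, 1, z], [0, 1, z]],
                        [[0, 1, 2], [0, 2, 3]])


class TestMinDistances:
    def test_self_distance_zero(self, sphere10):
        assert min_distances(sphere10, sphere10).max() < 1e-12

    def test_parallel_planes_offset(self):
        d = min_distances(square(0.0), square(2.0))
        assert np.allclose(d, 2.0, atol=1e-12)

    def test_matches_brute_force_on_random_meshes(self, rng):
        for _ in range(3):
            a = random_mesh(rng)
            b = random_mesh(rng)
            b.vertices += rng.uniform(-3, 3, 3)
            fast = min_distances(a, b)
            assert np.abs(fast - brute_force_min_distances(a, b)).max() < 1e-9


class TestHausdorff:
    def test_identity_zero(self, sphere10):
        assert hausdorff(sphere10, sphere10) == 0.0

    def test_concentric_spheres(self):
        a = icosphere_mesh(10.0, 3)
        b = icosphere_mesh(12.0, 3)
        assert hausdorff(a, b) == pytest.approx(2.0, rel=0.01)

    def test_symmetry_exact(self, rng):
        a = random_mesh(rng)
        b = random_mesh(rng)
        assert hausdorff(a, b) == hausdorff(b, a)

    def test_triangle_inequality_on_sphere_family(self):
        a = icosphere_mesh(8.0, 2)
        b = icosphere_mesh(10.0, 2, center=(1.0, 0, 0))
        c = icosphere_mesh(12.0, 2, center=(0, 2.0, 0))
        assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-9


class TestMeanMinReport:
    def test_identical_meshes_all_zero(self, sphere10):
        rep = mean_min_report(sphere10, sphere10)
        assert rep.hausdorff == 0.0
        assert rep.max_mean_min == 0.0

    def test_parallel_planes(self):
        rep = mean_min_report(square(0.0), square(1.5))
        assert rep.mean_min_a_to_b == pytest.approx(1.5)
        assert rep.mean_min_b_to_a == pytest.approx(1.5)
        assert rep.max_mean_min == pytest.approx(1.5)
        assert rep.hausdorff == pytest.approx(1.5)

    def test_metric_ordering_on_random_meshes(self, rng):
        for _ in range(3):
            a = random_mesh(rng)
            b = random_mesh(rng)
            rep = mean_min_report(a, b)
            assert rep.hausdorff >= rep.max_mean_min >= rep.mean_min_a_to_b >= 0
            assert rep.max_mean_min >= rep.mean_min_b_to_a
            # hausdorff agrees with the brute-force definition
            brute = max(brute_force_min_distances(a, b).max(),
                        brute_force_min_distances(b, a).max())
            assert rep.hausdorff == pytest.approx(brute, abs=1e-9)


class TestSignedDistances:
    def test_identical_zero(self, sphere10):
        assert np.abs(signed_distances(sphere10, sphere10).values).max() < 1e-12

    def test_inflation_positive_one(self):
        base = icosphere_mesh(10.0, 3)
        grown = icosphere_mesh(11.0, 3)
        vals = signed_distances(base, grown).values
        assert np.all(vals > 0)
        assert np.allclose(vals, 1.0, atol=0.02)

    def test_deflation_negative_one(self):
        base = icosphere_mesh(10.0, 3)
        shrunk = icosphere_mesh(9.0, 3)
        vals = signed_distances(base, shrunk).values
        assert np.all(vals < 0)
        assert np.allclose(vals, -1.0, atol=0.02)

    def test_magnitude_equals_min_distance_and_flip_negates(self, rng):
        a = random_mesh(rng)
        b = random_mesh(rng)
        field = signed_distances(a, b)
        assert np.allclose(np.abs(field.values), min_distances(a, b),
                           atol=1e-12)
        flipped = signed_distances(a.flipped(), b)
        assert np.allclose(flipped.values, -field.values, atol=1e-12)


class TestProcrustes:
    def test_identity(self, rng):
        pts = rng.uniform(-5, 5, size=(20, 3))
        res, aligned = procrustes_align(pts, pts)
        assert res.scale == pytest.approx(1.0, abs=1e-12)
        assert res.residual_rms < 1e-12
        assert np.allclose(aligned, pts)

    def test_similarity_recovery(self, rng):
        pts = rng.uniform(-5, 5, size=(50, 3))
        rot = RigidTransform.from_euler((30, -40, 70)).rotation
        target = 1.3 * pts @ rot.T + np.array([2.0, -1.0, 4.0])
        res, aligned = procrustes_align(pts, target)
        assert res.scale == pytest.approx(1.3, abs=1e-9)
        assert np.abs(res.rotation - rot).max() < 1e-9
        assert res.residual_rms < 1e-9

    def test_without_scaling_matches_orthogonal_procrustes(self, rng):
        # independent oracle: scipy's orthogonal Procrustes rotation
        from scipy.linalg import orthogonal_procrustes

        a = rng.uniform(-5, 5, size=(30, 3))
        b = 1.3 * a @ RigidTransform.from_euler((10, 20, -30)).rotation.T + 5.0
        res, aligned = procrustes_align(a, b, with_scaling=False)
        assert res.scale == 1.0
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        r_oracle, _ = orthogonal_procrustes(ac, bc)
        resid_oracle = np.sqrt(np.mean(np.sum((ac @ r_oracle - bc) ** 2, 1)))
        assert res.residual_rms == pytest.approx(resid_oracle, rel=1e-9)

    def test_residual_invariant_to_presimilarity(self, rng):
        a = rng.uniform(-5, 5, size=(25, 3))
        b = rng.uniform(-5, 5, size=(25, 3))
        res0, _ = procrustes_align(a, b)
        pre = RigidTransform.from_euler((15, 25, 35), (3, -2, 1))
        res1, _ = procrustes_align(0.7 * pre.apply(a), b)
        assert res1.residual_rms == pytest.approx(res0.residual_rms, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            procrustes_align(np.ones((5, 3)), np.ones((5, 3)))
        with pytest.raises(ValueError, match="count"):
            procrustes_align(np.zeros((4, 3)), np.zeros((5, 3)))


class TestVolumeChange:
    def test_no_change(self):
        assert volume_change(5.0, 5.0) == (0.0, 0.0)

    @pytest.mark.parametrize("base,followup,delta,pct", [
        (8.130, 11.130, 3.000, 36.90),
        (7.424, 10.824, 3.400, 45.80),
    ])
    def test_growth_examples(self, base, followup, delta, pct):
        d, p = volume_change(base, followup)
        assert d == pytest.approx(delta, abs=1e-9)
        assert p == pytest.approx(pct, abs=0.01)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            volume_change(0.0, 1.0)


class TestExportColormap:
    def test_zero_field_green_and_exact_scalars(self, tmp_path, sphere10):
        field = SurfaceScalarField(sphere10, np.zeros(sphere10.n_vertices))
        p = tmp_path / "zero.vtk"
        export_colormap(field, p)
        back = read_mesh(p)
        assert np.all(back.scalars["remodelling_mm"] == 0.0)
        text = p.read_text()
        assert "COLOR_SCALARS" in text

    def test_inflation_field_roundtrip(self, tmp_path):
        base = icosphere_mesh(10.0, 2)
        grown = icosphere_mesh(11.0, 2)
        field = signed_distances(base, grown)
        p = tmp_path / "growth.vtk"
        export_colormap(field, p)
        back = read_mesh(p)
        assert np.abs(back.scalars["remodelling_mm"] - field.values).max() < 1e-6

    def test_mixed_field_colors(self, tmp_path, sphere10, rng):
        from bonemorph.morpho import remodelling_colors

        vals = rng.uniform(-2, 2, size=sphere10.n_vertices)
        rgb = remodelling_colors(vals, near_zero_band=0.2)
        assert np.all(rgb[vals > 0.2, 0] == 1.0)   # red outward
        assert np.all(rgb[vals < -0.2, 2] == 1.0)  # blue inward
        band = np.abs(vals) <= 0.2
        assert np.all(rgb[band] == [0.0, 1.0, 0.0])
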