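"""Cross-sections, clipping, lofting, and full restoration recovery."""

import numpy as np
import pytest

import tandemflow as tf
from tandemflow import restoration as rest
from tandemflow.io import validate_mesh
from tandemflow.metrics import point_surface_distance, symmetric_hausdorff
from tandemflow.types import ValidationError
from scipy.spatial import cKDTree


def _segment_mask(mesh, centerline, s0, s1):
    dense_s = np.linspace(0, centerline.length, 2000)
    tree = cKDTree(centerline.point_at(dense_s))
    _, idx = tree.query(mesh.vertices)
    s = dense_s[idx]
    return (s > s0) & (s < s1)


@pytest.fixture(scope="module")
def variants(tandem_phantom):
    return rest.build_model_variants(
        tandem_phantom.diseased_mesh,
        tandem_phantom.centerline,
        (10.0, 18.0),
        (21.5, 30.5),
        circumferential_resolution=48,
        junction_smoothing_steps=3,
    )


class TestMeasureCrossSection:
    def test_perpendicular_cylinder_diameter(self):
        spec = tf.PhantomSpec(centerline_kind="line", length=20.0, radius=2.0,
                              circumferential_resolution=64, axial_resolution=40)
        mesh = tf.make_phantom(spec).clean_mesh
        cs = rest.measure_cross_section(mesh, tf.Plane([10, 0, 0], [1, 0, 0]))
        assert cs.equivalent_diameter == pytest.approx(4.0, rel=0.005)

    def test_oblique_cut_ellipse_area(self):
        spec = tf.PhantomSpec(centerline_kind="line", length=20.0, radius=2.0,
                              circumferential_resolution=64, axial_resolution=80)
        mesh = tf.make_phantom(spec).clean_mesh
        th = np.deg2rad(30)
        cs = rest.measure_cross_section(mesh, tf.Plane([10, 0, 0], [np.cos(th), np.sin(th), 0]))
        assert cs.section_area == pytest.approx(np.pi * 4 / np.cos(th), rel=0.01)

    def test_plane_missing_mesh_rejected(self, straight_tube):
        with pytest.raises(ValidationError):
            rest.measure_cross_section(straight_tube.clean_mesh, tf.Plane([100, 0, 0], [1, 0, 0]))


class TestClipSegment:
    def test_removed_lateral_area(self, straight_tube):
        mesh, cl = straight_tube.clean_mesh, straight_tube.centerline
        p_in = tf.Plane(cl.point_at(5.0), cl.tangent_at(5.0))
        p_out = tf.Plane(cl.point_at(15.0), cl.tangent_at(15.0))
        parts = rest.clip_segment(mesh, p_in, p_out)
        removed = mesh.area() - parts["open_mesh"].area()
        assert removed == pytest.approx(2 * np.pi * 2.0 * 10.0, rel=0.02)

    def test_boundary_loops_planar(self, straight_tube):
        mesh, cl = straight_tube.clean_mesh, straight_tube.centerline
        p_in = tf.Plane(cl.point_at(5.0), cl.tangent_at(5.0))
        p_out = tf.Plane(cl.point_at(15.0), cl.tangent_at(15.0))
        parts = rest.clip_segment(mesh, p_in, p_out)
        assert np.abs(p_in.signed_distance(parts["loop_in"])).max() < 1e-7
        assert np.abs(p_out.signed_distance(parts["loop_out"])).max() < 1e-7

    def test_reversed_plane_order_rejected(self, straight_tube):
        mesh, cl = straight_tube.clean_mesh, straight_tube.centerline
        p_in = tf.Plane(cl.point_at(15.0), cl.tangent_at(15.0))
        p_out = tf.Plane(cl.point_at(5.0), cl.tangent_at(5.0))
        with pytest.raises(ValidationError, match="order"):
            rest.clip_segment(mesh, p_in, p_out)


class TestLoftTube:
    def _line(self):
        n = 50
        return tf.Centerline(np.column_stack([np.linspace(0, 20, n), np.zeros(n), np.zeros(n)]))

    def test_straight_constant_diameter_cylinder(self):
        tube = rest.loft_tube(self._line(), 2.0, 18.0, 4.0, 4.0, m=32, n=20)
        r = np.linalg.norm(tube.vertices[:, 1:], axis=1)
        np.testing.assert_allclose(r, 2.0, atol=1e-9)

    def test_linear_diameter_midpoint(self):
        tube = rest.loft_tube(self._line(), 5.0, 15.0, 2.0, 6.0, m=32, n=21)
        ring = tube.vertices[10 * 32 : 11 * 32]
        mid_d = 2 * np.linalg.norm(ring[:, 1:], axis=1).mean()
        assert mid_d == pytest.approx(4.0, abs=1e-9)

    def test_rings_perpendicular_to_tangent_on_arc(self, tandem_phantom):
        cl = tandem_phantom.centerline
        m, n = 32, 15
        tube = rest.loft_tube(cl, 5.0, 25.0, 4.0, 4.0, m=m, n=n)
        s = np.linspace(5.0, 25.0, n)
        pts, tg = cl.point_at(s), cl.tangent_at(s)
        for k in (0, n // 2, n - 1):
            ring = tube.vertices[k * m : (k + 1) * m]
            assert np.abs((ring - pts[k]) @ tg[k]).max() < 1e-7

    def test_self_intersection_guard(self):
        t = np.linspace(0, np.pi, 100)
        tight = tf.Centerline(np.column_stack([3 * np.cos(t), 3 * np.sin(t), np.zeros_like(t)]))
        with pytest.raises(ValidationError, match="curvature"):
            rest.loft_tube(tight, 1.0, 8.0, 8.0, 8.0, m=16, n=12)


class TestRestore:
    def test_recovers_clean_tube_over_segment(self, tandem_phantom):
        b = tandem_phantom
        job = rest.RestorationJob(b.diseased_mesh, b.centerline, 10.0, 18.0,
                                  circumferential_resolution=48, junction_smoothing_steps=3)
        restored = rest.restore(job)
        sm = b.centerline.length / b.spec.length
        mask_r = _segment_mask(restored, b.centerline, 10.2 * sm, 17.8 * sm)
        mask_c = _segment_mask(b.clean_mesh, b.centerline, 10.2 * sm, 17.8 * sm)
        h = symmetric_hausdorff(restored, b.clean_mesh, mask_r, mask_c)
        assert h <= 0.02 * b.spec.radius

    def test_restore_without_bulge_keeps_diameters(self, straight_tube):
        mesh, cl = straight_tube.clean_mesh, straight_tube.centerline
        restored = rest.restore(rest.RestorationJob(mesh, cl, 5.0, 15.0, circumferential_resolution=32))
        for s in (7.0, 10.0, 13.0):
            cs = rest.measure_cross_section(restored, tf.Plane(cl.point_at(s), cl.tangent_at(s)))
            assert cs.equivalent_diameter == pytest.approx(4.0, rel=0.02)

    def test_identity_outside_segment(self, tandem_phantom):
        b = tandem_phantom
        job = rest.RestorationJob(b.diseased_mesh, b.centerline, 10.0, 18.0,
                                  circumferential_resolution=48, junction_smoothing_steps=0)
        restored = rest.restore(job)
        sm = b.centerline.length / b.spec.length
        outside = ~_segment_mask(b.diseased_mesh, b.centerline, 9.0 * sm, 19.0 * sm)
        tree = cKDTree(restored.vertices)
        d, _ = tree.query(b.diseased_mesh.vertices[outside])
        assert d.max() == 0.0

    def test_non_watertight_input_rejected(self, tandem_phantom):
        b = tandem_phantom
        open_mesh = tf.SurfaceMesh(b.diseased_mesh.vertices.copy(), b.diseased_mesh.triangles[:-1].copy())
        with pytest.raises(ValidationError, match="watertight"):
            rest.restore(rest.RestorationJob(open_mesh, b.centerline, 10.0, 18.0))

    def test_restored_mesh_watertight(self, variants):
        for name in ("model_P", "model_D", "model_A"):
            report = validate_mesh(getattr(variants, name))
            assert report["watertight"] and report["non_manifold_edges"] == 0


class TestModelVariants:
    def test_model_a_matches_clean_tube_globally(self, tandem_phantom, variants):
        h = symmetric_hausdorff(variants.model_A, tandem_phantom.clean_mesh)
        assert h <= 0.02 * tandem_phantom.spec.radius

    def test_model_p_retains_distal_bulge(self, tandem_phantom, variants):
        d = point_surface_distance(variants.model_P.vertices, tandem_phantom.clean_mesh).max()
        assert d == pytest.approx(tandem_phantom.annotations[1].bulge.amplitude, rel=0.05)

    def test_model_d_retains_proximal_bulge(self, tandem_phantom, variants):
        d = point_surface_distance(variants.model_D.vertices, tandem_phantom.clean_mesh).max()
        assert d == pytest.approx(tandem_phantom.annotations[0].bulge.amplitude, rel=0.05)

    def test_diameter_profile_linear(self, tandem_phantom):
        """Tapered phantom: restored diameters linear in arc length."""
        spec = tf.PhantomSpec(centerline_kind="arc", length=40.0, radius=2.0, radius_out=2.8,
                              bulges=[tf.Bulge(14.0, 2.2, 2.8, [0, 0, 1])],
                              circumferential_resolution=48, axial_resolution=140)
        b = tf.make_phantom(spec)
        restored = rest.restore(rest.RestorationJob(b.diseased_mesh, b.centerline, 10.0, 18.0,
                                                    circumferential_resolution=48, junction_smoothing_steps=3))
        cl, sm = b.centerline, b.centerline.length / spec.length
        ss = np.linspace(10.5, 17.5, 12)
        ds = np.array([
            rest.measure_cross_section(restored, tf.Plane(cl.point_at(s * sm), cl.tangent_at(s * sm))).equivalent_diameter
            for s in ss
        ])
        A = np.vstack([ss, np.ones_like(ss)]).T
        _, res, *_ = np.linalg.lstsq(A, ds, rcond=None)
        r2 = 1 - res[0] / np.sum((ds - ds.mean()) ** 2)
        assert r2 > 0.999

    def test_order_invariance(self, tandem_phantom, variants):
        swapped = rest.build_model_variants(
            tandem_phantom.diseased_mesh, tandem_phantom.centerline,
            (21.5, 30.5), (10.0, 18.0),
            circumferential_resolution=48, junction_smoothing_steps=3,
        )
        for name in ("model_P", "model_D", "model_A"):
            a, bm = getattr(variants, name), getattr(swapped, name)
            np.testing.assert_allclose(
                np.sort(a.vertices.ravel()), np.sort(bm.vertices.ravel()), atol=1e-12
            )

    def test_model_a_segments_match_single_restorations(self, tandem_phantom, variants):
        """Restored-region geometry of Model A coincides with Model P / D."""
        b = tandem_phantom
        sm = b.centerline.length / b.spec.length
        for other, lo, hi in ((variants.model_P, 10.2, 17.8), (variants.model_D, 21.7, 30.3)):
            mask = _segment_mask(variants.model_A, b.centerline, lo * sm, hi * sm)
            d, _ = cKDTree(other.vertices).query(variants.model_A.vertices[mask])
            assert d.max() < 1e-6

    def test_overlapping_segments_rejected(self, tandem_phantom):
        with pytest.raises(ValidationError, match="overlap"):
            rest.build_model_variants(
                tandem_phantom.diseased_mesh, tandem_phantom.centerline, (10.0, 22.0), (18.0, 30.0)
            )
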