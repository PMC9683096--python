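"""Surface indicator oracles, Q-criterion exactness, vortex cores."""

import numpy as np
import pytest

import tandemflow as tf
from tandemflow import hemodynamics as hemo, synthetic
from tandemflow.types import ValidationError


@pytest.fixture(scope="module")
def small_mesh():
    spec = tf.PhantomSpec(centerline_kind="line", length=20.0, radius=2.0,
                          circumferential_resolution=16, axial_resolution=20)
    return tf.make_phantom(spec).clean_mesh


class TestTawss:
    def test_steady_exact(self, small_mesh):
        s = synthetic.analytic_wss_series("steady", {"tau0": [3, 4, 0]}, small_mesh, 20)
        np.testing.assert_allclose(hemo.tawss(s).values, 5.0)

    def test_pulsating_mean_recovered(self, small_mesh):
        s = synthetic.analytic_wss_series("pulsating_magnitude", {"tau0": [5, 0, 0], "a": 0.5}, small_mesh, 64)
        np.testing.assert_allclose(hemo.tawss(s).values, 5.0, atol=1e-10)

    def test_reversing_two_over_pi(self, small_mesh):
        n = 100
        s = synthetic.analytic_wss_series("reversing", {"tau0": [3, 0, 0]}, small_mesh, n)
        expected = 3.0 * 2 / np.pi
        assert np.abs(hemo.tawss(s).values - expected).max() < 3.0 * 5.0 / n**2

    def test_quadrature_error_second_order(self, small_mesh):
        """Halving the time step cuts the reversing-series error ~4x."""
        errs = []
        for n in (50, 100):  # even n so the |sin| kinks stay on grid points
            s = synthetic.analytic_wss_series("reversing", {"tau0": [3, 0, 0]}, small_mesh, n)
            errs.append(np.abs(hemo.tawss(s).values - 3.0 * 2 / np.pi).max())
        assert errs[1] <= errs[0] / 3.0


class TestAfi:
    def test_steady_unity(self, small_mesh):
        s = synthetic.analytic_wss_series("steady", {"tau0": [2, 0, 0]}, small_mesh, 10)
        np.testing.assert_allclose(hemo.afi(s, 4).values, 1.0)

    def test_antiparallel_instant_gives_minus_one(self, small_mesh):
        s = synthetic.analytic_wss_series("reversing", {"tau0": [3, 0, 0], "bias": 0.2}, small_mesh, 100)
        np.testing.assert_allclose(hemo.min_afi(s).values, -1.0, atol=1e-12)

    def test_sixty_degree_rotation_gives_half(self, small_mesh):
        """Two instants at +-60 deg in the tangent plane: the mean vector
        bisects them, so AFI = cos(60) exactly."""
        fr = hemo.tangent_frames(small_mesh)
        c, s60 = np.cos(np.pi / 3), np.sin(np.pi / 3)
        tau = np.stack([c * fr.p + s60 * fr.q, c * fr.p - s60 * fr.q])
        series = tf.WssSeries(small_mesh, np.array([0.0, 0.4]), tau, period=0.8)
        np.testing.assert_allclose(hemo.afi(series, 0).values, 0.5, atol=1e-9)

    def test_degenerate_mean_flagged(self, small_mesh):
        s = synthetic.analytic_wss_series("reversing", {"tau0": [3, 0, 0]}, small_mesh, 50)
        field = hemo.afi(s, 10)
        assert field.flagged.all()
        np.testing.assert_allclose(field.values, 1.0)

    def test_min_afi_lower_envelope(self, small_mesh):
        s = synthetic.analytic_wss_series("reversing", {"tau0": [2, 1, 0], "bias": 0.4}, small_mesh, 30)
        lower = hemo.min_afi(s).values
        for k in range(s.n_times):
            assert (lower <= hemo.afi(s, k).values + 1e-12).all()


class TestTangentFrames:
    def test_orthonormal_on_phantom(self, small_mesh):
        fr = hemo.tangent_frames(small_mesh)
        for a, b in ((fr.p, fr.q), (fr.p, fr.n), (fr.q, fr.n)):
            assert np.abs(np.einsum("ij,ij->i", a, b)).max() < 1e-9
        for a in (fr.p, fr.q, fr.n):
            np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-9)

    def test_cylinder_normals_radial(self, small_mesh):
        fr = hemo.tangent_frames(small_mesh)
        lateral = (small_mesh.vertices[:, 0] > 2) & (small_mesh.vertices[:, 0] < 18)
        radial = small_mesh.vertices[lateral].copy()
        radial[:, 0] = 0
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", fr.n[lateral], radial)
        assert np.abs(dots - 1.0).max() < 0.01


class TestGon:
    def test_steady_zero(self, small_mesh):
        s = synthetic.analytic_wss_series("steady", {"tau0": [4, 0, 0], "gradient": [0.1, 0, 0]}, small_mesh, 20)
        np.testing.assert_allclose(hemo.gon(s).values, 0.0, atol=1e-12)

    def test_reversing_linear_field_unity(self, small_mesh):
        s = synthetic.analytic_wss_series("reversing", {"tau0": [3, 0, 0], "gradient": [0.02, 0, 0]}, small_mesh, 50)
        field = hemo.gon(s)
        assert np.abs(field.values[~field.flagged] - 1.0).max() < 1e-9

    def test_range_on_random_series(self, small_mesh, rng):
        """GON in [0,1], AFI in [-1,1], TAWSS >= 0 on 100 random series."""
        nv = len(small_mesh.vertices)
        frames = hemo.tangent_frames(small_mesh)
        for _ in range(100):
            tau = rng.normal(size=(6, nv, 3))
            series = tf.WssSeries(small_mesh, 0.8 * np.arange(6) / 6, tau, period=0.8)
            g = hemo.gon(series, frames).values
            assert (g >= 0).all() and (g <= 1).all()
            assert (hemo.tawss(series).values >= 0).all()
            a = hemo.afi(series, 2).values
            assert (np.abs(a) <= 1).all()

    def test_matches_direct_summation_oracle(self, rng):
        """GON re-derived with an explicit per-face loop implementation."""
        spec = tf.PhantomSpec(centerline_kind="line", length=10.0, radius=1.5,
                              circumferential_resolution=10, axial_resolution=10)
        mesh = tf.make_phantom(spec).clean_mesh
        nv = len(mesh.vertices)
        nt = 5
        tau = rng.normal(size=(nt, nv, 3))
        series = tf.WssSeries(mesh, 0.8 * np.arange(nt) / nt, tau, period=0.8)
        frames = hemo.tangent_frames(mesh)
        got = hemo.gon(series, frames).values

        # oracle: slow loops, least-squares in-plane gradient per face
        areas = mesh.triangle_areas()
        G = np.zeros((nt, nv, 2))
        wsum = np.zeros(nv)
        for t_idx in range(nt):
            acc = np.zeros((nv, 3, 2))
            for f, (i, j, k) in enumerate(mesh.triangles):
                fp = [tau[t_idx, v] @ frames.p[v] for v in (i, j, k)]
                fq = [tau[t_idx, v] @ frames.q[v] for v in (i, j, k)]
                a, b, c = mesh.vertices[[i, j, k]]
                M = np.vstack([b - a, c - a])
                gp, *_ = np.linalg.lstsq(M, np.array([fp[1] - fp[0], fp[2] - fp[0]]), rcond=None)
                gq, *_ = np.linalg.lstsq(M, np.array([fq[1] - fq[0], fq[2] - fq[0]]), rcond=None)
                for v in (i, j, k):
                    acc[v, :, 0] += areas[f] * gp
                    acc[v, :, 1] += areas[f] * gq
                    if t_idx == 0:
                        wsum[v] += areas[f]
            for v in range(nv):
                G[t_idx, v, 0] = (acc[v, :, 0] / wsum[v]) @ frames.p[v]
                G[t_idx, v, 1] = (acc[v, :, 1] / wsum[v]) @ frames.q[v]
        num = np.linalg.norm(G.mean(axis=0), axis=1)
        den = np.linalg.norm(G, axis=2).mean(axis=0)
        expected = 1.0 - num / den
        np.testing.assert_allclose(got, expected, atol=1e-8)


class TestFrameInvariance:
    def test_indicators_invariant_under_global_rotation(self, small_mesh, rng):
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        s = synthetic.analytic_wss_series(
            "reversing", {"tau0": [3, 1, 0], "bias": 0.3, "gradient": [0.05, 0.02, 0]}, small_mesh, 20
        )
        mesh_r = tf.SurfaceMesh(small_mesh.vertices @ q.T, small_mesh.triangles.copy())
        s_r = tf.WssSeries(mesh_r, s.times, s.tau @ q.T, period=s.period)
        np.testing.assert_allclose(hemo.tawss(s_r).values, hemo.tawss(s).values, atol=1e-9)
        np.testing.assert_allclose(hemo.afi(s_r, 7).values, hemo.afi(s, 7).values, atol=1e-9)
        fr = hemo.tangent_frames(small_mesh)
        fr_r = hemo.TangentFrameSet(mesh_r, fr.p @ q.T, fr.q @ q.T, fr.n @ q.T)
        np.testing.assert_allclose(hemo.gon(s_r, fr_r).values, hemo.gon(s, fr).values, atol=1e-9)


class TestQCriterion:
    @pytest.fixture(scope="class")
    @staticmethod
    def box():
        return synthetic.box_tet_mesh((-1, -1, -1), (1, 1, 1), (4, 4, 4))

    @pytest.mark.parametrize(
        "kind,params,expected",
        [
            ("solid_rotation", {"omega": 10.0}, 100.0),
            ("pure_shear", {"gamma": 3.0}, 0.0),
            ("planar_strain", {"gamma": 3.0}, -9.0),
        ],
    )
    def test_exact_on_affine_fields(self, box, kind, params, expected):
        pts, tets = box
        qf = hemo.q_field(synthetic.analytic_velocity(kind, params, pts, tets))
        assert np.abs(qf.q - expected).max() < 1e-9

    def test_poiseuille_nonpositive_and_converging(self):
        errs = []
        for nr, nz in [(5, 8), (10, 16)]:
            pts, tets = synthetic.cylinder_tet_mesh(1.0, 3.0, nr, nz)
            qf = hemo.q_field(synthetic.analytic_velocity("poiseuille", {"u_max": 1.0, "radius": 1.0}, pts, tets))
            assert qf.q.max() <= 1e-12 * qf.gradient_scale
            errs.append(np.abs(qf.q).max())
        assert errs[1] <= 0.75 * errs[0]

    def test_poiseuille_empty_core_set(self):
        pts, tets = synthetic.cylinder_tet_mesh(1.0, 3.0, 8, 10)
        qf = hemo.q_field(synthetic.analytic_velocity("poiseuille", {"u_max": 1.0, "radius": 1.0}, pts, tets))
        assert len(hemo.extract_vortex_cores(qf, 0.08)) == 0

    def test_degenerate_tet_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        with pytest.raises(ValidationError):
            tf.VolumeField(pts, np.array([[0, 1, 2, 3]]), np.zeros((4, 3)))


class TestVortexCores:
    @pytest.fixture(scope="class")
    @staticmethod
    def lamb_oseen():
        pts, tets = synthetic.cylinder_tet_mesh(2.0, 8.0, 10, 14)
        field = synthetic.analytic_velocity("lamb_oseen", {"circulation": 60.0, "core_radius": 0.6}, pts, tets)
        return hemo.q_field(field)

    def test_single_component_on_axis(self, lamb_oseen):
        cores = hemo.extract_vortex_cores(lamb_oseen, 0.08)
        assert len(cores) == 1
        cen = cores.components[0]["centroid"]
        assert np.hypot(cen[0], cen[1]) < 0.6

    def test_threshold_monotonicity(self, lamb_oseen):
        tight = hemo.extract_vortex_cores(lamb_oseen, 0.5)
        loose = hemo.extract_vortex_cores(lamb_oseen, 0.08)
        s_t = set(np.concatenate([c["tet_ids"] for c in tight.components]).tolist())
        s_l = set(np.concatenate([c["tet_ids"] for c in loose.components]).tolist())
        assert s_t <= s_l

    def test_components_sorted_by_volume(self, lamb_oseen):
        cores = hemo.extract_vortex_cores(lamb_oseen, 0.02)
        vols = [c["volume"] for c in cores.components]
        assert vols == sorted(vols, reverse=True)

    def test_proximity_to_roi(self, lamb_oseen, straight_tube):
        # place an ROI patch right next to the vortex axis region
        mesh = straight_tube.clean_mesh
        near = np.flatnonzero(np.linalg.norm(mesh.triangle_centroids() - [0.0, 0.0, 2.0], axis=1) < 3.0)
        roi = tf.RoiPatch(mesh, near)
        report = hemo.core_roi_proximity(hemo.extract_vortex_cores(lamb_oseen, 0.08), roi, delta=5.0)
        assert len(report) == 1 and report[0]["near_roi"]

    def test_empty_core_set_empty_report(self, straight_tube):
        pts, tets = synthetic.cylinder_tet_mesh(1.0, 3.0, 6, 8)
        qf = hemo.q_field(synthetic.analytic_velocity("poiseuille", {"u_max": 1.0, "radius": 1.0}, pts, tets))
        cores = hemo.extract_vortex_cores(qf, 0.08)
        roi = tf.RoiPatch(straight_tube.clean_mesh, np.array([0, 1]))
        assert hemo.core_roi_proximity(cores, roi, 1.0) == []

    def test_distance_invariant_under_joint_rigid_motion(self, lamb_oseen, straight_tube, rng):
        mesh = straight_tube.clean_mesh
        roi = tf.RoiPatch(mesh, np.arange(20))
        cores = hemo.extract_vortex_cores(lamb_oseen, 0.08)
        d0 = hemo.core_roi_proximity(cores, roi, 1.0)[0]["distance"]
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([5.0, -2.0, 9.0])
        vol = lamb_oseen.volume
        vol_r = tf.VolumeField(vol.points @ q.T + shift, vol.tets.copy(), vol.velocity @ q.T)
        qf_r = hemo.QField(vol_r, lamb_oseen.q.copy(), lamb_oseen.gradient_scale)
        mesh_r = tf.SurfaceMesh(mesh.vertices @ q.T + shift, mesh.triangles.copy())
        roi_r = tf.RoiPatch(mesh_r, np.arange(20))
        cores_r = hemo.extract_vortex_cores(qf_r, 0.08)
        d1 = hemo.core_roi_proximity(cores_r, roi_r, 1.0)[0]["distance"]
        assert abs(d0 - d1) < 1e-8
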