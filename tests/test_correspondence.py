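import numpy as np
import pytest

from faceage.correspondence import (CpdParams, build_correspondence, cpd_nonrigid,
                                    prune_vertices, rigid_prealign)
from faceage.exceptions import DegenerateGeometryError, ValidationError
from faceage.geometry import project_to_surface
from faceage.mesh_io import LandmarkSet, LongitudinalSeries, TriangleMesh
from faceage.rigid import RigidTransform


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


# ---------------------------------------------------------------- prealign

class TestRigidPrealign:
    def test_identity(self, template_small):
        _, lms = template_small
        t = rigid_prealign(lms, lms)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(t.translation).max() < 1e-9

    def test_exact_recovery_of_known_motion(self, template_small):
        _, lms = template_small
        R, t = _rot_z(30.0), np.array([5.0, 0.0, 0.0])
        dst = LandmarkSet.from_array(lms.as_array() @ R.T + t)
        rec = rigid_prealign(lms, dst)
        assert np.abs(rec.apply(lms.as_array()) - dst.as_array()).max() < 1e-9

    def test_noisy_fit_beats_random_transforms(self, template_small):
        _, lms = template_small
        rng = np.random.default_rng(42)
        src = lms.as_array()
        dst = src @ _rot_z(12.0).T + [3.0, -2.0, 1.0] + rng.normal(0, 0.5, src.shape)
        fit = rigid_prealign(lms, LandmarkSet.from_array(dst))
        best = ((fit.apply(src) - dst) ** 2).sum()
        # brute-force oracle: random rigid transforms must never do better
        for _ in range(10_000):
            A = rng.normal(size=(3, 3))
            Q, _r = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] = -Q[:, 0]
            tr = dst.mean(0) - Q @ src.mean(0) + rng.normal(0, 1.0, 3)
            rss = ((src @ Q.T + tr - dst) ** 2).sum()
            assert best <= rss + 1e-9

    def test_collinear_landmarks_rejected(self):
        arr = np.zeros((9, 3))
        arr[:, 0] = np.arange(9)          # all on the x-axis
        with pytest.raises(DegenerateGeometryError):
            rigid_prealign(LandmarkSet.from_array(arr), LandmarkSet.from_array(arr))


# ---------------------------------------------------------------- CPD

class TestCpd:
    def test_identity_registration_moves_nothing(self, template_small):
        mesh, _ = template_small
        params = CpdParams.from_points(mesh.vertices)
        res = cpd_nonrigid(mesh.vertices, mesh.vertices, params)
        disp = np.linalg.norm(res.displaced - mesh.vertices, axis=1)
        assert disp.max() < 1e-3 * params.beta

    def test_smooth_bump_recovered(self, template_small):
        mesh, _ = template_small
        V = mesh.vertices
        params = CpdParams.from_points(V)
        c = np.array([10.0, -20.0, 30.0])
        amp = 2.0 * np.exp(-((V - c) ** 2).sum(1) / (2 * (1.2 * params.beta) ** 2))
        target = V + amp[:, None] * np.array([0.3, 0.2, 0.93])
        res = cpd_nonrigid(V, target, params)
        rms = np.sqrt(((res.displaced - target) ** 2).sum(1).mean())
        assert rms < 0.25

    def test_outlier_robustness(self, template_small):
        mesh, _ = template_small
        V = mesh.vertices
        rng = np.random.default_rng(1)
        c = np.array([0.0, 10.0, 35.0])
        params = CpdParams.from_points(V)
        amp = 2.0 * np.exp(-((V - c) ** 2).sum(1) / (2 * (1.5 * params.beta) ** 2))
        truth = V + amp[:, None] * np.array([0.0, 0.3, 0.95])
        # controlled comparison: identical params (w = 0.5) with and
        # without 30% junk points appended to the target
        params_w = CpdParams.from_points(V, w=0.5)
        clean_rms = np.sqrt(((cpd_nonrigid(V, truth, params_w).displaced - truth) ** 2)
                            .sum(1).mean())
        n_out = int(0.3 * len(V))
        junk = rng.uniform(V.min(0) - 20, V.max(0) + 20, (n_out, 3))
        noisy_target = np.vstack([truth, junk])
        noisy_rms = np.sqrt(((cpd_nonrigid(V, noisy_target, params_w).displaced - truth) ** 2)
                            .sum(1).mean())
        assert noisy_rms < 2 * clean_rms + 0.05

    def test_rigid_equivariance(self, template_small):
        mesh, _ = template_small
        V = mesh.vertices[::2]
        rng = np.random.default_rng(5)
        bump = 1.5 * np.exp(-((V - [0, 0, 30]) ** 2).sum(1) / (2 * 30.0 ** 2))
        target = V + bump[:, None] * np.array([0.2, 0.1, 0.97])
        R = _rot_z(25.0)
        t = np.array([4.0, -7.0, 2.0])
        params = CpdParams.from_points(V, max_iter=60)
        plain = cpd_nonrigid(V, target, params).displaced
        moved = cpd_nonrigid(V @ R.T + t, target @ R.T + t, params).displaced
        assert np.abs(moved - (plain @ R.T + t)).max() < 1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            CpdParams(beta=-1.0)
        with pytest.raises(ValidationError):
            CpdParams(beta=1.0, w=1.0)

    def test_low_rank_matches_exact(self, template_small):
        mesh, _ = template_small
        V = mesh.vertices
        c = np.array([10.0, -20.0, 30.0])
        amp = 2.0 * np.exp(-((V - c) ** 2).sum(1) / (2 * 30.0 ** 2))
        target = V + amp[:, None] * np.array([0.3, 0.2, 0.93])
        exact = cpd_nonrigid(V, target, CpdParams.from_points(V)).displaced
        lowrank = cpd_nonrigid(V, target, CpdParams.from_points(
            V, low_rank_threshold=100, low_rank_k=80)).displaced
        assert np.sqrt(((exact - lowrank) ** 2).sum(1).mean()) < 0.05


# ---------------------------------------------------------------- projection

class TestProjection:
    def test_point_on_surface_is_fixed(self, template_small):
        mesh, _ = template_small
        tri = mesh.vertices[mesh.faces[7]]
        p = tri.mean(axis=0)
        proj, dist, fid = project_to_surface(p[None], mesh)
        assert dist[0] < 1e-12
        assert np.abs(proj[0] - p).max() < 1e-12

    def test_orthogonal_drop_to_centroid(self):
        mesh = TriangleMesh(np.array([[0., 0, 0], [2, 0, 0], [0, 2, 0]]),
                            np.array([[0, 1, 2]]))
        centroid = mesh.vertices.mean(axis=0)
        h = 3.7
        proj, dist, fid = project_to_surface((centroid + [0, 0, h])[None], mesh)
        assert abs(dist[0] - h) < 1e-12
        assert np.abs(proj[0] - centroid).max() < 1e-12

    def test_matches_trimesh_oracle_on_random_points(self, template_small):
        mesh, _ = template_small
        rng = np.random.default_rng(0)
        pts = rng.uniform([-80, -100, -20], [80, 100, 80], (500, 3))
        proj, dist, fid = project_to_surface(pts, mesh)
        from trimesh.proximity import closest_point_naive
        cp, d, _tid = closest_point_naive(mesh.as_trimesh(), pts)
        assert np.abs(proj - cp).max() < 1e-9
        assert np.abs(dist - d).max() < 1e-9

    def test_projected_point_lies_on_reported_face(self, template_small):
        mesh, _ = template_small
        rng = np.random.default_rng(3)
        pts = rng.uniform([-60, -80, 0], [60, 80, 60], (100, 3))
        proj, _dist, fid = project_to_surface(pts, mesh)
        for p, f in zip(proj, fid):
            tri = mesh.vertices[mesh.faces[f]]
            # gap between p and its own closest point on that triangle
            from faceage.geometry import closest_point_on_triangles
            again = closest_point_on_triangles(p[None], tri[None])[0, 0]
            assert np.abs(again - p).max() < 1e-9


# ---------------------------------------------------------------- pruning

class TestPruning:
    def test_all_zero_distances_keep_everything(self):
        mask = prune_vertices(np.zeros((4, 100)), 1.0)
        assert mask.all()

    def test_single_bad_vertex_removed_everywhere(self):
        D = np.zeros((5, 50))
        D[2, 17] = 10.0
        mask = prune_vertices(D, 1.0)
        assert not mask[17]
        assert mask.sum() == 49

    def test_over_pruning_aborts(self):
        D = np.full((2, 10), 5.0)
        with pytest.raises(ValidationError, match="%"):
            prune_vertices(D, 1.0)

    def test_hole_vertices_are_pruned(self):
        from faceage.synthetic import SynthConfig, build_dataset
        cfg = SynthConfig(n_subjects=1, template_vertices=800, noise_sd_mm=0.0,
                          remesh=False, hole_fraction=0.05, cohorts=((7, 12),), seed=9)
        series, gt = build_dataset(cfg)
        s = series[0]
        sub = [LongitudinalSeries(s.subject_id, s.sex, s.records[:2])]
        # noise-free scans justify a tight pruning threshold (1 median edge);
        # a vertex hovering over a hole sits about its in-plane rim distance
        # away from the surviving surface, so the threshold sets how deep
        # into the hole pruning can reach
        res = build_correspondence(sub, base_choice=0, prune_k=1.0)
        xy0 = gt.scan_xy[(s.subject_id, s.records[0].age)]
        spacing = 1.5 * s.records[0].mesh.median_edge_length()
        deep_hole = np.zeros(len(xy0), dtype=bool)
        for rec in s.records[1:2]:
            c, r = gt.hole_discs[(s.subject_id, rec.age)]
            deep_hole |= np.linalg.norm(xy0 - c, axis=1) < (r - spacing)
        assert deep_hole.sum() > 0
        assert (~res.mask[deep_hole]).mean() >= 0.9
        # and the surviving fraction is still the vast majority of the face
        assert res.mask.mean() > 0.8


# ---------------------------------------------------------------- pipeline

class TestBuildCorrespondence:
    def test_self_correspondence(self, template_small):
        mesh, lms = template_small
        from faceage.mesh_io import SpecimenRecord
        rec = SpecimenRecord("s1", "F", 8.0, 1.3, 30.0, mesh, lms)
        rec2 = SpecimenRecord("s1", "F", 9.0, 1.3, 30.0, mesh, lms)
        series = [LongitudinalSeries("s1", "F", [rec, rec2])]
        res = build_correspondence(series, base_choice=0)
        assert len(res.samples) == 2
        assert np.abs(res.samples[0].points - mesh.vertices).max() < 1e-3

    def test_output_dimension_follows_base_choice(self, clean_pair):
        series, _gt = clean_pair
        res = build_correspondence([series], base_choice=1)
        V = series.records[1].mesh.n_vertices
        assert all(len(s.points) == V for s in res.samples)

    def test_remeshed_pair_recovers_true_homology(self, clean_pair):
        series, gt = clean_pair
        res = build_correspondence([series], base_choice=0)
        sid = series.subject_id
        xy0 = gt.scan_xy[(sid, series.records[0].age)]
        m = res.mask
        for samp, rec in zip(res.samples, series.records):
            truth = gt.jitters[(sid, rec.age)].apply(gt.surface(sid, xy0, rec.age))
            rms = np.sqrt(((samp.points[m] - truth[m]) ** 2).sum(1).mean())
            assert rms < 0.5

    def test_error_decreases_with_noise(self):
        from faceage.synthetic import SynthConfig, build_dataset
        errs = []
        for sig in (1.0, 0.1, 0.0):
            cfg = SynthConfig(n_subjects=1, template_vertices=500, noise_sd_mm=sig,
                              remesh=True, seed=3)
            series, gt = build_dataset(cfg)
            s = series[0]
            sub = [LongitudinalSeries(s.subject_id, s.sex, s.records[:2])]
            res = build_correspondence(sub, base_choice=0)
            xy0 = gt.scan_xy[(s.subject_id, s.records[0].age)]
            rec = s.records[1]
            truth = gt.jitters[(s.subject_id, rec.age)].apply(
                gt.surface(s.subject_id, xy0, rec.age))
            m = res.mask
            errs.append(float(np.sqrt(((res.samples[1].points[m] - truth[m]) ** 2)
                                      .sum(1).mean())))
        assert errs[0] >= errs[1] >= errs[2] - 0.05
        assert errs[2] < errs[0]
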