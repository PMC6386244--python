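import numpy as np
import pytest
from scipy import stats

from faceage.exceptions import ValidationError
from faceage.prediction import (PredictionResult, age_transform, baseline_comparison,
                                cohort_evaluation, prediction_error)
from faceage.shape_space import AlignedSample, fit_pca, from_scores, to_scores
from faceage.trajectory import LinearAgeModel, hermite_glue


def _space(rng, V=20, n=6):
    pts = [rng.normal(0, 20, (V, 3)) for _ in range(n)]
    aligned = [AlignedSample(f"s{i}", 7.0 + i, "F", p) for i, p in enumerate(pts)]
    return fit_pca(aligned, 1.0), aligned


def _traj(K, slope=0.5):
    y = LinearAgeModel(np.zeros(K), np.full(K, slope), (7.0, 12.0))
    o = LinearAgeModel(np.full(K, 2.0), np.full(K, slope * 0.4), (12.0, 17.0))
    return hermite_glue(y, o, "F")


class TestAgeTransform:
    def test_zero_portion_is_pca_round_trip(self):
        rng = np.random.default_rng(0)
        space, aligned = _space(rng)
        traj = _traj(space.n_components)
        s = aligned[2]
        pred = age_transform(s, s.age, traj, space)
        ref = from_scores(to_scores(s, space), space)
        assert np.abs(pred - ref).max() < 1e-12

    def test_progress_then_regress_returns(self):
        rng = np.random.default_rng(1)
        space, aligned = _space(rng)
        traj = _traj(space.n_components)
        s = aligned[1]
        fwd = age_transform(s, 12.0, traj, space)
        fwd_sample = AlignedSample(s.subject_id, 12.0, "F", fwd)
        back = age_transform(fwd_sample, s.age, traj, space)
        direct = age_transform(s, s.age, traj, space)
        assert np.abs(back - direct).max() < 1e-9

    def test_sex_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        space, aligned = _space(rng)
        traj = _traj(space.n_components)
        bad = AlignedSample("x", 8.0, "M", aligned[0].points)
        with pytest.raises(ValidationError):
            age_transform(bad, 10.0, traj, space)

    def test_on_trajectory_subject_predicted_exactly(self):
        # subject whose scans lie exactly on the generator's trajectory:
        # ageing 7 -> 12 must land on the true age-12 surface (up to PCA truncation)
        from faceage.correspondence import CorrespondedSample
        from faceage.shape_space import gpa_align
        from faceage.synthetic import SynthConfig, build_dataset
        from faceage.trajectory import fit_global_trajectory
        cfg = SynthConfig(n_subjects=6, template_vertices=300, noise_sd_mm=0.0,
                          remesh=False, jitter_rot_deg=0.0, jitter_trans_mm=0.0,
                          identity_sd_mm=0.0, seed=31)   # no identity: all on trajectory
        series, gt = build_dataset(cfg)
        samples = [CorrespondedSample(s.subject_id, r.age, s.sex,
                                      gt.true_points[(s.subject_id, r.age)])
                   for s in series if s.sex == "F" for r in s.records]
        aligned, _ = gpa_align(samples)
        space = fit_pca(aligned, 1.0 - 1e-12)
        scores = {}
        for s in aligned:
            scores.setdefault(s.subject_id, []).append((s.age, to_scores(s, space).scores))
        traj, _, _ = fit_global_trajectory(scores, 12.0, "F")
        young = next(s for s in aligned if s.age == 7.0)
        truth12 = next(s for s in aligned
                       if s.subject_id == young.subject_id and s.age == 12.0)
        pred = age_transform(young, 12.0, traj, space)
        rms = np.sqrt(((pred - truth12.points) ** 2).sum(1).mean())
        assert rms < 0.5


class TestPredictionError:
    def test_exact_prediction_is_zero(self):
        pts = np.random.default_rng(3).normal(size=(15, 3))
        actual = AlignedSample("a", 12.0, "F", pts)
        res = prediction_error(pts, actual)
        assert res.mean_error == 0.0

    def test_uniform_offset(self):
        pts = np.random.default_rng(4).normal(size=(15, 3))
        actual = AlignedSample("a", 12.0, "F", pts)
        res = prediction_error(pts + [2.0, 0, 0], actual)
        assert np.abs(res.per_vertex_error - 2.0).max() < 1e-12
        assert abs(res.mean_error - 2.0) < 1e-12

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        pred = rng.normal(size=(30, 3))
        act = rng.normal(size=(30, 3))
        res = prediction_error(pred, AlignedSample("a", 12.0, "F", act))
        looped = np.array([np.sqrt(((pred[i] - act[i]) ** 2).sum()) for i in range(30)])
        assert np.abs(res.per_vertex_error - looped).max() < 1e-12
        assert abs(res.mean_error - looped.mean()) < 1e-12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        pred = rng.normal(size=(25, 3))
        act = rng.normal(size=(25, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        t = np.array([3.0, -1.0, 7.0])
        e1 = prediction_error(pred, AlignedSample("a", 12.0, "F", act)).mean_error
        e2 = prediction_error(pred @ Q.T + t,
                              AlignedSample("a", 12.0, "F", act @ Q.T + t)).mean_error
        assert abs(e1 - e2) < 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            prediction_error(np.zeros((5, 3)), AlignedSample("a", 12.0, "F", np.zeros((6, 3))))


class TestCohortEvaluation:
    @staticmethod
    def _flat_traj(K):
        y = LinearAgeModel(np.zeros(K), np.zeros(K), (7.0, 12.0))
        o = LinearAgeModel(np.zeros(K), np.zeros(K), (12.0, 17.0))
        return hermite_glue(y, o, "F")

    @staticmethod
    def _two_scan_cohort(rng, offsets):
        """Subjects whose old face is the young face plus a known offset."""
        young = rng.normal(0, 20, (10, 3))
        subj = []
        for i, off in enumerate(offsets):
            subj.append(AlignedSample(f"s{i}", 7.0, "F", young + rng.normal(0, 5, (10, 3))))
            subj.append(AlignedSample(f"s{i}", 12.0, "F",
                                      subj[-1].points + np.array([off, 0.0, 0.0])))
        return subj

    def test_two_subject_average_map(self):
        # constant trajectory + full-rank PCA: prediction == young face,
        # so per-subject error maps are exactly the programmed offsets
        rng = np.random.default_rng(7)
        subj = self._two_scan_cohort(rng, [1.0, 3.0])
        space = fit_pca(subj, 1.0)
        results, group_map = cohort_evaluation(subj, self._flat_traj(space.n_components),
                                               space)
        assert np.abs(group_map - 2.0).max() < 1e-6     # (1 + 3) / 2

    def test_zero_error_when_prediction_exact(self):
        rng = np.random.default_rng(19)
        subj = self._two_scan_cohort(rng, [0.0, 0.0, 0.0])
        space = fit_pca(subj, 1.0)
        _results, group_map = cohort_evaluation(subj, self._flat_traj(space.n_components),
                                                space)
        assert np.abs(group_map).max() < 1e-6

    def test_single_scan_subjects_skipped(self):
        rng = np.random.default_rng(8)
        subj = self._two_scan_cohort(rng, [1.0, 2.0, 3.0])
        space = fit_pca(subj, 1.0)
        extras = [AlignedSample("solo", 9.0, "F", subj[0].points)]
        results, _ = cohort_evaluation(subj + extras,
                                       self._flat_traj(space.n_components), space)
        assert "solo" not in [r.subject_id for r in results]
        assert len(results) == 3


class TestBaselineComparison:
    def _results(self, errors, ids=None):
        ids = ids or [f"s{i}" for i in range(len(errors))]
        return [PredictionResult(i, 7.0, 12.0, np.zeros((1, 3)), np.zeros(1), e)
                for i, e in zip(ids, errors)]

    def test_identical_errors_no_difference(self):
        aged = self._results([1.0, 2.0, 3.0])
        comp = baseline_comparison(aged, self._results([1.0, 2.0, 3.0]))
        assert comp.mean_improvement == 0.0
        assert comp.p_value == 1.0
        assert comp.degenerate

    def test_constant_shift_flagged_degenerate(self):
        aged = self._results([1.0, 2.0, 3.0])
        base = self._results([2.0, 3.0, 4.0])
        comp = baseline_comparison(aged, base)
        assert comp.mean_improvement == 1.0
        assert comp.degenerate and comp.p_value == 0.0

    def test_matches_textbook_paired_t(self):
        rng = np.random.default_rng(9)
        aged_err = rng.uniform(1.0, 2.0, 8)
        base_err = aged_err + rng.normal(1.0, 0.3, 8)
        comp = baseline_comparison(self._results(aged_err), self._results(base_err))
        d = base_err - aged_err
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t_ref), len(d) - 1)
        assert abs(comp.t_statistic - t_ref) < 1e-10
        assert abs(comp.p_value - p_ref) < 1e-10

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            baseline_comparison(self._results([1, 2, 3]),
                                self._results([1, 2, 3], ids=["a", "b", "c"]))
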