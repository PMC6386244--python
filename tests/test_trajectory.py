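import numpy as np
import pytest

from faceage.exceptions import ValidationError
from faceage.trajectory import (GlobalTrajectory, LinearAgeModel, evaluate_trajectory,
                                fit_global_trajectory, fit_series_linear,
                                group_mean_model, hermite_glue, load_trajectory,
                                save_trajectory, trajectory_speed)


def _line_model(b, v, rng=(7.0, 12.0)):
    return LinearAgeModel(np.atleast_1d(b), np.atleast_1d(v), rng)


class TestSeriesFit:
    def test_exact_line_recovered(self):
        b = np.array([1.0, -2.0, 0.5])
        v = np.array([0.3, 0.0, -1.1])
        obs = [(a, b + v * a) for a in [7.0, 8.0, 9.0, 11.0]]
        m = fit_series_linear(obs)
        assert np.abs(m.intercept - b).max() < 1e-10
        assert np.abs(m.slope - v).max() < 1e-10
        assert m.age_range == (7.0, 11.0)

    def test_two_points_interpolate(self):
        obs = [(8.0, np.array([1.0])), (10.0, np.array([5.0]))]
        m = fit_series_linear(obs)
        assert abs(m(8.0)[0] - 1.0) < 1e-12
        assert abs(m(10.0)[0] - 5.0) < 1e-12

    def test_equal_ages_rejected(self):
        with pytest.raises(ValidationError):
            fit_series_linear([(8.0, np.zeros(2)), (8.0, np.ones(2))])

    def test_slope_unbiased_under_noise(self):
        # 500 Monte-Carlo replicates of a 6-age series with score noise
        rng = np.random.default_rng(17)
        v_true = 0.7
        ages = np.arange(7.0, 13.0)
        slopes = []
        for _ in range(500):
            scores = 2.0 + v_true * ages + rng.normal(0, 0.1, len(ages))
            slopes.append(fit_series_linear(list(zip(ages, scores[:, None]))).slope[0])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - v_true) < 2 * se + 1e-12


class TestGroupMean:
    def test_single_model_is_identity(self):
        m = _line_model([1.0, 2.0], [0.1, 0.2])
        g = group_mean_model([m])
        assert np.array_equal(g.intercept, m.intercept)
        assert np.array_equal(g.slope, m.slope)

    def test_opposite_slopes_cancel(self):
        g = group_mean_model([_line_model(0.0, 1.0), _line_model(0.0, -1.0)])
        assert np.abs(g.slope).max() == 0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            group_mean_model([])

    def test_age_range_is_union(self):
        g = group_mean_model([_line_model(0, 1, (7, 11)), _line_model(0, 1, (8, 12))])
        assert g.age_range == (7.0, 12.0)


class TestHermiteGlue:
    def test_collinear_cohorts_degenerate_to_line(self):
        m = _line_model([2.0], [0.5], (7.0, 12.0))
        m2 = _line_model([2.0], [0.5], (12.0, 17.0))
        traj = hermite_glue(m, m2)
        for a in np.linspace(9.5, 14.5, 21):
            assert abs(evaluate_trajectory(traj, a)[0] - (2.0 + 0.5 * a)) < 1e-12

    def test_endpoint_interpolation(self):
        y = _line_model([1.0, 0.0], [0.2, -0.1], (7.0, 12.0))
        o = _line_model([-3.0, 4.0], [0.6, 0.0], (12.0, 17.0))
        traj = hermite_glue(y, o)
        c_y, c_o = traj.knots
        assert np.abs(evaluate_trajectory(traj, c_y) - y(c_y)).max() < 1e-12
        assert np.abs(evaluate_trajectory(traj, c_o) - o(c_o)).max() < 1e-12

    def test_midpoint_matches_hand_basis_arithmetic(self):
        # values 0 -> 1 with zero slopes: h00(.5) * 0 + h01(.5) * 1 = 0.5
        y = LinearAgeModel([0.0], [0.0], (9.0, 10.0))    # centre 9.5, value 0
        o = LinearAgeModel([1.0], [0.0], (14.0, 15.0))   # centre 14.5, value 1
        traj = hermite_glue(y, o)
        mid = 0.5 * (traj.knots[0] + traj.knots[1])
        assert abs(evaluate_trajectory(traj, mid)[0] - 0.5) < 1e-12

    def test_wrong_order_rejected(self):
        y = _line_model([0.0], [1.0], (12.0, 17.0))
        o = _line_model([0.0], [1.0], (7.0, 12.0))
        with pytest.raises(ValidationError):
            hermite_glue(y, o)

    def test_endpoint_derivatives_match_cohort_slopes(self):
        y = _line_model([1.0], [0.4], (7.0, 12.0))
        o = _line_model([-2.0], [0.9], (12.0, 17.0))
        traj = hermite_glue(y, o)
        h = 1e-6
        for knot, slope in zip(traj.knots, (0.4, 0.9)):
            d = (evaluate_trajectory(traj, knot + h) -
                 evaluate_trajectory(traj, knot - h)) / (2 * h)
            assert abs(d[0] - slope) < 1e-6


class TestEvaluate:
    def _traj(self):
        y = _line_model([0.0, 1.0], [1.0, 0.0], (7.0, 12.0))
        o = _line_model([5.0, 1.0], [0.2, 0.3], (12.0, 17.0))
        return hermite_glue(y, o)

    def test_value_at_young_knot_is_young_model(self):
        traj = self._traj()
        c_y = traj.knots[0]
        assert np.abs(evaluate_trajectory(traj, c_y) - traj.young(c_y)).max() < 1e-12

    def test_c1_across_knots(self):
        traj = self._traj()
        h = 1e-5
        for knot in traj.knots:
            left = (evaluate_trajectory(traj, knot) -
                    evaluate_trajectory(traj, knot - h)) / h
            right = (evaluate_trajectory(traj, knot + h) -
                     evaluate_trajectory(traj, knot)) / h
            assert np.abs(left - right).max() < 1e-4

    def test_guard_band(self):
        traj = self._traj()
        with pytest.raises(ValidationError):
            evaluate_trajectory(traj, 4.0)
        evaluate_trajectory(traj, 4.0, allow_extrapolation=True)   # no raise

    def test_affine_reparameterization_equivariance(self):
        # scaling + shifting every score axis consistently transforms the trajectory
        traj = self._traj()
        a, b = 2.5, np.array([1.0, -3.0])
        y2 = LinearAgeModel(a * traj.young.intercept + b, a * traj.young.slope,
                            traj.young.age_range)
        o2 = LinearAgeModel(a * traj.old.intercept + b, a * traj.old.slope,
                            traj.old.age_range)
        traj2 = hermite_glue(y2, o2)
        for age in np.linspace(7.5, 16.5, 13):
            v1 = evaluate_trajectory(traj, age, allow_extrapolation=True)
            v2 = evaluate_trajectory(traj2, age, allow_extrapolation=True)
            assert np.abs(a * v1 + b - v2).max() < 1e-9

    def test_serialization_round_trip(self, tmp_path):
        traj = self._traj()
        save_trajectory(traj, tmp_path / "t.json")
        back = load_trajectory(tmp_path / "t.json")
        ages = np.linspace(7.0, 17.0, 11)
        assert np.abs(evaluate_trajectory(back, ages) -
                      evaluate_trajectory(traj, ages)).max() < 1e-12


class TestSyntheticTruth:
    def _fit_for_sex(self, sex, seed=23):
        """Fit trajectory on ground-truth score paths of a two-cohort dataset."""
        from faceage.correspondence import CorrespondedSample
        from faceage.shape_space import fit_pca, gpa_align, to_scores
        from faceage.synthetic import SynthConfig, build_dataset
        cfg = SynthConfig(n_subjects=8, template_vertices=300, noise_sd_mm=0.3,
                          remesh=False, seed=seed)
        series, gt = build_dataset(cfg)
        samples = [CorrespondedSample(s.subject_id, r.age, s.sex,
                                      gt.true_points[(s.subject_id, r.age)])
                   for s in series if s.sex == sex for r in s.records]
        aligned, _ = gpa_align(samples)
        space = fit_pca(aligned, 0.95)
        scores = {}
        for s in aligned:
            scores.setdefault(s.subject_id, []).append((s.age, to_scores(s, space).scores))
        traj, _, _ = fit_global_trajectory(scores, 12.0, sex)
        return traj, gt

    def test_girls_peak_before_boys(self):
        traj_f, gt = self._fit_for_sex("F")
        traj_m, _ = self._fit_for_sex("M")
        ages = np.linspace(10.0, 15.0, 51)
        peak_f = ages[np.argmax(trajectory_speed(traj_f, ages))]
        peak_m = ages[np.argmax(trajectory_speed(traj_m, ages))]
        assert gt.velocity_peak_age("F") < gt.velocity_peak_age("M")
        assert peak_f < peak_m
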