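import numpy as np
import pandas as pd
import pytest

from platetrace import (
    AssayTable,
    CalibrationModel,
    SimConfig,
    compute_factors,
    correct_sensors,
    estimate_calibration,
    normalize_to_target,
    recalibrate,
    simulate_empty_plate,
    to_log_domain,
)
from platetrace.sensor_correction import CalibrationDegenerateWarning


def make(time, cols, **kw):
    return AssayTable(time=np.asarray(time, float), data=pd.DataFrame(cols), **kw)


UNIT = CalibrationModel(plateau=0.0, span=1.0, window=(0.0, 1.0))


class TestLogDomain:
    def test_hand_values(self):
        t = make([0.0, 1.0], {"A": [np.e**2, np.e**2]})
        z = to_log_domain(t, UNIT)
        np.testing.assert_allclose(z.values(), 2.0)
        calib = CalibrationModel(plateau=5.0, span=3.0)
        t2 = make([0.0, 1.0], {"A": [5 + 3 * np.e] * 2})
        np.testing.assert_allclose(to_log_domain(t2, calib).values(), 1.0)

    def test_plateau_value_raises_listing_cells(self):
        calib = CalibrationModel(plateau=1.0, span=2.0)
        t = make([0.0, 1.0], {"A": [3.0, 1.0]})
        with pytest.raises(ValueError, match=r"sensor=A"):
            to_log_domain(t, calib)

    def test_clip_mode_is_opt_in(self):
        calib = CalibrationModel(plateau=1.0, span=2.0)
        t = make([0.0, 1.0], {"A": [3.0, 1.0]})
        z = to_log_domain(t, calib, clip_epsilon=1e-9)
        assert z.values()[1, 0] == pytest.approx(np.log(1e-9))


class TestComputeFactors:
    def test_hand_means(self):
        # window-z values {2,2} and {4,4} -> m_s = {2,4}, m_p = 3
        t = make([0.0, 1.0], {"A": np.exp([2.0, 2.0]), "B": np.exp([4.0, 4.0])})
        f = compute_factors(t, UNIT)
        np.testing.assert_allclose(f.m_s, [2.0, 4.0])
        assert f.m_p == pytest.approx(3.0)
        np.testing.assert_allclose(f.factors, [1.5, 0.75])
        # internal consistency: mean of m_s equals m_p
        assert np.mean(f.m_s) == pytest.approx(f.m_p)

    def test_identical_sensors_give_unit_factors(self):
        t = make([0.0, 1.0], {"A": [7.0, 7.0], "B": [7.0, 7.0]})
        np.testing.assert_allclose(compute_factors(t, UNIT).factors, 1.0)

    def test_single_sensor_factor_is_one(self):
        t = make([0.0, 1.0], {"A": [5.0, 5.0]})
        np.testing.assert_allclose(compute_factors(t, UNIT).factors, 1.0)

    def test_window_needs_two_points(self):
        t = make([0.0, 5.0], {"A": [2.0, 2.0]})
        calib = CalibrationModel(plateau=0.0, span=1.0, window=(0.0, 1.0))
        with pytest.raises(ValueError, match="window"):
            compute_factors(t, calib)

    def test_zero_mean_rejected(self):
        # z = 0 over the window -> factor division undefined
        t = make([0.0, 1.0], {"A": [1.0, 1.0], "B": [np.e, np.e]})
        with pytest.raises(ValueError, match="zero log-domain mean"):
            compute_factors(t, UNIT)


class TestRecalibrate:
    def test_two_sensor_hand_case(self):
        # sensors reading e^2 and e^4 both correct to e^3
        t = make([0.0, 1.0], {"A": [np.e**2] * 2, "B": [np.e**4] * 2})
        f = compute_factors(t, UNIT)
        out = recalibrate(t, UNIT, f)
        np.testing.assert_allclose(out.values(), np.e**3, rtol=1e-12)

    def test_unit_factors_are_identity(self):
        t = make([0.0, 1.0, 2.0], {"A": [2.0, 3.0, 4.0], "B": [2.0, 3.0, 4.0]})
        f = compute_factors(t, UNIT)
        out = recalibrate(t, UNIT, f)
        np.testing.assert_allclose(out.values(), t.values(), rtol=1e-12)

    def test_idempotence(self):
        cfg = SimConfig(gain_delta=0.05, noise_sd=0.0, seed=3)
        calib = CalibrationModel(plateau=cfg.plateau, span=cfg.span, window=(0.0, 0.07))
        t = simulate_empty_plate(cfg, levels=(48.1,), points_per_level=20)
        once = recalibrate(t, calib, compute_factors(t, calib))
        f2 = compute_factors(once, calib)
        np.testing.assert_allclose(f2.factors, 1.0, atol=1e-9)
        twice = recalibrate(once, calib, f2)
        np.testing.assert_allclose(twice.values(), once.values(), rtol=1e-9)

    def test_homogenization_of_noiseless_gains(self):
        """Between-sensor spread collapses at every constant-level segment."""
        cfg = SimConfig(gain_delta=0.05, noise_sd=0.0, seed=11)
        t = simulate_empty_plate(cfg, points_per_level=20)
        calib = CalibrationModel(plateau=cfg.plateau, span=cfg.span, window=(0.0, 0.07))
        out = recalibrate(t, calib, compute_factors(t, calib))
        pre_sd = t.values().std(axis=1)
        post_sd = out.values().std(axis=1)
        assert np.all(post_sd <= 1e-9 * np.maximum(pre_sd, 1e-12))


class TestNormalizeToTarget:
    def test_window_means_become_exactly_target(self):
        t = make([0.0, 1.0, 5.0], {"A": [90.0, 90.0, 50.0], "B": [92.0, 92.0, 60.0]})
        calib = CalibrationModel(plateau=1.0, span=2.0, window=(0.0, 1.0))
        out = normalize_to_target(t, calib, 91.3)
        means = out.values()[:2].mean(axis=0)
        np.testing.assert_array_equal(means, [91.3, 91.3])

    def test_target_equal_to_mean_is_identity(self):
        t = make([0.0, 1.0], {"A": [90.0, 90.0]})
        calib = CalibrationModel(plateau=1.0, span=2.0, window=(0.0, 1.0))
        out = normalize_to_target(t, calib, 90.0)
        np.testing.assert_allclose(out.values(), t.values())

    def test_full_two_step_recovers_true_level(self):
        cfg = SimConfig(gain_delta=0.05, noise_sd=0.0, seed=5)
        calib = CalibrationModel(plateau=cfg.plateau, span=cfg.span, window=(0.0, 0.07))
        t = simulate_empty_plate(cfg, levels=(48.1,), points_per_level=20)
        out, _ = correct_sensors(t, calib, 48.1)
        np.testing.assert_allclose(out.values(), 48.1, atol=1e-6)


def test_log_correction_beats_naive_linear_correction():
    """At every oxygen level the log method leaves less between-sensor spread
    than the classical divide-by-window-mean/multiply-by-target correction."""
    cfg = SimConfig(gain_delta=0.05, noise_sd=0.0, seed=17)
    levels = (91.3, 72.1, 48.1, 24.0, 4.8)
    t = simulate_empty_plate(cfg, levels=levels, points_per_level=20)
    calib = CalibrationModel(plateau=cfg.plateau, span=cfg.span, window=(0.0, 0.07))
    corrected, _ = correct_sensors(t, calib, levels[0])
    window = t.time <= 0.07
    naive = t.values() * (levels[0] / t.values()[window].mean(axis=0))[None, :]
    for i in range(len(levels)):
        seg = slice(i * 20, (i + 1) * 20)
        sd_log = corrected.values()[seg].std(axis=1).max()
        sd_naive = naive[seg].std(axis=1).max()
        assert sd_log <= sd_naive + 1e-12


class TestEstimateCalibration:
    @staticmethod
    def levels_from(P, S, alpha, ys, n=4):
        return [(y, np.full(n, P + S * np.exp(alpha * y))) for y in ys]

    def test_recovers_exact_exponential(self):
        levels = self.levels_from(2.0, 5.0, 0.03, [0.0, 20.0, 40.0, 70.0, 100.0])
        model = estimate_calibration(levels)
        assert model.plateau == pytest.approx(2.0, rel=1e-6)
        assert model.span == pytest.approx(5.0, rel=1e-6)
        assert model.alpha == pytest.approx(0.03, rel=1e-6)

    def test_two_levels_underdetermined(self):
        with pytest.raises(ValueError, match="3 distinct"):
            estimate_calibration(self.levels_from(2.0, 5.0, 0.03, [0.0, 50.0]))

    def test_linear_data_flags_degeneracy(self):
        ys = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        levels = [(y, np.full(4, 3.0 + 0.1 * y)) for y in ys]
        with pytest.warns(CalibrationDegenerateWarning):
            model = estimate_calibration(levels)
        assert abs(model.alpha) * 100.0 < 1e-2
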