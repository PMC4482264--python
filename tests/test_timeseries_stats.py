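import numpy as np
import pandas as pd
import pytest

from platetrace import (
    AssayTable,
    PlateLayout,
    WellSpec,
    aggregate_replicates,
    normalize_to_reference,
    scale_values,
    smooth,
    windowed_slope,
)


def make(time, cols, **kw):
    return AssayTable(time=np.asarray(time, float), data=pd.DataFrame(cols), **kw)


def brute_force_ols(t, y):
    """Independent per-window oracle: textbook simple linear regression."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = t.size - 2
    rse = np.sqrt(resid @ resid / dof) if dof > 0 else 0.0
    return coef[1], rse


class TestNormalizeToReference:
    def layout4(self):
        return PlateLayout(
            wells={
                "R1": WellSpec(group="med", role="medium_control"),
                "R2": WellSpec(group="med", role="medium_control"),
                "S1": WellSpec(group="s1", role="sample", dose=1.0),
                "S2": WellSpec(group="s2", role="sample", dose=2.0),
            }
        )

    def test_hand_arithmetic(self):
        t = make([0.0, 1.0], {"R1": [10.0, 10], "R2": [12.0, 12], "S1": [22.0, 22], "S2": [11.0, 11]})
        out = normalize_to_reference(t, self.layout4(), 100.0)
        assert out.data["S1"][0] == pytest.approx(200.0)
        ref_mean = out.data[["R1", "R2"]].mean(axis=1)
        np.testing.assert_array_equal(ref_mean.to_numpy(), 100.0)

    def test_sample_tracking_reference_becomes_constant(self):
        ref = np.array([10.0, 11.0, 13.0])
        t = make([0, 1, 2], {"R1": ref, "R2": ref, "S1": ref, "S2": 2 * ref})
        out = normalize_to_reference(t, self.layout4(), 91.3)
        np.testing.assert_allclose(out.data["S1"], 91.3)
        np.testing.assert_allclose(out.data["S2"], 2 * 91.3)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        t = make(np.arange(6.0), {c: rng.uniform(50, 90, 6) for c in ["R1", "R2", "S1", "S2"]})
        once = normalize_to_reference(t, self.layout4(), 91.3)
        twice = normalize_to_reference(once, self.layout4(), 91.3)
        np.testing.assert_allclose(twice.values(), once.values(), rtol=1e-12)

    def test_zero_reference_mean_names_time(self):
        t = make([0.0, 1.0], {"R1": [1.0, -1.0], "R2": [1.0, 1.0], "S1": [1, 1], "S2": [1, 1]})
        with pytest.raises(ValueError, match="1.0"):
            normalize_to_reference(t, self.layout4(), 100.0)

    def test_requires_reference_columns(self):
        t = make([0.0, 1.0], {"S1": [1, 1]})
        layout = PlateLayout(wells={"S1": WellSpec(group="s", role="sample")})
        with pytest.raises(ValueError, match="reference"):
            normalize_to_reference(t, layout, 100.0)


class TestAggregateReplicates:
    def test_triplicate_mean_and_sample_sd(self):
        layout = PlateLayout(wells={c: WellSpec(group="g") for c in "ABC"})
        t = make([0.0], {"A": [1.0], "B": [2.0], "C": [3.0]})
        agg = aggregate_replicates(t, layout)
        assert agg.means["g"][0] == pytest.approx(2.0)
        assert agg.sds["g"][0] == pytest.approx(1.0)  # ddof=1

    def test_identical_replicates_have_zero_sd(self):
        layout = PlateLayout(wells={c: WellSpec(group="g") for c in "AB"})
        t = make([0.0, 1.0], {"A": [5.0, 6.0], "B": [5.0, 6.0]})
        agg = aggregate_replicates(t, layout)
        np.testing.assert_array_equal(agg.sds["g"].to_numpy(), 0.0)

    def test_singleton_group_flagged_with_zero_sd(self):
        layout = PlateLayout(wells={"A": WellSpec(group="only")})
        agg = aggregate_replicates(make([0.0], {"A": [4.0]}), layout)
        assert agg.singleton_groups == ["only"]
        assert agg.sds["only"][0] == 0.0

    def test_missing_values_excluded_pairwise(self):
        layout = PlateLayout(wells={c: WellSpec(group="g") for c in "ABC"})
        t = make([0.0, 1.0], {"A": [1.0, np.nan], "B": [2.0, np.nan], "C": [3.0, np.nan]})
        agg = aggregate_replicates(t, layout)
        assert agg.means["g"][0] == pytest.approx(2.0)
        assert np.isnan(agg.means["g"][1])  # whole group missing -> missing out

    def test_thirteen_dose_groups_plus_control(self):
        from platetrace import SimConfig, simulate_treatment_experiment

        table, layout = simulate_treatment_experiment(SimConfig(seed=1))
        agg = aggregate_replicates(table, layout)
        assert len(agg.groups) == 14  # 13 dose conditions + medium control
        assert (agg.counts.to_numpy() == 3).all()

    def test_mean_commutes_with_scaling(self):
        layout = PlateLayout(wells={c: WellSpec(group="g") for c in "AB"})
        rng = np.random.default_rng(0)
        t = make(np.arange(5.0), {"A": rng.normal(size=5), "B": rng.normal(size=5)})
        a = aggregate_replicates(scale_values(t, 3.0), layout).means
        b = aggregate_replicates(t, layout).means * 3.0
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)


class TestSmooth:
    def test_three_point_means(self):
        t = make(np.arange(5.0), {"A": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = smooth(t, 3)
        assert out.data["A"].tolist() == [2.0, 3.0, 4.0]
        assert out.time.tolist() == [1.0, 2.0, 3.0]

    def test_edge_loss_count(self):
        t = make(np.arange(30.0), {"A": np.arange(30.0)})
        out = smooth(t, 11)
        assert out.n_points == 30 - 10  # (n-1)/2 = 5 points lost per end
        assert out.time[0] == 5.0 and out.time[-1] == 24.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="uneven"):
            smooth(make(np.arange(10.0), {"A": np.arange(10.0)}), 4)

    def test_constant_series_unchanged(self):
        t = make(np.arange(9.0), {"A": np.full(9, 7.7)})
        np.testing.assert_array_equal(smooth(t, 5).data["A"].to_numpy(), 7.7)

    def test_linear_series_reproduced(self):
        time = np.arange(20.0)
        t = make(time, {"A": 2.0 * time + 5.0})
        out = smooth(t, 7)
        np.testing.assert_allclose(out.data["A"].to_numpy(), 2.0 * out.time + 5.0, rtol=1e-12)

    def test_periodic_series_mean_preserved(self):
        time = np.arange(48.0)
        y = np.sin(2 * np.pi * time / 12.0)
        out = smooth(make(time, {"A": y}), 5)
        # windows fully covering whole periods keep the global mean ~0
        assert abs(out.data["A"][10:34].mean()) < 1e-12


class TestWindowedSlope:
    def test_exact_line_any_halfwidth(self):
        time = np.arange(15.0)
        t = make(time, {"A": 2.0 * time + 5.0})
        for n in (1, 3, 5):
            st = windowed_slope(t, n)
            np.testing.assert_allclose(st.slopes["A"].to_numpy(), 2.0, rtol=1e-12)
            np.testing.assert_allclose(st.residuals["A"].to_numpy(), 0.0, atol=1e-10)

    def test_constant_series_zero_slope(self):
        t = make(np.arange(9.0), {"A": np.full(9, 3.0)})
        np.testing.assert_allclose(windowed_slope(t, 2).slopes["A"].to_numpy(), 0.0, atol=1e-14)

    def test_three_point_closed_form(self):
        # points (0,0), (1,1), (2,4): slope 2, residual sqrt(2/3)
        t = make([0.0, 1.0, 2.0], {"A": [0.0, 1.0, 4.0]})
        st = windowed_slope(t, 1)
        assert st.time.tolist() == [1.0]
        assert st.slopes["A"][0] == pytest.approx(2.0)
        assert st.residuals["A"][0] == pytest.approx(np.sqrt(2.0 / 3.0))
        oracle_m, oracle_r = brute_force_ols([0, 1, 2], [0, 1, 4])
        assert st.slopes["A"][0] == pytest.approx(oracle_m, abs=1e-12)
        assert st.residuals["A"][0] == pytest.approx(oracle_r, abs=1e-12)

    def test_agrees_with_brute_force_on_random_series(self):
        rng = np.random.default_rng(42)
        time = np.sort(rng.uniform(0, 10, 50))
        y = rng.normal(size=(50, 2))
        t = make(time, {"A": y[:, 0], "B": y[:, 1]})
        for n in (1, 3, 7):
            st = windowed_slope(t, n)
            for ci, c in enumerate("AB"):
                for w in range(st.time.size):
                    m, r = brute_force_ols(time[w : w + 2 * n + 1], y[w : w + 2 * n + 1, ci])
                    assert st.slopes[c][w] == pytest.approx(m, abs=1e-12)
                    assert st.residuals[c][w] == pytest.approx(r, abs=1e-12)

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="too short"):
            windowed_slope(make([0.0, 1.0], {"A": [1.0, 2.0]}), 1)

    def test_missing_values_excluded_within_window(self):
        time = np.arange(7.0)
        y = 3.0 * time
        y[3] = np.nan
        st = windowed_slope(make(time, {"A": y}), 2)
        # every window still contains >= 4 valid points of an exact line
        np.testing.assert_allclose(st.slopes["A"].to_numpy(), 3.0, rtol=1e-12)

    def test_slope_of_cumulative_sum_recovers_series(self):
        # integrate a sinusoid, then differentiate by windowed slope
        time = np.linspace(0, 4 * np.pi, 400)
        dt = time[1] - time[0]
        y = np.sin(time)
        integral = np.cumsum(y) * dt
        st = windowed_slope(make(time, {"A": integral}), 3)
        # slope index w corresponds to original time index w + 3
        rec = st.slopes["A"].to_numpy()[97:297]
        truth = y[100:300]
        assert np.max(np.abs(rec - truth)) / np.max(np.abs(truth)) < 0.05
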