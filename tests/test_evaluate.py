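"""Error statistics, sweep mechanics, and the ANOVA/Tukey/correlation tools."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

import canopyheight as ch
from canopyheight.evaluate import summarize_detail


def truth_table(values_mm):
    return ch.TruthTable(heights_mm=np.asarray(values_mm, float), n_probes=5, seed=0)


def estimates_frame(values_mm):
    frame = pd.DataFrame({
        "subplot_id": np.arange(len(values_mm)),
        "estimate_mm": values_mm,
        "n_valid_cells": 9,
    })
    return frame


class TestAbsoluteErrorStats:
    def test_hand_computed_example(self):
        st = ch.absolute_error_stats(estimates_frame([410, 420, 430]),
                                     truth_table([400, 400, 400]))
        npt.assert_allclose(st.errors["abs_error_mm"], [10, 20, 30])
        assert st.mae_mm == pytest.approx(20.0)
        assert st.sd_mm == pytest.approx(10.0)  # sample SD of (10, 20, 30)

    def test_perfect_estimates(self):
        st = ch.absolute_error_stats(estimates_frame([400, 350]), truth_table([400, 350]))
        assert st.mae_mm == 0.0 and st.sd_mm == 0.0

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        est = rng.uniform(300, 500, 25)
        tru = rng.uniform(300, 500, 25)
        st = ch.absolute_error_stats(estimates_frame(est), truth_table(tru))
        errs = np.abs(est - tru)
        assert st.mae_mm == pytest.approx(errs.mean(), rel=1e-12)
        assert st.sd_mm == pytest.approx(errs.std(ddof=1), rel=1e-12)

    def test_subplot_mismatch_rejected(self):
        frame = estimates_frame([400, 410, 420])
        frame["subplot_id"] = [0, 1, 7]
        with pytest.raises(ValueError, match="truth"):
            ch.absolute_error_stats(frame, truth_table([400, 400]))


class TestAnovaTukey:
    def test_hand_computed_f_statistic(self):
        """Closed-form one-way ANOVA on the 9-number worked instance.

        Groups (1,2,3), (2,3,4), (21,22,23): between-group SS = 762 on 2 df,
        within-group SS = 6 on 6 df, so F = 381 exactly.
        """
        res = ch.anova_tukey({"a": [1, 2, 3], "b": [2, 3, 4], "c": [21, 22, 23]})
        assert res.f_statistic == pytest.approx(381.0, abs=1e-10)
        assert res.p_value < 1e-6
        pw = res.pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "significant"]
        assert pw.loc[("b", "c"), "significant"]
        assert not pw.loc[("a", "b"), "significant"]
        assert res.alpha == 0.01  # study significance level

    def test_identical_groups_nothing_significant(self):
        res = ch.anova_tukey({"a": [5, 5, 5], "b": [5, 5, 5], "c": [5, 5, 5]})
        assert res.p_value == 1.0
        assert not res.pairwise["significant"].any()

    def test_adjusted_p_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        res = ch.anova_tukey({k: rng.normal(10 * i, 1, 8)
                              for i, k in enumerate("abc")})
        assert ((res.pairwise["p_adj"] >= 0) & (res.pairwise["p_adj"] <= 1)).all()

    def test_rejects_degenerate_group_counts(self):
        with pytest.raises(ValueError):
            ch.anova_tukey({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            ch.anova_tukey({"a": [1, 2], "b": [3]})


class TestCorrelation:
    def test_perfect_and_anti_correlation(self):
        t = np.array([300.0, 350.0, 420.0, 480.0])
        assert ch.correlation(t, t) == pytest.approx(1.0)
        assert ch.correlation(-t + 700.0, t) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 1, 25), rng.uniform(0, 1, 25)
        expected = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert ch.correlation(a, b) == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_reports_nodata(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(ch.correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_rejects_short_or_unequal_input(self):
        with pytest.raises(ValueError):
            ch.correlation([1.0, 2.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def small_sweep():
    """A tiny but complete two-sensor sweep on a noiseless constant scene."""
    layout = ch.make_layout(1.0, 2, 0.5, 0.3)
    ground = ch.generate_ground(layout, 0.0, 0.5, seed=0)
    pre = ch.generate_canopy(ground, layout, [400.0] * 4, 0.0, 4000.0, seed=1)
    truth = ch.ruler_truth(pre, seed=2)
    post = ch.harvest(pre, 0.03)
    sensors = {
        "lidar": ch.lidar_sensor(seed=3, scale=1.0),
        "uav_sfm": ch.uav_sfm_sensor(seed=4, scale=0.05),
    }
    clouds = {n: (ch.sample_cloud(pre, s), ch.sample_cloud(post, s))
              for n, s in sensors.items()}
    return ch.sweep(clouds, layout, truth), truth, clouds, layout


class TestSweep:
    def test_full_factorial_shape(self, small_sweep):
        table, *_ = small_sweep
        counts = table.summary.groupby("sensor").size()
        assert (counts == 28).all()  # 4 methods x 7 cell sizes

    def test_degenerate_sweep_equals_single_error_stats(self, small_sweep):
        _, truth, clouds, layout = small_sweep
        table = ch.sweep({"lidar": clouds["lidar"]}, layout, truth,
                         methods=["maximum_minimum"], cell_sizes_mm=[20.0])
        assert len(table.summary) == 1
        grid = ch.make_grid(layout.extent, 0.02)
        b = ch.rasterize(clouds["lidar"][0], grid, "max")
        a = ch.rasterize(clouds["lidar"][1], grid, "min")
        hr = ch.estimate_height(b, a, ch.METHODS["maximum_minimum"])
        st = ch.absolute_error_stats(ch.subplot_summary(hr, layout), truth)
        assert table.summary["mae_mm"].iloc[0] == pytest.approx(st.mae_mm)
        assert table.summary["sd_mm"].iloc[0] == pytest.approx(st.sd_mm)

    def test_missing_epoch_rejected(self, small_sweep):
        _, truth, clouds, layout = small_sweep
        with pytest.raises(ValueError, match="missing an epoch"):
            ch.sweep({"lidar": (clouds["lidar"][0], None)}, layout, truth)


class TestCompareSensors:
    @staticmethod
    def _detail(rows):
        return pd.DataFrame(rows, columns=["sensor", "method", "cell_size_mm",
                                           "subplot_id", "estimate_mm", "truth_mm",
                                           "abs_error_mm"])

    def test_dominating_sensor_selected_first(self):
        rows = []
        for sensor, err in (("good", 1.0), ("bad", 50.0)):
            for cell in (20.0, 50.0):
                for sub in range(4):
                    rows.append((sensor, "maximum_minimum", cell, sub,
                                 400 + err + sub, 400.0, err + sub))
        table = ch.SweepTable(detail=self._detail(rows),
                              summary=summarize_detail(self._detail(rows)))
        report = ch.compare_sensors(table)
        assert report.best.iloc[0]["sensor"] == "good"
        assert report.anova.pairwise["significant"].all()

    def test_mae_tie_prefers_larger_cells(self):
        rows = []
        for cell in (20.0, 50.0):
            for sensor in ("s1", "s2"):
                for sub in range(3):
                    rows.append((sensor, "maximum_minimum", cell, sub,
                                 410.0 + sub, 400.0 + sub, 10.0))
        detail = self._detail(rows)
        table = ch.SweepTable(detail=detail, summary=summarize_detail(detail))
        report = ch.compare_sensors(table)
        assert (report.best["cell_size_mm"] == 50.0).all()

    def test_incomplete_sweep_rejected(self, small_sweep):
        table, *_ = small_sweep
        only_one = table.summary[table.summary["sensor"] == "lidar"]
        with pytest.raises(ValueError):
            ch.compare_sensors(ch.SweepTable(detail=table.detail, summary=only_one))
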