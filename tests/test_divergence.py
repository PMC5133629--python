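"""Divergence statistics: pooling, F-tests, first-divergence hour, ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from topocell.divergence import (METRICS, NEVER, assemble_timeseries,
                                 divergence_table, divergence_time, f_test,
                                 mean_ratio_trajectory)


def shape_table(rows):
    df = pd.DataFrame(rows)
    for name, col in METRICS.items():
        if col not in df:
            df[col] = 1.0
    return df


class TestAssemble:
    def test_pooling_across_fovs(self):
        rows = [{"condition": "flat", "replicate": 1, "fov_id": f"fov{f}",
                 "timestamp_h": 0.0, "area_um2": float(i)}
                for f in (1, 2) for i in range(5)]
        series = assemble_timeseries(shape_table(rows), metrics=("area",))
        s = series[("flat", "area")]
        assert len(s.values[0]) == 10  # 2 FOVs x 5 objects pooled

    def test_one_series_per_metric(self):
        rows = [{"condition": "flat", "replicate": 1, "fov_id": "fov1",
                 "timestamp_h": t, "area_um2": 1.0} for t in (0.0, 1.0)]
        series = assemble_timeseries(shape_table(rows))
        assert set(series) == {("flat", m) for m in METRICS}
        np.testing.assert_allclose(series[("flat", "area")].timestamps_h,
                                   [0.0, 1.0])

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            assemble_timeseries(shape_table([{"condition": "flat",
                                              "replicate": 1, "fov_id": "f",
                                              "timestamp_h": 0.0}]),
                                metrics=("volume",))

    def test_mean_area_rises_then_plateaus(self):
        """Pooled series from a simulated spreading population reproduces the
        generator's saturating trajectory."""
        from topocell.synthetic import (ConditionParams, FrameGeometry,
                                        make_schedule, simulate_experiment,
                                        spreading_trajectory)

        cond = ConditionParams("flat", n_cells_per_fov=4, area_timescale_h=4.0)
        schedule = make_schedule([(0, 24, 4)])
        sim = simulate_experiment([cond], schedule, n_replicates=1, n_fovs=2,
                                  rng_seed=3, geometry=FrameGeometry(512, 512))
        series = assemble_timeseries(sim.truth, metrics=("area",))
        means = series[("flat", "area")].means
        expected = [spreading_trajectory(t, cond)[0]
                    for t in schedule.timestamps_h]
        # same saturating shape: strictly increasing, within 20% of the
        # noise-free trajectory despite per-cell heterogeneity
        assert np.all(np.diff(means) > 0)
        np.testing.assert_allclose(means, expected, rtol=0.2)


class TestFTest:
    def test_equal_samples_give_null(self):
        r = f_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.F == 0.0
        assert r.p == 1.0

    def test_equals_squared_t(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 1, rng.integers(3, 12))
            r = f_test(a, b)
            t, p = stats.ttest_ind(a, b, equal_var=True)
            assert r.F == pytest.approx(t ** 2, rel=1e-10)
            assert r.p == pytest.approx(p, rel=1e-10)

    def test_matches_scipy_anova(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, 10)
        r = f_test(a, b)
        F, p = stats.f_oneway(a, b)
        assert r.F == pytest.approx(F, rel=1e-10)
        assert r.p == pytest.approx(p, rel=1e-10)

    def test_degenerate_zero_variance(self):
        r = f_test([0.0, 0.0], [1.0, 1.0])
        assert r.degenerate and r.p == 0.0
        r2 = f_test([1.0, 1.0], [1.0, 1.0])
        assert r2.F == 0.0 and r2.p == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(size=9)
        for mode in ("anova",):
            ra, rb = f_test(a, b, mode), f_test(b, a, mode)
            assert ra.F == pytest.approx(rb.F)
            assert ra.p == pytest.approx(rb.p)

    def test_variance_mode_two_sided(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 3.0, 30)
        b = rng.normal(0, 1.0, 30)
        r = f_test(a, b, mode="variance")
        assert r.F == pytest.approx(a.var(ddof=1) / b.var(ddof=1))
        assert r.p < 0.05
        rsym = f_test(b, a, mode="variance")
        assert r.p == pytest.approx(rsym.p, rel=1e-9)

    def test_type_one_error_calibration(self):
        """Under the null, the ANOVA-mode F-test rejects at ~alpha: over
        1000 simulated timepoints (n=50 per group), the p < 0.05 fraction
        sits within 0.05 +/- 0.02."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            if f_test(a, b).p < 0.05:
                rejections += 1
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            f_test([1.0], [1.0, 2.0])


class TestDivergenceTime:
    def test_never_when_all_nonsignificant(self):
        t = np.arange(10.0)
        assert divergence_time(np.full(10, 0.5), t) == NEVER

    def test_first_crossing_on_grid(self):
        t = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        p = np.array([0.5, 0.5, 0.5, 0.01, 0.01])
        assert divergence_time(p, t, persistence_k=1) == 1.5

    def test_persistence_skips_isolated_blip(self):
        t = np.arange(6.0)
        p = np.array([0.5, 0.01, 0.5, 0.01, 0.01, 0.01])
        assert divergence_time(p, t, persistence_k=3) == 3.0

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        t = np.arange(50.0)
        h_strict = divergence_time(p, t, alpha=0.01)
        h_loose = divergence_time(p, t, alpha=0.10)
        assert h_strict >= h_loose

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            divergence_time([], [])

    def test_changepoint_recovery(self):
        """A 1-SD mean shift injected at hour 12 (n=200 objects/timepoint) is
        recovered within two 1-h grid steps in the median over 50 seeds."""
        t = np.arange(0.0, 25.0)
        hours = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ps = []
            for ti in t:
                a = rng.normal(0.0, 1.0, 200)
                shift = 1.0 if ti >= 12.0 else 0.0
                b = rng.normal(shift, 1.0, 200)
                ps.append(f_test(a, b).p)
            hours.append(divergence_time(ps, t, alpha=0.05, persistence_k=1))
        med = float(np.median(hours))
        assert 12.0 <= med <= 14.0

    def test_identical_conditions_rarely_diverge(self):
        """Round-trip null: two identically generated conditions yield NEVER
        for >= 95% of seeds at alpha 0.05 with persistence 3."""
        t = np.arange(0.0, 20.0)
        never = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            ps = [f_test(rng.normal(size=60), rng.normal(size=60)).p for _ in t]
            if divergence_time(ps, t, alpha=0.05, persistence_k=3) == NEVER:
                never += 1
        assert never / n_seeds >= 0.95


class TestDivergenceTable:
    def _records(self):
        rng = np.random.default_rng(5)
        rows = []
        for cond, shift in (("flat", 0.0), ("aligned", 2.0)):
            for t in (0.0, 1.0, 2.0):
                onset = shift if t >= 1.0 else 0.0
                for i in range(20):
                    rows.append({"condition": cond, "replicate": 1,
                                 "fov_id": "fov1", "timestamp_h": t,
                                 "area_um2": rng.normal(onset, 1.0),
                                 "circularity": rng.normal(0.5, 0.05),
                                 "major_axis_um": rng.normal(50, 5),
                                 "minor_axis_um": rng.normal(20, 2)})
        return pd.DataFrame(rows)

    def test_layout_and_detection(self):
        table, results = divergence_table(self._records())
        assert list(table.index) == ["area", "circularity", "major_axis",
                                     "minor_axis"]
        assert list(table.columns) == ["flat/aligned"]
        assert table.loc["area", "flat/aligned"] == 1.0
        assert table.loc["circularity", "flat/aligned"] == "N/A"
        res = results[(("flat", "aligned"), "area")]
        assert res.diverged and res.divergence_hour == 1.0
        assert res.mode == "anova"


class TestMeanRatio:
    def _series(self, values):
        from topocell.divergence import MetricTimeSeries

        return MetricTimeSeries("c", "area", np.arange(float(len(values))),
                                [np.asarray(v, float) for v in values])

    def test_identical_series_unity(self):
        s = self._series([[1.0, 2.0], [3.0, 4.0]])
        ratio, summary = mean_ratio_trajectory(s, s)
        np.testing.assert_allclose(ratio, 1.0)
        assert summary == 0.0

    def test_doubled_series(self):
        a = self._series([[1.0, 2.0], [3.0, 4.0]])
        b = self._series([[2.0, 4.0], [6.0, 8.0]])
        ratio, summary = mean_ratio_trajectory(a, b)
        np.testing.assert_allclose(ratio, 0.5)
        assert summary == pytest.approx(np.log(2.0))

    def test_zero_denominator_flagged_nan(self):
        a = self._series([[1.0, 2.0]])
        b = self._series([[1.0, -1.0]])
        ratio, _ = mean_ratio_trajectory(a, b)
        assert np.isnan(ratio[0])

    def test_random_condition_most_dissimilar(self):
        """With the study parameter set, every pair summary furthest from
        unity involves the random condition — the generator's small-area
        phenotype drives the contrast."""
        from itertools import combinations

        from topocell.synthetic import spreading_trajectory, study_conditions

        conds = {c.name: c for c in study_conditions()}
        t_grid = np.linspace(0, 48, 13)
        series = {}
        for name, c in conds.items():
            vals = [[spreading_trajectory(t, c)[0]] * 2 for t in t_grid]
            series[name] = self._series(vals)
        summaries = {}
        for a, b in combinations(conds, 2):
            _, s = mean_ratio_trajectory(series[a], series[b])
            summaries[(a, b)] = s
        worst = max(summaries, key=summaries.get)
        assert "random" in worst
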