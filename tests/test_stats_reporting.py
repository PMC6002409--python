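"""Paired tests, OLS, correlation matrix with BH-FDR, and report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiostop.behavioural_metrics import apply_exclusions
from cardiostop.stats_reporting import (VARIABLES, build_reports,
                                        correlation_matrix_fdr, fdr_adjust,
                                        linear_regression, paired_t)

from conftest import build_exclusion_fixture


class TestPairedT:
    def test_symmetric_differences_give_zero_t(self):
        res = paired_t([10.0, 11.0, 12.0], [11.0, 11.0, 11.0])
        assert res.t == pytest.approx(0.0)
        assert res.mean_diff == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # differences {2,4,6,8}: mean 5, sd 2.582, se 1.291, t = 3.873, df 3
        res = paired_t([2.0, 4.0, 6.0, 8.0], [0.0, 0.0, 0.0, 0.0])
        assert res.mean_diff == pytest.approx(5.0)
        assert res.t == pytest.approx(3.873, abs=1e-3)
        assert res.df == 3
        assert res.ci95[0] <= res.mean_diff <= res.ci95[1]
        assert res.eta_squared == pytest.approx(res.t ** 2 / (res.t ** 2 + 3))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t([5.0, 6.0, 7.0], [0.0, 1.0, 2.0])

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)
        assert a.ci95[0] == pytest.approx(-b.ci95[1])


class TestLinearRegression:
    def test_exact_fit(self):
        x = np.arange(10.0)
        res = linear_regression(2 * x + 1, x, names=["x"])
        assert res.params["x"] == pytest.approx(2.0)
        assert res.params["const"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 2.0, 3.0], np.eye(3)[:, :2])

    def test_collinear_columns_named(self):
        x = np.arange(12.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="b"):
            linear_regression(x, X, names=["a", "b"])

    def test_null_pvalues_calibrated(self):
        """Slope p-values are ~uniform under the null: rejection at 0.05
        stays near 5% over replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0, 1, 40)
            res = linear_regression(y, x, names=["x"])
            rejections += res.pvalues["x"] < 0.05
        assert 0.02 <= rejections / reps <= 0.09


class TestCorrelationMatrixFDR:
    def test_hand_computed_r(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [1, 3, 2, 4],
                           "c": [4, 3, 2, 1]})
        table = correlation_matrix_fdr(df, variables=("a", "b", "c"))
        assert table.r.loc["a", "b"] == pytest.approx(0.8)
        assert table.r.loc["a", "c"] == pytest.approx(-1.0)

    def test_bh_adjustment_by_hand(self):
        # p = {0.01, 0.02, 0.03, 0.04}, m = 4: adjusted all equal 0.04
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_constant_variable_flagged_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 2, 2, 2, 2],
                           "c": [5.0, 3, 4, 1, 2]})
        table = correlation_matrix_fdr(df, variables=("a", "b", "c"))
        assert np.isnan(table.r.loc["a", "b"])
        assert not np.isnan(table.r.loc["a", "c"])

    def test_pairwise_deletion(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, np.nan, 6],
                           "b": [2.0, 1, 4, 3, 5, np.nan],
                           "c": [1.0, 2, 3, 4, 5, 6]})
        table = correlation_matrix_fdr(df, variables=("a", "b", "c"))
        assert table.n.loc["a", "b"] == 4
        assert table.n.loc["a", "c"] == 5

    def test_fdr_invariants_vs_oracle(self):
        """BH adjusted p >= raw p, monotone in rank, and equal to a
        brute-force step-up recomputation."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = rng.integers(2, 30)
            raw = rng.uniform(0, 1, m)
            adj = fdr_adjust(raw)
            # independent step-up oracle with cumulative minimum
            order = np.argsort(raw)
            scaled = raw[order] * m / (np.arange(m) + 1)
            stepped = np.minimum.accumulate(scaled[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            assert np.allclose(adj, expected)
            assert np.all(adj >= raw - 1e-12)
            assert np.all(np.diff(adj[order]) >= -1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20))
    def test_fdr_oracle_property(self, raw):
        raw = np.asarray(raw)
        adj = fdr_adjust(raw)
        m = raw.size
        order = np.argsort(raw, kind="stable")
        scaled = raw[order] * m / (np.arange(m) + 1)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(adj, expected)


class TestBuildReports:
    def _cohort_frame(self, n=46, seed=0):
        rng = np.random.default_rng(seed)
        data = {v: rng.normal(0, 1, n) for v in VARIABLES}
        data["go_rt_systole"] = rng.normal(471, 30, n)
        data["go_rt_diastole"] = rng.normal(474, 30, n)
        return pd.DataFrame(data)

    def test_table_has_45_pairs(self):
        bundle = build_reports(self._cohort_frame())
        assert len(bundle.table1) == 45  # 10 choose 2

    def test_fig2_has_six_condition_means(self):
        bundle = build_reports(self._cohort_frame())
        assert len(bundle.fig2_means) == 6
        assert set(bundle.fig2_means["measure"]) == {"go_rt", "ssrt", "ssd"}

    def test_missing_column_yields_missing_cells(self):
        df = self._cohort_frame().drop(columns=["awareness"])
        bundle = build_reports(df)
        aw = bundle.table1[(bundle.table1["var_a"] == "awareness")
                           | (bundle.table1["var_b"] == "awareness")]
        assert aw["r"].isna().all()
        assert len(bundle.table1) == 45

    def test_exclusion_flow_sixty_to_fortysix(self):
        summaries = build_exclusion_fixture()
        res = apply_exclusions(summaries)
        bundle = build_reports(self._cohort_frame(), exclusion_flow=res.flow)
        assert bundle.exclusion_flow["entrants"] == 60
        assert bundle.exclusion_flow["after_pass1"] == 52
        assert bundle.exclusion_flow["retained"] == 46

    def test_report_renders(self):
        from cardiostop.stats_reporting import render_report_md
        bundle = build_reports(self._cohort_frame())
        text = render_report_md(bundle)
        assert "Correlations" in text and "SSRT-s" in text
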