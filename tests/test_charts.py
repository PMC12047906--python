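import json

import numpy as np
import pandas as pd
import pytest

from cervimetry.charts import (
    CHART_RESPONSES,
    ChartError,
    MeasurementTable,
    TrendModel,
    ancova,
    build_charts,
    fit_trend,
    icc_absolute_agreement,
)
from cervimetry.phantom import generate_cohort


def _table(n=60, seed=0, ga_slope=-0.3, field_offset=0.0, noise=1.0, response_base=35.0):
    """Synthetic measurement table with known GA slope / field-strength offset
    on cervical length and canal volume respectively."""
    rng = np.random.default_rng(seed)
    ga = rng.uniform(16, 40, n)
    field = rng.choice([0.55, 3.0], n)
    length = response_base + ga_slope * (ga - 16) + rng.normal(0, noise, n)
    canal = 1300 + field_offset * (field == 3.0) + rng.normal(0, 80, n)
    cyst = np.abs(rng.normal(0, 10, n))
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "ga": ga,
            "field_strength": field,
            "maternal_age": rng.normal(33, 4, n),
            "height": rng.normal(165, 6, n),
            "weight": rng.normal(70, 10, n),
            "bmi": rng.normal(26, 4, n),
            "ethnicity": rng.choice(["white", "asian", "black"], n),
            "canal_volume": canal,
            "inner_volume": rng.normal(4800, 300, n),
            "outer_volume": rng.normal(14000, 900, n),
            "cyst_volume": cyst,
            "cervical_length": length,
            "inlet_diameter": rng.normal(7, 0.7, n),
            "outlet_diameter": rng.normal(6, 0.6, n),
        }
    )
    df["total_canal_volume"] = df["canal_volume"] + df["cyst_volume"]
    return MeasurementTable(df)


class TestMeasurementTable:
    def test_validation_errors(self):
        tbl = _table(10)
        bad = tbl.data.copy()
        bad.loc[0, "ga"] = 50.0
        with pytest.raises(ChartError, match="weeks"):
            MeasurementTable(bad)
        bad2 = tbl.data.copy()
        bad2.loc[0, "total_canal_volume"] = 0.0
        with pytest.raises(ChartError, match="total_canal"):
            MeasurementTable(bad2)
        with pytest.raises(ChartError, match="missing columns"):
            MeasurementTable(tbl.data.drop(columns=["bmi"]))

    def test_csv_round_trip(self, tmp_path):
        tbl = _table(12)
        p = tbl.to_csv(tmp_path / "t.csv")
        back = MeasurementTable.from_csv(p)
        pd.testing.assert_frame_equal(back.data, tbl.data)

    def test_from_cohort_truth_mode(self):
        cases = generate_cohort(8, seed=3, rasterise=False)
        tbl = MeasurementTable.from_cohort(cases)
        assert len(tbl) == 8
        assert np.allclose(
            tbl.data["total_canal_volume"],
            tbl.data["canal_volume"] + tbl.data["cyst_volume"],
        )


class TestFitTrend:
    def test_exact_linear_noiseless(self):
        tbl = _table(40, noise=0.0)
        m = fit_trend(tbl, "cervical_length", degree=1)
        assert m.slope == pytest.approx(-0.3, abs=1e-9)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-6)
        assert m.p_value_ga < 1e-10

    def test_slope_recovered_within_ci(self):
        cases = generate_cohort(100, seed=17, rasterise=False)
        tbl = MeasurementTable.from_cohort(cases)
        m = fit_trend(tbl, "cervical_length", degree=1)
        import statsmodels.api as sm

        x = sm.add_constant(tbl.data["ga"].to_numpy())
        fit = sm.OLS(tbl.data["cervical_length"].to_numpy(), x).fit()
        lo, hi = fit.conf_int()[1]
        assert lo <= -0.3 <= hi
        assert m.slope == pytest.approx(fit.params[1])

    def test_centile_coverage_on_fresh_sample(self):
        fit_tbl = _table(400, seed=1, noise=2.0)
        m = fit_trend(fit_tbl, "cervical_length", degree=1)
        fresh = _table(400, seed=2, noise=2.0)
        y = fresh.data["cervical_length"].to_numpy()
        ga = fresh.data["ga"].to_numpy()
        inside = (y >= m.centile(ga, 5)) & (y <= m.centile(ga, 95))
        # binomial error on 400 draws at p=0.9: 3 sd ~ 0.045
        assert np.mean(inside) == pytest.approx(0.90, abs=0.05)

    def test_constant_response_warns_zero_slope(self):
        tbl = _table(20)
        df = tbl.data.copy()
        df["cervical_length"] = 30.0
        with pytest.warns(UserWarning, match="constant"):
            m = fit_trend(MeasurementTable(df), "cervical_length")
        assert m.slope == 0.0

    def test_insufficient_rows(self):
        with pytest.raises(ChartError, match="rows"):
            fit_trend(_table(5), "cervical_length", degree=1)

    def test_model_json_round_trip(self):
        m = fit_trend(_table(50), "cervical_length")
        m2 = TrendModel.from_json(m.to_json())
        gg = np.linspace(16, 40, 50)
        for q in (5, 50, 95):
            assert np.allclose(m.centile(gg, q), m2.centile(gg, q))

    def test_centiles_ordered_and_median_is_mean(self):
        m = fit_trend(_table(50), "cervical_length")
        gg = np.linspace(*m.ga_range, 30)
        assert np.all(m.centile(gg, 5) < m.centile(gg, 50))
        assert np.all(m.centile(gg, 50) < m.centile(gg, 95))
        assert np.allclose(m.centile(gg, 50), m.mean(gg))


class TestAncova:
    def test_field_strength_offset_recovered(self):
        tbl = _table(120, seed=5, field_offset=200.0)
        eff = ancova(tbl, "canal_volume", covariates=["field_strength"])
        row = eff.loc["C(field_strength)"]
        assert row["p_value"] < 1e-6
        assert row["estimate"] == pytest.approx(200.0, abs=60.0)

    def test_ga_term_null_when_no_effect(self):
        hits = 0
        n_rep = 100
        for r in range(n_rep):
            tbl = _table(40, seed=1000 + r, ga_slope=0.0, field_offset=200.0)
            eff = ancova(tbl, "canal_volume", covariates=["field_strength"])
            if eff.loc["ga", "p_value"] > 0.05:
                hits += 1
        assert hits >= 90  # type-I error ~ 5%

    def test_constant_response_across_groups(self):
        tbl = _table(60, seed=9, ga_slope=0.0, noise=1.0)
        df = tbl.data.copy()
        rng = np.random.default_rng(0)
        df["inlet_diameter"] = rng.normal(7.0, 0.5, len(df))  # no structure
        eff = ancova(MeasurementTable(df), "inlet_diameter")
        assert (eff["p_value"].drop(labels=[t for t in eff.index if t == "Intercept"],
                                    errors="ignore") > 0.05).mean() >= 0.8

    def test_permutation_null_p_values_uniform(self):
        from scipy import stats

        tbl = _table(80, seed=3, ga_slope=-0.3)
        rng = np.random.default_rng(42)
        pvals = []
        df = tbl.data.copy()
        for _ in range(200):
            df["cervical_length"] = rng.permutation(df["cervical_length"].to_numpy())
            eff = ancova(MeasurementTable(df), "cervical_length", covariates=[])
            pvals.append(eff.loc["ga", "p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_rank_deficiency_reported(self):
        tbl = _table(40, seed=6)
        df = tbl.data.copy()
        df["bmi2"] = df["bmi"] * 1.0
        t2 = MeasurementTable(df)
        with pytest.raises(ChartError, match="rank-deficient"):
            ancova(t2, "cervical_length", covariates=["bmi", "bmi2"])


class TestICC:
    # 6-subject, 2-rater worked example; expected value frozen from the
    # two-way ANOVA mean-squares computation done by hand:
    # rows (subjects) x raters, grand mean 7.0
    TABLE = np.array(
        [[4.0, 5.0], [6.0, 7.0], [7.0, 9.0], [8.0, 8.0], [9.0, 11.0], [5.0, 5.0]]
    )
    # row means: 4.5, 6.5, 8, 8, 10, 5; col means: 6.5, 7.5
    # SSR = 2*sum((rm-7)^2) = 2*21.5 = 43 -> MSR = 43/5 = 8.6
    # SSC = 6*((6.5-7)^2+(7.5-7)^2) = 3 -> MSC = 3
    # SST = sum((x-7)^2) = 48 -> SSE = 48-43-3 = 2 -> MSE = 2/5 = 0.4
    # ICC = (8.6-0.4)/(8.6 + 0.4 + 2*(3-0.4)/6) = 8.2/(148/15) = 123/148
    EXPECTED = 123.0 / 148.0

    def test_worked_example_matches_hand_mean_squares(self):
        assert icc_absolute_agreement(self.TABLE) == pytest.approx(self.EXPECTED, abs=1e-6)

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        n, k = self.TABLE.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": self.TABLE.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        ref = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_absolute_agreement(self.TABLE) == pytest.approx(ref, abs=1e-9)

    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc_absolute_agreement(x, x) == pytest.approx(1.0)

    def test_bias_penalised_unlike_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 10.0
        icc = icc_absolute_agreement(x, y)
        assert icc < 0.2  # Pearson would be 1.0

    def test_symmetry_and_common_rescaling(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 2, 12)
        y = x + rng.normal(0, 0.5, 12)
        assert icc_absolute_agreement(x, y) == pytest.approx(icc_absolute_agreement(y, x))
        assert icc_absolute_agreement(3 * x, 3 * y) == pytest.approx(
            icc_absolute_agreement(x, y), abs=1e-9
        )

    def test_degenerate_inputs(self):
        assert icc_absolute_agreement(np.full((5, 2), 3.0)) is None
        with pytest.raises(ChartError):
            icc_absolute_agreement(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestBuildCharts:
    def test_bundle_completeness_and_round_trip(self, tmp_path):
        tbl = _table(60, seed=11)
        models = build_charts(tbl, tmp_path)
        assert set(models) == set(CHART_RESPONSES)
        for resp in CHART_RESPONSES:
            assert (tmp_path / f"{resp}_chart.png").exists()
            assert (tmp_path / f"{resp}_model.json").exists()
        # regenerating centiles from the serialised model is bit-identical
        m = models["cervical_length"]
        m2 = TrendModel.from_json((tmp_path / "cervical_length_model.json").read_text())
        gg = np.linspace(*m.ga_range, 100)
        assert np.array_equal(m.centile(gg, 5), m2.centile(gg, 5))
        assert m.ga_range == (
            float(tbl.data["ga"].min()),
            float(tbl.data["ga"].max()),
        )
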