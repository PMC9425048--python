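import logging

import numpy as np
import pandas as pd
import pytest

from rumigen.intake import (
    FeedSpec,
    daily_intake,
    energy_intake,
    feeding_behavior,
    fit_rfi,
    interpolate_growth,
    metabolic_midweight,
    regression_growth,
)


def _events(rows):
    return pd.DataFrame(rows, columns=["animal", "feeder", "entry", "exit", "grams"])


class TestDailyIntake:
    def test_sums_events_within_a_day(self):
        ev = _events(
            [("a", 1, f"2016-06-01T0{h}:00:00", f"2016-06-01T0{h}:10:00", 100.0) for h in range(3)]
        )
        table = daily_intake(ev, n_days=2)
        assert table.loc["a", 0] == pytest.approx(300.0)
        assert table.loc["a", 1] == 0.0

    def test_empty_log_warns_and_returns_zeros(self, caplog):
        ev = _events([("a", 1, "2016-06-01T01:00:00", "2016-06-01T01:05:00", -5.0)])
        with caplog.at_level(logging.WARNING):
            table = daily_intake(ev, n_days=3)
        assert (table.to_numpy() == 0).all()
        assert any("negative" in r.message for r in caplog.records)

    def test_midnight_event_assigned_to_entry_day(self):
        ev = _events([("a", 1, "2016-06-01T23:59:00", "2016-06-02T00:05:00", 50.0)])
        table = daily_intake(ev, n_days=2)
        assert table.loc["a", 0] == pytest.approx(50.0)
        assert table.loc["a", 1] == 0.0

    def test_conservation_of_total_grams(self, rng):
        rows = []
        for i in range(20):
            d, h = rng.integers(0, 42), rng.integers(0, 23)
            rows.append(("x", 1, f"2016-06-{d % 28 + 1:02d}T{h:02d}:00:00",
                         f"2016-06-{d % 28 + 1:02d}T{h:02d}:10:00", float(rng.uniform(10, 400))))
        ev = _events(rows)
        assert daily_intake(ev).to_numpy().sum() == pytest.approx(ev["grams"].sum())


class TestMeanIntake:
    def test_lsmeans_equals_mean_on_complete_data(self, rng):
        from rumigen.intake import mean_intake

        daily = pd.DataFrame(
            rng.uniform(2000, 3000, size=(6, 42)), index=[f"a{i}" for i in range(6)]
        )
        plain = mean_intake(daily, "mean")
        ls = mean_intake(daily, "lsmeans")
        np.testing.assert_allclose(ls.to_numpy(), plain.to_numpy(), rtol=1e-6)

    def test_lsmeans_adjusts_for_missing_day(self):
        from rumigen.intake import mean_intake

        # all animals eat 100 g more on day 1; animal b misses that day, so
        # its plain mean is biased low while the LS-mean corrects upward to
        # match its herd-mates
        daily = pd.DataFrame(
            {0: [2000.0, 2000.0, 2000.0],
             1: [2100.0, np.nan, 2100.0],
             2: [2000.0, 2000.0, 2000.0]},
            index=["a", "b", "c"],
        )
        ls = mean_intake(daily, "lsmeans")
        assert daily.loc["b"].mean() == pytest.approx(2000.0)  # plain mean biased
        assert ls["b"] == pytest.approx(ls["a"], abs=1e-6)
        assert ls["a"] == pytest.approx(2100.0 / 3 + 4000.0 / 3, abs=1e-6)


class TestEnergyIntake:
    @pytest.mark.parametrize(
        "grams,dm,me,expected",
        [
            (0.0, 0.93, 10.9, 0.0),
            (1000.0, 1.0, 10.0, 10.0),
            # year-1 pellets: ~2.5 kg/day at 93% DM and 10.9 MJ/kg DM
            (2500.0, 0.93, 10.9, 25.34),
        ],
    )
    def test_product_formula(self, grams, dm, me, expected):
        assert energy_intake(grams, FeedSpec(dm, me)) == pytest.approx(expected, abs=0.005)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FeedSpec(0.0, 10.0)
        with pytest.raises(ValueError):
            FeedSpec(0.9, -1.0)


class TestGrowth:
    def test_linear_data_midpoint(self):
        g = interpolate_growth([(0, 50.0), (42, 54.0)])
        assert g.day21_weight == pytest.approx(52.0)
        assert g.adg == pytest.approx(4.0 / 42.0)

    def test_constant_weight(self):
        g = interpolate_growth([(0, 50.0), (42, 50.0)])
        assert g.adg == 0.0
        assert g.mmwt == pytest.approx(50.0**0.75)

    def test_piecewise_evaluation(self):
        # hand piecewise: day 21 sits midway on the flat 14-28 segment
        g = interpolate_growth([(0, 50.0), (14, 52.0), (28, 52.0), (42, 56.0)])
        assert g.day21_weight == pytest.approx(52.0)

    def test_regression_equals_interpolation_on_exact_line(self):
        pts = [(d, 40.0 + 0.3 * d) for d in range(0, 43, 3)]
        gi = interpolate_growth(pts)
        gr = regression_growth(pts)
        assert gr.adg == pytest.approx(gi.adg)
        assert gr.mmwt == pytest.approx(gi.mmwt)

    def test_regression_matches_normal_equations(self):
        pts = [(0, 50.0), (14, 52.0), (21, 70.0), (28, 52.0), (42, 56.0)]  # one outlier
        day = np.array([p[0] for p in pts])
        kg = np.array([p[1] for p in pts])
        X = np.column_stack([np.ones_like(day), day])
        beta = np.linalg.solve(X.T @ X, X.T @ kg)
        g = regression_growth(pts)
        assert g.adg == pytest.approx(beta[1])

    def test_too_few_weighings_rejected(self):
        with pytest.raises(ValueError):
            interpolate_growth([(0, 50.0)])

    def test_metabolic_midweight(self):
        assert metabolic_midweight(16.0) == pytest.approx(8.0)
        assert metabolic_midweight(1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            metabolic_midweight(0.0)


class TestFeedingBehavior:
    def test_single_event(self):
        ev = _events([("a", 1, "2016-06-01T01:00:00", "2016-06-01T01:03:20", 100.0)])
        b = feeding_behavior(ev, n_days=1)
        assert b.loc["a", "mean_rate_g_per_s"] == pytest.approx(0.5)
        assert b.loc["a", "events_per_day"] == pytest.approx(1.0)

    def test_rate_is_mean_of_per_event_rates(self):
        # 100 g / 200 s and 300 g / 100 s: per-event mean 1.75, pooled 1.33
        ev = _events(
            [
                ("a", 1, "2016-06-01T01:00:00", "2016-06-01T01:03:20", 100.0),
                ("a", 1, "2016-06-01T02:00:00", "2016-06-01T02:01:40", 300.0),
            ]
        )
        b = feeding_behavior(ev, n_days=1)
        assert b.loc["a", "mean_rate_g_per_s"] == pytest.approx(1.75)

    def test_empty_log(self):
        b = feeding_behavior(_events([]))
        assert len(b) == 0


class TestFitRFI:
    @staticmethod
    def _data(n=120, seed=5, resid=None):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "animal": [f"a{i}" for i in range(n)],
                "mmwt": rng.normal(20.8, 2.0, n),
                "adg": rng.normal(0.35, 0.07, n),
                "flock": rng.choice(list("ABC"), n),
                "cohort": rng.choice(["1", "2a", "2b"], n),
            }
        )
        df["pen"] = rng.choice(list("AB"), n)
        df["energy_intake"] = 2.6 + 0.6 * df["mmwt"] + 30.0 * df["adg"]
        if resid is not None:
            df["energy_intake"] += resid
        return df

    def test_exact_model_data_gives_zero_rfi(self):
        fit = fit_rfi(self._data())
        assert np.abs(fit.residuals.to_numpy()).max() < 1e-9
        assert fit.r2 == pytest.approx(1.0)

    def test_recovers_injected_orthogonal_residuals(self):
        df = self._data()
        fit0 = fit_rfi(df)
        rng = np.random.default_rng(11)
        eps = rng.normal(0, 1.3, len(df))
        # project onto the orthogonal complement of the design
        X = fit0.design
        eps -= X @ np.linalg.lstsq(X, eps, rcond=None)[0]
        fit = fit_rfi(self._data(resid=eps))
        np.testing.assert_allclose(fit.residuals.to_numpy(), eps, atol=1e-8)

    def test_residuals_orthogonal_and_zero_sum(self):
        rng = np.random.default_rng(3)
        df = self._data(resid=rng.normal(0, 1.3, 120))
        fit = fit_rfi(df)
        r = fit.residuals.to_numpy()
        assert abs(r.sum()) < 1e-8
        assert abs(r @ df["mmwt"].to_numpy()) < 1e-7
        assert abs(r @ df["adg"].to_numpy()) < 1e-7
        # fitted + residual reconstructs the observation
        np.testing.assert_allclose(
            fit.fitted.to_numpy() + r, df["energy_intake"].to_numpy(), atol=1e-9
        )

    def test_aliased_columns_dropped_not_fatal(self):
        df = self._data()
        df["pen"] = "A"  # pen aliased with cohort after nesting
        fit = fit_rfi(df)
        assert fit.r2 == pytest.approx(1.0)
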