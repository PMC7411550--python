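"""Spline basis, design assembly, conditional likelihood, transforms."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from dusticu import ccmodel
from dusticu.ccmodel import (
    DesignSpec,
    FitResult,
    LagEstimate,
    fit_conditional_quasipoisson,
    lag_window_average,
    natural_spline_basis,
    percent_increase,
    scale_scenario,
)
from dusticu.exceptions import (
    DegenerateDataError,
    DomainError,
    SeparationError,
    UnidentifiedError,
)


class TestNaturalSplineBasis:
    def test_df_one_is_linear(self):
        x = np.array([1.0, 2.0, 5.0])
        assert np.array_equal(natural_spline_basis(x, 1), x[:, None])

    def test_rank_equals_df(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 300)
        for df in (2, 3, 5, 8):
            B = natural_spline_basis(x, df)
            assert B.shape[1] == df
            assert np.linalg.matrix_rank(B) == df

    def test_linear_beyond_boundary_knots(self):
        # finite-difference second derivative vanishes outside the boundary
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 200)
        probes = np.array([12.0, 12.1, 12.2, -3.2, -3.1, -3.0])
        B = natural_spline_basis(np.r_[x, probes], 4, boundary_knots=(x.min(), x.max()))
        for i in (len(x), len(x) + 3):
            fd2 = B[i] - 2 * B[i + 1] + B[i + 2]
            assert np.abs(fd2).max() < 1e-8

    def test_degenerate_values_rejected(self):
        with pytest.raises(DegenerateDataError):
            natural_spline_basis(np.array([1.0, 1.0, 1.0, 2.0]), 3)
        with pytest.raises(DomainError):
            natural_spline_basis(np.array([1.0, np.nan]), 2)


def _toy_days(n_strata=6, days_per=8, seed=0, span_years=1):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_strata):
        start = pd.Timestamp(f"{2005 + (s % span_years)}-01-01") + pd.Timedelta(days=30 * s)
        for i in range(days_per):
            rows.append(
                {
                    "stratum_id": f"s{s}",
                    "zip": "A",
                    "date": start + pd.Timedelta(days=i * 3),
                    "dust_lag0": int(i == 0),
                    "dust_lag1": int(i == 1),
                    "dust_lag2": int(i == 2),
                    "dust_lag3": int(i == 3),
                    "dust_lag4": int(i == 4),
                    "dust_lag5": int(i == 5),
                    "temperature": rng.normal(75, 10),
                    "temperature_lag1": rng.normal(75, 10),
                    "dewpoint": rng.normal(45, 8),
                    "pm25": rng.uniform(3, 20),
                    "ozone": rng.uniform(20, 80),
                    "count_respiratory": rng.poisson(3),
                }
            )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_dust_only_gives_six_columns(self):
        dm = ccmodel.build_design(_toy_days(), DesignSpec.dust_only())
        assert dm.names == [f"dust_lag{k}" for k in range(6)]

    def test_date_spline_df_is_eight_per_calendar_year(self):
        days = _toy_days(n_strata=10, span_years=2)
        spec = DesignSpec(
            temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0, pm25=False, ozone=False
        )
        dm = ccmodel.build_design(days, spec)
        n_date = sum(n.startswith("date_ns") for n in dm.names + dm.aliased)
        assert n_date == 16

    def test_duplicated_covariate_reported_aliased(self):
        days = _toy_days()
        days["ozone"] = days["pm25"]  # exact duplicate
        spec = DesignSpec(
            temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0, date_df_per_year=0
        )
        dm = ccmodel.build_design(days, spec)
        assert "ozone" in dm.aliased
        assert "pm25" in dm.names

    def test_empty_rows_rejected(self):
        days = _toy_days()
        days["pm25"] = np.nan
        with pytest.raises(DegenerateDataError):
            ccmodel.build_design(days, DesignSpec(date_df_per_year=0))


class TestConditionalFit:
    def test_closed_form_single_stratum(self):
        # p-hat = 2/3  =>  exp(b)/(1+exp(b)) = 2/3  =>  b = ln 2
        fit = fit_conditional_quasipoisson([1, 2], np.array([[0.0], [1.0]]), ["s", "s"])
        assert fit.beta.iloc[0] == pytest.approx(math.log(2), abs=1e-8)

    def test_matches_stratum_dummy_poisson(self):
        rng = np.random.default_rng(3)
        G, n = 10, 4
        sid = np.repeat(np.arange(G), n)
        X = rng.normal(size=(G * n, 3))
        y = rng.poisson(np.exp(rng.normal(size=G)[sid] + X @ np.array([0.3, -0.2, 0.1])))
        fit = fit_conditional_quasipoisson(y, X, sid)
        D = pd.get_dummies(sid).to_numpy(dtype=float)
        glm = sm.GLM(y, np.hstack([D, X]), family=sm.families.Poisson()).fit()
        assert np.abs(fit.beta.to_numpy() - glm.params[G:]).max() < 1e-6

    def test_stratum_constant_covariate_aliased_not_zero(self):
        days = _toy_days()
        days["pm25"] = days["stratum_id"].map(lambda s: float(ord(s[-1])))  # constant per stratum
        spec = DesignSpec(
            temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0, date_df_per_year=0
        )
        fit, dm = ccmodel.fit_stratum_table(days, "respiratory", spec)
        assert "pm25" in fit.aliased
        assert "pm25" not in fit.beta.index

    def test_adding_stratum_constant_column_changes_nothing(self):
        days = _toy_days(seed=5)
        spec = DesignSpec(
            temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0, date_df_per_year=0,
            pm25=False, ozone=False,
        )
        fit0, _ = ccmodel.fit_stratum_table(days, "respiratory", spec)
        days2 = days.copy()
        days2["pm25"] = days2["stratum_id"].map(lambda s: float(int(s[1:]) * 3 + 1))
        spec2 = DesignSpec(
            temperature_lag0_df=0, temperature_lag1_df=0, dewpoint_df=0, date_df_per_year=0,
            pm25=True, ozone=False,
        )
        fit1, _ = ccmodel.fit_stratum_table(days2, "respiratory", spec2)
        assert "pm25" in fit1.aliased
        shared = [n for n in fit0.beta.index]
        assert np.allclose(fit0.beta[shared], fit1.beta[shared], atol=1e-10)

    def test_complete_separation_raises(self):
        # all events on the exposed day: conditional likelihood is monotone
        with pytest.raises(SeparationError):
            fit_conditional_quasipoisson(
                [0, 50], np.array([[0.0], [1.0]]), ["s", "s"], max_iter=200
            )

    def test_vcov_symmetric_psd_and_dispersion_positive(self):
        rng = np.random.default_rng(9)
        sid = np.repeat(np.arange(20), 5)
        X = rng.normal(size=(100, 2))
        y = rng.poisson(np.exp(0.2 * X[:, 0]))
        fit = fit_conditional_quasipoisson(y, X, sid)
        V = fit.vcov.to_numpy()
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) > -1e-12)
        assert fit.dispersion > 0


class TestContrastsAndTransforms:
    def _fixture_fit(self):
        names = ["dust_lag0", "dust_lag1", "dust_lag2"]
        beta = pd.Series([0.10, 0.05, -0.02], index=names)
        V = np.array([[0.04, 0.01, 0.0], [0.01, 0.09, 0.02], [0.0, 0.02, 0.16]])
        return FitResult(
            beta=beta, vcov=pd.DataFrame(V, index=names, columns=names),
            dispersion=1.0, n_days=10, n_strata=3, n_params=3, n_iter=1, gradient_norm=0.0,
        )

    def test_single_lag_window_equals_lag_estimate(self):
        fit = self._fixture_fit()
        w = lag_window_average(fit, [1])
        direct = percent_increase(0.05, 0.3)
        assert w.percent == pytest.approx(direct.percent)
        assert w.se == pytest.approx(direct.se)

    def test_window_matches_hand_arithmetic(self):
        fit = self._fixture_fit()
        w = lag_window_average(fit, [0, 1, 2])
        c = np.full(3, 1 / 3)
        est = c @ fit.beta.to_numpy()
        var = c @ fit.vcov.to_numpy() @ c
        assert w.beta == pytest.approx(est)
        assert w.se == pytest.approx(math.sqrt(var))

    def test_equal_coefficients_diagonal_vcov_closed_form(self):
        names = [f"dust_lag{k}" for k in range(3)]
        b, v = 0.07, 0.09
        fit = FitResult(
            beta=pd.Series([b] * 3, index=names),
            vcov=pd.DataFrame(np.eye(3) * v, index=names, columns=names),
            dispersion=1.0, n_days=9, n_strata=3, n_params=3, n_iter=1, gradient_norm=0.0,
        )
        w = lag_window_average(fit, [0, 1, 2])
        assert w.beta == pytest.approx(b)
        assert w.se**2 == pytest.approx(v / 3)

    def test_missing_lag_raises(self):
        fit = self._fixture_fit()
        with pytest.raises(UnidentifiedError):
            lag_window_average(fit, [5])

    def test_percent_increase_reference_points(self):
        assert percent_increase(0.0, 0.1).percent == 0.0
        assert percent_increase(math.log(2), 0.1).percent == pytest.approx(100.0)
        est = percent_increase(0.046884, 0.022, label="lag 0")
        assert round(est.percent, 1) == 4.8
        assert est.ci_low < est.percent < est.ci_high

    def test_scenario_identity_when_target_equals_delta(self):
        est = LagEstimate("lag 0", 0.047, 0.022, 4.8, 0.4, 9.4, 0.033)
        sc = scale_scenario(est, delta_pm10=47.8, target_pm10=47.8)
        assert sc.percent == pytest.approx(4.8)
        assert sc.ci_high == pytest.approx(9.4)

    @given(st.floats(min_value=50, max_value=1000))
    def test_scenario_monotone_in_target(self, target):
        est = LagEstimate("lag 0", 0.047, 0.022, 4.8, 0.4, 9.4, 0.033)
        lo = scale_scenario(est, target_pm10=target).percent
        hi = scale_scenario(est, target_pm10=target + 10).percent
        assert hi > lo

    def test_scenario_continuous_at_zero(self):
        est = LagEstimate("lag 0", 0.0, 0.0, 1e-9, -1e-9, 1e-9, 1.0)
        sc = scale_scenario(est, target_pm10=400.0)
        assert abs(sc.percent) < 1e-6

    def test_scenario_domain_error(self):
        est = LagEstimate("lag 0", 0.0, 0.0, -100.0, -100.0, 0.0, 1.0)
        with pytest.raises(DomainError):
            scale_scenario(est)
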