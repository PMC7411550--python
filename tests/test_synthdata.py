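"""Generator contracts: calendars, environment shifts, count moments."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dusticu import synthdata
from dusticu.synthdata import SynthConfig, generate_bundle


def _calendar(cfg):
    return synthdata.generate_storm_calendar(cfg, np.random.default_rng(cfg.seed))


class TestStormCalendar:
    def test_degenerate_month_weights_put_every_storm_in_july(self):
        weights = tuple(1 if m == 7 else 0 for m in range(1, 13))
        cfg = SynthConfig(n_zips=8, years=(2005, 2006), month_weights=weights, seed=1)
        storms = _calendar(cfg)
        assert len(storms) > 0
        assert (storms["begin_date"].dt.month == 7).all()

    def test_same_seed_reproduces_identical_calendar(self):
        cfg = SynthConfig(n_zips=8, years=(2005, 2006), seed=2)
        assert _calendar(cfg).equals(_calendar(cfg))

    def test_july_august_dominate_with_default_weights(self):
        # ~10,000 storms: empirical monthly frequencies track the weights
        cfg = SynthConfig(n_zips=24, years=(2000, 2015), storm_rate=26.0, seed=3)
        storms = _calendar(cfg)
        assert len(storms) > 5000
        share = storms["begin_date"].dt.month.value_counts(normalize=True)
        jul_aug = share.get(7, 0) + share.get(8, 0)
        others = [
            share.get(m, 0) + share.get(m % 12 + 1, 0)
            for m in range(1, 13)
            if (m, m % 12 + 1) != (7, 8)
        ]
        assert jul_aug > max(others)

    def test_afternoon_peaked_begin_hours(self):
        cfg = SynthConfig(n_zips=24, years=(2000, 2015), storm_rate=5.0, seed=4)
        hours = _calendar(cfg)["begin_hour"]
        assert hours.between(0, 23).all()
        assert 13 <= hours.median() <= 16

    def test_zero_storm_rate_rejected(self):
        cfg = SynthConfig(n_zips=4, years=(2005, 2005), seed=1)
        cfg = dataclasses.replace(cfg, storm_rate=0.0)
        with pytest.raises(ValueError):
            _calendar(cfg)


class TestEnvironment:
    def test_dust_day_offsets_applied_exactly(self):
        # identical seeds with and without offsets isolate the additive shift
        base = dict(n_zips=8, years=(2005, 2006), storm_rate=3.0, monitor_missing_rate={}, seed=6)
        cfg_on = SynthConfig(**base)
        cfg_off = SynthConfig(**base, env_offsets={v: 0.0 for v in synthdata.DEFAULT_ENV_OFFSETS})
        b_on, b_off = generate_bundle(cfg_on), generate_bundle(cfg_off)
        merged = b_on.monitors.merge(
            b_off.monitors, on=["monitor_id", "date", "variable"], suffixes=("_on", "_off")
        )
        merged["delta"] = merged["value_on"] - merged["value_off"]
        dust_key = set(zip("M" + b_on.dust_days["zip"], b_on.dust_days["date"]))
        on_dust = [
            (m, d) in dust_key for m, d in zip(merged["monitor_id"], pd.to_datetime(merged["date"]))
        ]
        merged["on_dust"] = on_dust
        pm10 = merged[merged["variable"] == "pm10"]
        assert pm10.loc[pm10["on_dust"], "delta"].sub(47.8).abs().max() < 1e-9
        assert pm10.loc[~pm10["on_dust"], "delta"].abs().max() < 1e-9

    def test_total_missingness_removes_a_variable(self):
        cfg = SynthConfig(
            n_zips=4, years=(2005, 2005), storm_rate=2.0, monitor_missing_rate={"pm25": 1.0}, seed=7
        )
        b = generate_bundle(cfg)
        assert not (b.monitors["variable"] == "pm25").any()
        assert (b.monitors["variable"] == "pm10").any()

    def test_bundle_is_seed_deterministic(self, small_config):
        b1, b2 = generate_bundle(small_config), generate_bundle(small_config)
        assert b1.storms.equals(b2.storms)
        assert b1.monitors.equals(b2.monitors)
        assert b1.icu.equals(b2.icu)


def _flat_count_config(**overrides):
    base = dict(
        n_zips=1,
        years=(2000, 2015),
        storm_rate=1.0,
        dow_effects=(1.0,) * 7,
        zip_effect_sd=0.0,
        monitor_missing_rate={},
        seed=8,
    )
    base.update(overrides)
    return SynthConfig(**base)


def _no_dust_grid(cfg):
    y0, y1 = cfg.years
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    return pd.DataFrame({"zip": "84001", "date": dates, "dust": 0})


class TestIcuCounts:
    def test_zero_baseline_gives_zero_counts(self):
        cfg = _flat_count_config(baseline_mean={c: 0.0 for c in synthdata.COMPONENTS})
        counts = synthdata.generate_icu_counts(cfg, _no_dust_grid(cfg), np.random.default_rng(0))
        assert (counts["count"] == 0).all()

    def test_wrong_lag_rr_length_rejected(self):
        with pytest.raises(ValueError, match="lag_rr"):
            SynthConfig(lag_rr={"respiratory": (1.1, 1.0)})

    def test_overdispersion_below_one_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(overdispersion=0.5)

    def test_counts_respect_endpoint_nesting(self, small_bundle):
        wide = small_bundle.icu.pivot_table(
            index=["zip", "date"], columns="endpoint", values="count"
        )
        assert (wide["respiratory"] <= wide["all"]).all()
        assert (wide["cardiovascular"] <= wide["all"]).all()
        assert (small_bundle.icu["count"] >= 0).all()

    def test_variance_inflation_matches_configured_overdispersion(self):
        # fixed covariates: ratio of variance to mean estimates phi
        cfg = _flat_count_config(overdispersion=2.0)
        counts = synthdata.generate_icu_counts(cfg, _no_dust_grid(cfg), np.random.default_rng(1))
        resp = counts.loc[counts["endpoint"] == "respiratory", "count"]
        ratio = resp.var() / resp.mean()
        assert 1.7 < ratio < 2.3

    def test_poisson_limit_has_unit_variance_ratio(self):
        cfg = _flat_count_config(overdispersion=1.0)
        counts = synthdata.generate_icu_counts(cfg, _no_dust_grid(cfg), np.random.default_rng(2))
        resp = counts.loc[counts["endpoint"] == "respiratory", "count"]
        ratio = resp.var() / resp.mean()
        assert 0.85 < ratio < 1.15

    def test_log_linear_lag_structure_recovered_by_poisson_regression(self):
        rr = (1.5, 1.0, 1.0, 1.0, 1.0, 1.25)
        cfg = SynthConfig(
            n_zips=8,
            years=(2004, 2007),
            storm_rate=3.0,
            lag_rr={"respiratory": rr, "cardiovascular": (1.0,) * 6, "other": (1.0,) * 6},
            monitor_missing_rate={},
            seed=9,
        )
        b = generate_bundle(cfg)
        grid = b.icu[b.icu["endpoint"] == "respiratory"].merge(
            b.dust_days[["zip", "date"]].assign(dust=1), on=["zip", "date"], how="left"
        )
        grid["dust"] = grid["dust"].fillna(0)
        grid = grid.sort_values(["zip", "date"])
        lag_cols = []
        for k in range(6):
            col = f"lag{k}"
            grid[col] = grid.groupby("zip")["dust"].shift(k).fillna(0)
            lag_cols.append(col)
        X = pd.get_dummies(
            grid[["zip"]].assign(dow=pd.to_datetime(grid["date"]).dt.weekday.astype(str)),
            columns=["zip", "dow"],
            drop_first=True,
            dtype=float,
        )
        X = pd.concat([grid[lag_cols].reset_index(drop=True), X.reset_index(drop=True)], axis=1)
        X.insert(0, "const", 1.0)
        res = sm.GLM(grid["count"].values, X.values, family=sm.families.Poisson()).fit()
        for k, true_rr in [(0, rr[0]), (5, rr[5])]:
            j = 1 + k
            assert abs(res.params[j] - np.log(true_rr)) < 3 * res.bse[j]


def test_yaml_roundtrip(tmp_path):
    cfg = SynthConfig(n_zips=4, years=(2005, 2005), seed=3)
    p = tmp_path / "synth.yaml"
    p.write_text(
        "n_zips: 4\nyears: [2005, 2005]\nseed: 3\n"
        "lag_rr:\n  respiratory: [1.1, 1, 1, 1, 1, 1]\n"
        "  cardiovascular: [1, 1, 1, 1, 1, 1]\n  other: [1, 1, 1, 1, 1, 1]\n"
    )
    loaded = synthdata.SynthConfig.from_yaml(p)
    assert loaded.n_zips == cfg.n_zips
    assert loaded.lag_rr["respiratory"][0] == 1.1
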