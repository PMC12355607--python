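import numpy as np
import pandas as pd
import pytest

from aridaq.dust import flag_dust_days
from aridaq.synthetic import (
    MET_SIGN_PATTERN,
    DustEvent,
    SynthConfig,
    default_dust_events,
    gen_annual_gm_series,
    gen_hourly_year,
    gen_met_series,
    inject_dust,
)
from aridaq.timeseries import daily_table, monthly_means
from aridaq.trends import heating_label, pearson_matrix


class TestHourlyGenerator:
    def test_same_seed_reproduces_identical_records(self):
        cfg = SynthConfig(seed=7, n_stations=2)
        a, _ = gen_hourly_year(cfg)
        b, _ = gen_hourly_year(SynthConfig(seed=7, n_stations=2))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a, _ = gen_hourly_year(SynthConfig(seed=1, n_stations=1))
        b, _ = gen_hourly_year(SynthConfig(seed=2, n_stations=1))
        assert not a["concentration"].equals(b["concentration"])

    def test_concentrations_non_negative(self):
        rec, _ = gen_hourly_year(SynthConfig(seed=3, n_stations=1))
        assert (rec["concentration"] >= 0).all()

    def test_seasonal_shape_winter_vs_summer(self, noise_free_config):
        rec, _ = gen_hourly_year(noise_free_config)
        months = monthly_means(daily_table(rec))
        assert months.loc[1, "PM10"] > months.loc[7, "PM10"]
        assert months.loc[1, "NO2"] > months.loc[7, "NO2"]
        assert months.loc[7, "O3"] > months.loc[1, "O3"]

    def test_heating_multiplier_exact_in_noise_free_limit(self):
        cfg = SynthConfig(
            seed=0, n_stations=1, noise_sigma=0.0, station_sigma=0.0,
            seasonal_amplitude={p: 0.0 for p in
                                ("SO2", "NO2", "PM10", "PM2.5", "CO", "O3")},
            heating_multiplier={"SO2": 2.5},
        )
        rec, _ = gen_hourly_year(cfg)
        so2 = rec[rec["pollutant"] == "SO2"].set_index("datetime")["concentration"]
        heat = heating_label(so2.index.normalize()).to_numpy()
        assert so2[heat].mean() / so2[~heat].mean() == pytest.approx(2.5)


class TestDustInjection:
    def test_detector_recovers_every_injected_event(self, noise_free_config):
        rec, truth = gen_hourly_year(noise_free_config)
        flags = flag_dust_days(rec)
        detected = {pd.Timestamp(f.date) for f in flags if f.is_dust_affected}
        assert detected == set(truth.dust_days)
        assert len(detected) == 22

    def test_no_events_on_clean_baseline(self):
        cfg = SynthConfig(seed=0, n_stations=1, noise_sigma=0.0,
                          station_sigma=0.0)
        rec, _ = gen_hourly_year(cfg)
        flags = flag_dust_days(rec)
        assert not any(f.is_dust_affected for f in flags)

    def test_severe_event_is_deduction_eligible(self):
        cfg = SynthConfig(
            seed=0, n_stations=1, noise_sigma=0.0, station_sigma=0.0,
            dust_events=[DustEvent("2022-04-20", start_hour=10,
                                   duration_h=2, pm10=650.0, ratio=0.25)],
        )
        rec, truth = gen_hourly_year(cfg)
        flags = {pd.Timestamp(f.date): f for f in flag_dust_days(rec)}
        day = flags[pd.Timestamp("2022-04-20")]
        assert day.is_dust_affected and day.deduction_eligible
        assert truth.deduction_eligible_days == [pd.Timestamp("2022-04-20")]

    def test_overlapping_events_merged(self):
        cfg = SynthConfig(seed=0, n_stations=1, noise_sigma=0.0,
                          station_sigma=0.0)
        rec, _ = gen_hourly_year(cfg)
        events = [
            DustEvent("2022-05-01", start_hour=8, duration_h=4, pm10=300.0),
            DustEvent("2022-05-01", start_hour=10, duration_h=4, pm10=400.0),
        ]
        merged, truth = inject_dust(rec, events)
        assert truth.dust_days == [pd.Timestamp("2022-05-01")]
        day = merged[
            (merged["pollutant"] == "PM10")
            & (merged["datetime"].dt.normalize() == pd.Timestamp("2022-05-01"))
        ].set_index(merged.loc[
            (merged["pollutant"] == "PM10")
            & (merged["datetime"].dt.normalize() == pd.Timestamp("2022-05-01")),
            "datetime"].dt.hour)["concentration"]
        assert day.loc[8] == 300.0 and day.loc[10] == 400.0 and day.loc[13] == 400.0

    def test_default_calendar_has_22_events(self):
        assert len(default_dust_events(2022)) == 22


class TestAnnualSeriesGenerator:
    def test_noise_free_law_is_deterministic(self):
        a1, _ = gen_annual_gm_series(0.1, 50.0, 48.0, 6)
        a2, _ = gen_annual_gm_series(0.1, 50.0, 48.0, 6)
        assert np.array_equal(a1, a2)

    def test_negative_a_grows_strictly(self):
        x, _ = gen_annual_gm_series(-0.05, 100.0, 95.0, 8)
        assert np.all(np.diff(x) > 0)

    def test_small_noise_keeps_grade_one_with_high_probability(self):
        from aridaq.gm11 import accuracy, fit_gm11

        good = 0
        for seed in range(30):
            x, _ = gen_annual_gm_series(0.05, 100.0, 95.0, 8,
                                        noise_sd=1.0, seed=seed)
            if accuracy(fit_gm11(x)).grade == 1:
                good += 1
        assert good >= 27

    def test_nonpositive_outcome_rejected(self):
        with pytest.raises(ValueError):
            gen_annual_gm_series(3.0, 1.0, 1.0, 6)


class TestMetGenerator:
    def test_configured_signs_reproduced(self):
        table, truth = gen_met_series(n_months=120, seed=0, strength=0.8)
        corr = pearson_matrix(table)
        signs = truth.correlation_signs
        for met in signs.index:
            for pol in signs.columns:
                assert np.sign(corr.r.loc[met, pol]) == signs.loc[met, pol]

    def test_zero_strength_gives_weak_correlations(self):
        table, _ = gen_met_series(n_months=200, seed=1, strength=0.0)
        corr = pearson_matrix(table)
        off = corr.r.to_numpy()[~np.eye(len(corr.r), dtype=bool)]
        assert np.mean(np.abs(off)) < 0.15

    def test_positive_target_sign_is_stable_over_seeds(self):
        signs = pd.DataFrame({"P": {"met": 1}})
        hits = 0
        for seed in range(40):
            table, _ = gen_met_series(signs, n_months=120, seed=seed,
                                      strength=0.9)
            if table["met"].corr(table["P"]) > 0:
                hits += 1
        assert hits >= 38

    def test_infeasible_sign_matrix_rejected(self):
        # a 2x2 pattern with three + and one - cannot come from one factor
        signs = pd.DataFrame({"A": {"m1": 1, "m2": 1}, "B": {"m1": 1, "m2": -1}})
        with pytest.raises(ValueError, match="infeasible"):
            gen_met_series(signs, n_months=12, seed=0)

    def test_default_pattern_is_factorizable(self):
        table, _ = gen_met_series(n_months=12, seed=0)
        assert set(MET_SIGN_PATTERN.index).issubset(table.columns)


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(baselines={"PM10": -1.0})
    with pytest.raises(ValueError):
        SynthConfig(dust_events=[DustEvent("2022-01-01", ratio=1.5)])
    with pytest.raises(ValueError):
        SynthConfig(year=2022, dust_events=[DustEvent("2021-05-01")])
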