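import math

import numpy as np
import pandas as pd
import pytest

from aridaq.dust import (
    DustDayFlag,
    deduction_eligible,
    dust_contribution,
    dust_day_calendar,
    flag_dust_day,
    index_contribution,
    limit_multiple,
)


def _day(pm10_peak, ratio, base_pm10=80.0, base_ratio=0.6, hours=(12,)):
    """24 paired hourly values with a spike of given PM10 and fine/coarse
    ratio at the listed hours."""
    pm10 = np.full(24, base_pm10)
    pm25 = pm10 * base_ratio
    for h in hours:
        pm10[h] = pm10_peak
        pm25[h] = pm10_peak * ratio
    return pm10, pm25


class TestFlagDustDay:
    def test_summer_low_ratio_spike_is_dust(self):
        pm10, pm25 = _day(200.0, 0.25)
        flag = flag_dust_day(pm10, pm25, "2022-07-15")
        assert flag.is_dust_affected
        assert flag.max_hourly_pm10 == 200.0

    def test_winter_relaxed_ratio_threshold(self):
        # ratio 0.35 passes only under the winter (Dec-Feb) 0.40 threshold
        pm10, pm25 = _day(200.0, 0.35)
        assert flag_dust_day(pm10, pm25, "2022-01-15").is_dust_affected
        assert not flag_dust_day(pm10, pm25, "2022-07-15").is_dust_affected

    def test_high_ratio_day_is_not_dust(self):
        pm10, pm25 = _day(400.0, 0.55, base_ratio=0.55)
        assert not flag_dust_day(pm10, pm25, "2022-04-01").is_dust_affected

    def test_high_pm10_alone_is_not_enough(self):
        pm10 = np.full(24, 300.0)
        pm25 = pm10 * 0.5
        assert not flag_dust_day(pm10, pm25, "2022-04-01").is_dust_affected

    def test_no_paired_hours_is_unassessable(self):
        pm10 = np.full(24, math.nan)
        flag = flag_dust_day(pm10, pm10, "2022-04-01")
        assert not flag.assessable and not flag.is_dust_affected

    def test_zero_pm10_hours_are_skipped(self):
        pm10 = np.zeros(24)
        pm10[5] = 200.0
        pm25 = np.full(24, 10.0)
        flag = flag_dust_day(pm10, pm25, "2022-07-01")
        assert flag.is_dust_affected  # only hour 5 is assessable; ratio 0.05


class TestDeductionEligibility:
    def test_two_consecutive_hours_above_600(self):
        pm10 = np.full(24, 100.0)
        pm10[10], pm10[11] = 650.0, 700.0
        assert deduction_eligible(pm10)

    def test_single_hour_above_1000(self):
        pm10 = np.full(24, 100.0)
        pm10[3] = 1005.0
        assert deduction_eligible(pm10)

    def test_below_thresholds_not_eligible(self):
        pm10 = np.full(24, 100.0)
        pm10[5:8] = 599.0
        assert not deduction_eligible(pm10)

    def test_non_consecutive_600_hours_not_eligible(self):
        pm10 = np.full(24, 100.0)
        pm10[5], pm10[7] = 700.0, 700.0
        assert not deduction_eligible(pm10)

    def test_invariant_to_other_channels(self):
        # eligibility depends on PM10 only; the flag carries it even on a
        # day whose ratio rule did not fire
        pm10, pm25 = _day(650.0, 0.9, hours=(10, 11), base_ratio=0.9)
        flag = flag_dust_day(pm10, pm25, "2022-07-01")
        assert flag.deduction_eligible and not flag.is_dust_affected


def _year_daily(dust_value, n_dust=22, base=72.0, year=2022):
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    vals = np.full(len(idx), base)
    dust_dates = idx[30:30 + n_dust]
    vals[30:30 + n_dust] = dust_value
    flags = [
        DustDayFlag(d, True, False, "rule", dust_value, 0.2)
        for d in dust_dates
    ]
    return pd.Series(vals, index=idx), flags


class TestDustContribution:
    def test_printed_arithmetic_shape(self):
        # 343 clean days at 72 plus 22 dust days chosen so the with-dust
        # mean is 77: increment 5, rate 5/77 = 6.5%
        dust_value = (77.0 * 365 - 72.0 * 343) / 22
        series, flags = _year_daily(dust_value)
        c = dust_contribution(series, flags)
        assert c.mean_deducted == pytest.approx(72.0)
        assert c.mean_with_dust == pytest.approx(77.0)
        assert c.increment == 5.0
        assert c.rate == 6.5

    def test_no_dust_days_means_zero_contribution(self):
        series, _ = _year_daily(72.0, n_dust=0)
        c = dust_contribution(series, [])
        assert c.increment == 0.0 and c.rate == 0.0
        assert c.mean_deducted == c.mean_with_dust

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(5)
        idx = pd.date_range("2022-01-01", "2022-12-31", freq="D")
        vals = rng.uniform(40, 120, len(idx))
        dust_dates = set(rng.choice(idx, size=25, replace=False))
        vals[[d in dust_dates for d in idx]] += rng.uniform(100, 400, 25)
        series = pd.Series(vals, index=idx)
        flags = [
            DustDayFlag(d, d in dust_dates, False, None, 0.0, 0.0) for d in idx
        ]
        c = dust_contribution(series, flags)
        with_mean = vals.mean()
        ded_mean = np.mean([v for d, v in zip(idx, vals) if d not in dust_dates])
        assert c.mean_with_dust == pytest.approx(with_mean)
        assert c.mean_deducted == pytest.approx(ded_mean)
        assert c.rate_raw == pytest.approx((with_mean - ded_mean) / with_mean * 100)
        assert c.mean_deducted <= c.mean_with_dust

    def test_all_days_dust_is_an_error(self):
        idx = pd.date_range("2022-01-01", periods=10, freq="D")
        series = pd.Series(200.0, index=idx)
        flags = [DustDayFlag(d, True, False, None, 0.0, 0.0) for d in idx]
        with pytest.raises(ValueError):
            dust_contribution(series, flags)


class TestIndexContribution:
    def test_printed_arithmetic(self):
        value, rate = index_contribution(4.45, 4.40)
        assert value == 0.05 and rate == 1.1

    def test_identical_indices(self):
        assert index_contribution(4.0, 4.0) == (0.0, 0.0)

    def test_direct_arithmetic(self):
        assert index_contribution(5.0, 4.5) == (0.5, 10.0)

    def test_nonpositive_index_rejected(self):
        with pytest.raises(ValueError):
            index_contribution(0.0, 0.0)


def test_limit_multiple_of_peak_dust_day():
    assert limit_multiple(360.0, 150.0) == 2.4
    assert limit_multiple(65.0, 150.0) == 0.4


class TestCalendar:
    def test_monthly_counts_sum(self):
        monthly = {3: 1, 4: 6, 5: 6, 7: 1, 8: 1, 9: 2, 10: 4, 11: 1}
        flags = []
        for month, count in monthly.items():
            for j in range(count):
                flags.append(DustDayFlag(
                    pd.Timestamp(2022, month, j + 1), True, False, None, 0, 0
                ))
        cal = dust_day_calendar(flags)
        assert cal["total"] == 22
        assert {m: c for m, c in cal["monthly_counts"].items() if c} == monthly

    def test_empty_calendar(self):
        cal = dust_day_calendar([])
        assert cal["total"] == 0
        assert all(v == 0 for v in cal["monthly_counts"].values())

    def test_pollution_attribution_split(self):
        flags = [
            DustDayFlag(pd.Timestamp(2022, 4, d), True, False, None, 0, 0)
            for d in (1, 2, 3)
        ]
        levels = {
            pd.Timestamp(2022, 4, 1): 2,
            pd.Timestamp(2022, 4, 2): 3,
            pd.Timestamp(2022, 4, 3): 5,
        }
        cal = dust_day_calendar(flags, aqi_levels=levels)
        assert cal["caused_pollution_days"] == 2
        assert cal["benign_days"] == 1
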