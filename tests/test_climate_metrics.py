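import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ccre.climate_metrics import (
    METRICS, SCALING, ClimateConfig, annual_range, change_metric,
    collinearity_screen, compute_all_changes, compute_era_metrics,
    max_drought_duration, max_dryspell_duration, max_heatwave_duration,
    monthly_window_stat, seasonal_precip_extremes, vpd_from_t_rh, window_years,
)
from conftest import COLLECTION, make_daily


def brute_force_ehf_duration(values, n_window, w=3, pct=95.0, accl=30, min_run=3):
    """Independent EHF enumeration with explicit python loops (oracle)."""
    values = list(map(float, values))
    lead = len(values) - n_window
    win_means = []
    for j in range(n_window):
        i = lead + j
        win_means.append(sum(values[i - w + 1:i + 1]) / w)
    t95 = np.percentile(win_means, pct)
    flags = []
    for j in range(n_window):
        i = lead + j
        accl_mean = sum(values[i - w - accl + 1:i - w + 1]) / accl
        sig = win_means[j] - t95
        excess = win_means[j] - accl_mean
        ehf = sig * max(1.0, excess)
        flags.append(ehf > 0)
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best if best >= min_run else 0


class TestWindows:
    def test_five_anniversary_windows(self, flat_series):
        wins = window_years(flat_series, "2015-03-01", 5)
        assert len(wins) == 5
        assert wins[0] == (dt.date(2014, 3, 1), dt.date(2015, 2, 28))
        assert wins[4] == (dt.date(2010, 3, 1), dt.date(2011, 2, 28))
        # contiguous, non-overlapping
        for (s1, e1), (s2, e2) in zip(wins[1:], wins[:-1]):
            assert e1 + dt.timedelta(days=1) == s2

    def test_single_window_year_length(self, flat_series):
        (start, end), = window_years(flat_series, "2015-03-01", 1)
        assert (end - start).days + 1 in (365, 366)

    def test_leap_day_collection_maps_to_feb28(self):
        df = make_daily(start="2014-01-01", end="2020-02-28")
        wins = window_years(df, "2020-02-29", 5)
        # hand-built table of prior anniversaries: 2019-02-28 ... 2015-02-28
        assert wins[0] == (dt.date(2019, 2, 28), dt.date(2020, 2, 28))
        assert wins[1] == (dt.date(2018, 2, 28), dt.date(2019, 2, 27))

    def test_insufficient_span_names_ranges(self, flat_series):
        with pytest.raises(ValueError, match="covers"):
            window_years(flat_series, "2030-01-01", 5)


class TestMonthlyStats:
    def test_constant_series(self, flat_series, collection_date):
        assert monthly_window_stat(flat_series, collection_date, "tmean_c",
                                   "median") == pytest.approx(20.0)
        assert monthly_window_stat(flat_series, collection_date, "tmean_c",
                                   "cv") == pytest.approx(0.0)

    def test_cv_direct_evaluation_on_tiled_window(self):
        # oracle: sd/mean evaluated directly on the 30 constructed values
        df = make_daily()
        tile = np.tile([8.0, 10.0, 12.0], 10)
        for k in range(5):
            ann = dt.date(2015 - k, 3, 15)
            start = ann - dt.timedelta(days=30)
            mask = (df["date"] >= pd.Timestamp(start)) & (df["date"] < pd.Timestamp(ann))
            df.loc[mask, "tmean_c"] = tile
        expected = np.std(tile, ddof=1) / np.mean(tile)
        got = monthly_window_stat(df, COLLECTION, "tmean_c", "cv")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_all_dry_month_flags_cv_missing(self):
        df = make_daily(precip=0.0)
        assert monthly_window_stat(df, COLLECTION, "precip_mm",
                                   "mean") == pytest.approx(0.0)
        assert monthly_window_stat(df, COLLECTION, "precip_mm", "cv") is None

    def test_unknown_stat_and_column(self, flat_series, collection_date):
        with pytest.raises(ValueError, match="stat"):
            monthly_window_stat(flat_series, collection_date, "tmean_c", "max")
        with pytest.raises(ValueError, match="column"):
            monthly_window_stat(flat_series, collection_date, "nope", "mean")


class TestAnnualRange:
    def test_constant_is_zero(self, flat_series, collection_date):
        assert annual_range(flat_series, collection_date, "tmean_c") == 0.0

    def test_sinusoid_range_is_2a(self):
        df = make_daily()
        doy = df["date"].dt.dayofyear.to_numpy()
        amp = 7.0
        df["tmean_c"] = 20.0 + amp * np.sin(2 * np.pi * doy / 365.25)
        got = annual_range(df, COLLECTION, "tmean_c")
        assert got == pytest.approx(2 * amp, rel=0.01)

    def test_single_spike_raises_mean_by_fifth(self, flat_series, collection_date):
        df = flat_series.copy()
        df.loc[df["date"] == "2013-07-01", "tmean_c"] = 30.0
        base = annual_range(flat_series, collection_date, "tmean_c")
        got = annual_range(df, collection_date, "tmean_c")
        assert got - base == pytest.approx(10.0 / 5.0)


class TestSeasonalExtremes:
    def test_uniform_rain_month_length_dependent(self, flat_series, collection_date):
        mx, mn = seasonal_precip_extremes(flat_series, collection_date)
        # months before March: Nov(30) Dec(31) Jan(31) Feb(28/29)
        assert mx == pytest.approx(31.0)
        assert mn == pytest.approx((28 * 4 + 29) / 5)  # Feb avg over 2010-2014... 2012 leap

    def test_rain_in_single_month(self):
        df = make_daily(precip=0.0)
        for year in range(2011, 2016):
            mask = (df["date"] >= f"{year}-01-01") & (df["date"] <= f"{year}-01-30")
            df.loc[mask, "precip_mm"] = 3.0
        mx, mn = seasonal_precip_extremes(df, COLLECTION)
        assert mx == pytest.approx(90.0)
        assert mn == pytest.approx(0.0)

    def test_monsoon_profile_by_inversion(self):
        # monthly totals {Nov: 10, Dec: 200, Jan: 150, Feb: 5} each year
        df = make_daily(precip=0.0)
        totals = {11: 10.0, 12: 200.0, 1: 150.0, 2: 5.0}
        month = df["date"].dt.month
        days_in_month = df["date"].dt.days_in_month
        for m, tot in totals.items():
            df.loc[month == m, "precip_mm"] = (tot / days_in_month[month == m])
        mx, mn = seasonal_precip_extremes(df, COLLECTION)
        assert mx == pytest.approx(200.0, abs=1e-9)
        assert mn == pytest.approx(5.0, abs=1e-9)


class TestVpd:
    def test_saturation_gives_zero(self):
        for t in (-5.0, 10.0, 25.0, 40.0):
            assert vpd_from_t_rh(t, 100.0) == pytest.approx(0.0)

    def test_hand_evaluated_tetens(self):
        # e_s(25) = 0.6108*exp(17.27*25/262.3); VPD at 50% RH
        es = 0.6108 * np.exp(17.27 * 25.0 / (25.0 + 237.3))
        assert vpd_from_t_rh(25.0, 50.0) == pytest.approx(es * 0.5, abs=1e-12)
        assert vpd_from_t_rh(25.0, 50.0) == pytest.approx(1.584, abs=2e-3)

    def test_monotone_in_temperature(self):
        temps = np.linspace(0, 45, 50)
        vals = vpd_from_t_rh(temps, 60.0)
        assert np.all(np.diff(vals) > 0)

    def test_rh_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="humidity"):
            vpd_from_t_rh(20.0, 101.0)


class TestExtremeDurations:
    def test_constant_temperature_no_heatwave(self, flat_series, collection_date):
        assert max_heatwave_duration(flat_series, collection_date) == 0

    def test_five_day_block_gives_seven(self, flat_series, collection_date):
        df = flat_series.copy()
        hot = (df["date"] >= "2013-06-01") & (df["date"] <= "2013-06-05")
        df.loc[hot, "tmean_c"] = 30.0
        assert max_heatwave_duration(df, collection_date) == 7

    def test_two_runs_returns_longer(self, flat_series, collection_date):
        df = flat_series.copy()
        r1 = (df["date"] >= "2012-06-01") & (df["date"] <= "2012-06-03")
        r2 = (df["date"] >= "2013-01-10") & (df["date"] <= "2013-01-15")
        cold = (df["date"] >= "2012-12-28") & (df["date"] <= "2013-01-03")
        df.loc[r1, "tmean_c"] = 30.0
        df.loc[r2, "tmean_c"] = 30.0
        df.loc[cold, "tmean_c"] = 10.0
        got = max_heatwave_duration(df, collection_date)
        # oracle: exhaustive enumeration over the constructed series
        start = dt.date(2010, 3, 15)
        lead = 32
        sub = df[(df["date"] >= pd.Timestamp(start - dt.timedelta(days=lead)))
                 & (df["date"] <= pd.Timestamp(dt.date(2015, 3, 14)))]
        n_window = (dt.date(2015, 3, 14) - start).days + 1
        expected = brute_force_ehf_duration(sub["tmean_c"].to_numpy(), n_window)
        assert got == expected
        assert got == 8  # 6 hot days + 2 trailing-window days

    def test_heatwave_matches_bruteforce_on_noise(self, collection_date, rng):
        df = make_daily()
        df["tmean_c"] = 20.0 + rng.normal(0, 3.0, len(df))
        got = max_heatwave_duration(df, collection_date)
        start = dt.date(2010, 3, 15)
        sub = df[(df["date"] >= pd.Timestamp(start - dt.timedelta(days=32)))
                 & (df["date"] <= pd.Timestamp(dt.date(2015, 3, 14)))]
        n_window = (dt.date(2015, 3, 14) - start).days + 1
        assert got == brute_force_ehf_duration(sub["tmean_c"].to_numpy(), n_window)

    def test_shift_invariance(self, flat_series, collection_date, rng):
        df = flat_series.copy()
        df["tmean_c"] = 20.0 + rng.normal(0, 3.0, len(df))
        base = max_heatwave_duration(df, collection_date)
        shifted = df.assign(tmean_c=df["tmean_c"] + 7.3)
        assert max_heatwave_duration(shifted, collection_date) == base

    def test_insufficient_lead_in_errors(self):
        df = make_daily(start="2010-03-10")
        with pytest.raises(ValueError, match="covers"):
            max_heatwave_duration(df, COLLECTION)

    def test_dryspell_constant_zero(self, collection_date):
        df = make_daily(vpd_kpa=1.0)
        assert max_dryspell_duration(df, collection_date) == 0

    def test_dryspell_eight_day_spike_gives_ten(self, collection_date):
        df = make_daily(vpd_kpa=1.0)
        spike = (df["date"] >= "2012-06-01") & (df["date"] <= "2012-06-08")
        df.loc[spike, "vpd_kpa"] = 3.0
        assert max_dryspell_duration(df, collection_date) == 10

    def test_dryspell_shift_invariance(self, collection_date):
        df = make_daily(vpd_kpa=1.0)
        spike = (df["date"] >= "2012-06-01") & (df["date"] <= "2012-06-08")
        df.loc[spike, "vpd_kpa"] = 3.0
        base = max_dryspell_duration(df, collection_date)
        assert max_dryspell_duration(
            df.assign(vpd_kpa=df["vpd_kpa"] + 2.5), collection_date) == base

    def test_dryspell_via_rh_when_vpd_absent(self, flat_series, collection_date):
        assert max_dryspell_duration(flat_series, collection_date) == 0

    def test_drought_uniform_rain_zero(self, flat_series, collection_date):
        assert max_drought_duration(flat_series, collection_date) == 0

    def test_drought_embedded_dry_block_bruteforce(self, flat_series, collection_date):
        df = flat_series.copy()
        dry = (df["date"] >= "2013-01-01") & (df["date"] <= "2013-04-30")
        df.loc[dry, "precip_mm"] = 0.0
        got = max_drought_duration(df, collection_date)
        # brute force: trailing 30-day totals per window day, 10th pct threshold
        start = dt.date(2010, 3, 15)
        sub = df[(df["date"] >= pd.Timestamp(start - dt.timedelta(days=29)))
                 & (df["date"] <= pd.Timestamp(dt.date(2015, 3, 14)))]
        x = sub["precip_mm"].to_list()
        totals = [sum(x[i:i + 30]) for i in range(len(x) - 29)]
        thr = np.percentile(totals, 10.0)
        best = cur = 0
        for t in totals:
            cur = cur + 1 if t < thr else 0
            best = max(best, cur)
        assert got == best > 0

    def test_drought_scale_invariance(self, flat_series, collection_date):
        df = flat_series.copy()
        dry = (df["date"] >= "2013-01-01") & (df["date"] <= "2013-04-30")
        df.loc[dry, "precip_mm"] = 0.0
        base = max_drought_duration(df, collection_date)
        assert max_drought_duration(
            df.assign(precip_mm=df["precip_mm"] * 3.7), collection_date) == base


class TestChangeMetric:
    def test_temperature_difference(self):
        delta, reason = change_metric(18.0, 19.5, "mean_temp")
        assert delta == pytest.approx(1.5) and reason == ""

    def test_precip_log_ratio(self):
        delta, _ = change_metric(50.0, 100.0, "mean_precip")
        assert delta == pytest.approx(np.log(2.0), abs=1e-12)

    def test_duration_zero_offset_identity(self):
        delta, _ = change_metric(0.0, 0.0, "max_heatwave_dur")
        assert delta == 0.0

    def test_nonpositive_log_ratio_flagged(self):
        delta, reason = change_metric(0.0, 5.0, "mean_precip")
        assert delta is None and "positive" in reason

    def test_unknown_metric(self):
        with pytest.raises(KeyError, match="unknown metric"):
            change_metric(1.0, 2.0, "windspeed")

    @pytest.mark.parametrize("metric", METRICS)
    def test_self_comparison_is_zero(self, metric):
        delta, _ = change_metric(4.2, 4.2, metric)
        assert delta == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("metric", METRICS)
    def test_antisymmetry_under_era_swap(self, metric):
        fwd, _ = change_metric(3.0, 5.0, metric)
        rev, _ = change_metric(5.0, 3.0, metric)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestAllChanges:
    def test_identical_series_all_zero(self, flat_series, collection_date, rng):
        df = flat_series.copy()
        df["tmean_c"] = 20.0 + rng.normal(0, 2.0, len(df))
        df["precip_mm"] = rng.gamma(1.0, 2.0, len(df))
        cs = compute_all_changes(df, df, collection_date, collection_date)
        for m in METRICS:
            if cs.values[m] is not None:
                assert cs.values[m] == pytest.approx(0.0, abs=1e-12), m

    def test_scaling_registry_complete(self):
        assert set(SCALING) == set(METRICS)
        assert SCALING["mean_temp"] == "difference"
        assert SCALING["temp_var"] == "difference"
        assert SCALING["vpd"] == "log_ratio"

    def test_era_metrics_invariant_to_row_order(self, flat_series, collection_date, rng):
        df = flat_series.copy()
        df["tmean_c"] = 20.0 + rng.normal(0, 2.0, len(df))
        vals1, _ = compute_era_metrics(df, collection_date)
        shuffled = df.sample(frac=1.0, random_state=1)
        vals2, _ = compute_era_metrics(shuffled, collection_date)
        for m in METRICS:
            assert vals1[m] == pytest.approx(vals2[m], abs=1e-12)


class TestCollinearityScreen:
    def test_duplicated_metric_flagged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=10)
        corr, flags = collinearity_screen(df)
        pair = flags[(flags["metric_a"] == "a") & (flags["metric_b"] == "b")]
        assert len(pair) == 1 and pair.iloc[0]["r"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        corr, _ = collinearity_screen(df)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_constant_metric_flagged_undefined(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        _, flags = collinearity_screen(df)
        assert (flags["reason"] == "undefined (constant metric)").any()

    def test_independent_metrics_rarely_flagged(self, rng):
        n_flagged = 0
        for _ in range(30):
            df = pd.DataFrame(rng.normal(size=(32, 4)), columns=list("abcd"))
            _, flags = collinearity_screen(df)
            n_flagged += len(flags)
        # |r|>=0.6 at n=32 under independence is very rare (~2e-4 per pair)
        assert n_flagged <= 2

    def test_too_few_species(self):
        with pytest.raises(ValueError, match="3 species"):
            collinearity_screen(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))
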