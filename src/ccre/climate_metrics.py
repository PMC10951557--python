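"""Per-era climate metrics from daily weather series, and their changes.

Twelve metrics are computed from the five years preceding each seed
collection date:

=====================  =========================================================
mean_temp              mean over 5 years of the median daily temperature in the
                       30 days before each collection anniversary
mean_precip            same windows, mean daily precipitation
temp_var, precip_var   same windows, coefficient of variation (sd/mean)
temp_range             mean over the 5 anniversary years of (yearly max - min)
precip_range           likewise for daily precipitation
max/min_seasonal_precip  mean over 5 years of the max/min monthly total among
                       the 4 calendar months preceding the anniversary month
vpd                    mean daily vapour-pressure deficit in the monthly windows
max_heatwave_dur       longest run (>= 3 days) of positive excess heat factor
max_dryspell_dur       the same machinery applied to daily VPD
max_drought_dur        longest run of days whose trailing 30-day precipitation
                       total falls below the window's 10th percentile
=====================  =========================================================

Historic -> modern change uses plain differences for temperature metrics
and log ratios of means for the precipitation-like metrics; duration
metrics take a +1 offset inside the log ratio so that zero durations
stay admissible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "METRICS",
    "SCALING",
    "ClimateConfig",
    "ClimateChangeSet",
    "window_years",
    "monthly_window_stat",
    "annual_range",
    "seasonal_precip_extremes",
    "vpd_from_t_rh",
    "max_heatwave_duration",
    "max_dryspell_duration",
    "max_drought_duration",
    "change_metric",
    "compute_era_metrics",
    "compute_all_changes",
    "collinearity_screen",
]

METRICS = (
    "mean_temp", "mean_precip", "temp_var", "precip_var",
    "temp_range", "precip_range", "max_seasonal_precip", "min_seasonal_precip",
    "vpd", "max_drought_dur", "max_heatwave_dur", "max_dryspell_dur",
)

# scaling registry: temperature metrics are differenced, everything
# precipitation-like (incl. VPD and the duration indices) is a log ratio
SCALING = {
    "mean_temp": "difference",
    "temp_var": "difference",
    "temp_range": "difference",
    "mean_precip": "log_ratio",
    "precip_var": "log_ratio",
    "precip_range": "log_ratio",
    "max_seasonal_precip": "log_ratio",
    "min_seasonal_precip": "log_ratio",
    "vpd": "log_ratio",
    "max_drought_dur": "log_ratio",
    "max_heatwave_dur": "log_ratio",
    "max_dryspell_dur": "log_ratio",
}

DURATION_METRICS = ("max_drought_dur", "max_heatwave_dur", "max_dryspell_dur")


@dataclass(frozen=True)
class ClimateConfig:
    """Tunable constants of the metric definitions (all defaults documented)."""

    n_years: int = 5
    month_window_days: int = 30        # "month prior" = trailing 30-day window
    season_months: int = 4             # seasonal extremes look back 4 calendar months
    ehf_window: int = 3                # trailing-mean width for the excess heat factor
    ehf_percentile: float = 95.0       # significance percentile
    ehf_accl_days: int = 30            # acclimatisation look-back
    ehf_min_run: int = 3               # minimum heatwave/dry-spell run length
    drought_agg_days: int = 30         # trailing precipitation aggregation
    drought_percentile: float = 10.0
    duration_offset: float = 1.0       # +1 inside duration log ratios


@dataclass
class ClimateChangeSet:
    """The 12 per-metric deltas for one species/site pair."""

    values: dict[str, float | None]
    scaling: dict[str, str]
    missing: dict[str, str] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series({m: self.values.get(m, np.nan) for m in METRICS}, dtype=float)


# ---------------------------------------------------------------------------
# series handling

def _as_frame(series) -> pd.DataFrame:
    df = pd.DataFrame(series).copy()
    if "date" not in df.columns:
        raise ValueError("daily series needs a 'date' column")
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    dates = df["date"].to_numpy()
    if len(df) > 1:
        steps = np.diff(dates) / np.timedelta64(1, "D")
        if np.any(steps != 1.0):
            raise ValueError("daily series must be contiguous with no duplicate dates")
    return df


def _to_date(d) -> dt.date:
    if isinstance(d, str):
        return dt.date.fromisoformat(d)
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, dt.datetime):
        return d.date()
    return d


def _anniversary(collection: dt.date, k: int) -> dt.date:
    """k years before the collection date; Feb 29 maps to Feb 28."""
    try:
        return collection.replace(year=collection.year - k)
    except ValueError:
        return collection.replace(year=collection.year - k, day=28)


def _slice(df: pd.DataFrame, start: dt.date, end: dt.date) -> pd.DataFrame:
    """Rows with start <= date <= end, erroring if the span is not covered."""
    lo, hi = df["date"].iloc[0].date(), df["date"].iloc[-1].date()
    if start < lo or end > hi:
        raise ValueError(
            f"series covers {lo}..{hi} but {start}..{end} is required"
        )
    dates = df["date"].to_numpy().astype("datetime64[D]")
    i = np.searchsorted(dates, np.datetime64(start))
    j = np.searchsorted(dates, np.datetime64(end), side="right")
    return df.iloc[i:j]


def window_years(series, collection_date, n_years: int = 5):
    """Anniversary year-windows counting back from the collection date.

    Window k (k = 1..n_years) runs from the k-th anniversary to the day
    before the (k-1)-th; windows are contiguous and non-overlapping and
    their union spans exactly n_years years.
    """
    df = _as_frame(series)
    c = _to_date(collection_date)
    windows = []
    for k in range(1, n_years + 1):
        start = _anniversary(c, k)
        end = _anniversary(c, k - 1) - dt.timedelta(days=1)
        _slice(df, start, end)  # raises if uncovered
        windows.append((start, end))
    return windows


# ---------------------------------------------------------------------------
# window statistics

_STATS = ("median", "mean", "cv")


def _window_values(df, collection, k, window_days, column):
    end = _anniversary(_to_date(collection), k)  # exclusive
    start = end - dt.timedelta(days=window_days)
    sub = _slice(df, start, end - dt.timedelta(days=1))
    return sub[column].to_numpy(dtype=float)


def monthly_window_stat(series, collection_date, variable: str, stat: str,
                        cfg: ClimateConfig = ClimateConfig()):
    """Mean over n_years of a statistic on the trailing monthly window.

    ``stat='cv'`` is sample sd / mean; a window with zero mean makes the
    metric undefined and returns ``None`` (flagged missing upstream —
    never coerced to 0 or inf).
    """
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {_STATS}")
    df = _as_frame(series)
    if variable not in df.columns:
        raise ValueError(f"series has no column {variable!r}")
    yearly = []
    for k in range(cfg.n_years):
        vals = _window_values(df, collection_date, k, cfg.month_window_days, variable)
        if stat == "median":
            yearly.append(np.median(vals))
        elif stat == "mean":
            yearly.append(np.mean(vals))
        else:
            mu = np.mean(vals)
            if mu == 0:
                return None
            yearly.append(np.std(vals, ddof=1) / mu)
    return float(np.mean(yearly))


def annual_range(series, collection_date, variable: str,
                 cfg: ClimateConfig = ClimateConfig()) -> float:
    """Mean over the anniversary years of (yearly daily max - daily min)."""
    df = _as_frame(series)
    ranges = []
    for start, end in window_years(df, collection_date, cfg.n_years):
        vals = _slice(df, start, end)[variable].to_numpy(dtype=float)
        ranges.append(vals.max() - vals.min())
    return float(np.mean(ranges))


def _month_start(year: int, month: int) -> dt.date:
    return dt.date(year, month, 1)


def _shift_month(year: int, month: int, delta: int) -> tuple[int, int]:
    m = month - 1 + delta
    return year + m // 12, m % 12 + 1


def seasonal_precip_extremes(series, collection_date,
                             cfg: ClimateConfig = ClimateConfig()):
    """(max, min) monthly precipitation total among the months of the
    season preceding each anniversary month, averaged over n_years."""
    df = _as_frame(series)
    c = _to_date(collection_date)
    maxes, mins = [], []
    for k in range(cfg.n_years):
        ann = _anniversary(c, k)
        totals = []
        for back in range(cfg.season_months, 0, -1):
            y, m = _shift_month(ann.year, ann.month, -back)
            start = _month_start(y, m)
            y2, m2 = _shift_month(y, m, 1)
            end = _month_start(y2, m2) - dt.timedelta(days=1)
            totals.append(_slice(df, start, end)["precip_mm"].sum())
        maxes.append(max(totals))
        mins.append(min(totals))
    return float(np.mean(maxes)), float(np.mean(mins))


# ---------------------------------------------------------------------------
# vapour pressure deficit

def vpd_from_t_rh(tmean, rh):
    """Vapour-pressure deficit (kPa) via the Tetens saturation curve.

    ``e_s = 0.6108 * exp(17.27 T / (T + 237.3))``; VPD = e_s (1 - RH/100).
    """
    t = np.asarray(tmean, dtype=float)
    r = np.asarray(rh, dtype=float)
    if np.any((r < 0) | (r > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    out = es * (1.0 - r / 100.0)
    return float(out) if out.ndim == 0 else out


def _vpd_column(df: pd.DataFrame) -> pd.DataFrame:
    if "vpd_kpa" in df.columns:
        return df
    if "rh_pct" not in df.columns:
        raise ValueError("series needs either a vpd_kpa or an rh_pct column")
    df = df.copy()
    df["vpd_kpa"] = vpd_from_t_rh(df["tmean_c"].to_numpy(), df["rh_pct"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# extreme-event durations

def _trailing_mean(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[w:] - c[:-w]) / w


def _longest_run(flags: np.ndarray, min_run: int) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best if best >= min_run else 0


def _ehf_duration(values: np.ndarray, n_window: int, cfg: ClimateConfig) -> int:
    """Longest run of positive excess heat factor over the final
    ``n_window`` days of ``values`` (which must carry enough lead-in)."""
    w, accl = cfg.ehf_window, cfg.ehf_accl_days
    lead = len(values) - n_window
    if lead < accl + w - 1:
        raise ValueError(
            f"need {accl + w - 1} lead-in days before the window, have {lead}"
        )
    tm = _trailing_mean(values, w)                    # tm[i] = mean of values[i..i+w-1]
    # trailing w-day means for window days: indices lead..len-1 map to tm[lead-w+1..]
    win_means = tm[lead - w + 1:]
    t95 = np.percentile(win_means, cfg.ehf_percentile)
    am = _trailing_mean(values, accl)                 # mean of values[i..i+accl-1]
    # acclimatisation for window day j (abs idx i=lead+j): days i-accl-w+1 .. i-w
    accl_means = am[np.arange(n_window) + lead - accl - w + 1]
    sig = win_means - t95
    excess = win_means - accl_means
    ehf = sig * np.maximum(1.0, excess)
    return _longest_run(ehf > 0, cfg.ehf_min_run)


def _five_year_window(df, collection_date, cfg, lead_days):
    c = _to_date(collection_date)
    start = _anniversary(c, cfg.n_years)
    end = c - dt.timedelta(days=1)
    sub = _slice(df, start - dt.timedelta(days=lead_days), end)
    n_window = (end - start).days + 1
    return sub, n_window


def max_heatwave_duration(series, collection_date,
                          cfg: ClimateConfig = ClimateConfig()) -> int:
    """Longest excess-heat-factor heatwave (days) in the 5 years prior.

    EHF(i) = [mean3(i) - T95] * max(1, mean3(i) - mean30(prior)) computed
    per day; a heatwave is a run of at least ``ehf_min_run`` consecutive
    days with EHF > 0.
    """
    df = _as_frame(series)
    lead = cfg.ehf_accl_days + cfg.ehf_window - 1
    sub, n_window = _five_year_window(df, collection_date, cfg, lead)
    return _ehf_duration(sub["tmean_c"].to_numpy(dtype=float), n_window, cfg)


def max_dryspell_duration(series, collection_date,
                          cfg: ClimateConfig = ClimateConfig()) -> int:
    """Extreme-dryness analogue of the heatwave index, driven by VPD."""
    df = _vpd_column(_as_frame(series))
    lead = cfg.ehf_accl_days + cfg.ehf_window - 1
    sub, n_window = _five_year_window(df, collection_date, cfg, lead)
    return _ehf_duration(sub["vpd_kpa"].to_numpy(dtype=float), n_window, cfg)


def max_drought_duration(series, collection_date,
                         cfg: ClimateConfig = ClimateConfig()) -> int:
    """Longest run of days whose trailing 30-day precipitation total is
    strictly below the 10th percentile of all such totals in the window.

    This index is a documented stand-in (the aggregation length and
    percentile are config keys); it is scale-equivariant in precipitation.
    """
    df = _as_frame(series)
    agg = cfg.drought_agg_days
    sub, n_window = _five_year_window(df, collection_date, cfg, agg - 1)
    if n_window < agg:
        raise ValueError("window shorter than drought aggregation length")
    x = sub["precip_mm"].to_numpy(dtype=float)
    totals = _trailing_mean(x, agg) * agg             # one per window day
    thr = np.percentile(totals, cfg.drought_percentile)
    return _longest_run(totals < thr, 1)


# ---------------------------------------------------------------------------
# per-era metric sets and changes

def compute_era_metrics(series, collection_date,
                        cfg: ClimateConfig = ClimateConfig()):
    """All 12 metrics for one era; returns (values, missing-reasons)."""
    df = _vpd_column(_as_frame(series))
    values: dict[str, float | None] = {}
    missing: dict[str, str] = {}

    values["mean_temp"] = monthly_window_stat(df, collection_date, "tmean_c", "median", cfg)
    values["mean_precip"] = monthly_window_stat(df, collection_date, "precip_mm", "mean", cfg)
    for name, col in (("temp_var", "tmean_c"), ("precip_var", "precip_mm")):
        v = monthly_window_stat(df, collection_date, col, "cv", cfg)
        values[name] = v
        if v is None:
            missing[name] = "cv undefined: window mean is 0"
    values["temp_range"] = annual_range(df, collection_date, "tmean_c", cfg)
    values["precip_range"] = annual_range(df, collection_date, "precip_mm", cfg)
    mx, mn = seasonal_precip_extremes(df, collection_date, cfg)
    values["max_seasonal_precip"] = mx
    values["min_seasonal_precip"] = mn
    values["vpd"] = monthly_window_stat(df, collection_date, "vpd_kpa", "mean", cfg)
    values["max_drought_dur"] = float(max_drought_duration(df, collection_date, cfg))
    values["max_heatwave_dur"] = float(max_heatwave_duration(df, collection_date, cfg))
    values["max_dryspell_dur"] = float(max_dryspell_duration(df, collection_date, cfg))
    return values, missing


def change_metric(historic, modern, metric_name: str,
                  cfg: ClimateConfig = ClimateConfig()):
    """Historic -> modern delta under the metric's registered scaling.

    Returns ``(delta, reason)`` where ``delta`` is ``None`` (and the
    reason set) for inadmissible inputs, e.g. a non-positive value fed to
    a log-ratio metric.
    """
    if metric_name not in SCALING:
        raise KeyError(f"unknown metric {metric_name!r}")
    if historic is None or modern is None:
        return None, "input metric missing"
    h, m = float(historic), float(modern)
    if not (np.isfinite(h) and np.isfinite(m)):
        return None, "non-finite input"
    if SCALING[metric_name] == "difference":
        return m - h, ""
    if metric_name in DURATION_METRICS:
        h += cfg.duration_offset
        m += cfg.duration_offset
    if h <= 0 or m <= 0:
        return None, f"log ratio needs positive values (historic {h}, modern {m})"
    return float(np.log(m / h)), ""


def compute_all_changes(hist_series, mod_series, hist_date, mod_date,
                        cfg: ClimateConfig = ClimateConfig()) -> ClimateChangeSet:
    """Per-era metric sets for both collections, then all 12 deltas."""
    hist_vals, hist_missing = compute_era_metrics(hist_series, hist_date, cfg)
    mod_vals, mod_missing = compute_era_metrics(mod_series, mod_date, cfg)
    values, missing = {}, {}
    for name in METRICS:
        if name in hist_missing or name in mod_missing:
            values[name] = None
            missing[name] = hist_missing.get(name) or mod_missing.get(name)
            continue
        delta, reason = change_metric(hist_vals[name], mod_vals[name], name, cfg)
        values[name] = delta
        if reason:
            missing[name] = reason
    return ClimateChangeSet(values=values, scaling=dict(SCALING), missing=missing)


def collinearity_screen(changes: pd.DataFrame, threshold: float = 0.6):
    """Pairwise-complete Pearson correlations between metric deltas
    across species, with flags at |r| >= threshold.

    Returns ``(corr, flags)``; constant metrics produce NaN correlations
    and are flagged as undefined.
    """
    if len(changes) < 3:
        raise ValueError("collinearity screen needs at least 3 species")
    corr = changes.corr(method="pearson", min_periods=3)
    flags = []
    cols = list(changes.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r):
                flags.append({"metric_a": a, "metric_b": b, "r": np.nan,
                              "reason": "undefined (constant metric)"})
            elif abs(r) >= threshold:
                flags.append({"metric_a": a, "metric_b": b, "r": float(r),
                              "reason": f"|r| >= {threshold}"})
    return corr, pd.DataFrame(flags, columns=["metric_a", "metric_b", "r", "reason"])
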