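"""From raw feeder visits to meals and the six daily feeding components.

Components per pig-day: intake (kg), duration (s), frequency (meals),
rate (g/s), night intake (proportion of daily intake in 21:00-03:59) and
circadian rhythm strength (median daily Morlet wavelet power of hourly
intake in the 23.5-24.5 h period band).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pywt

from .config import COMPONENTS, NIGHT_HOURS, CleaningRules


def clean_visits(
    visits: pd.DataFrame, rules: CleaningRules | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply configured cleaning rules to visit records.

    Records with negative values, or zero duration with positive intake, are
    fully removed; records exceeding the rate ceiling keep their timing but
    get intake and duration nulled. Returns (cleaned, removal log).
    """
    rules = rules or CleaningRules()
    v = visits.copy()
    log = {"negative": 0, "zero_duration_with_intake": 0, "rate_ceiling_nulled": 0}
    if rules.remove_negative:
        bad = (v["duration_s"] < 0) | (v["intake_kg"] < 0)
        log["negative"] = int(bad.sum())
        v = v[~bad]
    if rules.remove_zero_duration_with_intake:
        bad = (v["duration_s"] == 0) & (v["intake_kg"] > 0)
        log["zero_duration_with_intake"] = int(bad.sum())
        v = v[~bad]
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 1000.0 * v["intake_kg"] / v["duration_s"]
    over = rate > rules.rate_ceiling_g_s
    log["rate_ceiling_nulled"] = int(over.sum())
    v = v.copy()
    v.loc[over, ["intake_kg", "duration_s"]] = np.nan
    return v.reset_index(drop=True), log


def aggregate_meals(visits: pd.DataFrame, criterion_s: float) -> pd.DataFrame:
    """Merge consecutive visits of a pig into meals.

    Visits whose gap (next start minus previous end) is shorter than the
    meal criterion belong to the same meal; merging is transitive. Meal
    intake and duration are the sums over merged visits.
    """
    v = visits.copy()
    if not v.groupby("pig_id")["start"].apply(lambda s: s.is_monotonic_increasing).all():
        warnings.warn("visits not sorted by start; sorting internally", stacklevel=2)
    v = v.sort_values(["pig_id", "start"], kind="mergesort")
    end = v["start"] + pd.to_timedelta(v["duration_s"].fillna(0.0), unit="s")
    prev_end = end.groupby(v["pig_id"]).shift()
    gap = (v["start"] - prev_end).dt.total_seconds()
    new_meal = gap.isna() | (gap >= criterion_s)
    v["_meal"] = new_meal.cumsum()
    meals = (
        v.groupby(["pig_id", "_meal"], sort=True)
        .agg(
            pen_id=("pen_id", "first"),
            round_id=("round_id", "first"),
            start=("start", "first"),
            duration_s=("duration_s", "sum"),
            intake_kg=("intake_kg", "sum"),
            n_visits=("start", "size"),
        )
        .reset_index()
        .drop(columns="_meal")
    )
    meals["date"] = meals["start"].dt.normalize()
    return meals


def daily_components(
    meals: pd.DataFrame, coverage: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per pig-day intake, duration, frequency and rate.

    ``coverage`` (columns pig_id, date) lists the pig-days on which the
    feeder was recording: covered days without meals become true zeros,
    days outside the coverage are absent (missing). By default coverage is
    the full span of each pig's round.
    """
    daily = (
        meals.groupby(["pig_id", "date"])
        .agg(
            pen_id=("pen_id", "first"),
            round_id=("round_id", "first"),
            intake=("intake_kg", "sum"),
            duration=("duration_s", "sum"),
            frequency=("intake_kg", "size"),
        )
        .reset_index()
    )
    if coverage is None:
        coverage = _full_coverage(meals)
    meta = meals.groupby("pig_id").agg(pen_id=("pen_id", "first"), round_id=("round_id", "first"))
    grid = coverage[["pig_id", "date"]].drop_duplicates()
    daily = grid.merge(daily.drop(columns=["pen_id", "round_id"]), on=["pig_id", "date"], how="left")
    daily = daily.merge(meta, on="pig_id", how="left")
    daily[["intake", "duration"]] = daily[["intake", "duration"]].fillna(0.0)
    daily["frequency"] = daily["frequency"].fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        daily["rate"] = np.where(
            daily["duration"] > 0, 1000.0 * daily["intake"] / daily["duration"], np.nan
        )
    if ((daily["duration"] == 0) & (daily["intake"] > 0)).any():
        warnings.warn("pig-days with intake but zero duration: rate set missing", stacklevel=2)
    return daily.sort_values(["pig_id", "date"]).reset_index(drop=True)


def _full_coverage(meals: pd.DataFrame) -> pd.DataFrame:
    spans = meals.groupby("pig_id")["date"].agg(["min", "max"]).reset_index()
    rows = []
    for _, r in spans.iterrows():
        for d in pd.date_range(r["min"], r["max"], freq="D"):
            rows.append({"pig_id": r["pig_id"], "date": d})
    return pd.DataFrame(rows)


def hourly_intake(meals: pd.DataFrame, coverage: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sum of meal intakes within each clock hour per pig (regular hourly grid).

    A meal's intake is assigned to the hour of its start. Hours of pig-days
    outside the coverage are NaN (missing); covered hours without meals are 0.
    """
    m = meals.copy()
    m["hour"] = m["start"].dt.hour
    m["date"] = m["start"].dt.normalize()
    agg = m.groupby(["pig_id", "date", "hour"])["intake_kg"].sum()
    if coverage is None:
        coverage = _full_coverage(meals)
    rows = []
    for _, r in coverage[["pig_id", "date"]].drop_duplicates().iterrows():
        for h in range(24):
            rows.append((r["pig_id"], r["date"], h))
    grid = pd.DataFrame(rows, columns=["pig_id", "date", "hour"])
    out = grid.merge(agg.rename("intake_kg"), on=["pig_id", "date", "hour"], how="left")
    out["intake_kg"] = out["intake_kg"].fillna(0.0)
    return out.sort_values(["pig_id", "date", "hour"]).reset_index(drop=True)


def night_intake(hourly: pd.DataFrame, night_hours: tuple = NIGHT_HOURS) -> pd.DataFrame:
    """Proportion of daily intake in the night hours of the calendar day.

    Missing (NaN) when the day's total intake is zero.
    """
    h = hourly.copy()
    h["night"] = h["hour"].isin(night_hours)
    g = h.groupby(["pig_id", "date"])
    total = g["intake_kg"].sum()
    night = h[h["night"]].groupby(["pig_id", "date"])["intake_kg"].sum()
    night = night.reindex(total.index, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(total > 0, night / total, np.nan)
    out = total.reset_index()[["pig_id", "date"]]
    out["night_intake"] = prop
    return out


def wavelet_preprocess(series: np.ndarray, window_h: int = 168) -> tuple[np.ndarray, np.ndarray]:
    """Prepare an hourly intake series for wavelet analysis.

    Removes the linear trend, normalises amplitude by a centred rolling
    standard deviation (default window one week), and substitutes missing
    hours with 0 after recording their positions.

    Returns (processed series, missing mask).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < window_h:
        raise ValueError(f"series of {len(x)} h shorter than window {window_h} h")
    missing = ~np.isfinite(x)
    t = np.arange(len(x))
    ok = ~missing
    if ok.sum() >= 2:
        coef = np.polyfit(t[ok], x[ok], 1)
        x = x - np.polyval(coef, t)
    elif ok.any():
        x = x - np.nanmean(x)
    s = pd.Series(np.where(missing, np.nan, x))
    roll_sd = s.rolling(window_h, center=True, min_periods=window_h // 4).std()
    roll_sd = roll_sd.bfill().ffill().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(roll_sd > 0, x / roll_sd, x)
    x = np.where(missing, 0.0, x)
    return x, missing


def circadian_strength(
    processed: np.ndarray,
    missing_days: np.ndarray | None = None,
    period_range_h: tuple[float, float] = (8.0, 48.0),
    band_h: tuple[float, float] = (23.5, 24.5),
    period_step_h: float = 0.5,
    edge_days: int = 2,
) -> np.ndarray:
    """Daily circadian rhythm strength from an hourly processed series.

    Continuous wavelet transform with a Morlet wavelet over periods 8-48 h;
    power is the squared modulus. For each day the median power over the
    day's 24 hours within the 23.5-24.5 h period band is returned. Days
    within +/- ``edge_days`` of a missing day are set missing (edge effects
    of the zero substitution).
    """
    x = np.asarray(processed, dtype=float)
    n_days = len(x) // 24
    if n_days < 5:
        raise ValueError("series must cover at least 5 days")
    if missing_days is None:
        missing_days = np.zeros(n_days, dtype=bool)
    missing_days = np.asarray(missing_days, dtype=bool)
    if missing_days.all():
        return np.full(n_days, np.nan)
    periods = np.arange(period_range_h[0], period_range_h[1] + period_step_h / 2, period_step_h)
    scales = pywt.central_frequency("morl") * periods
    coef, freqs = pywt.cwt(x[: n_days * 24], scales, "morl", sampling_period=1.0)
    power = np.abs(coef) ** 2
    got = 1.0 / freqs
    band = (got >= band_h[0]) & (got <= band_h[1])
    out = np.empty(n_days)
    for d in range(n_days):
        out[d] = np.median(power[band, d * 24 : (d + 1) * 24])
    drop = missing_days.copy()
    for d in np.flatnonzero(missing_days):
        lo, hi = max(0, d - edge_days), min(n_days, d + edge_days + 1)
        drop[lo:hi] = True
    out[drop] = np.nan
    return out


def compute_daily_components(
    visits: pd.DataFrame,
    criterion_s: float,
    rules: CleaningRules | None = None,
    coverage: pd.DataFrame | None = None,
    night_hours: tuple = NIGHT_HOURS,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full visit-to-components pipeline for one round.

    Returns (daily components table, meals, cleaning log). The daily table
    has one row per covered pig-day with the six components (NaN = missing)
    and a 1-based ``day`` index within the round.
    """
    cleaned, log = clean_visits(visits, rules)
    meals = aggregate_meals(cleaned.dropna(subset=["intake_kg", "duration_s"]), criterion_s)
    daily = daily_components(meals, coverage)
    hourly = hourly_intake(meals, coverage)
    ni = night_intake(hourly, night_hours)
    daily = daily.merge(ni, on=["pig_id", "date"], how="left")

    daily["circadian_strength"] = np.nan
    for pig, sub in hourly.groupby("pig_id"):
        sub = sub.sort_values(["date", "hour"])
        x = sub["intake_kg"].to_numpy()
        dates = sub["date"].drop_duplicates().to_numpy()
        n_days = len(dates)
        if n_days < 5 or len(x) < 24 * 5:
            continue
        window = min(168, (len(x) // 24) * 24)
        proc, _ = wavelet_preprocess(x, window_h=window)
        # a day counts as missing when it recorded no intake at all
        day_missing = x.reshape(n_days, 24).sum(axis=1) <= 0
        strength = circadian_strength(proc, day_missing)
        mask = daily["pig_id"] == pig
        cs = daily.loc[mask, "date"].map(dict(zip(dates, strength)))
        daily.loc[mask, "circadian_strength"] = cs.values

    first = daily.groupby("round_id")["date"].transform("min")
    daily["day"] = (daily["date"] - first).dt.days + 1
    for comp in COMPONENTS:
        daily[f"{comp}_missing"] = ~np.isfinite(daily[comp].astype(float))
    return daily, meals, log
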