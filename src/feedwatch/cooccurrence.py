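"""Alert description, feeding-strategy classification and sensitivities.

Sensitivity = 100 * TP / (TP + FN): the percentage of welfare-issue onset
windows that co-occur with at least one alert of the queried type. Windows
with more than a third of their days missing are excluded, and cells whose
onsets touch fewer than ten unique pigs are computed but flagged as not
reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    ALERT_TYPES,
    MIN_UNIQUE_PIGS,
    ONSET_MISSING_FRACTION,
    STRATEGY_DIMENSIONS,
    STRATEGY_PERCENTILES,
)
from .welfare import OnsetWindow

#: alert types a sensitivity cell can query (any/positive/negative x CI level)
SENSITIVITY_ALERT_TYPES = (
    "any95", "any99", "any999",
    "pos95", "pos99", "pos999",
    "neg95", "neg99", "neg999",
)


def _with_any_levels(results: pd.DataFrame) -> pd.DataFrame:
    out = results.copy()
    for level in ("99", "999"):
        out[f"any{level}"] = out[[f"pos{level}", f"neg{level}"]].any(axis=1).where(
            ~out["missing"].astype(bool), np.nan
        )
    return out


def alert_frequency_table(
    results: pd.DataFrame, month_length_d: int = 30, round_of: dict | None = None
) -> dict[str, pd.DataFrame]:
    """Percentages of pig-days with each alert type per feeding component.

    The denominator excludes missing days. Breakdowns: total, per 30-day
    month from round start, per round (if pig->round mapping given) and per
    pig (mean +/- SEM, min, max of the per-pig percentage).
    """
    res = results.copy()
    res["month"] = (res["day"] - 1) // month_length_d + 1
    if round_of is not None:
        res["round_id"] = res["pig_id"].map(round_of)
    ok = res[~res["missing"].astype(bool)].copy()
    for a in ALERT_TYPES:
        ok[a] = ok[a].astype(float)

    def pct(frame: pd.DataFrame) -> pd.Series:
        return frame[list(ALERT_TYPES)].mean() * 100

    total = ok.groupby("component").apply(pct, include_groups=False)
    total["n_days"] = ok.groupby("component").size()
    by_month = ok.groupby(["component", "month"]).apply(pct, include_groups=False)
    out = {"total": total.reset_index(), "by_month": by_month.reset_index()}
    if round_of is not None:
        out["by_round"] = (
            ok.groupby(["component", "round_id"]).apply(pct, include_groups=False).reset_index()
        )
    per_pig = ok.groupby(["component", "pig_id"]).apply(pct, include_groups=False)
    stats = per_pig.groupby("component").agg(["mean", "sem", "min", "max"])
    stats.columns = ["_".join(c) for c in stats.columns]
    out["by_pig"] = stats.reset_index()
    return out


def alert_overlap_matrix(results: pd.DataFrame, kind: str = "any95") -> pd.DataFrame:
    """Component x component daily alert overlap percentages.

    Entry (i, j) is the percentage of pig-days with a ``kind`` alert for
    component i upon which component j also had *any* type of alert
    (any95). Asymmetric; the diagonal is 100 by construction.
    """
    res = _with_any_levels(results)
    comps = sorted(res["component"].unique())
    flags = {}
    anyflag = {}
    for c in comps:
        sub = res[res["component"] == c].set_index(["pig_id", "day"])
        flags[c] = sub.index[sub[kind] == True]  # noqa: E712  (NaN-safe)
        anyflag[c] = set(sub.index[sub["any95"] == True])  # noqa: E712
    mat = pd.DataFrame(index=comps, columns=comps, dtype=float)
    for i in comps:
        days = flags[i]
        for j in comps:
            if len(days) == 0:
                mat.loc[i, j] = np.nan
            else:
                hit = sum(1 for d in days if d in anyflag[j])
                mat.loc[i, j] = 100.0 * hit / len(days)
    return mat


def classify_strategies(
    daily: pd.DataFrame,
    excluded_days: set[int] | dict | None = None,
    dimensions: tuple = STRATEGY_DIMENSIONS,
    percentiles: tuple = STRATEGY_PERCENTILES,
    min_days: int = 5,
) -> pd.DataFrame:
    """Tertile feeding-strategy categories per pig and dimension.

    Disturbance days (before the first health observation, after first
    slaughter, severe-issue days +/- 3 d — supplied via ``excluded_days``
    as day indices, optionally per pig) are dropped; values are scaled per
    farm-day (subtract the round-day mean, divide by the round-day sd over
    pigs); each pig's median scaled value is assigned per round to low
    (<= 33rd percentile), high (> 67th) or intermediate. Ties at either
    percentile go to intermediate.
    """
    rows = []
    d = daily.copy()
    if excluded_days:
        if isinstance(excluded_days, dict):
            mask = d.apply(
                lambda r: r["day"] in excluded_days.get(r["pig_id"], ()), axis=1
            )
        else:
            mask = d["day"].isin(excluded_days)
        d = d[~mask]
    for dim in dimensions:
        x = d[np.isfinite(d[dim].astype(float))].copy()
        g = x.groupby(["round_id", "day"])[dim]
        mu = g.transform("mean")
        sd = g.transform("std").replace(0.0, np.nan)
        x["scaled"] = (x[dim] - mu) / sd
        med = (
            x.groupby(["round_id", "pig_id"])
            .agg(median_scaled=("scaled", "median"), n_days=("scaled", "size"))
            .reset_index()
        )
        for rnd, sub in med.groupby("round_id"):
            assigned = sub[sub["n_days"] >= min_days].copy()
            skipped = sub[sub["n_days"] < min_days]
            if len(skipped):
                import warnings

                warnings.warn(
                    f"{len(skipped)} pigs with < {min_days} retained days left "
                    f"unassigned for {dim} in round {rnd}",
                    stacklevel=2,
                )
            lo = np.percentile(assigned["median_scaled"], percentiles[0])
            hi = np.percentile(assigned["median_scaled"], percentiles[1])
            cat = np.where(
                assigned["median_scaled"] < lo,
                "low",
                np.where(assigned["median_scaled"] > hi, "high", "intermediate"),
            )
            for pig, c, m in zip(assigned["pig_id"], cat, assigned["median_scaled"]):
                rows.append(
                    {
                        "pig_id": pig,
                        "round_id": rnd,
                        "dimension": dim,
                        "category": c,
                        "median_scaled": m,
                    }
                )
    return pd.DataFrame(rows)


def aggregate_alerts_over_onset(
    window: OnsetWindow,
    pig_results: pd.DataFrame,
    missing_fraction: float = ONSET_MISSING_FRACTION,
) -> dict | None:
    """Aggregate one component's alerts over an onset window.

    Returns None when the window is excluded (more than ``missing_fraction``
    of its days have missing alerts, strict >). Otherwise a mapping alert
    type -> present (the most extreme alert per direction is retained by
    keeping per-level presence).
    """
    res = _with_any_levels(pig_results)
    sub = res[res["day"].isin(window.days)]
    n = len(window.days)
    n_missing = n - int((~sub["missing"].astype(bool)).sum())
    if n_missing / n > missing_fraction:
        return None
    ok = sub[~sub["missing"].astype(bool)]
    return {a: bool((ok[a] == True).any()) for a in SENSITIVITY_ALERT_TYPES}  # noqa: E712


def compute_sensitivities(
    windows: list[OnsetWindow],
    results: pd.DataFrame,
    subgroups: pd.DataFrame | None = None,
    alert_types: tuple = SENSITIVITY_ALERT_TYPES,
    min_unique_pigs: int = MIN_UNIQUE_PIGS,
    missing_fraction: float = ONSET_MISSING_FRACTION,
) -> pd.DataFrame:
    """Sensitivity per (component, indicator, alert type[, subgroup]).

    TP = included onsets co-occurring with >= 1 alert of the type; FN = the
    rest; sensitivity = 100*TP/(TP+FN) (NaN when no onsets are included).
    Cells with onsets in fewer than ``min_unique_pigs`` unique pigs are
    flagged ``reported = False``. With ``subgroups`` (pig_id, dimension,
    category), sensitivities are additionally computed per strategy
    subgroup.
    """
    group_defs = [("all", "all", None)]
    if subgroups is not None:
        for (dim, cat), sub in subgroups.groupby(["dimension", "category"]):
            group_defs.append((dim, cat, set(sub["pig_id"])))

    rows = []
    by_comp = dict(tuple(results.groupby("component")))
    for comp, comp_res in by_comp.items():
        by_pig = dict(tuple(comp_res.groupby("pig_id")))
        indicators = sorted({w.indicator for w in windows})
        for ind in indicators:
            wins = [w for w in windows if w.indicator == ind]
            agg = []
            for w in wins:
                pig_res = by_pig.get(w.pig_id)
                if pig_res is None:
                    agg.append((w, None))
                    continue
                agg.append((w, aggregate_alerts_over_onset(w, pig_res, missing_fraction)))
            for dim, cat, pigs in group_defs:
                sel = [
                    (w, a) for w, a in agg if pigs is None or w.pig_id in pigs
                ]
                included = [(w, a) for w, a in sel if a is not None]
                unique_pigs = len({w.pig_id for w, _ in included})
                for atype in alert_types:
                    tp = sum(1 for _, a in included if a[atype])
                    fn = len(included) - tp
                    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else np.nan
                    rows.append(
                        {
                            "component": comp,
                            "indicator": ind,
                            "alert_type": atype,
                            "dimension": dim,
                            "subgroup": cat,
                            "tp": tp,
                            "fn": fn,
                            "n_onsets_included": len(included),
                            "n_onsets_excluded": len(sel) - len(included),
                            "n_unique_pigs": unique_pigs,
                            "sensitivity_pct": sens,
                            "reported": unique_pigs >= min_unique_pigs,
                        }
                    )
    return pd.DataFrame(rows)


def chance_sensitivity(alert_rate: float, window_length_d: int) -> float:
    """Expected sensitivity (%) under independence of alerts and onsets.

    With a daily alert probability p and onset windows of k days, the
    chance of at least one alert in a window is 1 - (1-p)^k; e.g.
    100 * (1 - (1 - 0.087)^3) ~= 23.9 for p = 8.7% and 3-day windows.
    """
    if not 0 <= alert_rate <= 1:
        raise ValueError("alert_rate must be a proportion in [0, 1]")
    if window_length_d < 1:
        raise ValueError("window_length_d must be >= 1")
    return 100.0 * (1.0 - (1.0 - alert_rate) ** window_length_d)


def shift_alert_calendars(
    results: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Circularly shift each pig's alert calendar by a random offset.

    Used as a permutation null: shifting breaks any alignment between
    alerts and onsets while preserving each pig's alert frequency and
    run-length structure.
    """
    out = []
    for (pig, comp), sub in results.groupby(["pig_id", "component"]):
        sub = sub.sort_values("day").copy()
        k = int(rng.integers(0, len(sub)))
        cols = list(ALERT_TYPES) + ["missing", "y_obs", "innovation"]
        cols = [c for c in cols if c in sub.columns]
        sub[cols] = np.roll(sub[cols].to_numpy(), k, axis=0)
        out.append(sub)
    return pd.concat(out, ignore_index=True)
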