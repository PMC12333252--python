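"""Welfare issue-days, heat stress and onset windows.

Twice-weekly discrete health scores are binarised per indicator, pen cough
counts become pen-wide coughing days, and climate records yield heat-stress
days via the temperature-humidity index (THI) confirmed by panting. Onset
windows are derived with the three-step procedure: interpolate across
non-observation days, keep switches from no-issue to issue, and extend each
onset back through the unobserved days since the previous observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    CLIMATE_AT_MIN,
    CLIMATE_RH_MAX,
    CLIMATE_RH_MIN,
    COUGH_THRESHOLD,
    PANTING_THRESHOLD,
    THI_THRESHOLD,
)

ISSUE, NO_ISSUE, MISSING = 1, 0, -1


@dataclass
class OnsetWindow:
    """Consecutive days (1-4; 1 for heat stress) marking one issue onset."""

    pig_id: str
    indicator: str
    days: tuple
    excluded: bool = False
    reason: str = ""

    @property
    def first_day(self) -> int:
        return self.days[0]

    @property
    def last_day(self) -> int:
        return self.days[-1]


def clean_climate(
    records: pd.DataFrame,
    at_min: float = CLIMATE_AT_MIN,
    rh_min: float = CLIMATE_RH_MIN,
    rh_max: float = CLIMATE_RH_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove unreasonable sensor values (AT below 16 degC; RH outside 40-90%).

    Removal is per measurement: an out-of-range AT nulls at_c only, an
    out-of-range RH nulls rh_pct only. Returns (cleaned, per-sensor log).
    """
    rec = records.copy()
    bad_at = rec["at_c"] < at_min
    bad_rh = (rec["rh_pct"] < rh_min) | (rec["rh_pct"] > rh_max)
    log = (
        pd.DataFrame(
            {"room_id": rec["room_id"], "at_removed": bad_at, "rh_removed": bad_rh}
        )
        .groupby("room_id")
        .sum()
        .reset_index()
    )
    rec.loc[bad_at, "at_c"] = np.nan
    rec.loc[bad_rh, "rh_pct"] = np.nan
    return rec, log


def compute_thi(at, rh):
    """Temperature-humidity index from ambient temperature (degC) and RH (%).

    THI = (1.8*AT + 32) - (0.55 - 0.0055*RH) * (1.8*AT - 26)
    """
    at = np.asarray(at, dtype=float)
    rh = np.asarray(rh, dtype=float)
    return (1.8 * at + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * at - 26.0)


def heat_risk_days(climate: pd.DataFrame, threshold: float = THI_THRESHOLD) -> pd.DataFrame:
    """Daily heat-stress-risk flags per round.

    The 15-min THI values are aggregated to daily medians per room, then to
    the round level as the median across rooms; a day is at risk iff the
    round-level median exceeds the threshold (strict >).
    """
    c = climate.dropna(subset=["at_c", "rh_pct"]).copy()
    c["thi"] = compute_thi(c["at_c"], c["rh_pct"])
    room_daily = c.groupby(["round_id", "day", "room_id"])["thi"].median()
    round_daily = room_daily.groupby(["round_id", "day"]).median().rename("thi_median")
    out = round_daily.reset_index()
    out["risk"] = out["thi_median"] > threshold
    return out


def heat_stress_days(
    risk: pd.DataFrame,
    panting: pd.DataFrame,
    obs_days: list[int],
    panting_threshold: float = PANTING_THRESHOLD,
) -> pd.DataFrame:
    """Confirm risk days as heat-stress days using panting proportions.

    A risk day that is an observation day is a heat-stress day iff the
    panting proportion reaches the threshold (>=) that day. For risk days
    without an observation, the threshold counts as exceeded if it was
    exceeded on the nearest preceding or following observation day.
    """
    obs = sorted(obs_days)
    pant = panting.set_index(["round_id", "day"])["prop_panting"]
    rows = []
    for _, r in risk.iterrows():
        day, rnd = int(r["day"]), r["round_id"]
        stress = False
        if r["risk"]:
            if day in obs:
                stress = pant.get((rnd, day), 0.0) >= panting_threshold
            else:
                prev = max((d for d in obs if d < day), default=None)
                nxt = min((d for d in obs if d > day), default=None)
                for d in (prev, nxt):
                    if d is not None and pant.get((rnd, d), 0.0) >= panting_threshold:
                        stress = True
        rows.append({"round_id": rnd, "day": day, "heat_stress": stress})
    return pd.DataFrame(rows)


def binarize_scores(
    health: pd.DataFrame, thresholds: dict, excluded_indicators: set | None = None
) -> pd.DataFrame:
    """Convert discrete health scores to binary issue/no-issue per pig-day.

    A score at or above the indicator's threshold is an issue-day. Indicators
    listed in ``excluded_indicators`` are dropped; every other indicator must
    have a threshold.
    """
    excluded_indicators = excluded_indicators or set()
    h = health[~health["indicator"].isin(excluded_indicators)].copy()
    missing = set(h["indicator"].unique()) - set(thresholds)
    if missing:
        raise KeyError(f"no binary threshold configured for indicators: {sorted(missing)}")
    thr = h["indicator"].map(thresholds)
    h["issue"] = (h["score"] >= thr).astype(int)
    return h[["pig_id", "pen_id", "round_id", "day", "indicator", "issue"]]


def pen_coughing_days(
    coughs: pd.DataFrame, roster: pd.DataFrame, threshold: int = COUGH_THRESHOLD
) -> pd.DataFrame:
    """Pen-level cough counts to per-pig coughing issue-days.

    A count strictly above the threshold marks a coughing issue-day for
    every pig of the pen on that observation day.
    """
    c = coughs.copy()
    c["issue"] = (c["count"] > threshold).astype(int)
    out = c.merge(roster[["pig_id", "pen_id", "round_id"]], on=["pen_id", "round_id"])
    out["indicator"] = "coughing"
    return out[["pig_id", "pen_id", "round_id", "day", "indicator", "issue"]]


def interpolate_issue_days(
    obs_days: list[int], states: list[int], n_days: int
) -> np.ndarray:
    """Step one: interpolate issue states across non-observation days.

    Non-observation days become issue-days iff both neighbouring observation
    days are issue-days, and no-issue-days if at least one neighbour is a
    no-issue-day or missing (series edges count as missing neighbours).

    Returns an array of length ``n_days`` (index 0 = day 1) with values
    ISSUE / NO_ISSUE.
    """
    obs = np.asarray(obs_days, dtype=int)
    st = np.asarray(states, dtype=int)
    order = np.argsort(obs)
    obs, st = obs[order], st[order]
    out = np.full(n_days, NO_ISSUE, dtype=int)
    out[obs - 1] = st
    for d in range(1, n_days + 1):
        if d in obs:
            continue
        before = obs[obs < d]
        after = obs[obs > d]
        if len(before) and len(after):
            s_prev = st[np.searchsorted(obs, before[-1])]
            s_next = st[np.searchsorted(obs, after[0])]
            if s_prev == ISSUE and s_next == ISSUE:
                out[d - 1] = ISSUE
    return out


def onset_switch_days(obs_days: list[int], states: list[int]) -> list[int]:
    """Step two: observation days whose score switched from no-issue to issue.

    An issue on the first observation day is not an onset (no preceding
    no-issue observation).
    """
    obs = sorted(zip(obs_days, states))
    onsets = []
    for (d_prev, s_prev), (d, s) in zip(obs, obs[1:]):
        if s == ISSUE and s_prev == NO_ISSUE:
            onsets.append(d)
    return onsets


def back_extend(onset_day: int, obs_days: list[int]) -> tuple:
    """Step three: extend an onset back through the unobserved days.

    All days strictly after the previous observation day (by definition a
    no-issue-day) up to and including the onset day form the window.
    """
    prev = max((d for d in obs_days if d < onset_day), default=None)
    first = onset_day if prev is None else prev + 1
    return tuple(range(first, onset_day + 1))


def identify_onsets(binary: pd.DataFrame, n_days: int) -> list[OnsetWindow]:
    """Three-step onset identification for every pig and indicator."""
    windows: list[OnsetWindow] = []
    for (pig, ind), sub in binary.groupby(["pig_id", "indicator"], sort=True):
        sub = sub.sort_values("day")
        obs_days = sub["day"].astype(int).tolist()
        states = sub["issue"].astype(int).tolist()
        if len(obs_days) < 2:
            continue
        for onset_day in onset_switch_days(obs_days, states):
            windows.append(OnsetWindow(pig, ind, back_extend(onset_day, obs_days)))
    return windows


def heat_onsets(stress: pd.DataFrame, pig_ids: list[str]) -> list[OnsetWindow]:
    """Length-1 onset windows: heat-stress days following a no-stress day.

    Heat stress affects the whole farm, so each onset is replicated for
    every pig present in the round.
    """
    windows = []
    for rnd, sub in stress.groupby("round_id"):
        sub = sub.sort_values("day")
        flags = sub.set_index("day")["heat_stress"]
        for day in flags.index:
            if not flags[day]:
                continue
            if (day - 1) not in flags.index or flags[day - 1]:
                continue
            for pig in pig_ids:
                if pig.startswith(f"R{rnd}P"):
                    windows.append(OnsetWindow(pig, "heat_stress", (int(day),)))
    return windows


def any_issue(windows: list[OnsetWindow]) -> list[OnsetWindow]:
    """Union of onset days across indicators, re-derived as any-issue windows."""
    days_by_pig: dict[str, set[int]] = {}
    for w in windows:
        days_by_pig.setdefault(w.pig_id, set()).update(w.days)
    out = []
    for pig, days in sorted(days_by_pig.items()):
        run: list[int] = []
        for d in sorted(days):
            if run and d != run[-1] + 1:
                out.append(OnsetWindow(pig, "any_issue", tuple(run)))
                run = []
            run.append(d)
        if run:
            out.append(OnsetWindow(pig, "any_issue", tuple(run)))
    return out


def windows_to_frame(windows: list[OnsetWindow]) -> pd.DataFrame:
    """Tabulate onset windows (one row per window) for CSV export."""
    return pd.DataFrame(
        [
            {
                "pig_id": w.pig_id,
                "indicator": w.indicator,
                "first_day": w.first_day,
                "last_day": w.last_day,
                "excluded": w.excluded,
                "reason": w.reason,
            }
            for w in windows
        ]
    )
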