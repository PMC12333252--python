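"""Synthetic herd generator.

Emulates the data streams of a growing-finishing pig farm with electronic
single-space feeders: per-visit feeder records, twice-weekly discrete health
scoring, 15-min room climate records and daily farm-level panting
proportions. Pigs carry individual feeding strategies (nibbling/meal eating,
fast/slow eating, day/day-night eating, consistent/inconsistent eating) and
welfare episodes with controllable deviation signatures can be injected into
the feeding data, with the ground truth emitted alongside.

The generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import COMPONENTS

#: calendar anchor of round 1, a Monday, so that day 1 has weekday 0
ROUND1_START = pd.Timestamp("2022-01-03")
#: days between consecutive round starts
ROUND_SPACING_D = 120

CATEGORIES = ("low", "intermediate", "high")

#: target feeder visits per day by frequency-strategy category
VISITS_PER_DAY = {"low": 5.0, "intermediate": 9.0, "high": 14.0}
#: multiplier on daily feeding duration by rate-strategy category
#: (fast eaters = high rate = shorter duration)
DURATION_MULT = {"low": 1.25, "intermediate": 1.0, "high": 0.8}
#: per-pig-day phase jitter (h) by circadian-consistency category
PHASE_JITTER_H = {"low": 2.5, "intermediate": 1.2, "high": 0.4}


@dataclass
class HerdConfig:
    """Layout and statistical structure of the synthetic herd.

    Defaults mirror a conventional growing-finishing farm round: 110 pigs in
    10 single-sex pens of 11 (one feeder per pen), followed for ~92 days,
    with health observations twice a week (Monday/Thursday).
    """

    n_rounds: int = 1
    pens_per_round: int = 10
    pigs_per_pen: int = 11
    days_per_round: int = 92
    observation_weekdays: tuple[int, int] = (0, 3)
    seed: int = 0
    #: proportions of low/intermediate/high per strategy dimension
    strategy_mix: dict = field(
        default_factory=lambda: {
            d: (1 / 3, 1 / 3, 1 / 3)
            for d in ("frequency", "rate", "night_intake", "circadian_strength")
        }
    )
    #: relative day-to-day sd per component (frequency is Poisson-like)
    noise_sd: dict = field(
        default_factory=lambda: {
            "intake": 0.10,
            "duration": 0.12,
            "frequency": 0.15,
            "rate": 0.10,
            "night_intake": 0.50,
            "circadian_strength": 1.0,
        }
    )
    #: intake grows linearly (kg/d at round start and end)
    intake_start_kg: float = 1.2
    intake_end_kg: float = 2.6
    #: daily feeding duration rises then falls (s)
    duration_start_s: float = 3600.0
    duration_peak_s: float = 4800.0
    duration_end_s: float = 3900.0
    duration_peak_frac: float = 0.35
    #: proportion of daily intake taken at night per night-eating category
    night_shares: dict = field(
        default_factory=lambda: {"low": 0.02, "intermediate": 0.08, "high": 0.18}
    )
    #: diurnal peaks (h) — config parameters, not claims about real farms
    morning_peak_h: float = 7.0
    afternoon_peak_h: float = 15.5
    rooms_per_round: int = 5

    def __post_init__(self) -> None:
        for name in ("n_rounds", "pens_per_round", "pigs_per_pen", "days_per_round"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for dim, mix in self.strategy_mix.items():
            if len(mix) != 3 or abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError(f"strategy_mix[{dim}] must be 3 proportions summing to 1")
        if not 0 < self.duration_peak_frac < 1:
            raise ValueError("duration_peak_frac must be in (0, 1)")


@dataclass
class EpisodeSpec:
    """One injectable welfare episode with a controllable deviation signature."""

    indicator: str
    pig_ids: tuple
    onset_day: int
    duration_d: int
    affected_components: tuple = ("intake",)
    deviation_magnitude: float = 4.0
    deviation_direction: str = "negative"  # or "positive"
    deviation_shape: str = "sudden"  # or "gradual"
    persistence: str = "sustained"  # or "onset-only"

    def __post_init__(self) -> None:
        if self.deviation_magnitude < 0:
            raise ValueError("deviation_magnitude must be >= 0")
        if self.deviation_direction not in ("positive", "negative"):
            raise ValueError("deviation_direction must be positive or negative")
        if self.deviation_shape not in ("sudden", "gradual"):
            raise ValueError("deviation_shape must be sudden or gradual")
        if self.persistence not in ("onset-only", "sustained"):
            raise ValueError("persistence must be onset-only or sustained")
        unknown = set(self.affected_components) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {unknown}")


def round_start(round_id: int) -> pd.Timestamp:
    return ROUND1_START + pd.Timedelta(days=(round_id - 1) * ROUND_SPACING_D)


def observation_days(config: HerdConfig) -> list[int]:
    """Day indices (1-based) that are health-observation days."""
    return [
        d
        for d in range(1, config.days_per_round + 1)
        if (d - 1) % 7 in config.observation_weekdays
    ]


def assign_strategies(config: HerdConfig) -> pd.DataFrame:
    """Draw each pig's category on the four strategy dimensions.

    Returns one row per pig with columns pig_id, pen_id, round_id and the
    four dimension categories. Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for r in range(1, config.n_rounds + 1):
        for p in range(1, config.pens_per_round + 1):
            for i in range(1, config.pigs_per_pen + 1):
                pig = f"R{r}P{p:02d}-{i:02d}"
                row = {"pig_id": pig, "pen_id": f"R{r}P{p:02d}", "round_id": r}
                for dim, mix in config.strategy_mix.items():
                    row[dim] = rng.choice(CATEGORIES, p=mix)
                rows.append(row)
    return pd.DataFrame(rows)


def _lognorm_factor(rng: np.random.Generator, sd: float, size=None) -> np.ndarray:
    """Mean-one multiplicative lognormal noise; exactly 1 when sd = 0."""
    if sd == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(0.0, sd, size=size) - sd**2 / 2)


def _intake_curve(config: HerdConfig, day: int) -> float:
    f = (day - 1) / max(config.days_per_round - 1, 1)
    return config.intake_start_kg + f * (config.intake_end_kg - config.intake_start_kg)


def _duration_curve(config: HerdConfig, day: int) -> float:
    # quadratic through (0, start), (peak_frac, peak), (1, end)
    f = (day - 1) / max(config.days_per_round - 1, 1)
    p = config.duration_peak_frac
    s, m, e = config.duration_start_s, config.duration_peak_s, config.duration_end_s
    # Lagrange interpolation on the three anchors
    return (
        s * (f - p) * (f - 1) / ((0 - p) * (0 - 1))
        + m * (f - 0) * (f - 1) / ((p - 0) * (p - 1))
        + e * (f - 0) * (f - p) / ((1 - 0) * (1 - p))
    )


def _day_visit_hours(
    rng: np.random.Generator, n: int, config: HerdConfig, phase: float
) -> np.ndarray:
    """Bimodal daytime start hours, clipped outside the 21:00-03:59 trough."""
    morning = rng.random(n) < 0.45
    mu = np.where(morning, config.morning_peak_h, config.afternoon_peak_h) + phase
    sd = np.where(morning, 1.8, 2.2)
    hours = rng.normal(mu, sd)
    return np.clip(hours, 4.25, 19.5)


def _night_visit_hours(rng: np.random.Generator, n: int) -> np.ndarray:
    """Start hours uniform over the night window of the same calendar day."""
    h = rng.uniform(21.0, 28.0, n)
    return np.where(h >= 24.0, h - 24.0, h)


def generate_visits(
    config: HerdConfig, strategies: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Generate feeder-visit records for the whole herd.

    Visits of pigs sharing a pen never overlap in time (one single-space
    feeder per pen): visits are queued on the pen's shared timeline.
    """
    if strategies is None:
        strategies = assign_strategies(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sd_int = config.noise_sd["intake"]
    sd_dur = config.noise_sd["duration"]

    recs: list[dict] = []
    for (_, pig) in strategies.iterrows():
        r = int(pig["round_id"])
        start0 = round_start(r)
        v_target0 = VISITS_PER_DAY[pig["frequency"]]
        dur_mult = DURATION_MULT[pig["rate"]]
        night_share = config.night_shares[pig["night_intake"]]
        jitter = PHASE_JITTER_H[pig["circadian_strength"]]
        # stable per-pig individual offsets
        pig_int_mult = _lognorm_factor(rng, 0.05 if sd_int else 0.0)
        pig_dur_mult = _lognorm_factor(rng, 0.05 if sd_dur else 0.0)
        for day in range(1, config.days_per_round + 1):
            f = (day - 1) / max(config.days_per_round - 1, 1)
            intake_t = _intake_curve(config, day) * pig_int_mult * _lognorm_factor(rng, sd_int)
            dur_t = (
                _duration_curve(config, day)
                * dur_mult
                * pig_dur_mult
                * _lognorm_factor(rng, sd_dur)
            )
            v_target = v_target0 * (1 - 0.2 * f)
            n = max(1, int(rng.poisson(v_target)))
            n_night = int(rng.binomial(n, night_share))
            phase = rng.normal(0.0, jitter)
            hours = np.concatenate(
                [
                    _day_visit_hours(rng, n - n_night, config, phase),
                    _night_visit_hours(rng, n_night),
                ]
            )
            share = rng.dirichlet(np.full(n, 5.0))
            dshare = rng.dirichlet(np.full(n, 8.0))
            base = start0 + pd.Timedelta(days=day - 1)
            for h, si, sd_ in zip(hours, share, dshare):
                recs.append(
                    {
                        "pig_id": pig["pig_id"],
                        "pen_id": pig["pen_id"],
                        "round_id": r,
                        "day": day,
                        "start": base + pd.Timedelta(seconds=round(h * 3600)),
                        "duration_s": max(10.0, sd_ * dur_t),
                        "intake_kg": si * intake_t,
                    }
                )
    visits = pd.DataFrame(recs)
    return _queue_pen_visits(visits)


def _queue_pen_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Shift visit starts so visits within a pen never overlap."""
    visits = visits.sort_values(["pen_id", "start"], kind="mergesort").reset_index(drop=True)
    out_start = visits["start"].copy()
    for _, idx in visits.groupby("pen_id").groups.items():
        prev_end = None
        for i in idx:
            s = visits.at[i, "start"]
            if prev_end is not None and s < prev_end:
                s = prev_end
            out_start.at[i] = s
            # ceil to whole ns so queued visits can never overlap after
            # float-to-timestamp rounding
            dur_ns = int(np.ceil(float(visits.at[i, "duration_s"]) * 1e9))
            prev_end = s + pd.Timedelta(dur_ns, unit="ns")
    visits["start"] = out_start
    return visits.sort_values(["pig_id", "start"], kind="mergesort").reset_index(drop=True)


def _episode_day_factor(ep: EpisodeSpec, day: int) -> float:
    """Fraction of the full deviation applied on one episode day (0 outside)."""
    if not ep.onset_day <= day < ep.onset_day + ep.duration_d:
        return 0.0
    k = day - ep.onset_day  # 0-based day within episode
    if ep.persistence == "onset-only" and k >= 2:
        return 0.0
    if ep.deviation_shape == "gradual":
        return (k + 1) / ep.duration_d
    return 1.0


def inject_episodes(
    visits: pd.DataFrame,
    episodes: list[EpisodeSpec],
    config: HerdConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shift feeding behaviour during episodes; return (visits, ground truth).

    The deviation of each affected component is ``magnitude x noise_sd`` of
    that component (relative units), applied as a step (sudden) or linear
    ramp (gradual), over the whole episode (sustained) or its first two days
    (onset-only).
    """
    known = set(visits["pig_id"].unique())
    for ep in episodes:
        missing = set(ep.pig_ids) - known
        if missing:
            raise KeyError(f"unknown pig ids in episode: {sorted(missing)}")
    visits = visits.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sign = {"positive": 1.0, "negative": -1.0}
    truth = []
    for ep in episodes:
        for pig in ep.pig_ids:
            for day in range(ep.onset_day, ep.onset_day + ep.duration_d):
                f = _episode_day_factor(ep, day)
                if f == 0.0:
                    continue
                mask = (visits["pig_id"] == pig) & (visits["day"] == day)
                idx = visits.index[mask]
                if len(idx) == 0:
                    continue
                for comp in ep.affected_components:
                    delta = sign[ep.deviation_direction] * ep.deviation_magnitude
                    delta *= config.noise_sd[comp] * f
                    extra = _apply_component_shift(visits, idx, comp, delta, rng, config)
                    if extra is not None:
                        visits = pd.concat([visits, extra], ignore_index=True)
        truth.append(
            {
                "indicator": ep.indicator,
                "pig_ids": ";".join(ep.pig_ids),
                "onset_day": ep.onset_day,
                "duration_d": ep.duration_d,
                "components": ";".join(ep.affected_components),
                "magnitude": ep.deviation_magnitude,
                "direction": ep.deviation_direction,
                "shape": ep.deviation_shape,
                "persistence": ep.persistence,
            }
        )
    return visits, pd.DataFrame(truth)


def _apply_component_shift(visits, idx, comp, delta, rng, config) -> pd.DataFrame | None:
    if comp == "intake":
        visits.loc[idx, "intake_kg"] *= max(0.02, 1 + delta)
    elif comp == "duration":
        visits.loc[idx, "duration_s"] *= max(0.02, 1 + delta)
    elif comp == "rate":
        # rate = intake/duration: shift by scaling duration inversely
        visits.loc[idx, "duration_s"] /= max(0.02, 1 + delta)
    elif comp == "frequency":
        n = len(idx)
        k = min(n - 1, int(round(abs(delta) * n)))
        if k <= 0:
            return None
        chosen = rng.choice(idx, size=k, replace=False)
        if delta < 0:
            visits.drop(index=chosen, inplace=True, errors="ignore")
        else:
            # split visits in two halves separated by a gap longer than any
            # meal criterion, so meal frequency genuinely increases
            extra = visits.loc[chosen].copy()
            visits.loc[chosen, "intake_kg"] /= 2
            visits.loc[chosen, "duration_s"] /= 2
            extra["intake_kg"] /= 2
            extra["duration_s"] /= 2
            extra["start"] = extra["start"] + pd.to_timedelta(
                extra["duration_s"] + 120.0, unit="s"
            )
            return extra
    elif comp == "night_intake":
        base = visits.loc[idx, "start"].dt.normalize()
        hours = visits.loc[idx, "start"].dt.hour
        is_night = hours.isin([21, 22, 23, 0, 1, 2, 3])
        n = len(idx)
        k = min(n, int(round(abs(delta) * n)))
        if k <= 0:
            return
        if delta > 0:
            movable = idx[~is_night.values]
        else:
            movable = idx[is_night.values]
        if len(movable) == 0:
            return None
        chosen = movable if len(movable) <= k else rng.choice(movable, k, replace=False)
        if delta > 0:
            new_h = _night_visit_hours(rng, len(chosen))
        else:
            new_h = rng.uniform(10.0, 16.0, len(chosen))
        visits.loc[chosen, "start"] = base.loc[chosen] + pd.to_timedelta(
            np.round(new_h * 3600), unit="s"
        )
        return None
    elif comp == "circadian_strength":
        # negative deviation scrambles visit timing across the day,
        # positive tightens visits onto the diurnal peaks
        frac = min(1.0, abs(delta))
        n = len(idx)
        k = int(round(frac * n))
        if k <= 0:
            return
        chosen = rng.choice(idx, size=k, replace=False)
        base = visits.loc[chosen, "start"].dt.normalize()
        if delta < 0:
            new_h = rng.uniform(0.0, 24.0, k)
        else:
            peaks = np.where(
                rng.random(k) < 0.5, config.morning_peak_h, config.afternoon_peak_h
            )
            new_h = np.clip(rng.normal(peaks, 0.3), 4.25, 19.5)
        visits.loc[chosen, "start"] = base + pd.to_timedelta(np.round(new_h * 3600), unit="s")


def generate_health_observations(
    config: HerdConfig,
    episodes: list[EpisodeSpec] | None = None,
    thresholds: dict | None = None,
    strategies: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Twice-weekly discrete health scores plus pen-level cough counts.

    Scores reach the indicator's binary threshold on observation days inside
    an episode and stay below it otherwise. Coughing is emitted as counts
    per pen and observation day (above 15 during a coughing episode).
    """
    from .config import DEFAULT_THRESHOLDS

    episodes = episodes or []
    thresholds = thresholds or DEFAULT_THRESHOLDS
    if strategies is None:
        strategies = assign_strategies(config)
    obs_days = observation_days(config)

    indicators = sorted(
        {e.indicator for e in episodes if e.indicator not in ("coughing", "heat_stress")}
        | {"lameness", "tail_damage", "flank_damage"}
    )
    in_episode: dict[tuple[str, str], set[int]] = {}
    cough_pens: dict[int, set[str]] = {}
    pen_of = dict(zip(strategies["pig_id"], strategies["pen_id"]))
    for ep in episodes:
        days = set(range(ep.onset_day, ep.onset_day + ep.duration_d))
        if ep.indicator == "coughing":
            for pig in ep.pig_ids:
                for d in days:
                    cough_pens.setdefault(d, set()).add(pen_of[pig])
            continue
        for pig in ep.pig_ids:
            key = (pig, ep.indicator)
            in_episode.setdefault(key, set()).update(days)

    rows = []
    for (_, pig) in strategies.iterrows():
        for day in obs_days:
            for ind in indicators:
                thr = thresholds.get(ind, 1)
                issue = day in in_episode.get((pig["pig_id"], ind), ())
                score = thr if issue else max(0, thr - 1)
                rows.append(
                    {
                        "pig_id": pig["pig_id"],
                        "pen_id": pig["pen_id"],
                        "round_id": pig["round_id"],
                        "day": day,
                        "indicator": ind,
                        "score": score,
                    }
                )
    health = pd.DataFrame(rows)

    cough_rows = []
    for (_, pen) in strategies[["pen_id", "round_id"]].drop_duplicates().iterrows():
        for day in obs_days:
            count = 25 if pen["pen_id"] in cough_pens.get(day, ()) else 2
            cough_rows.append(
                {
                    "pen_id": pen["pen_id"],
                    "round_id": pen["round_id"],
                    "day": day,
                    "count": count,
                }
            )
    return health, pd.DataFrame(cough_rows)


def generate_climate(
    config: HerdConfig, heatwave_days: set[int] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """15-min climate records per room and daily farm panting proportions.

    On heatwave days the ambient temperature is high enough that the daily
    median THI exceeds 79 and >= 10% of pigs pant; on other days the median
    THI stays at summer-comfort levels well below 79.
    """
    heatwave_days = heatwave_days or set()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    recs = []
    pant = []
    for r in range(1, config.n_rounds + 1):
        start0 = round_start(r)
        for day in range(1, config.days_per_round + 1):
            hot = day in heatwave_days
            base_at = 32.0 if hot else 22.0
            for room in range(1, config.rooms_per_round + 1):
                t0 = start0 + pd.Timedelta(days=day - 1)
                hours = np.arange(96) * 0.25
                diurnal = 2.0 * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
                at = base_at + diurnal + rng.normal(0, 0.3, 96) + rng.normal(0, 0.4)
                rh = np.clip(65.0 + rng.normal(0, 3.0, 96), 45.0, 85.0)
                at = np.clip(at, 16.5, None)
                for k in range(96):
                    recs.append(
                        {
                            "room_id": f"R{r}room{room}",
                            "round_id": r,
                            "day": day,
                            "datetime": t0 + pd.Timedelta(minutes=15 * k),
                            "at_c": at[k],
                            "rh_pct": rh[k],
                        }
                    )
            prop = 0.15 if hot else 0.02
            pant.append({"round_id": r, "day": day, "prop_panting": prop})
    return pd.DataFrame(recs), pd.DataFrame(pant)
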