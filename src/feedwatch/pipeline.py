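"""End-to-end orchestration: simulate -> components -> welfare -> detect -> cooccur."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .components import compute_daily_components
from .cooccurrence import (
    alert_frequency_table,
    alert_overlap_matrix,
    classify_strategies,
    compute_sensitivities,
)
from .dlm import run_dlm_table
from .synthetic import (
    EpisodeSpec,
    HerdConfig,
    assign_strategies,
    generate_climate,
    generate_health_observations,
    generate_visits,
    inject_episodes,
    observation_days,
)
from .welfare import (
    any_issue,
    binarize_scores,
    clean_climate,
    heat_onsets,
    heat_risk_days,
    heat_stress_days,
    identify_onsets,
    pen_coughing_days,
    windows_to_frame,
)

log = logging.getLogger("feedwatch")


def _config_hash(config: RunConfig, herd: HerdConfig | None) -> str:
    blob = json.dumps(
        {
            "run": dataclasses.asdict(config),
            "herd": dataclasses.asdict(herd) if herd else None,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate(
    herd: HerdConfig,
    episodes: list[EpisodeSpec] | None = None,
    heatwave_days: set[int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate all synthetic input streams plus the episode ground truth."""
    strategies = assign_strategies(herd)
    visits = generate_visits(herd, strategies)
    truth = pd.DataFrame()
    if episodes:
        visits, truth = inject_episodes(visits, episodes, herd)
    health, coughs = generate_health_observations(herd, episodes, strategies=strategies)
    climate, panting = generate_climate(herd, heatwave_days)
    return {
        "visits": visits,
        "health": health,
        "coughing": coughs,
        "climate": climate,
        "panting": panting,
        "truth_episodes": truth,
        "roster": strategies,
    }


def run_all(
    config: RunConfig,
    herd: HerdConfig | None = None,
    episodes: list[EpisodeSpec] | None = None,
    heatwave_days: set[int] | None = None,
    data: dict[str, pd.DataFrame] | None = None,
    write: bool = True,
) -> dict:
    """Execute every stage; return a manifest plus the in-memory tables.

    When ``data`` is omitted a synthetic herd is generated from ``herd``
    (defaults seeded from the run config). Partial outputs are written as
    each stage completes, so a failing stage leaves earlier results behind.
    """
    out_dir = Path(config.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    def stage(name):
        log.info("stage: %s", name)

    def save(name: str, df: pd.DataFrame) -> None:
        tables[name] = df
        if write:
            df.to_csv(out_dir / f"{name}.csv", index=False)

    if data is None:
        stage("simulate")
        herd = herd or HerdConfig(seed=config.seed)
        data = simulate(herd, episodes, heatwave_days)
    for name in ("visits", "health", "coughing", "climate", "panting", "truth_episodes"):
        if name in data:
            save(name, data[name])
    roster = data.get("roster")
    if roster is None:
        roster = data["visits"][["pig_id", "pen_id", "round_id"]].drop_duplicates()

    stage("components")
    dailies = []
    for rnd, sub in data["visits"].groupby("round_id"):
        crit = config.meal_criteria_s.get(int(rnd), 43.0)
        daily, meals, clean_log = compute_daily_components(
            sub, crit, config.cleaning, night_hours=config.night_hours
        )
        dailies.append(daily)
    daily = pd.concat(dailies, ignore_index=True)
    save("daily_components", daily)

    stage("welfare")
    herd_for_days = herd or HerdConfig(seed=config.seed)
    obs_days = observation_days(herd_for_days)
    binary = binarize_scores(data["health"], config.thresholds)
    if "coughing" in data and len(data["coughing"]):
        binary = pd.concat(
            [binary, pen_coughing_days(data["coughing"], roster, config.cough_threshold)],
            ignore_index=True,
        )
    n_days = int(daily["day"].max())
    windows = identify_onsets(binary, n_days)
    if "climate" in data and len(data["climate"]):
        climate, _ = clean_climate(data["climate"])
        risk = heat_risk_days(climate, config.thi_threshold)
        stress = heat_stress_days(risk, data["panting"], obs_days, config.panting_threshold)
        save("heat_stress_days", stress)
        windows += heat_onsets(stress, sorted(roster["pig_id"].unique()))
    windows += any_issue(windows)
    save("onsets", windows_to_frame(windows))

    stage("detect")
    results = run_dlm_table(daily, config.dlm)
    save("dlm_results", results)

    stage("cooccur")
    round_of = dict(zip(roster["pig_id"], roster["round_id"]))
    freq = alert_frequency_table(results, round_of=round_of)
    save("alert_summary", freq["total"])
    save("overlap_matrix", alert_overlap_matrix(results).reset_index(names="component"))
    strategies = classify_strategies(daily, excluded_days=set(range(1, min(obs_days))))
    save("strategies", strategies)
    sens = compute_sensitivities(
        windows,
        results,
        subgroups=strategies,
        min_unique_pigs=config.min_unique_pigs,
        missing_fraction=config.onset_missing_fraction,
    )
    save("sensitivities", sens)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config, herd),
        "row_counts": {k: int(len(v)) for k, v in tables.items()},
        "outputs": sorted(tables),
    }
    if write:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["tables"] = tables
    return manifest
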