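import numpy as np
import pytest

from feedwatch.config import RunConfig
from feedwatch.pipeline import run_all
from feedwatch.synthetic import EpisodeSpec, HerdConfig, assign_strategies, observation_days


@pytest.fixture(scope="session")
def herd_cfg() -> HerdConfig:
    """One full round: 110 pigs in 10 pens of 11, 92 days, Mon/Thu scoring."""
    return HerdConfig(seed=7, n_rounds=1, pens_per_round=10, pigs_per_pen=11, days_per_round=92)


@pytest.fixture(scope="session")
def small_cfg() -> HerdConfig:
    """Two pens over a month, for cheap generator-level tests."""
    return HerdConfig(seed=3, n_rounds=1, pens_per_round=2, pigs_per_pen=11, days_per_round=31)


@pytest.fixture(scope="session")
def lameness_episodes(herd_cfg) -> list[EpisodeSpec]:
    """40 sustained sudden 6*sd negative intake episodes, onsets on
    observation days past the filter's early adaptation phase."""
    pigs = sorted(assign_strategies(herd_cfg)["pig_id"])
    obs = [d for d in observation_days(herd_cfg) if 22 <= d <= 78]
    rng = np.random.default_rng(11)
    episodes = []
    for i, pig in enumerate(rng.choice(pigs, size=40, replace=False)):
        episodes.append(
            EpisodeSpec(
                indicator="lameness",
                pig_ids=(pig,),
                onset_day=int(obs[i % len(obs)]),
                duration_d=7,
                affected_components=("intake",),
                deviation_magnitude=6.0,
                deviation_direction="negative",
                deviation_shape="sudden",
                persistence="sustained",
            )
        )
    return episodes


@pytest.fixture(scope="session")
def pipeline_run(herd_cfg, lameness_episodes) -> dict:
    """Full pipeline on the 110-pig round with injected lameness episodes
    and a 3-day heat wave; tables kept in memory."""
    cfg = RunConfig(seed=7)
    return run_all(
        cfg,
        herd=herd_cfg,
        episodes=lameness_episodes,
        heatwave_days={40, 41, 42, 60},
        write=False,
    )
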