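"""Configuration objects and the constants shared across pipeline stages.

All analysis constants (THI threshold, panting threshold, cough-count
threshold, confidence-interval z-values, onset missing-day fraction,
minimum unique pigs, strategy percentiles, meal criteria) live here as
defaults so that no stage hard-codes them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The six daily feeding-behaviour components, in canonical order.
COMPONENTS = (
    "intake",
    "duration",
    "frequency",
    "rate",
    "night_intake",
    "circadian_strength",
)

#: Components that define a feeding-strategy dimension.
STRATEGY_DIMENSIONS = ("frequency", "rate", "night_intake", "circadian_strength")

#: Hours of the calendar day counted as "night" (before the morning intake
#: peak and after the afternoon one): 21:00-23:59 and 00:00-03:59.
NIGHT_HOURS = (21, 22, 23, 0, 1, 2, 3)

#: z-values for the two-sided 95 / 99 / 99.9% confidence intervals.
Z_LEVELS = {"95": 1.96, "99": 2.575, "999": 3.291}

#: The seven alert types emitted per pig-day-component.
ALERT_TYPES = ("any95", "pos95", "neg95", "pos99", "neg99", "pos999", "neg999")

#: Daily round-median THI above which a day is at risk of heat stress (strict >).
THI_THRESHOLD = 79.0

#: Proportion of pigs panting needed to confirm a heat-stress day (>=).
PANTING_THRESHOLD = 0.10

#: Pen cough count above which a day is a coughing issue-day (strict >).
COUGH_THRESHOLD = 15

#: An onset window is excluded when more than this fraction of its days
#: has missing alerts (strict >).
ONSET_MISSING_FRACTION = 1.0 / 3.0

#: Sensitivities are reported only for issues with onsets in >= this many pigs.
MIN_UNIQUE_PIGS = 10

#: Tertile boundaries (percentiles) for feeding-strategy classification.
STRATEGY_PERCENTILES = (33.0, 67.0)

#: Default meal criterion (max inter-visit gap, s) per pig round.
MEAL_CRITERIA_S = {1: 43.0, 2: 61.0, 3: 30.0, 4: 50.0}

#: Climate cleaning bounds: AT below 16 degC removed; RH outside [40, 90] removed.
CLIMATE_AT_MIN = 16.0
CLIMATE_RH_MIN = 40.0
CLIMATE_RH_MAX = 90.0

#: Default score thresholds converting discrete health scores to binary
#: issue/no-issue. Tail damage switches at the first score indicating a
#: wound (2); binary indicators switch at 1.
DEFAULT_THRESHOLDS = {
    "tail_damage": 2,
    "ear_tip_damage": 2,
    "ear_base_damage": 2,
    "flank_damage": 2,
    "lameness": 1,
    "bursitis": 1,
    "conjunctivitis": 1,
    "rectal_prolapse": 1,
    "hernia": 1,
    "pumping": 1,
    "shivering": 1,
    "low_body_condition": 1,
}


@dataclass
class CleaningRules:
    """Visit-record cleaning rules (the criteria are configuration, not derived).

    ``rate_ceiling_g_s``: visits whose intake/duration rate exceeds this get
    their intake and duration nulled while the timing is kept.
    """

    remove_negative: bool = True
    remove_zero_duration_with_intake: bool = True
    rate_ceiling_g_s: float = 5.0


@dataclass
class DlmConfig:
    """Settings of the dynamic linear model / Kalman filter.

    The state is (mu, alpha, beta, gamma): level, linear trend, trend change
    and pen-average coefficient. Starting values follow the tuned values of
    the monitoring model: mu = 0.9 * first observation, alpha = beta = 0,
    gamma = 0.1, observation variance V0 = 0.1.

    System-error variances can be given either as a fixed diagonal W
    (``system_var``, interpreted as multiples of the series variance unless
    ``system_var_absolute``) or via a single discount factor
    (``discount`` set -> discount mode).
    """

    start_mu_factor: float = 0.9
    start_alpha: float = 0.0
    start_beta: float = 0.0
    start_gamma: float = 0.1
    start_obs_var: float = 0.1
    #: prior variance of (mu, alpha, beta, gamma) on day 1
    start_state_var: tuple[float, float, float, float] = (1.0, 0.01, 0.001, 0.01)
    #: diagonal system-error variances for (w1, w2, w3, w4)
    system_var: tuple[float, float, float, float] = (1e-3, 1e-5, 1e-6, 1e-5)
    #: if True, system_var and start_state_var are absolute; otherwise they
    #: scale with the observed series variance
    system_var_absolute: bool = False
    #: single discount factor; when set, covariance is inflated by 1/discount
    #: instead of adding W
    discount: float | None = None
    #: EWMA adaptation of the observation variance V_t from squared
    #: innovations; None disables adaptation (fixed V)
    obs_var_lambda: float | None = 0.95
    #: divide each series by its standard deviation before filtering
    normalize_scale: bool = False
    z_levels: dict = field(default_factory=lambda: dict(Z_LEVELS))

    def __post_init__(self) -> None:
        if self.start_obs_var <= 0:
            raise ValueError("start_obs_var must be > 0")
        if self.discount is not None and not (0 < self.discount <= 1):
            raise ValueError("discount must be in (0, 1]")
        if self.obs_var_lambda is not None and not (0 < self.obs_var_lambda <= 1):
            raise ValueError("obs_var_lambda must be in (0, 1]")
        zs = [self.z_levels[k] for k in ("95", "99", "999")]
        if not (0 < zs[0] < zs[1] < zs[2]):
            raise ValueError("z-levels must be positive and increasing")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; every default is the analysis value."""

    out_dir: str = "out"
    seed: int = 0
    meal_criteria_s: dict = field(default_factory=lambda: dict(MEAL_CRITERIA_S))
    cleaning: CleaningRules = field(default_factory=CleaningRules)
    dlm: DlmConfig = field(default_factory=DlmConfig)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    night_hours: tuple = NIGHT_HOURS
    thi_threshold: float = THI_THRESHOLD
    panting_threshold: float = PANTING_THRESHOLD
    cough_threshold: int = COUGH_THRESHOLD
    onset_missing_fraction: float = ONSET_MISSING_FRACTION
    min_unique_pigs: int = MIN_UNIQUE_PIGS
    percentiles: tuple = STRATEGY_PERCENTILES

    def __post_init__(self) -> None:
        if not 0 <= self.panting_threshold <= 1:
            raise ValueError("panting_threshold must be a proportion")
        if not 0 < self.onset_missing_fraction < 1:
            raise ValueError("onset_missing_fraction must be in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in raw:
            continue
        val = raw[f.name]
        if f.name == "cleaning":
            val = CleaningRules(**val)
        elif f.name == "dlm":
            val = DlmConfig(**val)
        kwargs[f.name] = val
    return RunConfig(**kwargs)


def load_thresholds(path: str | Path) -> dict:
    """Load an indicator -> binary-threshold table from YAML."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"thresholds file not found: {p}")
    table = yaml.safe_load(p.read_text())
    if not isinstance(table, dict):
        raise ValueError(f"thresholds file {p} must map indicator -> threshold")
    return {str(k): int(v) for k, v in table.items()}
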