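"""Day-by-day dynamic linear model with Kalman filter and alert generation.

Each pig x feeding-component series Y_t follows a quadratic trend model
that also incorporates the pen-average behaviour:

    Y_t     = mu_t + gamma_t * Ybar_t + v_t,   v_t ~ N(0, V_t)
    mu_t    = mu_{t-1} + alpha_{t-1} + beta_{t-1} + w_1t
    alpha_t = alpha_{t-1} + beta_{t-1} + w_2t
    beta_t  = beta_{t-1} + w_3t
    gamma_t = gamma_{t-1} + w_4t

with level mu, linear trend alpha, trend change beta and pen-average
coefficient gamma. The Kalman filter alternates a prediction stage (one-step
forecast of the coming day) with an updating stage (absorbing the real
observation), producing the innovation e_t and its variance E_t. Days on
which the observation falls outside the forecast's 95/99/99.9% confidence
interval yield alerts in seven types: any95, and positive/negative at each
CI level.

Note on the CI: the interval is (mu_t + gamma_t*Ybar_t) +/- z*sqrt(E_t),
i.e. z times the one-step forecast *standard deviation*. (A square root of
the innovation itself would be undefined for negative innovations.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ALERT_TYPES, COMPONENTS, DlmConfig

#: state transition of (mu, alpha, beta, gamma)
F = np.array(
    [
        [1.0, 1.0, 1.0, 0.0],
        [0.0, 1.0, 1.0, 0.0],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass
class DlmState:
    """Filtered state: mean vector (mu, alpha, beta, gamma), covariance, V_t."""

    m: np.ndarray
    C: np.ndarray
    V: float

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if not np.all(np.isfinite(self.m)) or not np.all(np.isfinite(self.C)):
            raise ValueError("state contains non-finite entries")


def initial_state(first_obs: float, config: DlmConfig, scale: float = 1.0) -> DlmState:
    """Starting state: mu = 0.9 * first observation, alpha = beta = 0,
    gamma = 0.1, V_0 = 0.1 (all configurable)."""
    m = np.array(
        [
            config.start_mu_factor * first_obs,
            config.start_alpha,
            config.start_beta,
            config.start_gamma,
        ]
    )
    var = np.asarray(config.start_state_var, dtype=float)
    if not config.system_var_absolute:
        var = var * scale**2
    return DlmState(m=m, C=np.diag(var), V=config.start_obs_var)


def _system_cov(config: DlmConfig, scale: float) -> np.ndarray:
    W = np.diag(np.asarray(config.system_var, dtype=float))
    if not config.system_var_absolute:
        W = W * scale**2
    return W


def kalman_predict(
    state: DlmState, config: DlmConfig, pen_mean: float | None, scale: float = 1.0
) -> tuple[DlmState, float, float]:
    """Prediction stage: propagate the state one day ahead.

    Returns (prior state, forecast mean, forecast variance). The forecast
    mean is mu + gamma * pen mean; with the pen mean missing the pen term is
    dropped for the day. Covariance is inflated either by the fixed diagonal
    system-error variances W or, in discount mode, by 1/delta.
    """
    a = F @ state.m
    R = F @ state.C @ F.T
    if config.discount is not None:
        R = R / config.discount
    else:
        R = R + _system_cov(config, scale)
    R = (R + R.T) / 2
    h = np.array([1.0, 0.0, 0.0, 0.0 if pen_mean is None else float(pen_mean)])
    f = float(h @ a)
    Q = float(h @ R @ h + state.V)
    return DlmState(m=a, C=R, V=state.V), f, Q


def kalman_update(
    prior: DlmState,
    y_obs: float,
    forecast_mean: float,
    forecast_var: float,
    pen_mean: float | None,
    config: DlmConfig,
) -> tuple[DlmState, float, float]:
    """Updating stage: absorb the observation, return (posterior, e_t, E_t).

    Standard Kalman gain update; optionally the observation variance V_t is
    adapted as an EWMA of squared innovations.
    """
    h = np.array([1.0, 0.0, 0.0, 0.0 if pen_mean is None else float(pen_mean)])
    e = float(y_obs - forecast_mean)
    K = prior.C @ h / forecast_var
    m = prior.m + K * e
    C = prior.C - np.outer(K, h) @ prior.C
    C = (C + C.T) / 2
    V = prior.V
    if config.obs_var_lambda is not None:
        lam = config.obs_var_lambda
        V = lam * V + (1 - lam) * e**2
    return DlmState(m=m, C=C, V=V), e, forecast_var


def generate_alerts(
    y_obs: float, forecast_mean: float, forecast_var: float, z_levels: dict
) -> dict:
    """Alert set for one day: positive/negative per CI level plus any95.

    An observation exactly on a CI boundary is not an alert (strict
    inequality). Containment holds by construction: 99.9% implies 99%
    implies 95%, and any95 iff pos95 or neg95.
    """
    sd = float(np.sqrt(forecast_var))
    alerts = {}
    for level in ("95", "99", "999"):
        z = z_levels[level]
        alerts[f"pos{level}"] = y_obs > forecast_mean + z * sd
        alerts[f"neg{level}"] = y_obs < forecast_mean - z * sd
    alerts["any95"] = alerts["pos95"] or alerts["neg95"]
    return alerts


def pen_mean_series(daily: pd.DataFrame, component: str) -> pd.DataFrame:
    """Arithmetic mean of a component over the non-missing pigs per pen-day."""
    out = (
        daily.groupby(["pen_id", "date"])[component]
        .mean()
        .rename("pen_mean")
        .reset_index()
    )
    return out


def run_dlm(
    y: np.ndarray,
    pen_mean: np.ndarray | None = None,
    config: DlmConfig | None = None,
) -> pd.DataFrame:
    """Filter one series day by day: predict -> alert -> update.

    ``y`` may contain NaN (missing feeder data): those days are
    predict-only, carry the prior forward and have missing alerts.
    Initialisation uses the first *observed* value.

    Returns one row per day with the forecast, innovation and alert flags.
    """
    config = config or DlmConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if pen_mean is None:
        pen_mean = np.full(n, np.nan)
    pen_mean = np.asarray(pen_mean, dtype=float)
    obs_idx = np.flatnonzero(np.isfinite(y))
    if len(obs_idx) == 0:
        import warnings

        warnings.warn("all-missing series: no filter output", stacklevel=2)
        return pd.DataFrame(
            columns=["day", "y_obs", "pen_mean", "y_pred", "forecast_var", "innovation"]
            + list(ALERT_TYPES)
            + ["missing"]
        )
    if n < 2:
        raise ValueError("series must span at least 2 days")
    scale = 1.0
    if not config.system_var_absolute:
        s = np.nanstd(y)
        scale = s if s > 0 else 1.0
    if config.normalize_scale:
        y = y / scale
        pen_mean = pen_mean / scale
        scale = 1.0

    state = initial_state(y[obs_idx[0]], config, scale)
    rows = []
    for t in range(n):
        pm = None if not np.isfinite(pen_mean[t]) else pen_mean[t]
        prior, f, Q = kalman_predict(state, config, pm, scale)
        missing = not np.isfinite(y[t])
        if missing:
            state = prior
            row = dict.fromkeys(ALERT_TYPES, np.nan)
            row.update(
                day=t + 1, y_obs=np.nan, pen_mean=pen_mean[t], y_pred=f,
                forecast_var=Q, innovation=np.nan, missing=True,
            )
        else:
            alerts = generate_alerts(y[t], f, Q, config.z_levels)
            state, e, E = kalman_update(prior, y[t], f, Q, pm, config)
            row = dict(alerts)
            row.update(
                day=t + 1, y_obs=y[t], pen_mean=pen_mean[t], y_pred=f,
                forecast_var=E, innovation=e, missing=False,
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    front = ["day", "y_obs", "pen_mean", "y_pred", "forecast_var", "innovation"]
    return out[front + list(ALERT_TYPES) + ["missing"]]


def run_dlm_table(
    daily: pd.DataFrame,
    config: DlmConfig | None = None,
    components: tuple = COMPONENTS,
) -> pd.DataFrame:
    """Filter every pig x component series of a daily-components table.

    Pen means are computed per pen-day over non-missing pigs. Returns the
    long results table (pig_id, component, day, forecast, innovation, seven
    alert flags, missing).
    """
    config = config or DlmConfig()
    results = []
    for comp in components:
        pens = pen_mean_series(daily, comp)
        merged = daily.merge(pens, on=["pen_id", "date"], how="left")
        for pig, sub in merged.groupby("pig_id"):
            sub = sub.sort_values("date")
            if not np.isfinite(sub[comp].astype(float)).any():
                continue
            res = run_dlm(
                sub[comp].to_numpy(dtype=float),
                sub["pen_mean"].to_numpy(dtype=float),
                config,
            )
            res["day"] = sub["day"].to_numpy()
            res["pig_id"] = pig
            res["component"] = comp
            results.append(res)
    out = pd.concat(results, ignore_index=True)
    cols = ["pig_id", "component", "day"]
    return out[cols + [c for c in out.columns if c not in cols]]


def simulate_from_model(
    n_days: int,
    config: DlmConfig,
    rng: np.random.Generator,
    init_state: np.ndarray = (2.0, 0.01, 0.0, 0.1),
    obs_var: float = 0.1,
    pen_mean: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one series exactly from the state-space model (for calibration).

    System errors use the (absolute) variances of ``config.system_var`` and
    observation noise variance ``obs_var``; ``pen_mean`` is an exogenous
    known series (zeros when omitted).
    """
    if pen_mean is None:
        pen_mean = np.zeros(n_days)
    x = np.asarray(init_state, dtype=float).copy()
    W_sd = np.sqrt(np.asarray(config.system_var, dtype=float))
    y = np.empty(n_days)
    for t in range(n_days):
        x = F @ x + rng.normal(0.0, W_sd)
        y[t] = x[0] + x[3] * pen_mean[t] + rng.normal(0.0, np.sqrt(obs_var))
    return y
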