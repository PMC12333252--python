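# Methods

## Problem and scope

`feedwatch` implements a monitoring pipeline for growing-finishing pigs fed
at electronic single-space feeding stations. Each pig's daily feeding
behaviour is summarised into six components — intake (kg/d), duration (s/d),
frequency (meals/d), rate (g/s), night intake (proportion of daily intake in
21:00–03:59) and circadian rhythm strength (wavelet power of hourly intake
near the 24 h period). A dynamic linear model (DLM) with Kalman filter
forecasts each pig × component series one day ahead; observations outside
the forecast confidence interval raise alerts. Alerts are then compared with
the onsets of welfare issues (twice-weekly health scores, THI-plus-panting
heat stress) through sensitivities, overall and within feeding-strategy
subgroups. A synthetic herd generator supplies every input stream so the
whole pipeline is testable end to end without farm data.

## The state-space model

For a pig and component, the observation on day *t* is

    Y_t     = mu_t + gamma_t * Ybar_t + v_t,   v_t ~ N(0, V_t)
    mu_t    = mu_{t-1} + alpha_{t-1} + beta_{t-1} + w_1t
    alpha_t = alpha_{t-1} + beta_{t-1} + w_2t
    beta_t  = beta_{t-1} + w_3t
    gamma_t = gamma_{t-1} + w_4t

with level `mu`, linear trend `alpha`, trend change `beta` and pen-average
coefficient `gamma`; `Ybar_t` is the arithmetic mean of the component over
the non-missing pigs of the pen that day. The Kalman filter alternates a
prediction stage (one-step forecast with variance `E_t`) and an updating
stage absorbing `Y_t` to give the innovation `e_t`.

Starting values: `mu = 0.9 * first observed value`, `alpha = beta = 0`,
`gamma = 0.1`, `V_0 = 0.1`. Alerts are produced from day 1; the state prior
is diffuse enough that early confidence intervals are visibly wider than
late ones, so early alerts are rare by construction rather than suppressed.

Two choices are deliberately configurable because a single published
recipe does not pin them down:

* **System-error variances.** Default is a fixed diagonal W with variances
  expressed as multiples of the series variance
  (`1e-3, 1e-5, 1e-6, 1e-5` for the four states); a single-discount-factor
  mode (`discount`, covariance inflated by 1/δ) is available instead.
* **Observation variance.** `V_t` adapts by default as an EWMA of squared
  innovations, `V_t = λ V_{t-1} + (1-λ) e_t²` with λ = 0.95; setting
  `obs_var_lambda = None` fixes `V` at `V_0`. Adaptation makes the single
  starting value 0.1 workable across components of very different scales;
  alternatively `normalize_scale=True` divides each series by its standard
  deviation before filtering.

**Confidence intervals.** The CI is `(mu_t + gamma_t*Ybar_t) ± z·sqrt(E_t)`
with z = 1.96 / 2.575 / 3.291 for 95 / 99 / 99.9%. The spread is the
one-step forecast standard deviation: a square root of the innovation
itself would be undefined whenever the innovation is negative. Seven alert
types are emitted per pig-day: positive and negative at each level plus
`any95`; a value exactly on a boundary is not an alert. Days without feeder
data are predict-only and carry missing alerts. When the pen mean is
missing the pen term is dropped for that day's forecast.

## Feeding components

Visits are cleaned by configurable rules (negative values and zero-duration
positive-intake records removed; records above a feeding-rate ceiling,
default 5 g/s, keep their timing but lose intake and duration). Consecutive
visits with a gap (next start − previous end) below the meal criterion are
merged into meals; the criteria are per-round configuration (43, 61, 30,
50 s). Daily intake/duration are meal sums, frequency the meal count, rate
their ratio. A covered day with no meals is a true zero — so anorexia can
raise alerts — while days without feeder coverage are missing. Night intake
is the proportion of the calendar day's intake in hours {21, 22, 23, 0, 1,
2, 3}; the window is kept inside one calendar day for determinism, as the
midnight-straddling alternative is not distinguishable from daily data.
Night intake and circadian strength are undefined on zero-intake days.

Circadian rhythm strength: the hourly intake series is detrended
(least-squares line), amplitude-corrected by a centred rolling standard
deviation (default window 7 d) and zero-filled at missing hours, then
transformed with a continuous Morlet wavelet over periods 8–48 h (0.5 h
grid). Power is the squared modulus; each day's value is the median power
over that day's 24 hours within the 23.5–24.5 h band. Days within ±2 d of
a missing day are set missing to avoid edge effects of the zero
substitution.

## Welfare events

Climate cleaning nulls AT < 16 °C and RH outside [40, 90] % (strict
bounds, per measurement). THI = (1.8·AT + 32) − (0.55 − 0.0055·RH)(1.8·AT −
26). Fifteen-minute THI values are aggregated to daily medians per room and
then to the round level as the median of room medians (the two-step median
reading of the aggregation); a day is at risk iff this median exceeds 79
(strict). A risk day becomes a heat-stress day if ≥ 10 % of pigs pant that
day, or — on non-observation days — if the threshold was exceeded on the
nearest preceding or following observation day.

Health scores binarise at per-indicator thresholds (tail damage at 2, the
first wound score; binary indicators at 1; the table is configuration).
Coughing is pen-level: a count strictly above 15 in the 5-min observation
marks a coughing day for every pig of the pen.

Onset identification (three steps): (1) non-observation days are issue-days
iff both neighbouring observation days are issue-days, no-issue otherwise
(series edges count as missing neighbours, hence no-issue); (2) observation
days switching no-issue → issue are retained — an issue on the first
observation day is not an onset; (3) each retained day is extended backward
through all days after the previous observation day, giving 1–4 d windows.
Heat stress, observed daily, uses step 2 only (length-1 windows). The
`any_issue` series is the per-pig union of onset days, re-segmented into
maximal consecutive runs.

## Sensitivities and chance level

Per onset window the alerts of a component are aggregated by retaining the
most extreme alert per direction; a window is excluded when more than one
third (strict) of its days has missing alerts. Sensitivity =
100·TP/(TP+FN) over included windows per (component, indicator, alert
type, subgroup); cells whose onsets touch fewer than ten unique pigs are
computed but flagged unreported. No specificity or predictive values are
computed: with twice-weekly observation, true negatives are unreliable.

Under independence the expected sensitivity is `100·(1 − (1 − p)^k)` for
daily alert rate `p` and window length `k`; the permutation null
(circularly shifting each pig's alert calendar by a random offset)
operationalises this and is checked in the test suite.

Feeding strategies: after dropping disturbance days (before the first
health observation, after first slaughter, severe-issue days ± 3 d — a
configurable exclusion calendar), values are scaled per farm-day (subtract
the round-day mean, divide by the round-day sd), each pig's median scaled
value is computed, and pigs fall below the 33rd / above the 67th percentile
of their round into low / high, the rest intermediate. Ties at a percentile
go to intermediate ("below" and "above" read strictly); percentiles use
linear interpolation. Pigs with fewer than 5 retained days stay unassigned.

## Synthetic herd

Defaults emulate one round of a conventional farm: 110 pigs in 10 pens of
11, one single-space feeder per pen, 92 days, health scoring on Mondays and
Thursdays. Daily targets follow growth curves (intake linear 1.2 → 2.6
kg/d; duration rising then falling 3600 → 4800 → 3900 s) with mean-one
lognormal day-to-day noise (intake sd 0.10, duration 0.12) and
Poisson-distributed visit counts — positivity and count nature motivate
these families. Each pig draws a category per strategy dimension
(visits/day 5 / 9 / 14; duration multiplier 1.25 / 1.0 / 0.8 for slow/fast
eating; night share 0.02 / 0.08 / 0.18; diurnal phase jitter 2.5 / 1.2 /
0.4 h for inconsistent/consistent eating). Visit start times are bimodal
(peaks at 07:00 and 15:30 — config parameters, not claims) with a
21:00–03:59 trough; night visits are placed uniformly in the trough.
Within a pen, visits are queued on a shared timeline so they never overlap.
Panting is generated at farm level directly (individual panting is
unreliable). On heat-wave days ambient temperature is raised so the daily
median THI exceeds 79 and panting reaches 15 %.

Episodes inject deviations of `magnitude × component noise-sd`, as a step
(sudden) or linear ramp (gradual), over the whole episode (sustained) or
its first two days (onset-only), by scaling visit intakes/durations,
dropping or splitting visits (frequency), or moving visit times (night
intake, circadian strength). The ground-truth table is always emitted.

What the generator does *not* emulate — competition and dominance at the
feeder, feeder malfunction missingness, drifting strategy categories,
correlated multi-indicator disease, seasonal climate — bounds what green
tests mean: they demonstrate that the machinery recovers the deviations it
is pointed at under the stated statistical structure, not that real farm
sensitivities would be high. On real farms, sensitivities near the chance
level are the expected outcome.

## Numerical and testing choices

Covariances are symmetrised after every propagation; the filter state prior
is diagonal (`1, 0.01, 0.001, 0.01` × series variance). Calibration is
verified on 50 pigs × 100 d simulated exactly from the model with known
variances: the post-burn-in (30 d) `any95` rate must sit within 3 Monte
Carlo standard errors of 5 %. Deviation recovery uses 40 sustained sudden
6-sd negative intake episodes with onsets on observation days: intake
sensitivity must exceed the chance level at the realized alert rate
(one-sided binomial, α = 0.01) while duration, frequency and night intake
stay within chance (rate shares intake's numerator and is genuinely
affected, so it is not part of the "unaffected" check). The permutation
null uses 30 circular shifts and a tolerance of 3 SE plus 2 points for
alert autocorrelation. These problem sizes keep the full suite to a few
minutes while leaving the Monte Carlo bands meaningful.

## Known limitations

* The Kalman formulation matches the published equations, but the original
  system-error variances are not public; with different W the alert counts
  (not the mechanics) would differ.
* Hour-of-start assignment of a meal's whole intake slightly coarsens the
  diurnal profile.
* Strategy classification assumes stable categories across the round.
* The pen-average coefficient is filtered per pig, so pen effects are not
  estimated jointly across pen mates.
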