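# Methods

This document states the model underlying `hrmonitor`, every assumption
and parameter, what the synthetic-athlete generator can and cannot claim
realism for, and the numerical conventions used throughout.

## 1. Monitoring markers

### Resting (daily, morning)

* **rMSSD** — root mean square of successive R-R differences, in ms;
  **Ln rMSSD** is its natural logarithm. Time-domain vagal indices are
  preferred for field monitoring over spectral measures (more reliable,
  less breathing-dependent, valid in ultra-short recordings).
* **Ln rMSSD / R-R ratio** — Ln rMSSD divided by the mean R-R interval
  expressed in seconds. At very low resting heart rates HRV can fall
  *because* vagal tone is high (parasympathetic saturation at the
  acetylcholine-receptor level); a concurrent decrease of HR, Ln rMSSD
  and this ratio flags saturation, whereas a decrease of Ln rMSSD with
  stable-or-rising HR is ordinary vagal withdrawal.
* **Artifact filter** — an interval is rejected when it deviates more
  than 30 % from the median of its up-to-5 nearest accepted neighbours;
  passes repeat until a fixed point, so the filter is idempotent.

### Exercise (weekly submaximal test)

A fixed 5-min, 3-stage shuttle run (1 + 1 + 3 min at 9.0 / 10.5 /
12.0 km/h, 28 m shuttles, 1 min passive recovery) yields:

* **HRex** — mean HR over the final 30–60 s before exercise cessation
  (window `[cessation − w, cessation)`), rejected when fewer than 80 %
  of the nominal 1 Hz samples are present;
* **HRR** — HR at cessation minus HR 60 s later, both anchors smoothed
  over a 5–15 s window *ending at* the anchor (causality at cessation);
* **%HRmax zones** — 10 %-wide lower-closed bands from 50 %HRmax,
  `[90, 100]` closed at the top.

### Load (per session)

Session-RPE load = RPE (0–10) × duration (min), in arbitrary units (AU).
Acute load = trailing 7-day sum; chronic load = trailing 28-day sum
scaled to one week, so a steady routine has acute:chronic ratio
(ACWR) exactly 1. An EWMA variant (decay 2/(N+1)) is provided. The ACWR
is reported as absent until 21 days of data exist. Days without sessions
count as 0 AU over the **whole log span** — rest is information, not
missing data. *Context*: recovery iff acute load is zero or ACWR < 0.8
(strict); otherwise training.

## 2. Meaningful change

All methods are implemented side by side because they genuinely
disagree on real series:

| Method | Band | Default |
| --- | --- | --- |
| SWC (percent) | % of baseline mean | 1 % HRex, 7 % HRR |
| SWC (SD) | multiple of baseline SD | 0.5 × SD (HRrest, Ln rMSSD) |
| TE | typical error, % of baseline mean | 3 % |
| SWC+TE | both bands | conjunction |
| Z retrospective | mean/SD of the entire series | \|z\| > 1 |
| Z rolling | mean/SD of data available at each date | \|z\| > 1, ≥ 4 points |

Conventions: all thresholds are **strict** inequalities (a change exactly
on the band is trivial); SDs are sample SDs (n−1); the baseline is the
mean/SD of the **first 4 weeks** and stays fixed unless re-baselined
explicitly; trends are OLS slopes in units per week whose sign class
compares |slope × window length| against an SWC band.

## 3. Decision engine

A fast-and-frugal table over
(context ∈ {training, recovery}) × (horizon ∈ {short_term, long_term}) ×
(ΔHRex ∈ {dec, triv, inc}) × (ΔRPE ∈ {dec, triv, inc}) — 36 cells, all
enumerable via `decision_table()`. Only combinations the evidence
resolves carry a named status:

* training / short: (dec, inc) → **acute_fatigue**; (dec, triv|dec) →
  **coping**; (inc, inc) → **warning_review** (possible sickness or
  non-training stress — the one extrapolated cell);
* recovery / short: (inc, dec|triv) → **recovered**; (triv|inc, inc) →
  **incomplete_recovery**;
* training / long: (dec, triv|dec) → **positive_adaptation**; (dec,
  inc) → **overreaching**;
* recovery / long: (inc, inc) → **detraining**;
* (triv, triv) → **normal** in every context; everything else →
  **ambiguous / review_context** — the engine refuses to guess.

`evaluate_log` runs this per test occasion: the short-term comparator is
the previous test (context from the trailing 2-day load vs 0.8 × the
chronic daily mean), the long-term comparator is the season baseline
(first 4 weeks; context from the ACWR). HRex changes are classified
against a 1 % band (strict); RPE against ±1.0 on the 0–10 scale
(non-strict, the smallest whole-scale increment — RPE is quantized to
0.5, so a strict band would be unreachable in practice).

## 4. The athlete simulator

### States

Two latents drive everything; both are normalized (≈ 0–1.5 range).

**Fitness F** (slow): at each day start, from the previous day's load,

```
F ← e^(−1/τ_F) · F + (1 − e^(−1/τ_F)) · w,    w = load_AU / 600
```

with τ_F = 30 d. Under sustained complete rest — three or more
consecutive zero-load days — decay switches to τ_detrain = 8 d. This
two-regime decay is a deliberate simplification of the asymmetry between
slow training adaptation and rapid early detraining (plasma-volume and
blood-volume loss within 1–2 weeks of cessation); an ordinary 2-day
weekend never triggers it.

**Acute perturbation A** (fast): per intensity class, exponential
impulses of size `w` added at the session hour (18:00), decaying with

| class | τ_A | ~95 % recovery (3τ) |
| --- | --- | --- |
| low | 8 h | ~24 h |
| threshold | 14 h | ~42 h |
| high | 20 h | ~60 h |

chosen to land inside the reported cardiac-autonomic recovery brackets
(≤ 24 h low, 24–48 h threshold, ≥ 48 h high intensity). This is also the
single acceptance target: after one high session, hourly sampling first
finds A < 5 % of peak at hour 60 = ⌈20 · ln 20⌉ ≥ 48.

### Observables

Resting channels at 07:00 daily, exercise channels at 17:00 on test
days, sessions at 18:00 (so a test never sees the same day's session):

```
HRex    = 165 · (1 − 0.06·F − 0.077·A)        · (1 + ε)
RPE     = clip(7 − 4.5·F + 4·A + η, 0, 10)    rounded to 0.5
HRrest  = 55  · (1 + 0.05·A_high − 0.05·F)    · (1 + ε)
LnRMSSD = 4.0 · (1 + 0.05·F − 0.08·A_high)    · (1 + ε)
HRR     = 50  · (1 + 0.15·F − 0.10·A)         · (1 + ε)
```

ε ~ N(0, noise_cv²) multiplicative (default CV 2 %), η ~ N(0, 0.5²)
additive on the bounded RPE scale. Directions encode the marker
semantics: fitness and acute load both *lower* HRex (which is exactly why
HRex alone cannot separate adaptation from fatigue and RPE is needed as
the disambiguator); only high-intensity acute load disturbs the resting
channels. Gains were calibrated once, analytically, so that the weekly
microcycle produces Friday HRex suppression of ≈ −5 to −7 bpm and Monday
rebounds of ≈ +4 to +6 bpm at the default dynamics — and were then frozen
before the evaluation runs.

### Ground truth

Labels per day from the latents at 17:00, precedence
overreached > fatigued > detrained > fresh:

* **fatigued**: A ≥ 0.35;
* **overreached**: A ≥ 0.6 on 7 consecutive days (sustained, not a
  single hard day);
* **detrained**: ≥ 14 days of near-zero load (trailing 14-day load
  ≤ 10 % of the season's mean daily load) *and* F below 90 % of its
  season peak;
* **fresh** otherwise.

### Schedules

* `microcycle_4_2` — Mon threshold 600 AU, Tue high 900, Wed threshold
  450, Thu high 900; Friday test-only; weekend rest; tests Monday and
  Friday. Four weeks = 16 training days, 8 rest days, 8 tests.
* `season_fig5` — 8-week preseason (5 ramped standard weeks at 0.8–1.2×
  plus a 3-week daily-high overload block), an in-season half with a
  Saturday game and Monday tests, a 2-week zero-load mid-season break, a
  second half, and a 4-week off-season; weekly Monday tests throughout.
  The season starts at residual fitness F₀ = 0.6 (players are not fully
  detrained entering preseason); all other scenarios start at F₀ = 0.
* `custom` — explicit day list.

### Realism and limits

The generator reproduces the *directional and temporal* structure of
field observations: acute suppression of HRex/HRV after hard sessions
with intensity-dependent washout, slow HRex decline with fitness, the
fatigue/adaptation ambiguity resolvable only via RPE, overreaching under
sustained overload, and rapid visible detraining across a multi-week
shutdown. It does **not** model: menstrual/circadian/thermal effects,
illness, plasma-volume dynamics as a separate state, day-to-day HRV
autocorrelation beyond what A induces, saturation kinetics (HRV-vs-RR
nonlinearity), non-Gaussian measurement error, or inter-athlete
parameter variability (athletes differ only by noise seed unless
parameters are varied explicitly). Agreement scores against its labels
are claims about the pipeline's internal consistency, not about clinical
accuracy.

## 5. Numerical conventions

* Dates are calendar days; all windows are trailing and inclusive of the
  current day (`[date − width + 1, date]`); monitoring decisions only use
  data available at decision time (the retrospective Z is explicitly the
  after-the-fact exception).
* Sample statistics use ddof = 1 throughout.
* OLS slopes are computed in closed form from centered dot products and
  are tested to 1e-9 against normal-equation and statsmodels oracles.
* Exponential decays use exact `exp(−Δt/τ)` over irregular gaps — no
  per-step discretization error.
* All randomness flows from one `numpy.random.default_rng(seed)` in a
  fixed draw order; equal seeds give byte-identical artifacts.
* CSV interchange: comma-separated UTF-8, ISO dates, `.` decimal; floats
  written with `repr` so write→read round-trips are exact.
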