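# hrmonitor

Heart-rate-based athlete monitoring for team sports: resting HR/HRV
metrics, submaximal exercise-test markers, session-RPE training load,
meaningful-change detection, and a contextual decision engine — plus a
fitness–fatigue simulator that generates labelled synthetic seasons to
validate the whole pipeline against.

## The science in one paragraph

Day-to-day heart-rate measures index cardiac autonomic modulation, not
performance itself, so the *same* observed change can mean opposite
things depending on context. A drop in submaximal exercise HR (HRex)
with unchanged perceived exertion after weeks of training signals
positive adaptation; the same drop with *elevated* exertion after four
hard days in a row signals acute fatigue; an *increase* in HRex with
elevated exertion after weeks of rest signals detraining, not freshness.
`hrmonitor` operationalizes this contextual reading: it tracks the
markers (Ln rMSSD and resting HR in the morning; HRex, HR recovery and
RPE from a weekly standardized submaximal run), quantifies training
context from session-RPE load accumulation (acute 1-week vs chronic
4-week windows), flags which changes are larger than noise and than the
smallest worthwhile change, and runs a fast-and-frugal decision table
over (context × horizon × ΔHRex × ΔRPE) that returns a status, a
recommendation, and the full rule trace behind it.

Because real monitoring logs come without ground truth, the package also
ships a generative model: a two-state fitness–fatigue simulator whose
slow state (fitness, τ ≈ 30 d) and fast state (acute autonomic
perturbation, intensity-dependent τ of 8–20 h, i.e. ~95 % recovery in
24–60 h) drive all observables with configurable noise — and whose latent
states yield per-day labels (fresh / fatigued / overreached / detrained)
that the decision engine can be scored against.

## Worked example

Simulate a classic preparatory microcycle (Mon–Thu training, Friday
test, weekend rest, tests Monday and Friday) and run the decision engine
over every test occasion:

```python
import dataclasses

from hrmonitor import build_schedule, default_params, evaluate_log, simulate

schedule = build_schedule("microcycle_4_2", n_weeks=12)
params = dataclasses.replace(default_params("microcycle_4_2"), seed=42, noise_cv=0.02)
log, days = simulate(schedule, params)

for decision in evaluate_log(log)[-6:]:
    print(
        f"{decision.date} {decision.horizon:>10} {decision.context:>8} "
        f"{decision.status:>19} -> {decision.recommendation}"
    )
```

Output:

```
2024-03-15  long_term training positive_adaptation -> continue
2024-03-15 short_term training       acute_fatigue -> reduce_load
2024-03-18  long_term training           ambiguous -> review_context
2024-03-18 short_term recovery           recovered -> resume_training
2024-03-22  long_term training positive_adaptation -> continue
2024-03-22 short_term training       acute_fatigue -> reduce_load
```

This is the canonical weekly monitoring pattern: every Friday — after
four consecutive training days — HRex is suppressed by accumulated acute
load while RPE is elevated, and the engine reads **acute fatigue, reduce
load**. Every Monday — after the weekend — HRex rebounds and RPE drops:
**recovered, resume training**. On the long horizon the season-long HRex
decline at stable RPE reads **positive adaptation**. (The Monday
long-term `ambiguous` is deliberate: a trivial HRex change with reduced
RPE resolves no named long-term status, and the engine refuses to
guess.)

The same pipeline from the command line:

```bash
hrmonitor simulate --template microcycle_4_2 --weeks 12 --seed 42 --out demo
hrmonitor decide --log demo/monitoring.csv | tail -5
```

```
2024-03-15,short_term,training,acute_fatigue,reduce_load
2024-03-18,long_term,training,ambiguous,review_context
2024-03-18,short_term,recovery,recovered,resume_training
2024-03-22,long_term,training,positive_adaptation,continue
2024-03-22,short_term,training,acute_fatigue,reduce_load
```

Other subcommands: `metrics` (acute/chronic load and context per day),
`flags` (per-method meaningful-change matrix with pairwise method
agreement), `report` (combined text summary). All accept `--config`
(validated YAML), log their effective seed to stderr, and write data to
files or stdout only.

## Package layout

| Module | Contents |
| --- | --- |
| `hrmonitor.core` | `RRSeries`, `HRTrace`, `AthleteLog`, phase calendar, trailing windows |
| `hrmonitor.hrv` | artifact filtering, rMSSD / Ln rMSSD, Ln rMSSD/R-R ratio, saturation |
| `hrmonitor.exercise` | submaximal protocol, HRex and HRR extraction, %HRmax zones |
| `hrmonitor.load` | session-RPE load, acute:chronic ratios (rolling & EWMA), context |
| `hrmonitor.change` | SWC / TE / SWC+TE, retrospective & rolling Z, trends, method comparison |
| `hrmonitor.decisions` | the 36-cell contextual decision table, traces, log evaluation |
| `hrmonitor.simulate` | fitness–fatigue simulator, schedule templates, ground-truth labels |
| `hrmonitor.io`, `hrmonitor.cli` | CSV/YAML formats and the `hrmonitor` CLI |

See `docs/methods.md` for the model equations, parameter table, and the
numerical conventions.

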