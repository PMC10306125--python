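# lickrig

A hardware-free task engine and analysis suite for head-fixed, lick-based
rodent behavior. `lickrig` re-implements the control logic of a
moving-lickspout behavioral rig as a pure discrete-event simulation: the
two-alternative forced-choice (2AFC), Go-NoGo (GNG) and passive-stimulation
state machines run on a virtual clock against a stochastic virtual subject,
producing the same kind of timestamped event logs, settings files and
DAQ-style channel traces the physical system would — fully deterministic
given a seed, and therefore fully testable.

## What's inside

| Module | Role |
| --- | --- |
| `lickrig.scheduler` | delay tables (min/max/steps grids), without-replacement sampling pools, 2AFC side selection with run/alternation constraints, CR-rule GNG trial selection, truncated-exponential ITIs, 70/30 training/novel mixes |
| `lickrig.engine` | the 2AFC / GNG / passive state machines on a virtual clock: initiation, pre/post-stimulus delays, spout travel timing (servo 50 mm/s, linear 25 mm/s), response windows, retrial mode, reward/punishment events |
| `lickrig.subject` | virtual subject: 4-parameter logistic choice model, go/nogo lick probabilities with optional delay decay, log-normal reaction times, ~10 Hz Poisson lick bursts |
| `lickrig.stimuli` | 9×16 LED-matrix patterns (full panel, bars at 4 angles, moving bar), 32-point lookup-table tone synthesis (2–32 kHz), column↔voltage-level encoding |
| `lickrig.session_io` | plain-text session logs (lossless round trip), settings store with default rollback, spreadsheet settings export, the 3-byte device-command codec, 10 ms lick debouncing, DAQ channel-trace rendering |
| `lickrig.analysis` | percent-right-by-column, binomial maximum-likelihood psychometric fits, d′ (with rate clipping), learning curves, stage-advancement criteria, lick rasters |

## CLI

Simulate a session and write its log, settings export and DAQ trace:

```bash
lickrig run --task gng --seed 7 --out out/ --daq
lickrig run --task 2afc --config session.cfg --subject subject.cfg --out out/
```

Analyze a previously written log:

```bash
lickrig analyze --log out/session.txt --report report/
```

Configuration files are flat `key=value` text; keys mirror the control-panel
vocabulary where labels exist (`Percentage of Go Trials`, `Delay Period (s)`,
`CR rule ON`, `Override Consec Constraint`, `Short ITI`, ...). Grouped
min/max/steps boxes are written as comma-separated triples, e.g.
`Delay Period (s)=1.0,5.0,6`.

## Library example

```python
from lickrig import SessionConfig, SubjectParams, run_session
from lickrig.analysis import column_counts, fit_psychometric

config = SessionConfig(task="2afc", n_trials=1800, fraction_training=0.0,
                       novel_columns="0,1,2,3,4,5,6,7,8", exact_mix=True)
subject = SubjectParams(alpha=4.0, beta=0.8, guess=0.05, lapse=0.05)
result = run_session(config, subject, seed=1)
fit = fit_psychometric(*column_counts(result.trials))
print(fit.params)  # recovers the generating alpha/beta/guess/lapse
```

## Timing semantics worth knowing

- The GNG "Delay Period" timer is referenced to stimulus **onset** by
  default (a `(1, 5, 6)` table with a 200 ms stimulus yields post-offset
  gaps of 0.8–4.8 s); set `delay_reference=offset` to reference offset.
- The response window never opens before the spout physically arrives;
  spout movement start/arrival events are separated by exactly
  travel-distance / actuator-speed.
- All randomness derives from one session seed through named sub-streams,
  so identical config + seed replays to a byte-identical session log.
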