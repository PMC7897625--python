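# cagephys

Analysis toolkit for automated group-housing home-cage (IntelliCage-style)
behavioral experiments and hippocampal field-potential recordings, built for
aging-cognition studies where both are collected from the same mouse lines.

Group-housed, RFID-tagged mice generate a continuous event stream — corner
*visits*, door *nosepokes*, bottle *licks* — while a sequence of operant
modules (place preference and its reversal, spatial sequence learning,
delayed-response learning, place avoidance) defines what a *correct* action
is at any moment. `cagephys` turns that stream into the quantities such
studies report, and pairs it with fEPSP/LTP quantification for slice
electrophysiology from the same cohorts.

## What it computes

- **Event model & I/O** (`cagephys.events`): validated CSV dialect for
  visit/nosepoke tables with a wall-clock anchor; visit classes
  (plain / nosepoke-only / lick visits).
- **Task labeling** (`cagephys.tasks`): deterministic replay of each
  module's rules — place preference (corner- and door-side level), the
  clockwise spatial-sequence chain that advances only after lick visits,
  delayed-response scoring with premature-poke termination, and place
  avoidance with separate visit- and poke-level correctness.
- **Learning criterion** (`cagephys.learning`): Wald's sequential
  probability ratio test on the per-animal correct-visit stream, between
  chance performance p₀ = 0.25 and criterion performance p₁ = 0.35 with
  α = β = 0.05. The log-likelihood ratio after k successes in n trials,

      Λₙ = k·ln(p₁/p₀) + (n−k)·ln((1−p₁)/(1−p₀)),

  is tracked until it crosses ln((1−β)/α) (learner) or ln(β/(1−α))
  (non-learner); the crossing trial is the *trials to criterion*, and
  group learning is summarized as the cumulative proportion of learners
  versus trial number.
- **Circadian analysis** (`cagephys.circadian`): single-component 24-h
  cosinor fit y(t) = M + A·cos(2π(t−φ)/24) by OLS — mesor M, amplitude A,
  acrophase φ (wall-clock hour of peak), with an F test of zero amplitude —
  plus actogram matrices (optionally double-plotted).
- **Behavioral reductions** (`cagephys.metrics`): binned per-animal time
  courses, day/night splits, linear trapezoidal AUCs of
  behavior-versus-time curves, a 16-parameter feature table for
  ordination, and the leader–follower graph (who enters a corner right
  after another animal left it).
- **Group statistics** (`cagephys.stats`): two-way ANOVA (between-subjects
  or split-plot with Huynh-Feldt df correction), Šidák-adjusted post hoc
  p values, unpaired t tests on AUCs, PCA and canonical discriminant
  analysis of the feature table.
- **Electrophysiology** (`cagephys.ephys`): initial (10–90%) fEPSP slope,
  input–output curves with trapezoidal AUC and the 30%-of-maximum
  stimulation intensity, Gaussian fits of AUC distributions,
  baseline-normalized LTP time courses, and the regression of LTP AUC on
  √(I/O AUC) with 90% CI.
- **Synthetic data** (`cagephys.simulate`): a cage-cohort simulator
  (cosinor-modulated nonhomogeneous Poisson visits, saturating reward
  learning with reversals, negative-binomial lick bouts, full ground-truth
  labels) and an fEPSP sweep generator (sigmoidal I/O, programmable LTP
  plateau/decay, excitability–LTP coupling, Gaussian noise).

## Worked example

```python
import numpy as np
from cagephys.simulate import CohortConfig, GroupParams, simulate_cohort
from cagephys.tasks import TaskDefinition, label_ppl, correct_visit_sequences
from cagephys.learning import SPRTConfig, sprt_track

cfg = CohortConfig(groups={"wt": GroupParams(tau_trials=20.0)},
                   n_per_group=3, duration_days=7.0, seed=1)
visits, pokes, meta, truth = simulate_cohort(cfg)
task = TaskDefinition(kind="PPL",
                      assignment={t: cfg.rewarded_corner for t in meta.roster})
lab = label_ppl(visits, task, meta)
for tag, seq in correct_visit_sequences(lab).items():
    r = sprt_track(seq, SPRTConfig())
    print(tag, r.decision, r.trials_to_criterion)
```

prints

```
wt00 LEARNER 19
wt01 LEARNER 29
wt02 LEARNER 25
```

i.e. all three simulated animals cross the Wald learner boundary, needing
19–29 in-window visits to reach the criterion — the same "visits to
criterion" statistic reported for real cohorts. With
`GroupParams(p_max=0.25)` (a chance-level agent) the decisions become
`NON_LEARNER`/`CENSORED`, and with `tau_trials=1e-9, p_max=1.0` an
always-correct animal reaches the criterion at the theoretical minimum of
9 trials.

The simulators are also exposed on the command line:

```
cagephys simulate cage   --seed 1 --out data/cage/
cagephys simulate sweeps --seed 1 --out data/sweeps/
```

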