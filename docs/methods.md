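# Methods

This note documents the models and procedures implemented in `cagephys`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions that make replays
reproducible.

## Time axis and light cycle

All event times are seconds since experiment start (t = 0 at cage
activation). A metadata sidecar carries the absolute wall-clock time of
t = 0, because task windows are defined in wall-clock terms while
durations and bins are naturally relative. The light (inactive) phase is
07:00–19:00 and the dark (active) phase 19:00–07:00, consistent with a
12-h light–dark cycle in which the night drinking session (23:00–02:00)
falls in darkness. The default drinking-session windows are the half-open
wall-clock intervals [11:00, 14:00) and [23:00, 02:00); a visit belongs
to a window iff its *start* lies inside, which assigns
boundary-straddling visits unambiguously.

## Event model and visit classes

Visits, nosepokes and lick summaries form a three-level hierarchy joined
by explicit `visit_id` references (never by time-window inference, so
integrity checks are exact). Visit classes partition every stream:
a visit with licks is an L-visit, one with pokes but no licks an
NP-visit ("unnecessary" exploration), and one with no pokes a plain
visit. Contact time is stored per nosepoke and aggregated downstream,
since the finer granularity loses nothing.

## Task labeling

Correctness labels are pure functions of the event stream, the task
definition and (only for the probabilistic DRL neutral corner) a seeded
per-animal random substream; identical inputs yield identical labels.

- **Place preference (PPL / reversal).** A visit is correct iff it goes
  to the animal's assigned corner inside an active window. "Place
  errors" are wrong-corner visits relative to all in-window visits;
  corner-level correctness is primary, with door-side correctness
  (left door by day, right by night, configurable) recorded on the
  nosepokes for side-level analyses.
- **Spatial sequence (SSL / reversal).** The rewarded corner advances
  along 1→2→3→4→1 (anti-clockwise when reversed) only after an L-visit
  to the current rewarded corner; exploratory visits never advance the
  chain. The state machine is validated against a brute-force replay
  oracle on random streams.
- **Delayed response (DRL).** Within a visit, the first poke on a door
  arms the trial; the next same-door poke decides it (delay ≥ 4 s or 6 s
  correct, premature incorrect and the visit is finished for scoring).
  Opposite-door pokes have no effect. The neutral corner opens with
  probability 0.5 from a dedicated seeded substream per animal.
- **Place avoidance (PAL / extinction).** Visit-level correctness is
  avoidance of the punished corner (chance 3/4); poke-level correctness
  is reported separately because animals may keep visiting the punished
  corner while withholding pokes there.

Trials for the learning criterion are in-window visits only; visits
outside the reward windows carry no reward information and are excluded.

## Sequential learning criterion

The "probability test" classifying animals as learners is Wald's
sequential probability ratio test between chance performance p₀ = 0.25
and criterion performance p₁ = 0.35 with α = β = 0.05 — the only
sequential test parameterized by exactly these four design numbers, and
the standard criterion analysis for four-corner place tasks. Boundaries
are ln((1−β)/α) = ln 19 ≈ 2.944 and ln(β/(1−α)) = −ln 19; the
log-likelihood ratio moves by ln(p₁/p₀) ≈ +0.3365 per correct visit and
ln((1−p₁)/(1−p₀)) ≈ −0.1431 per error. The first crossing decides;
an always-correct animal reaches criterion at trial ⌈ln 19/0.3365⌉ = 9,
an always-wrong one is classified non-learner at trial 21. Streams
exhausting `max_trials` (default 10⁴) undecided are reported CENSORED,
separately from non-learners. Implementation is verified by exhaustive
enumeration of all 8,190 outcome sequences up to length 12 and by Monte
Carlo against the design error rates. The vectorized Monte-Carlo runner
generates trials lazily in blocks of 512 so long undecided streams never
materialize a replicates × max-trials matrix.

## Cosinor analysis

Binned activity is regressed on y = M + β₁cos(ωt) + β₂sin(ωt) with
ω = 2π/24 (period fixed: the experiments probe entrainment, not
free-running rhythms). Amplitude is √(β₁²+β₂²); the acrophase is
reported as the wall-clock hour of the fitted peak in [0, 24) — a
deliberate convention choice (clock time rather than negative phase
angle) because group comparisons are about *when* animals are active.
Bin centers are the regression abscissae (unbiased for symmetric bins);
at least 4 bins spanning a full period are required. Rhythmicity is the
F test of (β₁,β₂) = (0,0) with 2 numerator df. A constant series returns
amplitude 0 with the acrophase flagged undefined and p = 1. Actograms
bin visits into day × time-of-day matrices (default 30 min), with
conventional 48-h double plotting available.

## Behavioral reductions

Time courses are per-animal binned series (1/3/12/24-h bins); count
statistics are normalized to events/hour and report 0 in empty bins,
ratio statistics (licks per visit, median contact time, correctness
proportions) report missing there. AUCs use the linear trapezoidal rule
with pairwise deletion of missing points; additivity at interior sample
points is tested, and values agree with an independent summation oracle
to 1e-12.

The ordination feature table has 16 parameters per animal: visit,
nosepoke and lick rates split by light phase (per day), the three
visit-class rates, licks per L-visit, mean lick duration, mean contact
time, mean visit duration, nosepokes per visit, in-window correct-visit
proportion, and latency to the first visit. The exact set is a
configurable package choice that covers every named loading family
(activity, goal-directed licking, exploration, accuracy) plus standard
completions; animals with no events in a period are imputed with the
group median and flagged.

Leader–follower analysis counts, per ordered pair (A, B), the visits by
B to a corner starting within `max_gap_s` (default 30 s — unspecified
upstream, exposed as a parameter) after A's visit to the same corner
ended, attributing each follower visit to the most recent qualifying
leader only.

## Group statistics

Two-way between-subjects ANOVA uses the statsmodels OLS decomposition
(type-II sums of squares; identical to type I/III on balanced designs).
The repeated-measures case is a split-plot decomposition implemented
directly (no pre-installed routine exposes the Huynh-Feldt epsilon):
the between factor is tested against subjects-within-groups, the within
factor and interaction against the subject × level residual with both
df multiplied by the Huynh-Feldt epsilon. Epsilon is the
Greenhouse-Geisser estimate from the orthonormally contrasted response
covariance, corrected to Huynh-Feldt in the Lecoutre multi-group form
and clipped to 1; Greenhouse-Geisser correction itself is deliberately
not offered as an output. Šidák adjustment is p_adj = 1 − (1−p)^k.
Unpaired AUC comparisons are Student's equal-variance t tests (Welch by
flag); two degenerate constant groups with equal means return p = 1.

PCA eigendecomposes the feature correlation matrix (features z-scored
per column so counts and durations mix unitlessly). Canonical
discriminant analysis eigendecomposes W⁻¹B of the z-scored features;
with two groups there is exactly one axis carrying 100% of the
between-group variance (an algebraic identity, tested as such).
A singular within-scatter (duplicated features) is ridge-regularized
with 1e-8·tr(W)/p on the diagonal and a warning. One calibration note:
because the canonical axis maximizes in-sample separation, a naive
t test on its scores is anti-conservative under the null; the test
suite therefore assesses null separation through the Hotelling T²
F transform of the maximal score t statistic, which is exact for two
groups.

## Field potentials

The fEPSP initial slope is the least-squares slope over the samples on
the falling (onset) phase whose deflection lies between 10% and 90% of
the negative peak, nearest-sample with no interpolation, reported as a
positive magnitude. The peak is searched 1–20 ms after the stimulus
with a 1-ms artifact blank — unspecified upstream; typical for CA1
field recordings. Sample *selection* runs on a 0.5-ms boxcar-smoothed
copy of the trace while the fit uses raw samples: selecting on the raw
trace lets noise correlate with inclusion at the band edges, which
biases the slope low by several percent at realistic SNR; smoothing the
selection removes that bias without touching the fitted values. Traces
with no deflection above the noise floor are flagged missing.

I/O curves require ≥ 5 strictly increasing intensities; the AUC is
trapezoidal over raw intensity (raw rather than rank — a documented
choice), the maximum response comes from a logistic fit (observed
maximum as fallback), and the intensity nearest 30% of that maximum is
reported for LTP induction. AUC distributions get maximum-likelihood
normal fits (ddof = 0). LTP series normalize all slopes to the mean of
the 20-min pre-TBS baseline (= 100% by construction, configurable
window) and integrate from TBS (t = 0) to the end; excitability–LTP
coupling is OLS of LTP AUC on √(I/O AUC) with a 90% CI on the slope.

## Synthetic generators

The cohort simulator draws visit times per animal from a
nonhomogeneous Poisson process with rate
λ(t) = max(0, M + A·cos(2π(t−φ)/24)) by thinning (exact for bounded
rates). Defaults — M = 3 visits/h, A = 2 visits/h, acrophase at
midnight, 12 animals/group, 7 days — are sized to a middle-aged female
mouse cohort in a four-corner cage. In-window corner choice is correct
with p(n) = p₀ + (p_max−p₀)(1−e^(−n/τ)) on the 1-based in-window trial
index n (so τ → 0 with p_max = 1 reduces exactly to the all-correct
stream and criterion at trial 9); defaults τ = 30 trials, p_max = 0.85.
A reversal switches the rewarded corner to its diagonal and rescales
the learned index by a configurable fraction (default full reset, since
renewed learning after reversal is the observed pattern but carryover
is not quantified). Lick counts per rewarded visit are negative
binomial (mean 30, size 5) — overdispersed, as licking bouts are.
Every visit's class and correctness, each animal's trial sequence and
its sequential-test decision are recorded in `truth.json` at generation
time, so full-loop recovery is testable exactly. The simulator treats
animals as independent: leader–follower structure is *not* emergent,
and test fixtures for it are scripted. Same seed ⇒ byte-identical CSVs
(times rounded to ms before labels are derived, so files and in-memory
labels agree exactly).

The sweep generator produces a flat baseline, a biphasic artifact
inside the blank window, and a field potential whose linear onset ramp
(1.5 ms to peak) encodes the sigmoidal I/O response at the sweep's
intensity; with zero noise the slope extractor recovers the programmed
slope to ~1e-6. Post-TBS sweeps are scaled by plateau/100 (optionally
decaying exponentially toward baseline), slices carry lognormal gain
variability, and LTP plateaus can be linearly coupled to the slice's
√(I/O AUC) to emulate an excitability–potentiation relationship.
What neither generator emulates: electrode drift, population spikes,
visit-level social interactions, door-hardware timing or LED cues —
so passing tests demonstrate correctness of the analysis chain, not
robustness to every artifact of real recordings.

## Problem sizes

Monte-Carlo checks use 10⁵ visits for chance-proportion labeling,
2×10⁴ replicates for the sequential-test error rates, 200 replicates
for cosinor acrophase recovery and ANOVA power/null calibration, and
20–40 replicate simulations for the ephys coupling sign — sizes chosen
so every stochastic assertion sits ≥ 3σ from its threshold while the
whole suite runs in well under a minute of compute per module.
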