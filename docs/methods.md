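# Methods

This note describes the model implemented by `pepsim`, the experimental
designs it simulates, the fixed parameterization and how it was calibrated,
and the limitations of the implementation.

## The model

`pepsim` simulates color-word Stroop performance with a small
interactive-activation network coupled to an instance (episodic) memory.
The model has no conflict monitor and no attention controller; all of its
context-sensitive behavior emerges from storing one episode per trial and
retrieving past episodes in parallel on later trials.

### Network

* **Input nodes** — four color words, four colors, and two screen
  locations (up/down). A node is driven toward a signal level by leaky
  integration while its stimulus is on screen and decays toward a noise
  floor otherwise. Gaussian noise perturbs every node on every cycle.
* **Identity nodes** — four color concepts. Word and color inputs feed the
  matching identity node; locations do not (location is task-irrelevant
  for color naming). Identity nodes compete through subtractive lateral
  inhibition. This competition is the source of the Stroop congruency
  effect: an incongruent word supports a rival identity and slows the
  correct one.
* **Response nodes** — four response accumulators, one per color. Each
  accumulates evidence from its identity node plus episodic facilitation
  (below), without leak, clamped at zero. The model responds when an
  accumulator crosses the current threshold. The number of cycles from
  target (color) onset to that crossing is the simulated response time;
  one cycle stands in for roughly one millisecond.

A trial presents the word alone for `word_lead_cycles` (100) cycles at the
trial's location, then removes the word and shows the color patch at the
same location until a response or `max_trial_cycles` (2000) elapse.
Timed-out trials are flagged, encoded with the deadline as their RT, and
excluded from RT analyses.

### Episodic memory

After every trial one **episode** is stored: word, color, location,
response made, and the trial's RT, with a response weight and a time
weight both starting at 1. On each cycle of each later trial, every
episode is activated in proportion to its overlap with what is currently
on screen: it sums the current activation of the input nodes it encodes,
and the sum is scaled by `match_mismatch_ratio` once for every feature
bank in which the episode differs from something currently presented.
Full matches therefore dominate, partial matches are retrieved more
weakly, and episodes from the other location are gated down as a whole —
a conjunctive, MINERVA-2-style similarity. A bank with nothing presented
(the word after target onset) imposes no penalty.

Retrieved episodes drive two learning mechanisms:

1. **Contingency learning.** Each episode pushes the response it encodes,
   proportional to its activation and its response weight
   (`facilitation_gain` scales the boost). Stimuli that reliably predict
   a response come to facilitate it; because retrieval is conjunctive,
   a word+location compound can predict a response in one location but
   not the other.
2. **Temporal learning.** The **pace** — the expected time to respond —
   starts each trial as a blend of the previous trial's pace and RT
   (`pace_blend`) and is pulled each cycle toward the activation- and
   time-weight-weighted mean of the RTs encoded in the retrieved episodes
   (`pace_update_rate`). The response threshold dips below baseline by
   `dip_depth` in a Gaussian of width `dip_width` centred on the pace:
   the model prepares to respond when it expects to respond ("rhythmic
   responding"). Faster expected times therefore yield faster responses,
   and each location context acquires its own rhythm.

Both weights of every episode are weakened multiplicatively in proportion
to its activation at the end of each trial (`time_weight_decay`), so
recent events dominate both predictions.

The **temporal lesion** fixes the threshold at baseline and changes
nothing else, isolating the contingency mechanism.

## Designs

All designs use 4 blocks of 96 trials (the contingency stream, 4 x 48),
shuffled within block.

* **Simulation 1 (simple CSPC).** In the mostly congruent (MC) location
  each word appears in its own color 9 times per block and once in each
  other color (75% congruent); in the mostly incongruent (MI) location
  every word x color cell occurs 3 times (75% incongruent). Every item is
  biased. The CSPC effect is the congruency effect at MC minus the
  congruency effect at MI.
* **Simulation 2 (inducer/diagnostic).** Two inducer words (red, green)
  are 100% congruent in one location and reciprocally 100% incongruent in
  the other (12 per cell per block); two diagnostic words (blue, yellow)
  are 50% congruent in both locations (6 per cell per block). Diagnostic
  items carry no contingency bias, so a diagnostic-item CSPC effect can
  only come from the temporal mechanism generalising across items within
  a location.
* **Contingency stream.** A single-location stream in which each word is
  paired with one fixed *incongruent* color on 9 of its 12 presentations
  per block (75%). Run with the temporal lesion, the high-minus-low
  contingency contrast (computed among incongruent trials only) measures
  contingency learning in isolation.

## Analysis

Cell means are computed within each simulated participant first (correct,
non-timeout trials for RT; errors as a percentage of non-timeout trials),
then averaged across participants unweighted. Effects are paired
contrasts of per-participant cell means; one-sample t-tests across
participants are reported where relevant.

## Parameterization and calibration

A single fixed parameterization (`pepsim.DEFAULT_PARAMETERS`) is shared
by every reported simulation; the runner rejects any other
parameterization unless an explicit exploratory override flag is set.

The defaults are the product of a one-time calibration with two
prescribed targets: overall correct RT in the 700-900 cycle range, and a
congruency effect of standard Stroop magnitude (roughly 100-150 cycles).
Calibration was done on the Simulation 1 design only, holding one
parameter subset at a time; no per-experiment refitting is performed.

| parameter | value | role / rationale |
| --- | --- | --- |
| `input_noise_sd` | 0.006 | per-cycle node noise; large enough that the word-primed wrong response occasionally crosses during early threshold dips (producing rare, incongruent-concentrated errors), small enough not to wash out dip timing |
| `input_signal_gain` | 1.0 | asymptotic input activation (unit scale) |
| `input_growth_rate` | 0.01 | leaky-integration rate; sets the activation timescale |
| `lateral_inhibition` | 0.10 | identity competition; sets the congruency-effect magnitude |
| `identity_to_response_gain` | 0.0007 | evidence rate; with the threshold, sets overall RT |
| `facilitation_gain` | 8e-5 | episodic boost; sets the contingency effect (~10-15 cycles) |
| `baseline_threshold` | 1.12 | with the evidence rate, puts mean correct RT in 700-900 |
| `dip_depth` | 0.42 | threshold drop at the expected time |
| `dip_width` | 90 | wide dips are what let an expected-time advantage span the natural RT spread; narrow dips made the temporal CSPC fragile |
| `pace_blend` | 0.5 | start-of-trial pace mix (previous pace vs previous RT) |
| `pace_update_rate` | 0.06 | within-trial convergence of the pace to the retrieved RTs |
| `time_weight_decay` | 0.05 | fast decay keeps the pace tracking recent RTs; slower decay made the pace lag practice speed-up and reversed the CSPC |
| `match_mismatch_ratio` | 0.50 | conjunctive retrieval gate; smaller values made pace item-specific rather than context-specific (reversing the temporal CSPC), larger values leak contingency knowledge across locations |
| `word_lead_cycles` | 100 | word-alone preview |
| `max_trial_cycles` | 2000 | response deadline from target onset |
| `initial_pace` | 800 | first-trial expected RT (near the calibrated grand mean) |

Under these defaults (100 participants per run): Simulation 1 normal
model CSPC ≈ 37 cycles; temporal-lesioned CSPC ≈ 11 cycles; Simulation 2
diagnostic-item CSPC ≈ 22 cycles; contingency-alone benefit ≈ 14 cycles;
mean correct RT ≈ 709 (normal) and ≈ 850 (lesioned) cycles; error rates
≈ 0.2-0.9%, concentrated on incongruent trials (no speed-accuracy
trade-off).

## Limitations

* **Magnitudes, not exact reproduction.** The calibration is re-derived,
  not copied, so effect sizes match published values only to within broad
  tolerance (the normal-model CSPC here is ~37 cycles vs a published 54;
  the diagnostic-item CSPC ~22 vs 27).
* **Error rates are very low** (well under 1%). The error *pattern* is
  right — errors concentrate on incongruent trials — but error-rate
  magnitudes should not be compared with human data.
* **Error CSPC interaction is not reproduced.** The congruency effect in
  errors is positive in both contexts, but its context difference is near
  zero under this parameterization, whereas RT shows a robust CSPC
  interaction.
* **No inter-individual variation.** All participants share one
  parameterization; only noise streams and trial orders differ.
* **Single task family.** Only the two-location color-word CSPC designs
  and a single-location contingency stream are implemented; transfer
  phenomena (sequence effects, list-level PC, practice power laws) are
  out of scope.
* **One cycle ≈ one millisecond is a convention**, not a fitted
  equivalence.
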