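# Methods

This note documents the models, conventions and design choices behind
`orsim`, in the spirit of a statistical package's methods appendix.  It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Scenario scripts and alarm semantics

A scenario script is a table with one row per second.  Timestamps are the
integers 1…N (N = 1800 for the 30-minute default); the header row of a file
is not counted, so "timestamp 752" is data row 752.  Tracks are float64;
alarm columns are {0, 1} and are *derived* state: a pure function of the
tracks and the active rule set, so re-evaluation is idempotent and a script
read from disk can always be re-verified.

Alarm rules are level-triggered and non-latching by default — the column is
1 exactly while the condition holds and returns to 0 when it clears —
because the scripted cell value tracks the condition.  A `latching: true`
config option holds an alarm on once triggered.  Threshold comparisons are
strict (`value < threshold` for low alarms): an HR track that touches
exactly 60 bpm has not yet "dropped below 60".

The shipped adult thresholds (HR <60/>100 → `cardmed`, SpO₂ <90 →
`oxyhigh`, NIBP_sys <90/>160 → `bpmed`, EtCO₂ <25/>60 → `co2med`, PIP >40 →
`airwaymed`, TV <200 → `airwayhigh`, the last a low-volume surrogate for a
circuit disconnect) are editable YAML.  Only the HR<60 bradycardia
threshold and the `cardmed` identifier are externally fixed reference
points; the rest are commonly used adult defaults.

Two file dialects carry the identical layout (`t`, parameter columns, alarm
columns): CSV (UTF-8) and XLSX.  Round trips are bit-exact — CSV floats use
shortest-round-trip repr, XLSX stores binary doubles.  Readers validate the
header, timestamp consecutiveness and alarm-cell binarity and report the
offending row/column; writers enforce configurable physiological range
checks per parameter.

## The scenario library

Events are piecewise-linear excursions: from baseline, ramp to a plateau,
hold, ramp back, reaching baseline *exactly* at the excursion end — so every
eventful script differs from baseline on exactly three disjoint intervals,
one per ten-minute window, and ends at baseline.  Baselines are clinically
normal constants (HR 75, SpO₂ 98, NIBP 120/80, MAP 93, EtCO₂ 35, RR 12,
PIP 20, TV 500).

Two trajectory facts are anchored externally: the hypovolemia event's HR
rises gradually over 300 s to a plateau *below* the high-HR alarm threshold
before systolic pressure falls through the low-BP threshold; and the
symptomatic-bradycardia HR ramp first passes strictly below 60 bpm at
timestamp 752.  The bradycardia onset is derived from the configurable
crossing anchor: with baseline b, target g, ramp length R and threshold θ,
the first integer step strictly past θ is j = ⌊R·(b−θ)/(b−g)⌋ + 1, so the
ramp starts at `crossing_at − j` (651 under the defaults: 75→45 over
200 s).  All other amplitudes and timings are clinically plausible
reconstructions, shipped in the editable `scenarios.yaml` and exercised by
tests only through their invariants (window containment, normalization,
which alarms fire).

Generation is deterministic given (name, config); there is no hidden random
state.

## Logs, latencies and timelines

Response entries carry a closed category vocabulary (detection,
differential, intervention, distractor_answer, other).  Human raters infer
these classes from free text; the toolkit carries the tag explicitly
because no published coding rules exist for the inference.  The log CSV
schema is `t, subject_id, category, text, scenario` — the scenario column
makes the file self-describing so read(write(log)) is lossless.

Latency for (subject, event, category) is the time from event onset (the
first second any track departs baseline, as recorded in the event manifest)
to the subject's **first** entry of that category inside the event window.
Subjects with no qualifying entry are excluded from the mean and counted as
misses, not imputed — missed detections are scored separately by the
checklist.  Cohort averages are computed per event (not per scenario).

The timeline bundle contains only the opaque subject code, preserving
blinding.  The stem plot's y axis is purely positional (bands at heights
3/2/1) and is hidden.  Rendering is deterministic (fixed metadata, Agg
backend): two renders of the same bundle are byte-identical, which is what
the test suite checks in place of a stored golden image.

## Instruments

GRS: five items, each 1–7, total 5–35.  CMC: eleven items in three
subscales; positive items 0/1/2, penalty items ("missed detection", "one or
more incorrect diagnoses", "one or more inappropriate actions") negative.
The penalty magnitudes are configurable and default to the mirrored scale
{0, −1, −2} — published forms do not print the magnitudes, and the
resulting −6…16 total range is consistent with observed score ceilings
near 14–15.  Scoring is additive, so any item-subset total plus its
complement equals the full total; item-removal variants (the GRS without
the crisis-resolution item, the CMC without the three penalty items) are
first-class arguments rather than separate instruments.

## Psychometrics

All variances are sample variances (ddof = 1).  Internal consistency is
computed on the rater-averaged item matrix; corrected item-total
correlation is Pearson r between an item and the sum of the *other* items;
α-if-deleted is α recomputed on the reduced matrix.

Interrater reliability uses the two-way single-measure ICC from ANOVA mean
squares.  Both variants are always computed and reported, because the
consistency form ICC(C,1) ignores a systematic rater offset while the
absolute-agreement form ICC(A,1) penalizes it, and analyses in this field
are frequently ambiguous about which was used; the CLI default display is
consistency.  The F test is F = MS_R/MS_E on (n−1, (n−1)(k−1)) df for both
variants; the "not significant" flag uses p > 0.05 and no multiple-testing
correction is applied, matching standard practice in first-round instrument
validation.  Aggregate ("all scenarios") reliability pools subject×scenario
cells as independent rows (n = subjects × scenarios); per-scenario blocks
use n = subjects.  A cell with no variance anywhere — e.g. a penalty item
scored 0 by both raters throughout — yields an `incalculable_zero_variance`
flag and NaN estimate, never a number.  Estimates may legitimately be
negative and are flagged as such.

Spearman rank correlation delegates to `scipy.stats.spearmanr` (midrank
ties, t-approximation p-values); the test suite checks it against an
independent midrank+Pearson computation.

Effect sizes: subjects' aggregate totals (averaged over raters and all
scenarios) are split (a) at the median into lower/upper halves (the middle
observation is excluded when n is odd) and (b) into the 2nd vs 3rd
quartiles; a third contrast compares two named scenarios across subjects.
For every row, difference = mean₂ − mean₁, percent difference =
difference / mean(mean₁, mean₂) × 100, and Cohen's *d* = difference divided
by the SD pooled over **all** subjects' aggregate scores.  That last
convention (full-sample SD, not the classical within-group pooled SD) is
deliberate: it is the documented convention of the reference analyses this
pipeline mirrors, and it is what makes reported d values reproducible from
the printed group means.

## Synthetic generators

Rater model: each subject×scenario cell draws a latent ability
a ~ N(0, σ_T) shared by all items, and each rater a holistic cell-level
error e_r ~ N(0, σ_E) (raters mis-judge the performance as a whole — a halo
assumption — rather than each item independently), plus optional per-item
jitter σ_item.  Observed scores are `clamp(round(center + a + bias_r + e_r
+ jitter))` onto the item's discrete scale.  With σ_item = 0 the implied
continuous-scale consistency ICC is σ²_T/(σ²_T+σ²_E) at both the item and
the instrument-total level; rounding and clamping attenuate estimates by a
few percent on the 7-point scale (more on the trichotomous scale, whose
default continuous SD is therefore smaller).  This is a modelling choice
for testability, not a claim about human raters: real raters have
item-specific biases, non-normal score distributions and floor/ceiling
behaviour the model does not emulate, so passing parameter-recovery tests
demonstrates correctness of the estimators under the model, not validity of
any real instrument.

Responder model: per event, with probability 1 − miss, a detection entry at
onset + L_det, then differential and intervention entries chained at
further Normal latencies (defaults 60 ± 10, 90 ± 20, 120 ± 30 s — plausible
response times for monitored emergencies); distractor answers arrive as a
Poisson stream (default 0.5/min).  Latencies are truncated at zero; entries
past the scenario end are clipped to the final second and marked
`[clipped]`.  Seeds are mandatory arguments everywhere; no global random
state is used, and equal seeds give byte-identical outputs.

## Problem sizes and numerical choices

The test suite runs the full study design (20 subjects × 6 scenarios × 2
raters) for parameter recovery, with 20 seeds per condition, and 200 random
matrices (≤ 20×11) for oracle-equivalence checks at 1e-10 — small enough to
complete in seconds while matching the design the statistics are meant for.
Degenerate inputs are rejected early with typed errors (domain, schema,
validation, missing-data) rather than propagated as NaN, except where a
flagged NaN is the documented result (incalculable reliability cells).

## Known limitations

* The scripted patient does not react to interventions (fixed-script
  design, as in screen-based assessment practice); closed-loop physiology
  is out of scope.
* Free-text classification into response categories is carried as data, not
  inferred; an NLP mapping would be needed for uninstrumented human logs.
* Only two-rater designs are supported by the report layer (the ICC core
  accepts k ≥ 2 columns).
* Five of the six event trajectories are reconstructions with editable
  defaults; analyses that depend on their exact shapes should treat the
  config as the source of truth.
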