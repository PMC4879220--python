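# orsim

A headless toolkit for **screen-based operating-room simulation** and the
**psychometric validation of performance-assessment instruments**.

In screen-based OR simulation a trainee (e.g. a first-year anesthesia
resident) watches scripted monitor and ventilator values evolve second by
second during a simulated "lunch break", and types observations, diagnoses
and interventions into a text box.  Because expert raters later see only the
timestamped entries — never the trainee — the assessment is fully blinded to
identity, gender and experimental condition.  `orsim` implements that whole
workflow without any GUI or audio:

* **Scenario scripts** — per-second tables (1800 rows for a 30-minute
  scenario) of physiological/ventilator parameters (HR, SpO₂, NIBP, EtCO₂,
  RR, PIP, TV, …) with binary alarm columns computed from editable
  adult-patient thresholds.  Alarm identifiers are symbolic IEC 60601-1-8
  category/priority names such as `cardmed` (medium-priority cardiac alarm).
* **Scenario library** — two uneventful and two eventful scripts; the
  eventful ones carry three intraoperative events each (circuit disconnect,
  symptomatic bradycardia, endobronchial tube migration; hypovolemia,
  pulmonary embolism, light anesthesia), one per ten-minute window, with all
  parameters returning to baseline between events.
* **Session playback** — replaying a script against a response stream and
  logging category-tagged, timestamped entries to CSV.
* **Blinded rating timelines** — the three-band stem plot raters work from:
  scripted events/alarms on top, the subject's entries in the middle,
  cohort-mean detection/differential/intervention times at the bottom.
* **Instruments** — a five-item, seven-point Global Rating Scale (GRS,
  totals 5–35) and an eleven-item, three-subscale Crisis Management
  Checklist (CMC) scored yes/marginal/no = 2/1/0 with three penalty items
  scored 0/−1/−2 (totals −6…16).
* **Psychometrics** — Cronbach's α, corrected item-total correlations and
  α-if-item-deleted; two-way single-measure intraclass correlations in both
  the consistency ICC(C,1) and absolute-agreement ICC(A,1) variants with F
  tests; Spearman rank correlation; and median-split / quartile-split /
  scenario-contrast effect sizes (raw difference, percent difference,
  Cohen's *d*).
* **Synthetic raters & responders** — generators with known ground truth
  (true-score variance, rater bias, noise; latency distributions and miss
  probabilities) so that the entire pipeline is testable end to end.

## The statistics at the core

For an observations × items matrix, internal consistency is

> α = k/(k−1) · (1 − Σⱼ σ²ⱼ / σ²_total)   (sample variances, ddof = 1)

For an n × k rater table with ANOVA mean squares MS_R (rows), MS_C
(columns) and MS_E (residual), the single-measure intraclass correlations
are

> ICC(C,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E)
> ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k·(MS_C − MS_E)/n)

with significance from F = MS_R/MS_E on (n−1, (n−1)(k−1)) df.  Cells with
no variance anywhere (e.g. a checklist item scored zero by both raters for
every subject) are flagged *incalculable* rather than reported as numbers.
Cohen's *d* in the effect-size tables is the raw group difference divided by
the standard deviation pooled over **all** subjects' aggregate scores, and
percent difference is the difference divided by the average of the two
group means.

## Worked example

```bash
# a synthetic study: 20 subjects x 6 emergency scenarios, 2 raters,
# generated at a true consistency ICC of 0.8
orsim simulate-raters --icc 0.8 --subjects 20 --scenarios 6 \
      --instrument grs --seed 17 --out ratings.csv
orsim reliability --ratings ratings.csv --instrument grs
orsim effect-sizes --ratings ratings.csv --instrument grs
```

prints (abridged):

```
Cronbach's alpha (grs, all items): 0.984
Cronbach's alpha without ['perceived_crisis_resolution']: 0.980
scope  name  scenario items             variant   estimate   n        F ...
total total  all      all               consistency 0.739190 120 6.668429
total total  all      excluding_flagged consistency 0.741144 120 6.726298

                    mean1    sd1   mean2    sd2  difference  percent_difference  cohens_d
median_split       18.133  1.674  22.158  0.871       4.025              19.979     1.650
quartile_split     19.433  0.904  21.600  0.501       2.167              10.561     0.888
scenario_contrast  17.625  7.309  22.575  8.184       4.950              24.627     2.029
```

The total-score consistency ICC (0.74, n = 120 subject×scenario rows)
recovers the generating value of 0.8 up to the attenuation introduced by
rounding continuous ratings onto the 7-point scale; the α near 1 reflects
that all five items score the same latent ability.  The median-split row
contrasts the weaker and stronger halves of the cohort: a 4.0-point raw
difference (≈20 % of the mid-mean), Cohen's *d* = 1.65 against the
full-cohort SD.

Scenario generation is just as direct:

```bash
orsim generate-scenario --name eventful_1 --out script.csv --manifest-out manifest.json
orsim simulate-subjects --scenario eventful_1 --n 20 --seed 3 --out logs/
orsim timeline --script script.csv --manifest manifest.json \
      --logs logs/ --subject S07 --out s07.png
```

`script.csv` has a header row plus 1800 data rows; in `eventful_1` the HR
track crosses below the 60 bpm bradycardia threshold so that the `cardmed`
column first flips to 1 at timestamp 752.

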