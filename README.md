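# aphasiakit

Scoring, norming and psychometric-validation toolkit for a 13-subtest
computerized aphasia battery.

Comprehensive aphasia batteries assess language at several linguistic
levels (phonological, lexical-semantic, syntactic, discourse) across
three domains — auditory comprehension, repetition, and oral production.
Standardizing such a battery means turning raw per-trial responses into
quantitative scores, deriving normative cutoffs from healthy controls,
classifying patients and grading severity, and demonstrating that the
instrument is reliable and valid.  `aphasiakit` implements that entire
quantitative pipeline for clinicians and researchers working with
tablet-based aphasia assessment data, together with a synthetic-cohort
generator so every stage can be exercised and validated without access
to patient data.

## The model

**Scoring.**  Each of the 13 subtests produces item scores on a legal
lattice: binary credit for choice and naming items; 1 / 0.5 / 0 for
repetition items (half credit for a phonological paraphasia); per-word
credits minus a single one-point word-order penalty for sentence
repetition; four binary criteria (0–4) per produced sentence; four
5-point analytic rating scales (4–20) for discourse production; and
pair-gated credit for discourse comprehension (a credit requires both
verification statements about the same story element to be correct).
Subtest accuracy is `100 · raw / max`.  The composite **General Aphasia
Quotient** is the unweighted mean of the 13 subtest percentages,

```
GAQ = (1/13) Σᵢ 100 · rawᵢ / maxᵢ   ∈ [0, 100],
```

defined only when every subtest was administered.

**Norms.**  Per subtest and age cohort (young 18–59 / elderly 60+), the
impairment cutoff is the 5th percentile of the control distribution
after a one-pass outlier screen (scores < 90% *and* > 3 SD below the
cohort mean); a cutoff at the subtest maximum is adjusted to the next
achievable score (for a 24-item binary subtest, 23/24 = 95.83%).  The
diagnostic GAQ cutoff is chosen per cohort from a ROC scan maximizing
sensitivity + specificity with "GAQ ≤ threshold" as the positive call.
Severity bands are the 34th/67th percentiles of impaired patients'
scores pooled across cohorts: severe ≤ P34 < moderate < P67 ≤ mild ≤
cutoff < normal.

**Psychometrics.**  Item passing rates and corrected item-total
correlations (< 0.2 flagged); Cronbach's alpha with Feldt confidence
intervals; ICC(A,1) — two-way random-effects, absolute-agreement,
single-measure intraclass correlation — for inter-rater and test-retest
reliability; Pearson and first-order partial correlation matrices with
Bonferroni control (.05/78 for 13 subtests); Welch t, Fisher exact, and
Kruskal–Wallis + Dunn/Holm age-band pooling.

**Synthetic cohorts.**  A single latent ability θ drives all subtests:
binary items follow a two-parameter logistic model with a chance-level
guessing floor, multi-point items a nested-threshold graded model.
Item difficulties are solved numerically so the patient population
(θ ~ N(0,1)) reproduces the passing-rate ordering a standardization
cohort exhibits, while controls (θ ~ N(3.3, 0.45)) sit near ceiling
except on the discourse tasks and sentence production.  Rater noise,
retest sessions and a correlated external severity total (an ASA-like
score) are layered on top.

## Worked example

```bash
aphasiakit simulate --seed 7 --out-dir sim
aphasiakit score --trials sim/pwa_trials.csv --out-dir pwa
aphasiakit score --trials sim/nhi_trials.csv --out-dir nhi
aphasiakit norms --nhi-profiles nhi/profiles.csv \
                 --pwa-profiles pwa/profiles.csv --out-dir norms
aphasiakit report --profiles pwa/profiles.csv \
                  --norms norms/norms.csv --participant PWA-y0003
```

The `norms` step prints the ROC-selected diagnostic cutoffs,

```
elderly: GAQ cutoff 93.13 (sens 0.951, spec 1.000)
young: GAQ cutoff 91.22 (sens 0.955, spec 1.000)
```

meaning a patient in the young cohort is flagged for aphasia when their
GAQ is at or below 91.22%, and that rule identifies 95.5% of the
simulated patients while flagging none of the controls.  The report
then grades one patient:

```
PWA-y0003 (young) — GAQ 81.11: APHASIA (moderate)
  nonword_discrimination     86.36%  moderate
  lexical_decision           95.83%  mild
  noun_comprehension        100.00%  normal
  ...
  discourse_production       40.00%  severe
```

Each line compares the subtest accuracy with its cohort cutoff and the
pooled severity bands — this profile shows spared single-word
comprehension with a severe discourse-production deficit, the kind of
multidimensional characterization the battery is designed to produce.

The same stages are available as library functions
(`aphasiakit.score_trials`, `aphasiakit.build_norm_table`,
`aphasiakit.fit_roc`, `aphasiakit.icc_a1`, ...).

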