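# Methods

This note documents the statistical procedures `aphasiakit` implements,
the design choices made where convention leaves room, what the
synthetic-data generator does and does not emulate, and the problem
sizes the validation suite uses.

## Scoring rules

Item scores live on per-subtest lattices (see `aphasiakit.catalogue`).
Decisions taken where the scoring conventions needed pinning down:

- **Sentence repetition** is scored per word (1 correct; 0.5
  phonological paraphasia or word-form error; 0 omission/other), minus
  a single one-point penalty if word order was altered anywhere in the
  sentence.  The penalized score is floored at 0: accuracies are
  defined on [0, 100] and a negative raw score has no interpretation.
  Content and function words carry identical weight.  The default item
  template uses six 3-word and six 5-word sentences (raw maximum 48);
  real transcripts carry their own word counts.
- **Phonological paraphasia** ("more than half the target spared,
  target recognizable") is a coder judgement encoded in the annotation;
  the engine never re-derives it from transcriptions.
- **Discourse production** ratings are integers 1–5 on four scales, so
  the lowest attainable accuracy is 4/20 = 20% while the subtest is
  attempted — a structural floor worth remembering when comparing raw
  accuracies across subtests.
- **Discourse comprehension** defaults to pair-gated credit (8 pairs,
  credit only when both statements about a story element are correct —
  the guessing safeguard).  A per-statement mode (16 credits) mirroring
  the application's raw log is available behind
  `per_statement_discourse=True`; the two agree only when errors come
  in pairs.
- **Self-corrections** carry no penalty and only the final response is
  scored; a single requested repetition of the stimulus is free;
  dysarthric distortions are never penalized.  All three are annotation
  semantics, enforced at coding time.
- Accuracies are computed at full precision and rounded half-up to two
  decimals only for presentation.

## Normative pipeline

- **Outlier screen** (controls only, per subtest, per age cohort): a
  score is removed iff it is below 90 *and* more than 3 SD below the
  cohort mean, with mean/SD from the full sample in a single pass.  The
  GAQ is never screened — averaging 13 subtests already damps single
  aberrant values.
- **Quantiles** use linear interpolation between order statistics
  (type 7), the default of the mainstream statistical environments;
  the convention is configurable (`quantile_method`) because printed
  norm tables rarely pin it down.
- **Ceiling adjustment**: when the 5th percentile equals the maximum,
  the cutoff becomes the largest achievable score strictly below the
  maximum on the subtest's lattice (binary: max−1 item; half-point
  lattices: max−0.5; rating scales: max−1 point).  Implemented
  generically from the lattice step, so it extends beyond the binary
  case.
- **ROC cutoff**: candidate thresholds are midpoints between
  consecutive distinct pooled GAQ values plus ∓∞ sentinels; positive
  means GAQ ≤ threshold; the selected threshold maximizes
  sensitivity + specificity, with ties broken toward the larger
  threshold (favoring sensitivity at equal sums).  Equivalence with an
  exhaustive threshold scan is asserted in the test suite.
- **Severity bands** are the 34th/67th percentiles of impaired
  (≤ cutoff) patient scores pooled across the two age cohorts; cutoffs
  stay cohort-specific while bands are shared.  If a pooled band
  exceeds a cohort's (lower) cutoff it is clipped to that cutoff so the
  band ordering invariant holds.  Degenerate bands (P34 = P67) leave an
  empty moderate range; scores at the shared value classify severe.
- Severity assignment: normal > cutoff; mild [P67, cutoff]; moderate
  (P34, P67); severe [0, P34].

## Psychometric statistics

- **Cronbach's alpha** on listwise-complete rows; zero-variance items
  are dropped with a warning rather than failing the subtest.  The
  default confidence interval is Feldt's exact F interval
  ((1−α̂)/(1−α) ~ F with (n−1), (n−1)(k−1) df); a participant bootstrap
  is available (`ci_method="bootstrap"`).  Both are offered because
  published tables often omit the CI method.
- **ICC(A,1)** follows the McGraw–Wong mean-squares form
  (MSR−MSE)/(MSR+(k−1)MSE+(k/n)(MSC−MSE)) with their F-based interval
  on Satterthwaite degrees of freedom.  The ANOVA decomposition is
  written out directly and verified against a brute-force oracle and
  against pingouin.
- **Correlation matrices** use pairwise-complete observations; pairs
  with fewer than 4 complete rows are marked unavailable.  The partial
  correlation is the first-order formula
  r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)), asserted equal to
  the residualization route to 1e−10.  Bonferroni families: 13
  (subtest-wise cohort contrasts), 26 (group contrasts in two cohorts),
  78 (all subtest pairs).
- **Dunn's post hoc** after Kruskal–Wallis uses tie-corrected rank
  variances and Holm adjustment; groups whose pairwise differences are
  all non-significant land in the same recommended pool (connected
  components), which is the age-band pooling logic.
- Two-sided p-values throughout; missingness is pairwise for
  correlations and listwise for alpha/ICC.

## Synthetic cohorts

The generator emulates the *statistical structure* of a standardization
study, not its content: no transcripts, lesions or aphasia subtypes —
a single latent ability θ with per-subtest discrimination is the whole
behavioural model, justified by the strong inter-subtest correlations
such batteries show.

- **Item model.**  Binary items: P(correct) = g + (1−g)·σ(a(θ−b_j))
  with the guessing floor g at the format's chance level (0.25 for
  4-alternative choice, 0.5 for 2-alternative/yes-no, 0 for open
  production).  Multi-point items pass nested thresholds sharing one
  uniform draw per credit unit — scores stay on the legal lattice and
  are monotone in θ.  Word-order errors in sentence repetition occur
  with probability 0.3·σ(−(θ+0.5)).
- **Calibration.**  Item difficulty centers are solved (Gauss–Hermite
  quadrature + Brent root-finding) so the reference patient population
  θ ~ N(0, 1) hits per-subtest mean passing-rate targets whose family
  means order as comprehension (≈0.87) > repetition (≈0.62) >
  production (≈0.57).  Controls are drawn at θ ~ N(3.3, 0.45), which
  puts binary comprehension near ceiling, keeps the discourse tasks and
  sentence production off ceiling, and yields a GAQ group separation
  whose attainable sensitivity + specificity is ≈1.94 — the regime in
  which a well-constructed battery operates.  Elderly controls receive
  an extra difficulty shift on the four phonology/memory-loaded
  subtests (discourse comprehension, nonword repetition, sentence
  repetition, sentence production) only.
- **Calibration is anchored**, not floating: item difficulties are
  solved against the fixed reference population, so drawing a milder
  sample (the chronic retest spec, θ ~ N(1.2, 0.7)) pushes single-word
  comprehension to ceiling instead of silently re-calibrating — which
  is precisely what produces the depressed test-retest ICC of
  near-ceiling subtests relative to repetition subtests.
- **Raters** perturb expressive item scores with Gaussian noise (plus
  an optional systematic shift) snapped back to the lattice; requesting
  rater noise on an automatically scored comprehension subtest is an
  error.  **Retest** adds N(0, session_sd) to θ (default 0.15) and
  regenerates items; the item stream can be reused to isolate the θ
  shift.  **Concurrent severity** is a logistic transform of θ plus
  noise calibrated from sample moments to hit a target correlation with
  the GAQ (default .925).
- **Randomness**: one root seed; sub-streams per (group, age cohort,
  subtest) plus a separate θ stream.  Identical (spec, seed) regenerate
  datasets exactly; generation is vectorized across participants.

What passing tests therefore show: the *pipeline* recovers generative
cutoffs and separations, and the reliability machinery reproduces the
qualitative ceiling-effect ordering.  What they cannot show: behaviour
under real response distributions (multidimensional deficits,
fluent/non-fluent profiles, item-level dependencies beyond one factor).

## Validation problem sizes

The suite's simulation-based checks use: 200 Monte-Carlo replicates of
the default cohort sizes (69/37 controls, 44/41 patients) for held-out
sensitivity/specificity recovery; 2000 controls × 20 seeds against a
100k reference draw for cutoff convergence; n = 5000 for the
compound-symmetry alpha limit and n = 500 for the ICC
variance-component limit; 200-patient chronic cohorts for the
test-retest ordering.  These sizes give the asserted tolerances
comfortable Monte-Carlo margins while keeping the default run fast.

## Known limitations

- One latent factor: partial-correlation structure beyond the shared
  severity factor is not emulated, so domain-specific residual
  correlation patterns cannot be studied on synthetic data.
- The trial dialect is this package's own versioned CSV; adapters are
  needed for other export schemas.
- Severity bands from small impaired samples (< 3 scores) are refused
  rather than extrapolated.
- No AUC inference, smoothed ROC curves, covariate-adjusted norms,
  factor models or reliable-change indices.
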