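# Methods

## Scope and data model

`uroscreen` analyses paired per-specimen tables: an instrument readout
(BACT, WBC, YLC, EC counts per µL; optional B_FSC/B_FLH channel values in
"ch"; a categorical flag; a training/validation cohort tag) and a culture
outcome (negative / positive / yeast / contaminated; a CFU/mL category for
positives, with thresholds at 10^4 and 10^5; up to two organisms with Gram
classes — more than two species is reported as contamination with no
organism list). Counts printed by the instrument as ×10^6/L are numerically
identical to /µL; the package uses /µL throughout.

Bacterial analyses exclude yeast-positive and contaminated cultures from the
denominator (a cohort of N specimens with k yeast cultures analyses N − k
against bacterial culture); the join step reports these exclusions.

## Screening statistics

* **Positivity convention.** A call is positive iff score ≥ cutoff: higher
  bacterial counts indicate infection, and tabulated cut-offs are lower
  bounds on positive calls.
* **ROC.** The empirical curve is evaluated at every distinct observed score
  plus ±∞ sentinels. The trapezoidal AUC of this curve equals the
  Mann–Whitney concordance probability with ties counted ½; the test suite
  verifies this identity exactly against brute-force pair counting.
* **AUC confidence interval.** DeLong's variance estimator with midranks
  (handles ties), Wald interval clipped to [0, 1]. At least 10 samples per
  class are required. DeLong is the default in the common clinical ROC
  software, and no pre-installed statistics library exposes it, so it is
  implemented here directly.
* **Cut-off at a sensitivity target.** The largest cutoff whose achieved
  sensitivity is ≥ the target. Sensitivity is non-increasing in the cutoff,
  so this maximizes specificity subject to the floor; the cutoff at the
  minimum observed score always attains 100% sensitivity, so any target in
  (0, 100] is attainable when positives exist.
* **Workload accounting.** culture_reduction = (TN+FN)/N and
  false_negative_rate = FN/(TN+FN), both as percentages. On unrounded
  values, culture_reduction × N recovers TN+FN exactly.
* **Rounding.** Reported percentages are rounded half-up to one decimal and
  AUCs to three decimals; unrounded values are retained on every result
  object. Undefined metrics (zero denominators) are reported as undefined
  (`None`), never as 0.
* **Combined marker.** The BACT+WBC combination is a linear logistic score
  on log(count+1), fitted by maximum likelihood; zero-variance covariates
  are dropped, so the score degenerates gracefully to the informative
  marker. The combination rule is a design choice of this package — only the
  ordering of scores matters for ROC purposes.
* **Group comparison.** Medians with a two-sided Mann–Whitney U p-value
  (counts and channel features are right-skewed, so a rank test is the
  defensible default; scipy enumerates the exact null for small tie-free
  samples).

## Flag agreement

The flag × culture cross-tab is built over specimens with BACT above a
screening cut-off (default 42.2/µL). Culture categories: two species of the
same Gram class count as that class; a culture containing both classes is
"Mixed". Cohen's κ is unweighted (the categories are nominal) and requires a
square table, but the six instrument flag levels do not match the four
culture levels, so the collapsing is an explicit, reported parameter:

* `three_class` (default): {GP, GN, Other} — the GP/GN, Unclassified, UTI
  and No-flag levels, and the Mixed/Negative culture levels, all map to
  "Other".
* `four_class`: {GP, GN, Mixed, Negative} — the GP/GN flag plays the mixed
  role; Unclassified/UTI/No-flag play the negative role.

On the published 455-specimen contingency table these schemes give
κ ≈ 0.371 and ≈ 0.379 respectively, whereas the original report quotes
κ = 0.227 without stating its category mapping; no collapsing we tested
reproduces that value, so κ is always reported alongside its scheme
identifier and exact reproduction of the published κ is out of scope.

Scoring one Gram flag as a binary test binarizes flags as "target flag vs
all others" and cultures as "pure target class vs anything else" (a
both-class mixed culture is not a pure target and counts on the non-target
side). PPV is then the flag's correct-call fraction.

## The scattergram-angle rule

With B_FLH on the abscissa and B_FSC on the ordinate, the specimen's ray
slope is r = B_FSC/B_FLH and its angle from the abscissa is
θ = arctan r ∈ [0°, 90°). This axis convention is forced by the published
correspondence between a ratio cut-off of 0.55 and a 28° angle
(arctan 0.55 = 28.81°). Integer angle reporting truncates toward zero
(28.81° → 28°); the full-precision angle is retained on the classifier.

Fitting calls Gram-negative when r ≤ cutoff (GN has the lower ratio) and
maximizes the Youden index over midpoints between adjacent distinct observed
ratios, breaking ties toward higher sensitivity. A fit whose best J is ≤ 0
is flagged low-separability. Classification applies "θ < cutoff ⇒ GN"; an
angle exactly at the cut-off goes to the Gram-positive side (the rule is
strictly "below"), and the ratio form (r < tan θ_cut) and angle form agree —
both are property-tested. Specimens below the BACT screening cut-off, or
lacking channel values, are excluded from classification and counted.
Mixed cultures containing Gram-negative organisms are labelled GN for
validation purposes.

## Synthetic cohort generator

The generator emulates the study conditions the analyses assume; its
defaults are fixed calibrations, not tuning knobs.

* **Culture structure.** Yeast fraction 31/823; among non-yeast specimens,
  bacterial positivity 0.318 at ≥10^4 CFU/mL; among positives, 0.885 at
  ≥10^5; Gram-negative fraction 0.76 (from the organism table of the study
  emulated: 186 of 244 single-species isolates); two-species cultures at
  8/252, split 50% GN+GN / 25% GP+GP / 25% mixed; contamination probability
  0 by default. Cohort membership (training vs validation) is an
  independent draw at fraction 699/1522.
* **Counts.** BACT and WBC are lognormal per culture stratum. The log-scale
  parameters — BACT negative (µ=3.14, σ=2.34), positive (µ=8.55, σ=2.92);
  WBC negative (2.08, 1.5), positive (3.36, 1.8) — were obtained by
  quantile-matching published cut-off/sensitivity/specificity operating
  points, giving closed-form binormal AUCs of 0.926 (BACT) and 0.708 (WBC)
  and P(BACT ≥ 42.2 | positive) = 0.950. Only medians and AUCs were
  published, so the distributional family and spreads are this package's
  calibration choices.
* **Channel features.** (B_FSC, B_FLH) is bivariate lognormal per Gram
  class, correlation 0 by default (none was published): GN medians
  (31.6, 101.2) ch with log-spreads (0.28, 0.20); GP medians (59.8, 87.6) ch
  with (0.12, 0.08). These spreads put the population-optimal ratio rule at
  sensitivity 0.950 / specificity 0.933 for a 0.55 cut-off, matching the
  published training operating point; at 80 GN / 15 GP training draws the
  Youden fit recovers a cut-off within ±0.10 of 0.55 in ≈97% of replicates.
  A mixed GN+GP culture draws its features from the GN law (Gram-negative
  morphology dominates the cloud). Culture-negative and yeast specimens draw
  from a broad low-grade background law (medians 45/70 ch, log-spreads 0.5).
* **Flags.** Eligibility is exactly WBC ≥ 10/µL AND BACT ≥ 100/µL;
  ineligible specimens carry "No flag". Eligible specimens receive their
  class's nominal flag (GN?, GP?, or Unclassified for culture-negatives)
  perturbed by per-class misflag probabilities fitted once so the simulated
  cross-tab is qualitatively like the published one (GN column dominated by
  the GN flag, a weak GP column, many spurious flags among negatives).
  The flag stream is seeded separately from the count stream, so
  re-flagging a cohort is reproducible.

**What the generator does not emulate.** A single positive BACT stratum is
used, so the slightly higher discrimination real data shows at the ≥10^5
criterion is not reproduced; channel features are exactly lognormal with no
instrument background interference, carryover, antibiotic-pretreatment
effects, or within-class species structure; counts and channels are drawn
independently given class. Passing tests therefore demonstrate correctness
of the analysis machinery under the calibrated joint structure, not
instrument-level realism.

## Numerical conventions and edge cases

Seeded `numpy.random.Generator` everywhere; identical config ⇒ byte-identical
cohorts. Ties in the Youden scan break toward higher sensitivity, then the
scan order fixes the remainder deterministically. κ is undefined (reported
as such) when expected agreement is 1. Validation files report errors with
1-based line numbers; duplicate specimen ids and negative counts are
rejected at read time. The pipeline degrades gracefully: missing channel
columns skip the angle stage with a notice while the other stages complete.

## Problem sizes

Desk-scale checks (published contingency tables, closed-form identities) run
in milliseconds. Simulation-backed checks use cohorts of 10,000 specimens
for marginal/AUC recovery and 100 replicates at 80 GN / 15 GP for cut-off
recovery — sizes at which the empirical medians are stable to ≈0.3 ch and
the whole suite stays fast.
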