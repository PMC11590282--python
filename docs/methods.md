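# Methods

## Classification model

Every biomarker is "higher is positive": a subject with value *v* and cutoff
*t* is **positive** iff *v* ≥ *t* (boundary inclusive), **negative** iff
*v* < *t*, and **unclassified** when the value is absent. Missingness is a
first-class state throughout the package — absent values are `None` in
memory and empty/`NA` cells on disk, never sentinel numbers — because the
combination rules depend on it:

* **Performance.** Sensitivity and specificity are computed over classified
  subjects only; unclassified subjects leave both the numerator and the
  denominator. An empty classified class raises an error rather than
  reporting 0/0 as zero. These two measures are used (rather than accuracy
  or predictive values) because they are invariant to the case/control mix,
  which differs drastically between clinics.
* **OR-combination.** Positive if any marker in the set is positive;
  negative only if all are present and negative; otherwise unclassified. A
  single exceeded cutoff is decisive even when other markers are missing;
  classification is withheld only when the missing marker could have flipped
  an all-negative call.
* **Overlap partition.** Venn-style counts are complete-case: a subject
  missing any marker of the set is excluded (and counted), each remaining
  subject lands in exactly the cell of its positive-marker subset.
* **Score panels.** score(x) = #{m : x_m ≥ t_m}; positive iff score ≥ s.
  Panel search and evaluation are complete-case over the whole candidate
  marker set, so every candidate panel is compared on identical subjects.

## ROC and thresholds

ROC operating points sit at the observed values themselves (one point per
distinct value, positivity `v ≥ t`), plus a +∞ point, making the curve
exactly consistent with the classifier; the endpoints attain (0, 1) and
(1, 0). AUC is the trapezoid area over (1 − specificity, sensitivity),
which for this construction equals the tie-adjusted Mann–Whitney
probability (#{case > control} + ½·#{ties}) / (n₁·n₀); the test suite
verifies the identity to 1e−12.

Percentile cutoffs (e.g. "the 95th percentile of controls") use the
nearest-rank convention: the ⌈q·n⌉-th order statistic. At least a
q-fraction of the defining controls then lie at or below the cutoff; with
≥-positivity the controls tied exactly at the cutoff are called positive,
so the specificity guarantee on the defining sample is q − k/n with k the
tie count at the cutoff (q − 1/n for distinct values).

The constrained single-marker operating point ("best sensitivity at ≥ 95%
specificity") takes, among qualifying ROC points, the one with maximal
sensitivity, breaking ties toward higher specificity and then higher
threshold — specificity is the protected quantity in this screening
setting.

## Wilcoxon rank-sum test

Group differences use the two-sided Wilcoxon rank-sum test with mid-ranks
for ties. For up to 25 observations per group the permutation distribution
of the rank sum is computed exactly by a subset-sum count over doubled
mid-ranks (exact under ties, no enumeration of combinations); the two-sided
p doubles the smaller tail, capped at 1. Larger samples use the normal
approximation with tie-corrected variance and a 0.5 continuity correction;
around the switchover sizes the two agree to better than 0.01. With heavy
ties and fewer than ~10 observations per group the normal approximation can
deviate from the exact p by ~0.1, which is why the exact path is the
default there. Identical pooled values give p = 1 by convention.

## Panel optimization

Candidate thresholds per marker are the ROC corner points: midpoints
between consecutive distinct observed values whose class composition
differs. No other cutoff can realise a distinct (sensitivity, specificity)
pair, so restricting the grid to corners loses nothing. When a marker has
more corners than `max_candidates_per_marker` (default 8), an evenly spaced
subsample is taken; this bounds the exhaustive five-marker grid near 10⁵
threshold combinations and is the one deliberate approximation in the
search (set the cap to `None` for the fully exhaustive grid — the oracle
tests run that way).

The search enumerates every marker subset up to `max_panel_size`, every
combination of candidate thresholds (vectorised as a broadcast score
tensor) and every score threshold s, and returns the panel maximising
training sensitivity subject to training specificity ≥ `min_specificity`
(default 0.95). Ties are broken by a fixed chain: higher specificity →
fewer markers → lower s → lexicographically earlier marker names → lower
thresholds. If no panel satisfies the constraint, the panel with the
highest specificity (then sensitivity) is returned flagged infeasible. A
hard guard on grid cells protects against accidentally enormous searches.

## Cross-validation

The selection procedure is validated by stratified k-fold cross-validation
repeated R times (default 3 folds × 10 repeats) on the complete-case
cohort. Stratification is on the binary case/control label only; fold
sizes differ by at most one within each class. For every fold the full
optimizer runs on the training folds and the selected panel is scored on
the held-out fold. "Mean performance across test sets" admits two
readings, so both are reported: the mean over all k·R fold evaluations
(the headline aggregate) and the per-repeat means. Everything is
deterministic given the seed.

Because thresholds, subset and s are all tuned on the training data, the
apparent training sensitivity is optimistic; the cross-validated mean is
systematically lower (an anti-optimism property the test suite checks by a
sign test over 20 synthetic cohorts), while held-out specificity stays near
the training constraint.

## Synthetic cohort generator

The generator emulates the verification collective at the analyte level
(no assay physics). Defaults:

* **Composition.** N = 1119 subjects: 71 UCa, 207 other cancer, 841 no
  cancer, with the published covariate margins (sex, age band, urine-stick
  leukocyte/erythrocyte bands, UCa history, tumor grade) reproduced as
  exact per-group counts. Covariate columns are independently permuted
  within a group: margins are exact, joint covariate structure is not
  modelled. A `scale` knob shrinks every block with largest-remainder
  rounding.
* **Marker distributions.** Methylation fractions ~ Beta (support [0, 1]);
  proteins ~ log-normal (positive, right-skewed). Each family has two free
  parameters, pinned by two published facts per marker and group: the group
  median and the probability of exceeding the fixed study cutoff (the
  reported sensitivity, or 1 − specificity). E.g. UCa CXCL16: median
  372.9 pg/mg, P(≥ 648.52) = 0.31; cancer-free controls: median 174.3,
  P(≥ 648.52) = 0.058. The "other cancer" group shares the cancer-free
  distributions except CXCL16, which is a mixture with a mildly elevated
  kidney-cancer component (median 328.1, weight 40/207). Medians for the
  methylation markers refer to the male low-leukocyte analysis population.
* **Missingness.** Missing completely at random, independent per marker,
  with per-group rates calibrated so the complete-case fractions over the
  five markers match the published arithmetic (65/71 of cases, 878/1048 of
  non-cases ⇒ per-marker rates ≈ 1.8% and 3.5%).
* **Dependence.** Markers are conditionally independent given the group by
  default; a Gaussian-copula `rank_correlation` hook couples them when
  required. Real methylation markers are strongly positively correlated
  (shared tumor biology), so under independence OR-combination sensitivity
  and optimized panel sensitivity run *higher* on synthetic cohorts than
  the published combination rows — single-marker quantities, complete-case
  bookkeeping, constraint satisfaction and the train-vs-CV gap are the
  quantities the synthetic cohort reproduces faithfully.
* **Determinism.** One explicitly seeded generator per call; identical
  seed and configuration yield byte-identical cohorts.

The separable-cohort fixture (`generate_separable_cohort`) draws each
marker uniformly on either side of a known threshold with prescribed
exceedance probabilities per class, giving exact per-marker operating
points up to binomial noise — used for parameter-recovery tests of the
optimizer and cross-validation.

## Numerical and design choices

* Fixed study cutoffs (defaults): ALOX5 0.435, TRPS1 0.465, Chr16 0.555
  (methylation fractions), CXCL16 648.52, TGFBI 1345.97 pg/mg creatinine.
  Narrative texts sometimes round the TRPS1/Chr16 cutoffs to 0.47/0.56; the
  tabulated values are used and are configurable via a YAML marker spec.
  Chr16 is treated as a single pre-aggregated fraction.
* Stick-test bands are ordinal categories, not counts; the "< 500/µL"
  leukocyte filter keeps bands strictly below the ~500 band. Subjects with
  an unknown value of a filtered covariate are excluded from that subgroup.
* Report percentages are rounded half-up to one decimal for display; raw
  ratios and counts are always retained in the machine-readable output.
* Cohort files are comma-separated UTF-8 with `.` decimals; marker columns
  carry the marker names verbatim; empty cells or `NA` mean missing.
* The acceptance script runs the full N = 1119 pipeline with the default
  candidate cap (8 per marker) and 10 × 3 cross-validation; the test suite
  uses smaller cohorts (scale 0.2–0.5, fewer repeats) to keep unit runs
  fast.

## Known limitations

* Group-level calibration uses medians and one tail point per marker; the
  full distribution shape (and hence AUC) is implied, not fitted, and can
  deviate from published AUCs by a few points.
* No joint covariate structure and no covariate–marker dependence in the
  generator (e.g. grade-specific protein levels are not modelled even
  though high-grade tumors shed more protein).
* Missingness is MCAR; real incomplete measurements may be informative.
* The optimizer's candidate cap makes the default search near-exhaustive
  rather than exhaustive for markers with many ROC corners.
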