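# uropanel

Statistical analysis of urinary biomarker panels for detecting urothelial
carcinoma (UCa) among a heterogeneous clinical population — cancer-free
individuals and patients with other urological or gynecological cancers.

Non-invasive UCa detection from urine rests on two kinds of analytes
measured in the same specimen: DNA-methylation fractions at tumor-associated
CpG units in the urine sediment (here called ALOX5, TRPS1 and Chr16), and
creatinine-normalised protein concentrations in the supernatant (CXCL16 and
TGFBI, in pg per mg creatinine). Each marker has a fixed positivity cutoff
from earlier identification studies; this package provides the complete
verification pipeline that evaluates such markers alone and in combination:

* **Fixed-cutoff classification** — a subject is positive for a marker when
  its value *v* satisfies *v* ≥ *t*; sensitivity and specificity are counted
  only over classified subjects, never silently imputing missing values.
* **OR-combination with an explicit missing-data contract** — positive if
  *any* marker exceeds its cutoff; unclassified when some markers are
  missing and all remaining ones are negative (a missing marker could have
  been the positive one); exact Venn/overlap partitioning of the
  positive-marker subsets on complete cases.
* **Score-panel optimization** — for a marker subset *M*, per-marker
  thresholds *t_m* and an integer score threshold *s*, the score is
  score(x) = #{m ∈ M : x_m ≥ t_m} and the call is positive iff score ≥ s.
  The optimizer exhaustively searches subsets, data-driven candidate
  thresholds (ROC corner points) and *s*, maximising training sensitivity
  subject to specificity ≥ 95% (configurable), with fully deterministic
  tie-breaking.
* **Stratified repeated k-fold cross-validation** (default 10 × 3-fold) of
  the entire selection procedure, reporting held-out sensitivity and
  specificity per fold, per repeat, and overall.
* **A calibrated synthetic cohort generator** — the real cohort is available
  only on request, so the generator emulates its structure: three diagnostic
  groups with the published covariate margins (N = 1119: 71 UCa, 207 other
  cancer, 841 no cancer), Beta/log-normal marker distributions pinned to the
  published group medians and fixed-cutoff operating points, and
  missing-completely-at-random gaps matching the published complete-case
  fractions.

## Worked example

Generate a half-scale synthetic cohort, then search for the best five-marker
score panel at ≥ 95% training specificity and cross-validate the selection:

```sh
$ uropanel simulate --seed 7 --scale 0.5 --out cohort.csv
wrote 560 subjects to cohort.csv

$ uropanel optimize cohort.csv
{
  "markers": ["ALOX5", "CXCL16", "Chr16", "TGFBI", "TRPS1"],
  "thresholds": [0.411, 809.7, 0.419, 3352.5, 0.283],
  "score_threshold": 2,
  "feasible": true,
  "train_sensitivity": 0.829,
  "train_specificity": 0.964,
  "n_used": 480
}

$ uropanel cv cohort.csv --repeats 2 --seed 7
{
  "k": 3,
  "repeats": 2,
  "mean_sensitivity": 0.672,
  "mean_specificity": 0.953,
  ...
}
```

Reading the output: of the 560 generated subjects, 480 have all five marker
values (`n_used`); the selected panel calls a subject positive when at least
2 of the 5 markers exceed their optimized thresholds, reaching 82.9%
sensitivity at 96.4% specificity *on the training data*. Because thresholds
and the score cutoff were fitted to that same data, the honest estimate is
the cross-validated one: 67.2% sensitivity at 95.3% specificity on held-out
folds — the expected optimism gap of an exhaustively tuned panel.

Other verbs: `uropanel verify` (per-marker fixed-cutoff performance and
AUC), `uropanel combine` (OR rule), `uropanel report` (full analysis plan:
per-subgroup single-marker tables, OR rows, overlap exports, panel + CV).
Everything is also available as a library (`import uropanel`).

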