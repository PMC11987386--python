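# Methods

## The cascade model

The multi-class problem (Normal + 7 cancer types; esophageal and gastric
cancers pooled as upper GI) is decomposed by iterative class peeling.
Level 1 frames Normal vs pooled Cancer; Normal rows are then removed and
each subsequent level pits the most frequent remaining class against the
pool of the rest, removing the peeled class afterwards; with three or
more classes the terminal level is a two-class head-to-head. Count ties
during peeling are broken alphabetically so the level order is a pure
function of the label counts. The decomposition assumes the label set is
closed and that each contest is learnable with a roughly balanced class
ratio — the main reason for peeling in descending frequency.

Each level is split 90/10 with stratification on the binary label,
independently per level (per-class test counts land within ±1 of
`round(0.10 · class size)`). Whether the source system used one global
split or per-level splits is not decidable from its published
per-level proportions; independent per-level splits are the default
here and the split seed is a recorded constant (17) so the partition is
reproducible without configuration.

**Routing.** At inference a sample descends the trained levels. The
published system evaluates levels in isolation and does not state a
deployed routing rule, so routing is a configuration knob
(`route_threshold`, default 0.5): exit with "Normal" if level 1's
cancer probability falls below the threshold; at intermediate levels
exit with the positive label once its probability reaches the
threshold; the terminal level decides by argmax. This rule is exhaustive
and exclusive — exactly one label out for any probability trace.

## Feature selection

Six scorers each nominate `floor(N/2)` features (21 of 43); a feature is
kept when at least `threshold` (default 3) scorers nominate it.

- **IV / WoE with monotonic binning.** Continuous features (≥ 5 distinct
  values) start from 20 quantile bins; adjacent bins are merged greedily
  — the first pair violating the dominant monotone direction each pass —
  until the per-bin weight of evidence is monotone or 3 bins remain.
  Features with fewer distinct values use one bin per value. Zero cells
  are smoothed by 0.5 before proportions so logs stay finite; the
  smoothing constant is a numerical choice, not fitted. IV is
  non-negative by construction (each term `(C1−C2)·ln(C1/C2) ≥ 0`).
- **Chi-square.** The standard 2×2 observed-vs-expected statistic
  without continuity correction, after dichotomizing each continuous
  feature at its median. A published variant of this statistic carries a
  denominator that does not match the standard 2×2 margins; since the
  source states it used a stock library routine, the standard form is
  implemented. The values-as-frequencies convention
  (`chi2_mode="frequency"`) is available for comparison. Degenerate
  margins score 0 with a warning.
- **Forest importances.** Random forest (100 trees, Gini, bootstrap) and
  extra trees (random split thresholds, no bootstrap) mean-decrease-in-
  impurity scores, normalized to sum to 1. The out-of-bag permutation
  form — mean absolute OOB error change after permuting a feature within
  each tree's OOB rows — is available as `flavor="oob_permutation"`;
  impurity is the default because the source's stated configuration
  (Gini importance) and its formula (OOB permutation) disagree.
- **RFE.** L2 logistic model (C = 1.0, lbfgs, max_iter 100, tol 1e-4) on
  standardized features, dropping the smallest-|coefficient| feature per
  step down to 21.
- **L1.** Linear SVM (squared hinge, C = 0.01, max_iter 1000, tol 1e-4,
  fixed internal seed for the liblinear solver) on standardized
  features; features ranked by |coefficient| with exact zeros last and
  name tie-breaks. Non-convergence warns and uses the final iterate.

Selectors fit on training rows by default. The source applies selection
to each level *before* its train/test split — an ordering that leaks
test information into selection — so that mode is exposed as
`paper_faithful_selection` but is not the default. A scorer that raises
abstains (reducing attainable votes) with a warning; more than two
abstentions abort. If no feature reaches the threshold the selector
falls back to the top-voted features rather than emitting an empty
design matrix, with a warning.

## Level models

Fixed registry (level: members): 1 GBT; 2 GBT+RF; 3 ET+RF; 4 ET; 5 QDA;
6 QDA+GBT; 7 RF. Gradient-boosted trees use 100 rounds, learning rate
0.3, max depth 6, min child weight 1, base score 0.5 with the logistic
link; forests use 100 trees, Gini, minimum split 2 / leaf 1 (RF
bootstrapped, ET not). Multi-member levels combine by unweighted soft
voting (arithmetic mean of member probabilities), which is a convex
combination per row.

QDA runs with no shrinkage (reg 0.0, tol 1e-4) and data-estimated
priors. On small levels a class covariance can be singular; rather than
crash, the fit falls back to an eigendecomposition with shrinkage 1e-6
(rank tolerance lowered accordingly) and logs a warning. This is a
numerical diagnostic, not a model change at default scale.

Cross-validation is stratified 10-fold. "The best CV model" is
ambiguous in the source; the default policy refits on all training rows
(standard practice), while `best-fold` keeps the fold model with the
highest AUC (ties: accuracy, then fold index) to reproduce the literal
description. The policy is recorded in the bundle manifest.

## Evaluation

All metrics derive from confusion counts; AUC is the trapezoidal ROC
area (equal to the tie-corrected Mann–Whitney statistic). Metrics with a
zero denominator are reported as undefined with a flag, never silently
coerced to 0. Cross-level aggregation is the unweighted (macro) mean —
verified to reproduce the published overall averages from the published
per-level values — with sample-weighted averaging as an option.
Percentages are rendered at two decimals in reports; internal math is at
full precision.

The assay cost model prices the six routinely ordered clinical assays
(AFP, CA19-9, CA-125, CEA, Prolactin, CA 15-3) at $2 and the remaining
33 panel members at $5.5, with 2.5 h per assay, summed serially: the
full 39-marker panel costs $193.5 and 97.5 h.

## Rank statistics

Friedman: within each level, methods are ranked 1..m (larger metric →
larger rank) with average ranks on ties — average ranks are required to
reproduce the published half-integer rank sums — and the chi-square
statistic carries the standard tie correction. Wilcoxon signed-rank:
zero differences are discarded before ranking; the exact two-sided
p-value enumerates all 2ⁿ sign assignments for n ≤ 15, and the normal
approximation (tie-corrected, no continuity correction) is available —
the latter reproduces the published p ≈ 0.0277 on six nonzero
differences, so both modes are exposed (`exact` is the statistical
default).

## Synthetic cohort

The generator emulates the structure of the public cohort the cascade
targets: exact class counts (Normal 812, Colorectum 388, Breast 209,
UpperGI 113, Lung 104, Pancreas 93, Ovary 54, Liver 44 = 1,817),
non-negative right-skewed biomarker concentrations (log-normal with
per-marker baseline locations spread over a seeded range; dispersion 1.0
on the log scale), demographics drawn from cohort-like marginals (age ~
N(63, 13) for cancer and N(49, 16) for controls within their published
ranges; sex and ethnicity at the published group frequencies; ovarian
cases female), and per-class planted informative markers shifting the
log-location by `effect × dispersion` (default: five clinically
associated markers per cancer class at 1 log-sd).

Omega scores are computed from four simulated wells per sample with UID
counts ~ U{50..150} and p-values ~ U(0.2, 1); for cancer rows the
normal-model p-values are exponentially depressed (mean depression 1.5)
so Ω > 0 in expectation for cancer, making the omega score an
informative, positively signed feature, consistent with its definition
as log evidence against the normal MAF distribution.

What the generator does **not** emulate: the real panel's marginal
concentration distributions, units, inter-marker correlations, stage
composition, or histology. Passing tests therefore demonstrate the
pipeline's correctness and its ability to recover planted signal under
realistic skew and imbalance — not clinical performance; the published
real-data results require the external cohort.

Missingness is MCAR only (each biomarker cell independently, the
mechanism used in the published robustness experiment; MAR variants are
out of scope). Imputation is k-NN (default k = 5) on standardized
features with mutually missing coordinates ignored, replacing each
missing cell with the mean of the feature over the k nearest rows;
observed cells are never altered.

## Problem sizes and seeds in the test suite

Unit tests run on a quarter-scale cohort (454 rows, same class
proportions) and 5-fold CV; planted-marker recovery uses 50 full-size
cohorts (1,817 rows) with five shared planted markers at 1 log-sd;
end-to-end determinism compares two quarter-scale runs byte-for-byte;
the acceptance script runs the full-size pipeline with 10-fold CV. One
seed block fans out to per-stage seeds via `SeedSequence.spawn`, so each
stage is independently reproducible; all randomness is seeded.

## Known limitations

- Published per-level CV/test tables from the real cohort are bundled as
  reference data for the rank comparison and aggregation arithmetic;
  reproducing them as model outputs requires the external dataset and
  the original split.
- No probability calibration across levels and no abstain option; the
  routing threshold trades early Normal exits against descent depth.
- Friedman p-values use the chi-square approximation; with only 7
  blocks and 5 methods, the approximation is adequate but not exact.
- The generator's class-conditional independence of markers (given the
  planted shifts) makes selection somewhat easier than correlated real
  panels; vote thresholds transfer, selected-set sizes need not.
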