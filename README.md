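# oncocascade

Multi-level binary classification for liquid-biopsy multi-cancer
detection: a seven-level peeling cascade over plasma protein biomarkers,
cfDNA mutation evidence and demographics, with six-selector majority-vote
feature selection, per-level soft-voting ensembles, full
confusion-matrix evaluation, and rank-based method comparison.

## The problem

A liquid biopsy measures tumor-derived material in a blood draw: 39
plasma protein biomarker concentrations (CA19-9, CA-125, IL-6, AFP, ...)
plus an *omega score* summarizing mutant-allele-frequency (MAF) evidence
in cell-free DNA. For sequencing wells `i = 1..w` with UID template
counts `u_i` and per-well p-values under the cancer and normal MAF
distributions,

    Ω = Σᵢ (uᵢ / Σⱼ uⱼ) · ln(pᵢᶜ / pᵢᴺ)

Given these 43 features (39 biomarkers + age + sex + ethnicity + Ω), the
task is to decide whether a sample is cancerous and, if so, localize the
tissue of origin among seven cancer types: colorectal, breast, upper
gastrointestinal (esophageal + gastric pooled), lung, pancreatic,
ovarian, and liver.

## The method

**Cascade.** Instead of one 8-class model, the problem is peeled into an
ordered sequence of binary contests: level 1 separates Normal from any
cancer; each later level pits the most frequent remaining cancer against
the pool of the rest and removes it; the terminal level is Ovary vs
Liver head-to-head. Each level keeps a roughly balanced two-class
problem, avoiding synthetic oversampling.

**Feature selection.** Six heterogeneous scorers each nominate the top
half (21 of 43) of the features per level: information value with
monotonic weight-of-evidence binning (`IV = Σ (C1ᵢ − C2ᵢ)·ln(C1ᵢ/C2ᵢ)`),
the 2×2 contingency χ², random-forest and extra-trees Gini importances,
recursive feature elimination on an L2 logistic model, and an
L1-penalized linear SVM. A feature enters a level's model when **≥ 3 of
the 6** selectors nominate it.

**Models.** Each level gets a fixed registry model, chosen per contest:
gradient-boosted trees (level 1), soft vote GBT+RF (2), soft vote ET+RF
(3), extra trees (4), QDA (5), soft vote QDA+GBT (6), random forest (7);
soft voting averages member class probabilities with equal weight.
Training uses stratified 90/10 splits and tenfold cross-validation;
evaluation reports Acc, Precision, Recall, F1, Specificity, balanced
accuracy and AUC per level plus their macro average.

**Method comparison.** Friedman average ranks (ties averaged, with tie
correction) and the Wilcoxon signed-rank test over method × level metric
matrices, as used to compare the majority vote against metaheuristic
selector baselines (EVO, FLA, FOX, RIME — consumed as published metric
tables; the optimizers themselves are out of scope).

Because the original cohort is external data, the package ships a
synthetic cohort generator with the same structure (1,817 samples,
published class mix, right-skewed non-negative concentrations, planted
informative markers with known ground truth, omega scores simulated from
wells), so the entire pipeline is testable offline, plus MCAR missingness
injection and k-NN imputation for robustness experiments.

## Worked example

```bash
$ oncocascade run --seed 17 --out demo_out
7 levels | overall accuracy 86.80%, AUC 93.03%, balanced accuracy 83.58%
```

This simulates the default synthetic cohort, builds and splits the seven
levels, selects features per level at vote threshold 3, cross-validates
and fits each level's registry model, and macro-averages the held-out
test metrics. (The numbers describe the synthetic cohort's difficulty
under this seed, not the published real-data results.) `demo_out/`
contains the cohort, per-level train/test CSVs, vote tallies, CV tables,
ROC points, and a reloadable model bundle.

```bash
$ oncocascade compare --metric Acc --out ranks.json
{"EVO": 16.5, "FLA": 22.0, "FOX": 17.0, "MajorityVoting": 33.0, "RIME": 16.5}
```

The Friedman rank sums over the bundled published per-level accuracies:
the majority-vote selection ranks first on every level (rank sum 33 =
7 levels × rank 5).

```python
>>> from oncocascade import compute_omega_score
>>> compute_omega_score(uid_counts=[3, 1], p_cancer=[0.01, 0.5], p_normal=[0.5, 0.5])
-2.9340172540711094   # 0.75·ln(0.02) + 0.25·ln(1)
```

The same functionality is available as a library: `generate_cohort`,
`build_levels`/`split_level`, `MajorityVoteSelector` (a scikit-learn
transformer), `CascadeClassifier` (a scikit-learn classifier),
`crossvalidate`, `metrics_from_predictions`/`aggregate_levels`,
`friedman_ranks`/`wilcoxon_signed_rank`.

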