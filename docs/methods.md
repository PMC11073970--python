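# Methods

This note documents the models and procedures implemented in `protriage`,
the assumptions behind them, the design choices that were genuinely open,
and what the synthetic-cohort tests do and do not demonstrate about real
RPPA data.

## The synthetic cohort generator

`protriage.synthetic` emulates a newly diagnosed adult AML cohort profiled
by reverse-phase protein arrays.  Defaults reproduce the reference study
conditions: 419 patients split into five latent clusters in proportions
91/69/113/85/61; two treatment arms with P(VH) = 79/419 ≈ 0.19 (the
post-filter arm sizes of the motivating cohort); and per-stratum
exponential overall survival whose medians equal the cluster×arm table

| cluster | VH (mo) | CC (mo) |
|---|---|---|
| C1 | 68.5 | 19.4 |
| C2 | 12.7 | 200* |
| C3 | 6.4 | 12.2 |
| C4 | 10.4 | 200* |
| C5 | 2.9 | 8.6 |

\* arms whose survival curve never reached its median within the ~120-month
follow-up are encoded as a finite large median (200 mo) so the exponential
rate `ln 2 / median` stays defined.  Exponential survival with
administrative censoring at `censor_horizon_months` (default 120) is the
simplest law with a closed-form median; only medians, not curve shapes, are
available to calibrate against.  Complete-remission duration is drawn the
same way from a default table of 0.7 × the OS medians for the ~65% of
patients who achieve remission (the source reports only that remission
outcomes follow "a similar pattern"); CRD is missing for the rest.

Expression is `signature[cluster] + N(0, noise_sd)` in log2-fold-change
units.  Within-cluster variance is not reported anywhere, so `noise_sd` is
a free parameter; the default 1.0 against a signature scale of 2.0 gives
visually heatmap-like block contrasts and a realistic screening regime
(roughly a quarter of proteins carry signal, and the p < 0.05 screen
retains on the order of a hundred proteins out of 411, comparable to the
109 prognostic proteins of the motivating cohort).

### Signature architecture

Signatures are built from six disjoint *contrast axes* rather than one
private marker block per cluster.  Each axis assigns a coefficient to every
cluster (e.g. the C1 anchor axis is (−2, 0, +1, 0, +1) over C1..C5); within
an axis block, half the proteins carry the pattern up and half down, like
the up- and down-regulated arms of a clustered heatmap.  Two properties are
engineered jointly:

- **Nesting.**  The five clusters embed so that C2/C3 and C4/C5 are the
  closest pairs.  A k=3 clustering therefore merges exactly those pairs,
  and k=2 within each merged pool separates them — the structure the
  sequential selector pipeline is designed to peel apart.
- **Screen survivability.**  Every axis opposes clusters with clearly
  different survival, so each marker protein is *marginally* prognostic and
  survives a survival-based screen.  This constraint is not cosmetic: under
  the reference survival table, a protein marking "C1 vs everyone" or
  "{C2,C3} vs {C4,C5}" is only weakly prognostic, because each side pools a
  long-lived and a short-lived subgroup into similar marginal curves
  (crossing KM curves defeat the log-rank).  Real prognostic proteins
  satisfy the constraint by construction — they were selected on survival.
  Simpler architectures (private blocks, pure super-group indicators) fail
  reproducibly: after per-protein standardization, cluster geometry is
  driven by *how many* markers of each contrast survive the screen, and
  whole blocks of weakly-prognostic markers drop out together because their
  p-values share the same latent survival contrast.

The pattern set is a `GeneratorConfig` field, so tests can plant
alternatives (e.g. three collapsed signatures for cluster-count recovery
experiments).  What these synthetic cohorts do **not** emulate: protein-
protein correlation within clusters (noise is independent across
proteins), heavy-tailed or batch-structured noise, missing values,
covariate structure (age, cytogenetics, mutations), and non-proportional
or non-exponential hazards.  Passing the recovery tests therefore shows
the pipeline's logic is correct and well-calibrated under its own model,
not that it would recover structure of comparable strength in a real
cohort.

## Survival statistics

Kaplan–Meier estimation and the G-group log-rank test (observed-minus-
expected event counts with hypergeometric covariance, chi-square with G−1
df) are implemented directly on numpy because the quantile screen performs
thousands of log-rank tests per cohort; both are cross-checked against
lifelines and against brute-force oracles in the test suite.  Median
survival is the first event time with S(t) ≤ 0.5 (right-continuous
convention), with `NOT_REACHED = inf` when the curve never drops that far;
"five-year" rates are S(60 months).  Cox proportional-hazards fitting
wraps lifelines' `CoxPHFitter` (Efron tie handling; ties are a non-issue
at RPPA cohort scale with continuous times) and reports
`converged=False` with a warning instead of raising on separation.
Benjamini–Hochberg adjustment wraps statsmodels.  Note that BH is *not*
idempotent — re-adjusting an adjusted vector can inflate it further (e.g.
adjusted [0.5, 1.0] becomes [1.0, 1.0]) — so the tests assert bounds and
rank-monotonicity only.

## The quantile screen

Each protein is split at sample quantiles into 2..6 groups (ties at a
boundary go to the lower group, which makes the split deterministic and
order-independent); groups are compared on OS by log-rank.  A protein's
screen p-value is the minimum over the five schemes — the most permissive
reading; per-scheme columns are kept so stricter readings remain possible.
Selection uses raw p-values at the 0.05/0.01 cutoffs (BH is available but
deliberately not applied at this stage, since the cutoffs are defined on
the raw table).  Null calibration of the per-scheme rejection rate is
verified at 0.05 ± 0.015 on 2000 structureless proteins.  Proteins with
missing values are excluded with a warning rather than imputed.

## Progeny clustering

For each candidate k, the cohort is clustered (k-means, k-means++
initialization, 10 restarts; Ward agglomerative available via a hook), and
artificial "progeny" are built per cluster by resampling each feature
independently with replacement from that cluster's members — preserving
marginals while destroying within-cluster feature covariance.  The
stability score per iteration is the sum of two terms:

1. **Co-assignment stability**: progeny are reclustered at k; score =
   mean same-origin co-assignment − mean different-origin co-assignment,
   minus the same quantity on label-shuffled progeny (the null reference).
   This penalizes over-clustering (split clusters scatter their progeny)
   but *saturates* for every k at or below the true count, because coarse
   clusterings of well-separated groups are perfectly stable.
2. **Chimera homogeneity**: progeny are also reclustered at a fine
   resolution (max candidate + 1).  Progeny of a homogeneous cluster
   resemble its members and stay together; progeny of a merged cluster are
   feature-wise chimeras of its sub-populations and disintegrate.  This
   term penalizes under-clustering.

The chosen k maximizes the mean summed score over 50 iterations (ties to
the smaller k); a single-element candidate list forces that k without a
sweep.  With defaults (50 iterations, 20 progeny per cluster), planted
cluster counts of 3 and 5 are recovered in 10/10 seeds on strong-signal
cohorts.

## Sequential selector construction

`build_selector` screens its (sub)cohort, forms candidate protein sets by
crossing the configured screen cutoffs with optional top-N truncations
(default: the single p < 0.05 list), z-scores the candidate submatrix
within the fitted cohort (so each protein contributes comparably to the
clustering), progeny-clusters it, and scores each candidate by
**treatment discrimination**: within each resulting cluster, VH vs CC OS
log-rank, Fisher-combined across clusters (CRD as tie-break).  An
arm-pooled log-rank across clusters was evaluated and rejected: under a
treatment-interactive truth it actively prefers partitions that merely
stratify marginal survival (each true super-group mixes a good and a bad
arm and looks unremarkable when arms are pooled), which is the opposite of
what a therapy-selection tool needs.

`run_sequential` then applies the study design: PS1 at k=3 on everyone;
each PS1 cluster is summarized by `arm_contrast` (per-arm KM medians and
S(60); the recorded margin is |S_VH(60) − S_CC(60)|, which stays finite
when a median is never reached).  The VH-preferring cluster with the
largest margin becomes C1; of the remaining two, the cluster with the
*smaller* arm margin — the one the selector could not triage — feeds PS2
(k=2 → C2, C3, ordered by best-arm survival), and the other feeds PS3
(k=2 → C4, C5).  C5, the PS3 cluster with the worse best-arm survival, is
recommended NEITHER when both of its arm medians fall below
`neither_threshold` (15 months — comfortably above C5's worst arm and
below every alternative's best arm; the NEITHER verdict is applied only at
the PS3 stage because that is where the no-benefit group arises by
construction, and applying it cohort-wide would make the flag noise-
sensitive for clusters whose CC median sits near the threshold).  All
other clusters are recommended their preferred arm.  If no cluster prefers
VH, the pipeline emits zero VH recommendations and logs it.  When the
clinical table carries regimen flags (`received_hma_ven`, `received_arac`),
patients on the combined regimen are dropped from VH and CC is restricted
to cytarabine-treated patients between PS1 and PS2, mirroring the
treatment-purity filtering of the study design; without the flags this is
a no-op.

## The classifier cascade

Stage definitions: (1) C1 vs rest on all patients; (2) {C2,C4} vs {C3,C5}
on the non-C1 sub-cohort; (3) C3 vs C5.  Each stage: stratified 80/20
development/test split, then 75/25 train/validation within development;
random-forest grid search on the training set scored by validation
C-index (the default grid is 10 × 5 × 3 = 150 combinations; ties go to the
smallest forest); Shapley ranking of all proteins on the development set;
exhaustive refit of all 63 nonempty subsets of the top six proteins, the
winner maximizing validation C-index (ties prefer smaller subsets, then
earlier ranks); the winner's held-out test C-index is reported.  The
classifier score is the predicted positive-class probability, and at
inference every patient routes through stage 1 first (positive → VH),
then stage 2 (positive → CC), then stage 3 (C3-like → CC with
intensification, C5-like → NEITHER).  Pooled sensitivity/specificity
are micro-averaged over the three stage confusion matrices.

Shapley attributions are computed by an exact path-dependent TreeSHAP
(polynomial-time propagation of subset-permutation weights down each
root-to-leaf path, numba-compiled).  It satisfies local accuracy to
machine precision and matches a brute-force subset-enumeration oracle
(Shapley values of the tree's cover-weighted conditional expectation) to
1e-10 in the tests; the `shap` library is not a dependency.

## Differential expression, correlation, triage arithmetic

One-vs-rest differential expression per cluster: two-sided Wilcoxon
rank-sum per protein, BH across the proteins of that comparison (not
across clusters, since each cluster's list stands alone), and an effect
gate |mean(cluster) − mean(rest)| ≥ 0.5 on the already-log2 scale.  A
cluster-vs-single-cluster variant is exposed via `versus=`.  Pearson
correlation reports the full matrix plus a long-format pair table with
pairs above r = 0.60 flagged.

The triage projection assigns each patient the KM S(60) of their (cluster,
recommended arm) stratum — NEITHER patients keep their actual arm, since
no counterfactual therapy exists for them; CC-with-intensification counts
as CC — and sums these probabilities into survivor counts.  Percentages
are rounded to whole percent *before* differencing and extrapolating,
because the headline arithmetic is defined on whole percentages
(43% − 30% = 13 points × 20,000/100 = 2,600 added cures; the unrounded
difference would give 2,625); raw unrounded fractions are also reported.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use cohorts of 400–600 patients
(411 proteins for screen-scale checks, 60 for clustering/classifier
checks), 5–10 seeds per stochastic claim, 2000 replicates for null
calibrations, and a reduced 8-combination hyperparameter grid for
end-to-end cascade runs (the 150-combination default grid is exercised for
its combinatorics and in grid-search unit tests); the full suite runs in a
few minutes on one CPU.  Every stochastic component takes an explicit seed
and the full training pipeline is a deterministic function of (data,
seed).

## Known limitations

- Exponential survival cannot represent plateaus or crossing hazards
  within a stratum; the ">120 months" arms are approximated by a 200-month
  median.
- The sequential role-assignment rules (largest-margin VH cluster → C1,
  smallest-margin → PS2) assume the k=3 stage yields one cluster per role;
  degenerate cohorts fall back to pooled routing with a log message.
- The NEITHER rule is a threshold on arm medians, a deliberately simple
  stand-in for a clinical judgment that was narrative in origin.
- Progeny clustering's chimera term assumes the base clusterer can detect
  sub-structure at the fine resolution; extremely low-dimensional,
  perfectly separated data can still tie.
- The cascade's printed performance on synthetic strong-signal cohorts
  (correct-therapy fraction ≈ 0.97 at a 4σ effect) is an upper bound of
  the regime the design targets, not a forecast for clinical data.
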