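# protriage

Proteomic therapy triage for newly diagnosed acute myeloid leukemia (AML).

Venetoclax plus a hypomethylating agent (**VH**) has transformed AML therapy,
but not every patient benefits from it over conventional anthracycline +
cytarabine chemotherapy (**CC**), and today there is no rational way to pick
between the two for an individual patient. `protriage` implements, as a
tested and reusable pipeline, a proteomics-based triage strategy built on
reverse-phase protein array (RPPA) profiles — expression of a few hundred
proteins per patient, as log2 fold-change (LFC) versus normal bone marrow
CD34+ cells:

1. **Prognostic screen** (`protriage.screen`) — each protein's expression is
   split into quantile groups under five schemes (median split, tertiles,
   quartiles, quintiles, sextiles); overall survival (OS) is compared across
   the groups with a log-rank test; a protein's screen p-value is the
   minimum over schemes, thresholded at p < 0.05 / p < 0.01.
2. **Protein selector sets** (`protriage.progeny`, `protriage.selectors`) —
   progeny clustering (stability-based resampling that also chooses the
   number of clusters) partitions patients from the standardized prognostic
   proteins.  Selectors are built **sequentially**: PS1 on the whole cohort
   (three clusters), whose treatment-arm survival contrasts identify the
   VH-responsive cluster **C1**; PS2 re-clusters the indeterminate cluster
   into **C2**/**C3**; PS3 re-clusters the remaining cluster into
   **C4**/**C5**, where C5 — poor median OS on *both* arms — is the
   "neither therapy" group.  Recommendation map:
   C1 → VH, C2/C3/C4 → CC, C5 → neither.
3. **Protein classifier** (`protriage.cascade`) — three sequential random
   forests (C1 vs rest; {C2,C4} vs {C3,C5}; C3 vs C5), each tuned by
   holdout grid search, ranked by Shapley attributions (an exact
   path-dependent TreeSHAP implementation ships in `protriage.shapley`),
   and pruned to at most six proteins by exhaustively refitting all 63
   subsets of the top six.  Model quality is the concordance index
   `(#concordant + 0.5·#ties) / #permissible` over positive–negative pairs.
4. **Profiling the no-benefit group** (`protriage.diffexpr`) — one-vs-rest
   Wilcoxon differential expression (BH-adjusted p < 0.05 and |mean LFC|
   ≥ 0.5) and pairwise Pearson correlation of the prognostic proteins.
5. **Counterfactual triage benefit** (`protriage.triage`) — how many
   patients would change therapy under the recommendation map, the
   projected five-year survivor count if every patient received the
   recommended arm (each patient contributes the Kaplan–Meier S(60 mo) of
   their cluster × arm stratum), and the extrapolated additional annual
   cures at a given incidence.

Because the real cohort is not redistributable, `protriage.synthetic`
generates RPPA cohorts with planted cluster structure and cluster×arm
exponential survival (the reference parameterization: 419 patients in
clusters of 91/69/113/85/61, ~19% VH, and cluster×arm median OS such as
68.5 vs 19.4 months for C1).  Every downstream stage is tested against what
the generator plants.

## Worked example

```python
from protriage import (GeneratorConfig, simulate_cohort, run_sequential,
                       SelectorConfig, count_reassigned, project_optimal,
                       summarize_benefit)
from sklearn.metrics import adjusted_rand_score

cohort = simulate_cohort(GeneratorConfig(seed=1))          # 419 patients, 411 proteins
final, selectors = run_sequential(cohort.expression, cohort.clinical,
                                  SelectorConfig(seed=1))
print(adjusted_rand_score(cohort.true_cluster, final.labels))
print(final.recommendation)
recs = final.labels.map(final.recommendation)
n_re = count_reassigned(cohort.clinical["arm"], recs)
proj = project_optimal(final.labels, cohort.clinical, final.recommendation)
s = summarize_benefit(len(final.labels), proj["baseline_raw"],
                      proj["optimized_raw"], 20_000, n_reassigned=n_re)
print(s.reassigned_pct, s.baseline_pct, s.optimized_pct)
```

prints

```
1.0
{'C1': 'VH', 'C2': 'CC', 'C3': 'CC', 'C4': 'CC', 'C5': 'NEITHER'}
33 26 35
```

i.e. the sequential selectors recover the five planted clusters exactly
(adjusted Rand index 1.0) with the intended therapy map; triaging this
cohort by protein profile would reassign 33% of patients and is projected
to raise five-year survival from 26% to 35%.

A command-line interface mirrors the library:
`protriage simulate | screen | cluster | selectors | classify | de | triage`
(each subcommand takes `--seed` wherever randomness exists and writes
CSV/JSON outputs).

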