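# ecckit

Extrachromosomal circular DNA (eccDNA) profiling for tumor/normal tissue
cohorts: from caller output to diagnostic and prognostic models.

eccDNA — circular DNA molecules existing apart from chromosomes — is
detected from short-read sequencing by split-read callers such as
Circle-Map. This package implements the downstream analysis for a breast
cancer profiling study design:

1. **Filtering** of candidate circles with five acceptance criteria
   (≥ 2 split reads; ≥ 3 total supporting reads; caller score ≥ 50;
   breakpoint depth ratio > 0.33 at both breakpoints; uncovered-base
   fraction < 0.1).
2. **Annotation** against 24 genomic categories — gene sub-features and
   2 kb flanks, intergenic, enhancers, DHS, CpG islands and shores, the
   seven RepeatMasker classes, Alu/MIR, transposons — with an internal
   interval engine matching `bedtools intersect` semantics (≥ 1 bp,
   half-open coordinates).
3. **Quantification** of 58 features per sample: total eccDNA per million
   mapped reads, per-category per-million counts and proportions, and raw
   counts for nine key categories; plus per-feature tumor-vs-normal
   Wilcoxon rank-sum comparisons.
4. **Diagnosis**: five classifiers (random forest, logistic regression,
   naive Bayes, SVM, KNN) compared by ten-fold cross-validated AUC on a
   stratified 2:1 split, held-out sensitivity/specificity/precision/F1/
   accuracy/AUC, and top-10 feature attribution by Monte-Carlo Shapley
   values.
5. **Prognosis** (disease-free survival): optimal-cutoff binarization per
   feature (exhaustive log-rank scan), Kaplan–Meier curves, univariate
   Cox hazard ratios with 95% CIs, and a DFS-event classifier reusing the
   diagnostic harness.

The cohort the design mirrors (81 tumor / 33 normal tissues) is under
controlled access, so the package ships a seeded synthetic-cohort
generator reproducing its statistical structure — bimodal tumor eccDNA
lengths (modes ≈ 180/360 bp), category-enrichment differences, ~18% DFS
event rate with planted feature-linked hazards — against which every stage
is tested. See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from ecckit.simulate import SimulationConfig, simulate_cohort, cohort_feature_matrix
from ecckit.diagnostic import HarnessConfig, run_harness

cohort = simulate_cohort(SimulationConfig(seed=1))     # 81 tumor / 33 normal
matrix, labels = cohort_feature_matrix(cohort)         # filter -> annotate -> quantify
print(matrix.shape)                                    # (114, 58)

report = run_harness(matrix, (labels == "tumor").astype(int).to_numpy(),
                     HarnessConfig(seed=1))
print(report["selected_model"], round(report["test_metrics"]["auc"], 3))
```

prints

```
(114, 58)
logistic_regression 0.916
```

i.e. each of the 114 samples gets the 58-feature quantification, and the
best-by-CV classifier separates held-out tumor from normal tissue with AUC
0.92 under this cohort's planted effect sizes. The same objects feed the
survival stage:

```python
from ecckit.prognostic import survival_screen

clin = cohort.clinical.set_index("sample_id")
tumor = clin[clin.tissue_label == "tumor"].dropna(subset=["dfs_time"])
screen = survival_screen(matrix.loc[tumor.index],
                         tumor["dfs_time"], tumor["dfs_event"].astype(int))
row = screen.loc["intron_proportion", ["cutoff", "hazard_ratio", "logrank_p"]]
print(row.astype(float).round(3))
```

```
cutoff          0.297
hazard_ratio    5.803
logrank_p       0.001
```

— a high intron-annotated proportion is hazardous here because the
generator plants exactly that log-hazard ratio; the reported p is the
naive log-rank p at the selected cutoff and is flagged as selection-biased
(a permutation-corrected p is available).

The `analysis/` directory holds the same pipeline as numbered narrative
drivers (`01_simulate_cohort.py` … `06_survival_analysis.py`) writing
their tables under `results/`; the `ecckit` console script exposes each
stage as a subcommand (`simulate | filter | annotate | quantify | compare |
diagnose | prognose | run`).

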