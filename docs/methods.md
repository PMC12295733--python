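# Methods

`ecckit` implements an eccDNA (extrachromosomal circular DNA) profiling
analysis for a tumor/normal tissue cohort: acceptance filtering of
Circle-Map-style candidate calls, annotation against functional and
repetitive genomic elements, a 58-feature per-sample quantification, a
multi-classifier diagnostic harness, and a disease-free-survival (DFS)
prognostic stage. Because the cohort the design mirrors is
access-controlled, every stage is exercised on a synthetic cohort whose
generator is itself first-class, tested code.

## Candidate filtering

A candidate circle is kept only if all five criteria hold:

1. split reads ≥ 2;
2. split + discordant reads ≥ 3;
3. caller score ≥ 50;
4. breakpoint depth ratio > 0.33 — strictly — at *both* breakpoints
   (the minimum of the two is compared; a `mean` mode is available);
5. fraction of uncovered bases inside the circle < 0.1 — strictly.

The two coverage statistics are the ones a split-read circle caller
reports: the relative coverage increase just inside each breakpoint,
`(mean_in − mean_out)/mean_in` over windows of up to 100 bp, clipped to
[0, 1] and defined as 0 when the inside mean is 0; and the zero-depth base
fraction within the interval. When a candidate table lacks them,
`compute_coverage_stats` recomputes both from a per-base depth array over
the interval plus flanks. Candidates missing the statistics pass criteria
4–5 in the default `permissive` mode (with a logged warning) and fail them
in `strict` mode; the choice is explicit because upstream tools differ in
which columns they emit. Whether criterion 4 should use the minimum, the
mean, or either breakpoint is not recoverable from the method description
the analysis follows; the minimum is the conservative default.

## Annotation

All internal coordinates are 0-based half-open (BED convention); readers
ingesting other conventions convert at the boundary. The overlap engine
merges each category's intervals into sorted non-overlapping arrays and
answers "≥ 1 bp overlap" queries with a single binary search, matching the
intersection semantics of standard BED tooling; tests hold it to exact
agreement with an all-pairs scan.

The catalog has 24 categories: gene, exon, intron, 5′/3′ UTR, 2 kb
upstream/downstream gene windows, intergenic, enhancer, DHS, CpG island
and its 2 kb flanks ("shores"), all repeats, the seven RepeatMasker
classes (SINE, LINE, LTR, DNA, simple, low-complexity, satellite), the Alu
and MIR SINE families, and "transposon". Derived tracks:

- upstream/downstream windows are strand-aware (upstream precedes the
  transcription start) and clipped at chromosome ends; a strandless mode
  exists for tracks without strand information;
- intergenic is the complement of the merged, strand-ignored gene spans,
  so genic ∪ intergenic tiles the genome exactly;
- CpG flanks are strandless 2 kb windows on each side;
- transposon is the union of the four interspersed transposon-derived
  classes (SINE + LINE + LTR + DNA); the source analysis never defines its
  transposon category, so the union of mobile-element classes is used;
- DHS regions are used as-is by default (`dhs_flanks` widens them by 2 kb
  when desired), since whether open-chromatin regions also received flanks
  is ambiguous in the design being followed.

Genome-wide density uses fixed windows (default 1 Mb); a circle is counted
once, in the window containing its start coordinate.

## Feature quantification

The default roster is exactly 58 features: the total eccDNA count per
million mapped reads (1); for each of the 24 categories the per-million
overlap count and the overlap proportion (48); and raw overlap counts for
nine categories of particular interest — gene, enhancer, DHS, all repeats,
SINE, LINE, LTR, Alu, MIR (9). The roster is configuration, not code; the
58-count is enforced only for the default. Proportions of a zero-eccDNA
sample are defined as 0 with a logged warning. Group comparisons use the
two-sided Mann–Whitney/Wilcoxon rank-sum test with tie correction and no
multiplicity adjustment by default (matching how such per-feature panels
are usually presented); Benjamini–Hochberg q-values are a flag away.

## Diagnostic harness

Five families — random forest, logistic regression, Gaussian naive Bayes,
RBF SVM (with probability calibration), k-nearest neighbors — are compared
by mean AUC over stratified ten-fold cross-validation on a stratified 2:1
train/test split, with small grid searches (≤ 4 combinations per family:
tree depth, regularization strength, smoothing, margin penalty, neighbor
count). The linear, margin and neighbor models see train-standardized
features inside the CV pipeline; tree and Bayes models see raw values.
The family with the highest CV AUC (ties to the first listed) is refit on
the full training set and evaluated held-out: sensitivity, specificity,
precision, F1 and accuracy at the 0.5 probability threshold, plus AUC.
With a single-class test set the AUC is flagged undefined rather than
faked. Everything is deterministic under the harness seed.

Feature attribution is a Monte-Carlo estimate of interventional Shapley
values, written in-package: feature orderings are sampled (default 8), the
model is evaluated on a background subsample (default 20 training rows)
with the explained sample's features revealed one at a time, and the
marginal probability changes are averaged. The telescoping construction
makes per-sample attributions sum exactly to `f(x) − E[f(background)]`,
which the tests assert. Features are ranked by mean |value|; the top 10
are reported. A permutation-importance fallback (AUC drop under feature
shuffling) is provided and flagged in the report.

## Survival stage

Kaplan–Meier estimation and Cox fits are delegated to lifelines (Efron
handling of tied event times). The log-rank statistic used inside the
cutoff scan is computed in-package, vectorized over event times, and is
cross-checked against lifelines in the tests.

Each feature is binarized at its *optimal cutoff*: an exhaustive scan over
midpoints between consecutive sorted unique values, restricted to the
10th–90th percentile band with both groups ≥ 3 samples, maximizing the
two-group log-rank statistic (ties break toward the lower cutoff). The
naive log-rank p at the selected cutoff is reported with an explicit
`selection_biased` flag — maximal selection inflates significance — and an
optional permutation-corrected p (feature values shuffled, max statistic
re-scanned) is available. Univariate Cox on the binarized groups yields
the hazard ratio with Wald 95% CI; non-convergence (e.g. complete
separation) is reported distinctly rather than as a silent number.
Samples with missing follow-up are dropped from survival stages only,
with a logged count.

The DFS-event classifier reuses the diagnostic harness with event (1) vs
event-free (0) labels. Events are rare (~15 of 80), so a stratified
ten-fold CV cannot be populated; the fold count is capped at the
minority-class size of the training split, with a warning. Binary event
classification (not time-to-event) is the endpoint because the stage
reports an AUC, not a concordance index.

## Synthetic cohort generator

The generator emulates the study conditions end to end and is fully
determined by `(config, seed)` (NumPy `SeedSequence` spawning; byte-
identical outputs on re-runs, asserted by tests).

- **Genome/tracks**: 3 chromosomes × 1 Mb by default. Genes are placed by
  a renewal process (exponential gaps, mean 12 kb; lengths 2–15 kb) with
  alternating exon/intron segments and terminal UTRs on random strands;
  enhancers (~60/Mb), CpG islands (~50/Mb) and DHS (~80/Mb) are uniform;
  the repeat table (~300/Mb) draws the seven RepeatMasker classes with
  SINE-heavy probabilities and assigns Alu/MIR families within SINE. Every
  class is guaranteed non-empty.
- **Cohort**: 81 tumor / 33 normal samples, mean 300 candidates each
  (Poisson) — a desk-scale stand-in for real per-sample counts, which run
  orders of magnitude higher; mapped reads uniform in 2–20 million.
- **Lengths**: tumors draw from a two-component log-normal mixture with
  modes 180 and 360 bp (weights 0.55/0.45, σ = 0.12), normals from a
  single mode at 150 bp with σ = 0.35. This reproduces the bimodal tumor
  profile and a tumor > normal mean-length ordering; the real-data mean
  (≈ 835 bp, driven by a long tail) is not a target at this scale.
- **Placement**: a category is sampled per candidate (background mass
  0.30; gene 0.25; regulatory and repeat categories the rest), then a
  start uniform among positions overlapping a random interval of that
  category. Tumor weights carry multiplicative uplifts (enhancer ×1.8,
  DHS ×1.7, CpG ×1.6, exon ×1.5, repeat classes ×1.3–1.5, satellite ×1.0),
  planting the direction of the observed group differences with
  satellite flat. `SimulationConfig.null()` zeroes every effect for
  calibration runs.
- **Read support**: 90% of candidates draw support above all five filter
  thresholds; the rest violate exactly one randomly chosen criterion, and
  the truth labels are serialized so filter recovery is checkable by
  construction.
- **Survival**: tumor DFS times are exponential proportional-hazards draws
  with baseline hazard 0.0022/month and planted log-hazard ratios (+0.7 on
  the standardized intron and all-repeat proportions — high values
  hazardous), administrative censoring at 60 months, a small independent
  censoring clock, and 12% lost to follow-up with missing DFS fields.
  These defaults center the event count near 18% of followed tumors and
  the lost count near 10 of 81, matching the cohort structure emulated.

What the generator does *not* model: read-level data, chimeric-read
artifacts, copy-number structure, sample-level burden dispersion over the
full real range, or inter-feature correlation beyond what shared placement
induces. Passing tests therefore demonstrate the pipeline's statistical
machinery — not that real tissue would yield the same numbers.

## Numerical and design choices

- Interval merging unions overlapping *and* abutting intervals (identical
  coverage; simplifies complements). Abutting query/target intervals do
  not overlap (half-open semantics).
- Coverage-increase ratios read from candidate tables are clipped into
  [0, 1] at the boundary; negative caller values mean "no increase".
- `compare_groups` returns p = 1 when all values are tied (no evidence of
  a shift, and the rank-sum statistic is degenerate there).
- Model selection ties break to the first-listed family; the split and
  every fold assignment derive from the single harness seed.
- The retrain-on-top-k-features mode is deliberately not the default: the
  harness trains on all 58 features, and the top-10 list is reporting.
- Problem sizes in the test-suite calibration runs (e.g. 50 effect-free
  cohorts of n = 120; Cox recovery at n = 400 × 100 replicates) were
  chosen as the smallest sizes at which the checked properties are
  statistically stable.

## Known limitations

- The optimal-cutoff naive p is biased by selection; the permutation
  correction is available but not free, and the screen's significance
  counts use the naive p by design (with the bias flagged in the output).
- The Shapley estimate is Monte-Carlo; ranks of near-tied features can
  swap across seeds. The efficiency identity, not rank stability, is the
  tested guarantee.
- With ~15 events, prognostic-model AUCs have very high seed-to-seed
  variance; single-split numbers at this n are descriptive, not
  benchmarks.
- The reader for Circle-Map tables assumes the documented 11-column
  Realign order; other layouts need the column-map override.
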