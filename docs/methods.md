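# Methods

## Scope and data model

The pipeline operates on a probes × samples expression matrix (log2
intensities after quantile normalisation), a clinical table with a
right-censored time-to-event outcome (time in months, event 1 = relapse,
0 = censored) and standard covariates (age, ER status, grade 1–3, tumour
size, nodal status), and flat gene sets in GMT format. Endpoint labels
(RFS, DRFS, …) are metadata only; the engine treats every input as generic
right-censored time-to-event data. Probe-to-gene annotation is taken as
given in the input's `gene_symbol` column; no re-annotation is attempted.

## Normalisation

Quantile normalisation forces every sample to the per-rank cross-sample
mean distribution while preserving within-sample order. Ties within a
column receive the mean of the rank means they span. The matrix must be
complete; probes missing in more than 20% of samples are dropped at read
time and the remainder can be imputed with the per-probe median
(`impute_row_median`). Upstream platform-specific background correction is
assumed done; no cross-platform normalisation is attempted — separate
series are analysed separately. Two display baselines for fold change are
provided: against the sample with the lowest expression of the gene
(reference FC = 1 by construction) and against the median of a panel of
normal-tissue pools; both operate per-probe on the log2 scale.

## Seed-clustering

The selection statistic for transcript g against seed probe s is the
bootstrap **support**: over B resamples of the n samples drawn with
replacement (resamples leaving a seed constant are redrawn), the fraction
in which Spearman's ρ(g, s) is significant after Bonferroni adjustment over
the m = P − 2 candidate transcripts **and** agrees in sign with the
full-data ρ. Spearman uses average ranks for ties and the two-sided
large-sample t approximation, p = 2·P(T_{n−2} ≥ |ρ|√((n−2)/(1−ρ²))).
**Concordance** across the two seed probes is min(support₁, support₂) when
the full-data signs agree and 0 otherwise.

A transcript is selected (co-expressed with both ρ > 0, inversely expressed
with both ρ < 0) when both supports reach `support_threshold` and its
concordance exceeds the cut of a **random-seed-pair null**: R pairs of
distinct non-seed probes are treated as pseudo-seeds, the identical
dual-seed computation is run for each, and the maximum concordance over
transcripts is recorded per pair; the cut is the empirical (1−α) quantile
of those R maxima. Using the per-pair *maximum* makes the cut familywise:
a real selection must beat what the best-looking transcript achieves under
a random seed pair. Randomising seed identity rather than permuting the
matrix preserves the global correlation structure that the null should
retain. Probes collapse to genes by the any-probe rule: a gene is selected
if any of its probes is.

Defaults: B = 1000 (unit tests and the acceptance run use 200; support is
a proportion, so B only sets its granularity), R = 200 (50 in the
acceptance run), α = 0.05, `support_threshold` = 0.95. The support rule is
monotone in α-stringency and reduces to the plain full-data test at B = 1
with an identity resample, which the tests exploit as an oracle hook. All
resampling is driven by one integer seed through numpy `SeedSequence`
spawning, so outputs are bit-reproducible.

Implementation note: the bootstrap engine ranks the whole resampled matrix
once per replicate and computes all seed correlations as one matrix
product, so the R null pairs share a single pass; it therefore requires a
complete matrix. Pairwise deletion of missing values is honoured in the
scalar `spearman` (used by the association tests) but not inside the
engine — impute or drop missing values first (the readers and
`impute_row_median` do this); pairwise deletion per probe would force
re-ranking the seed vector against every probe's missingness pattern.

## Survival analysis

Expression enters models in two forms. **Median dichotomisation** labels a
sample "high" iff its value strictly exceeds the cohort median (ties go to
"low" — a deterministic convention), used for Kaplan–Meier display,
log-rank tests and the univariate binary Cox model. **Rank normalisation**
maps values to (rank − 1)/(n − 1) with average ranks for ties, so the
fitted Cox model is invariant to any strictly monotone transform of the raw
scale; multivariate models always use this form. Kaplan–Meier, log-rank
and Cox partial-likelihood maximisation (Efron tie handling, Newton
iterations to precision 1e-9, 95% Wald intervals) are delegated to
`lifelines`; constant covariates and no-event inputs are rejected before
fitting, incomplete-covariate rows are dropped with logged counts, and
non-convergence (including monotone likelihoods from complete separation)
surfaces as an error suggesting penalisation.

**Backward selection** repeatedly refits the model without each unprotected
variable, computes the likelihood-ratio p-value of the removal (χ², 1 df;
the β = 0 Efron log-likelihood is computed directly from risk-set counts
when the last variable is tested), and drops the variable with the largest
p while that p ≥ `p_exit` (default 0.05; ties break by column order;
`p_exit` ≥ 1 is the "select nothing" convention that strips every
unprotected term). The studied gene is protected by default so its
adjusted hazard ratio is always reported. Covariate coding: grade ordinal
numeric 1–3, ER/nodes binary indicators, age and size continuous.

**Helmert contrast.** The four groups from median splits of two genes are
ordered (−/−, +/−, −/+, +/+) and coded with scaled Helmert columns (each
classical Helmert column divided by its level count) so that the k-th
coefficient equals the log-hazard of level k+1 minus the mean of levels
1..k directly; the model is saturated in the four levels, so the identity
holds for unbalanced groups. The reported contrast is the third
coefficient: the +/+ group against the average of the other three, with
its Wald CI and p. The coefficient is symmetric in which gene is called
"a" or "b". The scaling convention (difference of log-hazards, not the
classical Helmert coefficient, which is a quarter of it) is this package's
choice; published analyses rarely state theirs.

**Signature scores.** Published signatures arrive as flat gene lists. Each
matching probe is rank-normalised across samples, the per-sample mean over
probes is taken, and the mean is rank-normalised again to [0, 1]. This
mean-of-ranks score is a documented stand-in: the original signature
papers' scoring formulas are not reproduced here, but any score that is a
monotone function of the same ranks yields identical Cox fits after the
final rank normalisation.

## Association tests and enrichment

Expression vs binary ER status uses the Mann–Whitney U test, exact when
both groups have ≤ 8 observations and the tie-corrected normal
approximation otherwise; expression vs ordinal grade uses Spearman rank
association of expression against the grade codes. Both drop incomplete
rows per test with logged counts, and report display stars at 0.05 / 0.01
/ 0.001.

Over-representation uses the hypergeometric upper tail P(X ≥ k) for an
overlap of k between the query (n genes in the universe) and a set (K in
the universe of N), with Benjamini–Hochberg FDR across tested sets
(step-up with monotonicity enforcement, via scipy). The universe defaults
to all gene symbols on the expression matrix; sets are intersected with
the universe first and zero-overlap sets skipped; duplicate query symbols
are collapsed. Only single-annotation enrichment is implemented — no
ontology graph propagation or concurrent-annotation itemsets. Venn
counting for 2–4 lists enumerates every intersection pattern exactly.

## Synthetic cohorts

`gen_expression` draws a standard-normal latent factor f per sample;
module members get baseline + λf + ε and inverse members baseline − λf + ε
with ε ~ N(0, σ²), everything else pure noise. Pairwise member correlation
is λ²/(λ²+σ²); the default λ = √1.5, σ = 1 targets 0.6. The seed gene is
carried by two probes, mirroring dual-probeset arrays; `module_size = 0`
degenerates to an i.i.d. matrix for false-positive control. Defaults are
desk-scale stand-ins for the motivating cohorts: 150 samples, 2000 probes
(for a ~22k-probe array), a 100-gene module (mirroring the ~97-gene result
such analyses report), 20 inverse members.

`gen_clinical` draws ER-negativity from a logistic model in the
rank-normalised seed expression r ∈ [0, 1] (full-range odds ratio `or_er`,
default 3, baseline prevalence 30% at the cohort median) and grade from a
cumulative-logit ordinal model (slope `beta_grade`, default 1.5, grade mix
≈ 20/45/35% at the median); age ~ N(57, 10²) clipped to [30, 88] years,
tumour size log-normal around 2 cm, nodal positivity 35% — all independent
of expression. Note the full-range OR of 3 induces only a modest
point-biserial association (~0.15), so a Mann–Whitney test at n = 150
detects it in roughly 40% of cohorts; the null calibration (OR = 1) is
exact and is what the acceptance checks assert.

`gen_survival` draws exponential event times with hazard
`baseline_rate`·exp(Σβz) (default baseline 0.01/month) and independent
uniform administrative censoring whose horizon is bisected so the achieved
censoring fraction hits the target (default 0.6, i.e. ~40% events) within
±0.05; unattainable targets warn with the achieved rate. `gen_cohort`
composes the three generators with consistent sample ids and serialises
the planted truth as JSON. The planted log-hazards act on rank-normalised
expression of the seed gene and of a designated module partner gene,
defaults log 8 and log 3 — anchored to the effect magnitudes reported for
seed-gene prognosis in such cohorts (multivariate HR ~8 for the seed gene
as a ranked covariate; ~3 for a cyclin-E-like partner) so the two-gene
stratification reproduces the qualitative pattern of interest: the
double-overexpressing group has the worst Kaplan–Meier curve.

What the generator does **not** emulate: platform-specific probe
behaviour, batch effects, multi-factor module structure, informative
censoring, and covariate-dependent censoring. Passing recovery tests on
this design therefore shows the machinery is correct and calibrated under
its stated assumptions, not that any specific clinical finding replicates.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full planted design
(2000 × 150) with B = 200 and R = 50 for the single-seed recovery checks
and B = 60, R = 30 for the ten-seed average — support is a proportion, so
these sizes set Monte-Carlo granularity, not the statistic itself. Cox
engine calibration uses n = 500 for point recovery and 100–200 replicates
at n = 300 for CI coverage; the Helmert null uses 100 replicates at
n = 400; null-calibration checks use 500 simulations per test. Numerical
conventions: Spearman p values clip ρ to ±1 before the t transform;
quantile-normalisation ties average the spanned rank means; the
minimum-expression fold-change reference breaks ties by column order (and
logs the tie); bootstrap replicates with a constant seed are redrawn; the
backward-selection tie-break is column order. All stochastic stages
require an explicit integer seed and derive independent streams by
`SeedSequence` spawning; identical inputs and seed give byte-identical
outputs, including TSV formatting (`%.17g` for data, `%.10g` for result
tables).

## Known limitations

Cross-platform integration, probe re-annotation, raw-array preprocessing
and competing-risks/time-varying extensions are out of scope. The
random-seed-pair null assumes enough non-module probes that most random
pairs are unrelated; in a matrix dominated by one module the cut becomes
conservative. The backward-selection p-values are not adjusted for the
selection path (as is standard for this procedure). Proportional-hazards
diagnostics are limited to lifelines' warnings; no formal Schoenfeld test
is run.
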