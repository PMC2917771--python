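# seedsurv

Is a gene of interest the marker of a co-regulated transcriptional module,
and does its expression carry prognostic information that survives
adjustment for standard clinical variables? `seedsurv` implements the full
analysis pipeline for asking this of a clinical expression cohort —
originally motivated by the study of DNA-repair genes such as *POLQ* in
early breast cancer, but applicable to any seed gene measured on a bulk or
single-cell expression matrix with right-censored outcomes.

## What it computes

**Seed-clustering with bootstrap resampling.** The seed gene is represented
by two independent probes. For each seed probe and each of B bootstrap
resamples of the samples, every transcript is tested for Spearman rank
association with the seed (two-sided t-approximation, Bonferroni-adjusted
over the m candidate transcripts). A transcript's *support* is the fraction
of resamples in which it is significant with the same sign as on the full
data; its *concordance* is min(support₁, support₂) when the two seed probes
agree in sign, else 0. Transcripts are selected as co- or inversely
expressed when both supports reach a threshold (default 0.95) and the
concordance exceeds the empirical (1−α) quantile of a null distribution
built by rerunning the whole dual-seed computation on R random pairs of
non-seed probes, recording each pair's maximum concordance.

**Survival modelling.** Kaplan–Meier estimation and log-rank tests on
median-dichotomised expression; Cox proportional-hazards models (Efron tie
handling, via `lifelines`) with expression entered as a continuous
covariate ranked and normalised to [0, 1] — making the fit invariant to any
monotone transform of the raw values; stepwise backward likelihood-ratio
selection with the studied gene protected; and a Helmert-contrast analysis
of the four groups defined by median splits of two genes, whose final
contrast estimates the hazard of the double-overexpressing (+/+) group
against the average of the other three.

**Associations and enrichment.** Mann–Whitney U for expression vs binary
ER status, Spearman rank association vs ordinal grade, hypergeometric
over-representation of gene lists in GMT annotation sets with
Benjamini–Hochberg FDR, and exact Venn-region counting for 2–4 signature
lists.

**Synthetic cohorts with ground truth.** A generator plants a single-factor
co-expression module (member pairwise correlation λ²/(λ²+σ²), the seed gene
carried by two probes), clinical covariates whose ER status and grade shift
with seed expression, and exponential proportional-hazards survival with
administrative censoring tuned to a target rate — so every stage of the
pipeline can be scored against known truth.

## Worked example

```sh
seedsurv simulate --seed 21 --out cohort/
seedsurv seedclust --expr cohort/expr.tsv --seed1 SEEDG_P1 --seed2 SEEDG_P2 \
    --boot 200 --null-sims 50 --seed 17 --out cohort/clust.tsv
seedsurv survival --expr cohort/expr.tsv --clinical cohort/clin.tsv \
    --gene SEEDG --mode multivariate \
    --covariates er_status,node_status,age,grade,tumour_size \
    --out cohort/cox.tsv
```

The seed-clustering step prints

```
co-expressed genes: 98; inversely expressed: 20; null cut: 0.0600
```

— all 98 planted co-expressed genes and all 20 anti-correlated genes are
recovered; the random-pair null puts the concordance cut at 0.06, far below
the ≈1.0 concordance of true module members. The survival step prints

```
SEEDG: HR 52.612 (95% CI 17.245-160.515), p=3.32e-12; retained: SEEDG
```

— the hazard ratio of the seed gene per unit of rank-normalised expression
(lowest- to highest-expressing sample) after backward selection. The planted
full-range effect is HR 8, but the seed's rank also proxies the correlated
partner gene's planted effect (HR 3, omitted from this model), and with
only ~60 events the per-unit-rank estimate is noisy — hence the large point
estimate and wide interval; the clinical covariates are correctly dropped.

Library use mirrors the CLI: `seedsurv.seed_cluster`, `seedsurv.cox_fit`,
`seedsurv.backward_select`, `seedsurv.helmert_analysis`,
`seedsurv.hypergeom_enrich`, `seedsurv.gen_cohort`, etc.

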