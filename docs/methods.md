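# Methods

## Scope and model

`prostasig` treats a bulk prostate tumour transcriptome as a convex mixture
of four cell-compartment archetypes (luminal epithelium, basal epithelium,
fibromuscular stroma, endothelial stroma) and reads the tumour's position on
the luminal differentiation axis through rank-based single-sample enrichment
of compartment-specific gene sets. Everything downstream — quartile
stratification, the LumE-low phenotype, the 10-gene discriminant classifier,
compound ranking — is built on those scores.

## Signature discovery

For each compartment, genes are tested one-vs-rest with a Welch (unequal
variance) two-sample *t*; Welch is preferred over the pooled *t* because the
design is unbalanced (5 target vs 15 rest samples) and compartment-specific
expression inflates rest-group variance. Each group variance is floored at
ε = 1e-8 so constant genes yield t = 0 rather than a division by zero.

Significance uses label permutations: one stream of uniformly drawn sample
permutations (shared by all genes and all compartments in a call, seeded) and
the add-one estimate p = (1 + #{|t*| ≥ |t_obs|}) / (B + 1). With B = 1000 the
smallest attainable p is 1/1001 ≈ 0.001; this granularity, not the effect
size, is usually what limits recovery (below). Permutation p-values are
adjusted per compartment with Benjamini–Hochberg; the procedure is
implemented directly (a dozen lines) and cross-checked against statsmodels
in the tests.

Genes enter the compartment's metagene if q < 0.05 and t > 0, each gene is
assigned only to the compartment where its t is largest (making the panel
pairwise disjoint, which keeps downstream scores interpretable), and the top
`n_genes` by t are kept (default 138 per set; tests use the size of the
planted truth). Disjointness-by-max-t is our convention; an analysis that
allows shared genes can pass `n_genes` large and post-process `stats`.

### Limits of recovery at small effect sizes

At a marker effect of 3 within-group SDs with 5 replicates per type, the
one-vs-rest Welch t has expectation ≈ 5.8 but substantial spread (the
variance estimates carry 4 degrees of freedom), so roughly 5–10% of true
markers land at t < 3.5. For such genes the permutation p cannot reach the
BH threshold (≈ 0.002–0.005 at a 200-gene universe), because label
permutations that overlap the true grouping regenerate large |t*|. Marker
recovery at this effect size is therefore intrinsically knife-edged:
panel-level Jaccard against planted truth sits around 0.90–0.97 across
seeds, and reaches 1.0 once effects exceed ~5 SDs (tested). Recovery is
also universe-size dependent — the BH threshold scales with 1/m — which is
why the discovery tests use a compact 200-gene universe rather than a
genome-scale one; the statistical structure (FDR control, null behaviour,
top-t truncation) is identical.

## Single-sample enrichment

The per-sample score is the integrated running-sum statistic described in
the README, not the maximum deviation. Design choices:

- **Weight exponent α** defaults to 0.75 (the widely distributed module
  default); 0.25 is covered in tests and available via `alpha=`. Singleton
  sets are α-invariant by construction.
- **Ties**: tied expression values share an average rank for the weights;
  the walk order itself breaks ties by gene id ascending, so scoring is
  deterministic.
- **Monotone invariance**: only ranks enter, so any strictly increasing
  transform of a sample's values (including linear↔log2) leaves the score
  unchanged. This is what makes cross-platform cohorts comparable.
- **z-log2**: per set-row, log2 then z-score with sample SD (n−1). Raw
  scores can be negative, where log2 is undefined; such rows are shifted by
  (1 − min) first, with the offset recorded in `params` and a warning
  logged. This shift is our convention, chosen to preserve ordering and
  positive-scale invariance on the unshifted branch; constant rows
  standardise to zeros. A 1-sample matrix is rejected (no sample SD).
- **Range normalisation** (raw / (max − min) over the whole matrix) is
  provided but off by default, since z-log2 is the layer every downstream
  step consumes.

## Stratification and group statistics

Quartiles use linear interpolation between order statistics (the default of
mainstream numeric stacks); a sample is "low" iff score ≤ Q1 and "high" iff
score > Q3. The boundary rule matters only under ties and is stated rather
than discovered. AUC is the Mann–Whitney rank statistic with ties counted
0.5 (verified against an all-pairs oracle), and two-group comparisons are
Welch t-tests with the same ε floor for constant groups. Survival analysis
is deliberately out of scope: stratification labels export as TSV for any
survival package.

## Mini-classifier

Training reproduces the cross-cohort derivation structure: quartile labels
on the training cohort's LumE z-scores; candidates restricted to genes
present in all supplied datasets; the metagene members themselves excluded
(the classifier should generalise beyond the signature that defined its
labels); a signed fold-change screen on linear-scale expression
(r = mean_nonlow/mean_low, sFC = r or −1/r, strict |sFC| > 1.25); forward
stepwise selection minimising Wilks' Λ = det(W)/det(T) at each step (ties by
gene id; the count is fixed at 10, no p-to-enter rule); and a two-class
linear discriminant w = S_pooled⁻¹(μ_nonlow − μ_low) with pooled
within-class covariance (dof n−2). Priors default to training class
frequencies (≈ 25/75 under quartile labelling). When S_pooled is
near-singular (condition number > 1e8) a ridge λ = 1e-6·tr(S)/p is added.

The discriminant is fit on log2-scale expression (declared-linear input is
converted with a pseudocount of 1); the fold-change screen runs on the
linear scale. Positive coefficients mark genes overexpressed in
non-LumE-low samples. Prediction refuses silently imputing missing model
genes; the supported fallback is retraining on the remaining genes, which
the tests exercise as a 9-gene model. The published 10-gene panel (AMACR,
ANXA3, IDH1, KLK3, SLC13A3, C3, COL4A1, CYP7A1, MORF4L2, RRM1) ships as a
named constant for scoring-only use; its discriminant coefficients were
never published, so any fitted model here is numerically its own.

## Treatment shifts

Paired pre/post profiles are compared on one scoring layer (z-log2 by
default). Because z-log2 is cohort-relative, pre and post must be scored
jointly — scoring the arms separately would standardise the treatment
effect away, and `delta_scores` refuses mismatched layers or unmatched
sample keys. The listing rule keeps compounds whose mean LumE delta
strictly exceeds the threshold (default 2 standardised units); a
`base_down` direction and a `both` mode (LumE up AND BasE down, with
consistency across cellular contexts by intersecting pass lists) are also
provided. Whether the original ">2" rule operated on standardised
differences or fold changes of raw scores is not decidable from the
description; standardised differences are the default and the alternative
reading is available by ranking on the raw layer.

## Synthetic cohorts

Expression is log-normal: genes live on log2 scale at baseline 8.0 with
additive Gaussian noise (noise_sd, default 1.0 log2 units); a marker gains
`marker_effect` (default 3.0 log2 units = 8-fold = 3 within-group SDs) in
its own compartment. The sorted design is 4 types × 5 replicates. Bulk
samples draw mixture proportions from a Dirichlet (default concentration
(6, 3, 3, 3), luminal-dominant as in primary prostate tissue), mix the
*linear-scale* archetypes (transcripts add linearly), and multiply by
log-normal noise. A `low_luminal_fraction` subset (default 25%, matching
the quartile phenotype) draws its luminal concentration divided by 5; a
`dedifferentiation` flag instead models marker loss within luminal cells by
attenuating the luminal marker effect at unchanged mixture weights.
Platform families drop a random (1 − overlap) subset of background genes
per dataset, never markers.

Treatment pairs use low-luminal models (luminal weight /5) with tight
mixtures (concentrations ×30, replicate-level variability) so the luminal
score has headroom to rise. Planted shifts are defined on the *jointly
standardised* z-log2 scale; the per-compound marker boost that realises
each target is found by root-finding against the actual scoring function,
iterated a few rounds because every compound's boost feeds back into the
common scale. Two consequences are worth stating: a shift shared by every
sample would standardise itself away (the achievable mean delta is bounded
by ≈ 1/√(p(1−p)) for mover fraction p), so defaults plant geometrically
decreasing shifts (2.5, 1.25, 0.625, … and an untreated control at 0) in
which only the lead compound crosses the ">2" rule; and unreachable targets
raise an explicit error rather than silently under-shooting.

What the generators deliberately do not emulate: probe-level effects,
batch structure, platform-specific dynamic ranges, correlated gene modules
beyond cell-type identity, or clinical covariates (survival, grade,
mutations). Passing tests therefore demonstrate the correctness and
statistical behaviour of the machinery under a clean mixture model, not
performance on real tumours.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 200–1360-gene universes,
20-sample sorted designs, 300-sample bulk cohorts, 4-dataset families,
18 treatment pairs, 1000 permutations. All generators and analyses are pure
functions of (config, seed); CLI subcommands rerun with the same inputs
produce byte-identical files (tested).
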