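# prostasig

Prostate tumours are bulk mixtures of luminal and basal epithelium plus
fibromuscular and endothelial stroma, and where a tumour sits on the
luminal–basal axis carries prognostic information: primary tumours with low
luminal differentiation behave more aggressively and respond differently to
androgen-targeted therapy. `prostasig` implements the full analysis chain
for reading that axis out of transcriptomes:

1. **Signature discovery** — derive cell type-specific *metagenes* from a
   sorted-cell expression experiment by one-vs-rest Welch *t*-tests with
   permutation *p*-values and Benjamini–Hochberg FDR control, keeping the
   top-*t* genes per compartment as pairwise disjoint gene sets.
2. **Single-sample scoring** — compute rank-based single-sample enrichment
   (ssGSEA) scores of each metagene in each tumour. For one sample with *N*
   genes ranked by expression, a set *S* scores

   &nbsp;&nbsp;ES(S) = Σᵢ [ P_in(i) − P_out(i) ],&nbsp;
   P_in(i) = Σ_{g∈S, rank(g)≤i} r_g^α / Σ_{g∈S} r_g^α,&nbsp;
   P_out(i) = |{g∉S : rank(g)≤i}| / (N−|S|)

   with rank weights r_g = N − rank(g) + 1 — the *integrated* running sum,
   which distinguishes the single-sample statistic from the max-deviation
   statistic of two-group GSEA. Scores are standardised per set by
   *z-log2* (log2, then z-score across samples) so cohorts from different
   platforms are directly comparable. The four resulting scores per sample
   are the luminal, basal, fibromuscular and endothelial enrichments
   (LumE / BasE / FibromE / EndoE).
3. **Stratification** — split a cohort by LumE quartiles into low (≤ Q1),
   intermed, and high (> Q3) groups; the LumE-low quartile is the
   aggressive phenotype of interest.
4. **Mini-classifier** — train a compact linear discriminant
   (w = S_pooled⁻¹ Δμ, forward stepwise selection by Wilks' Λ, 10 genes by
   default, candidates restricted to genes shared across platforms, outside
   the metagenes, with |fold change| > 1.25) that calls LumE-low directly
   from a handful of expression values.
5. **Drug screening** — compare metagene scores in paired pre/post
   treatment profiles and list compounds whose LumE increase exceeds a
   threshold (default > 2 standardised units): luminal-restoring candidates.

A synthetic-cohort module generates every input with known ground truth —
sorted-cell experiments, Dirichlet-mixture bulk cohorts with a planted
low-luminal subpopulation, multi-platform dataset families, and pre/post
treatment pairs with planted score shifts — so the whole chain is testable
end to end without any external download.

## Worked example

```sh
python examples/02_score_and_stratify.py
```

```
Spearman(LumE z-score, true luminal fraction) = 0.952
stratification: 75 low / 150 intermed / 75 high  (cutpoints Q1=-0.20, Q3=0.62)
planted low-luminal vs rest: Welch t = -13.3, p = 8.47e-22
AUC of (low) LumE score for detecting planted low tumours: 0.964
```

300 synthetic bulk tumours are scored with the four metagenes; the
standardised luminal score tracks each sample's true luminal fraction with
Spearman ρ = 0.95, quartile stratification splits the cohort 75/150/75, and
the score alone detects the planted low-luminal subpopulation with AUC 0.96.
The other examples cover signature discovery (`01`), classifier training
and out-of-sample evaluation (`03`), and compound ranking (`04`).

Every stage is also exposed as a `prostasig` CLI subcommand
(`simulate`, `extract-signatures`, `score`, `stratify`, `train-classifier`,
`predict`, `drug-response`); identical inputs and seeds give byte-identical
outputs.

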