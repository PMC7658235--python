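# Methods

`azasig` analyzes baseline (pre-treatment) bulk expression of MDS
patients to separate azacitidine responders from non-responders and to
carry the resulting gene signatures into independent cohorts. This note
records the models, the parameter choices that matter, what the
synthetic data do and do not emulate, and the numerical decisions taken
where the design was genuinely open.

## Expression model and transform

All statistics operate on `log2(value + 1)` of a non-negative FPKM-like
gene-by-sample matrix. Raw FPKM spans orders of magnitude and its
variance grows with the mean, so t-tests and correlations on the raw
scale are dominated by the highest expressors; `log2(x + 1)` is the
conventional variance-stabilizing choice and is exact at zero. Missing
values are not permitted anywhere — the pipeline has no imputation, and
readers fail loudly rather than guess. Batch adjustment is out of scope:
the pipeline takes an already-adjusted matrix as given.

## Differential expression

Per gene, a two-sided Welch (unequal-variance) t-test between
responders and non-responders on the log2 view. Welch rather than the
pooled test because the groups are unbalanced (14 vs 9 by design) and
per-gene variances differ; with balanced variances the two tests agree
closely. DEGs are genes with unadjusted p < 0.01 — deliberately
uncorrected, matching the discovery-style screen this stage feeds
(enrichment and clustering downstream aggregate over genes, which is
where error control happens). Genes constant in both groups get t = 0,
p = 1 so counts remain well defined; a configurable low-expression
filter (default: drop genes zero in ≥ 90% of samples) runs before
testing and can be disabled.

The DEG submatrix is clustered in both dimensions with average linkage
on 1 − Pearson correlation distance after z-scoring each gene row — the
common heatmap default for expression data; the metric makes the result
invariant to each gene's scale and offset. The sample dendrogram is cut
at k = 2 (the analysis is a dichotomy by construction); constant rows
are dropped with a warning before correlations.

## Over-representation and the overlap network

One-sided (enrichment) Fisher's exact test per gene set from the 2×2
table {in-set × in-DEG} over a stated universe. The universe is the set
of genes that survived the expression filter — not the genome and not a
collection-specific universe — because that is the population the DEG
screen actually drew from. Bonferroni's m is the number of sets with a
nonzero intersection with the universe; significance is corrected
p < 0.05.

Redundancy among significant categories is summarized as a network: for
each pair of significant sets, a one-sided Fisher test of membership
overlap **restricted to the DEG list as universe**, an edge when p falls
below the threshold (default 0.05 Bonferroni-corrected over the number
of pairs), annotated with the shared DEGs. Using the DEG list as the
overlap universe asks "do these two categories tag the same part of the
differential signal?", which is the question the network answers; a
whole-genome universe would instead measure static curation overlap.

## GSEA

Authored from scratch (no enrichment library stands behind it):

- **Ranking.** Signal-to-noise per gene, (μ_R − μ_NR)/(σ_R + σ_NR) on
  the log2 view, each group σ floored at max(0.2·|μ|, 0.2). The floor
  keeps near-constant genes from claiming extreme ranks in a 23-sample
  cohort. Descending order, ties broken by gene ID.
- **Enrichment score.** Weighted KS running sum: hit increment
  |r|^p / Σ_hits |r|^p (default weight p = 1), miss decrement
  1/(N − N_hits); ES is the running sum's signed maximum absolute
  deviation and the peak index is recorded. On an exact tie between the
  positive and negative extremes — possible because the miss decrement
  is quantized — the positive extreme is taken, consistently in the
  scalar and vectorized paths. If every hit weight is zero the hit
  increments fall back to uniform.
- **Permutation null.** Phenotype-label permutations (n_perm = 1000 by
  default; all C(n, n_R) assignments enumerated when fewer exist, which
  matters only for very small cohorts — at 14 + 9 there are 817,190).
  Gene-set permutation is not offered: with ≥ 7 samples per group the
  phenotype null preserves gene–gene correlation, which the set null
  destroys.
- **Normalization.** NES = ES / mean(|permuted ES of matching sign|),
  per set; nominal p is the sign-matched permutation tail; FDR uses the
  pooled sign-matched normalized null against the observed NES
  distribution; FWER uses the per-permutation extreme normalized NES.
  All four derive from one shared permutation stream. Sets whose
  sign-matched null is empty get a missing NES (logged) and are excluded
  from the FDR pool.
- **Set-size bounds.** 15–500 after intersection with the matrix, both
  configurable. Leading edges are set members at ranks ≤ peak (ES > 0)
  or ≥ peak (ES < 0).

The vectorized permutation engine computes, per permutation, group
statistics by matrix products against the label masks and ES from hit
positions only (the running sum is extremal only adjacent to hits); unit
tests pin it to the scalar path and to a brute-force running sum.

A caveat users should know: under phenotype permutation, a very strong
planted (or real) signal inflates its own permutation null — label
assignments overlapping the true grouping reproduce part of the signal —
so NES saturates with effect size. Larger coherent sets obtain tighter
nulls and hence more extreme NES at the same per-gene effect. This is
inherent to the method, not an implementation artifact, and it shaped
the synthetic defaults below.

## Signature scoring, classification, survival

A signature set's score in a sample is the mean log2 expression of its
leading-edge genes found in that cohort (exact gene-ID match; coverage
below 0.3 is flagged, zero coverage is an error). Scores are z-scored
per set across samples before clustering so sets on different scales
contribute equally. Samples are clustered on the z-scores (1 − Pearson,
average linkage, k = 2 fixed); the cluster with the higher mean
orientation statistic — mean responder-up z minus mean non-responder-up
z — is named responder-like. Prediction accuracy is the fraction of
samples whose cluster name matches their known group.

Survival uses the standard two-group log-rank test (χ², 1 df) and
Kaplan–Meier estimates with right censoring, via lifelines; the test is
pinned against a hand-computed O/E/V table in the suite.

## Mechanism-of-action scoring

A deliberately simplified network-perturbation analysis, preserving the
mechanism (edge-level joint-distribution change → gene-level
integration) while remaining fully testable:

- Per edge (a, b): within each group, rank-transform each gene across
  that group's samples, bin the pairs on a 4×4 grid with add-half
  pseudocounts, and score ½·KL(P‖Q) + ½·KL(Q‖P). Rank binning makes the
  score invariant to monotone transforms of either gene; 4 bins with
  pseudocounts are stable at 9–14 samples per group.
- Permutation p per edge from phenotype-label permutations, one stream
  shared across all edges so a gene's incident edges see identical
  nulls.
- Per gene: Fisher's combination X = −2Σln p_i ~ χ²(2k) over incident
  edges (exact zeros floored at 1/(n_perm + 1)), then Benjamini–Hochberg
  across genes. Fold change is reported as mean_NR − mean_R on the log2
  view (positive = up in non-responders).

Fisher's combination assumes independent edge p-values; edges sharing a
gene are positively dependent, so integrated p-values for hubs are
anti-conservative in absolute terms. They are used for ranking, and the
false-positive control of the BH step is verified empirically under the
null generator. A dependence-corrected combination (Brown's method) is a
known possible refinement.

## Synthetic cohorts — what they emulate, and what not

The discovery generator plants, by default, the study design: 23
samples (14 responders, 9 non-responders), 5,000 genes, 200 planted
differential genes in three modules — RESPIRATION (90 genes, up in
responders, 1.0 log2 units), APOPTOSIS (30 genes, up in responders,
1.5), WNT (80 genes, up in non-responders, 1.0) — gene baselines
uniform on [2, 9] log2 units, i.i.d. Gaussian noise with σ = 0.5.
Expression is generated as y = baseline + shift + noise, clipped at 0,
and returned as 2^y − 1 so the pipeline's log2(x + 1) view recovers the
generative scale exactly. Module sizes and shifts were chosen so all
three programs are detectable per gene while the set-level enrichment
extremes are the respiration (positive) and Wnt (negative) programs:
because NES saturates with effect size under phenotype permutation (see
above), the extremes are controlled by module size; the small apoptosis
module carries a stronger per-gene shift but an intermediate NES.

Decoy gene sets (default 50, sizes 15–100) are sampled from the
non-module gene pool, so they are exchangeable with the phenotype and
serve as true negatives for enrichment calibration; each shares a
configurable fraction (default 0.5) of its members with a previously
generated decoy, planting positive edges for the overlap-network stage.

The validation generator draws each of (default) 123 samples as
latently responder-like or non-responder-like (probability ½), shifts
signature-set genes accordingly, and draws exponential survival with
hazard h0 · HR^z, where z is the z-scored non-responder orientation of
the **realized** expression signature (so survival is tied to what the
scorer can actually measure, not to the latent label directly).
Defaults: h0 = 0.028/month (median ~25 months at baseline, plausible
for higher-risk MDS), HR = 3 per SD, independent censoring with
probability 0.2 (a censored sample reports a uniform fraction of its
event time). The rewired-hub generator for MoA benchmarks plants one
hub correlated (ρ = 0.9) with five partners in responders and
independent in non-responders, with identical marginals in both groups.

What the generators do **not** emulate: library-size variation,
gene–gene correlation outside the planted structure, mean–dispersion
coupling of counts, batch effects, platform differences between
RNA-seq and arrays, and non-proportional hazards. Passing the planted
recovery suite therefore shows the pipeline is correct and calibrated
under its stated assumptions — not that real cohorts of this size carry
as much signal as the planted defaults.

## Numerical and reproducibility choices

- One integer seed; every stage derives a named substream
  (`SeedSequence([seed, crc32(name)])`), so toggling a stage never
  shifts another stage's draws and same-seed pipeline runs are
  byte-identical (manifests record sha256 per output).
- TSV everywhere, `#` comments ignored, floats written with 12
  significant digits (round trips are lossless at that precision);
  dendrograms exported as Newick, gene sets as GMT.
- Permutation p-values are reported as plain tail fractions (0 is
  possible and is shown as 0, as permutation GSEA conventionally does);
  only the MoA integration floors zeros, because Fisher's combination
  cannot accept them.
- Welch t on a gene with zero variance in both groups: p = 1, t = 0 if
  means are equal, else p = 0 with infinite t. Correlation distances are
  clipped to [0, 2]; undefined correlations (constant profiles) become
  distance 1.
- Test problem sizes are scaled to the structure being tested (400–5,000
  genes, 50–200 replicates), chosen as the smallest sizes at which the
  calibration bands and recovery rates are statistically meaningful.

## Known limitations

- The ORA/overlap-network p-values depend strongly on the universe
  choice; printed overlap p-values from other analyses are not
  comparable unless the universe construction matches.
- FDR/FWER follow the standard permutation-GSEA construction and
  inherit its granularity at moderate permutation counts; nominal p has
  resolution 1/n_perm.
- The MoA integration ranks genes well but its absolute p-values are
  anti-conservative for hubs (dependent edges, see above).
- Cross-cohort gene matching is exact-string; no probe-to-gene or
  ortholog mapping is attempted, and unmatched genes simply reduce
  coverage.
- k = 2 is fixed throughout; the pipeline does not test whether a
  two-group structure is present, only where the split lies.
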