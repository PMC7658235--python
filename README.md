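# azasig

Expression signatures of azacitidine (AZA) response in myelodysplastic
syndromes (MDS).

Hypomethylating agents are standard bridging therapy for higher-risk MDS
before stem cell transplantation, yet there is no reliable way to tell
beforehand which patients' marrows will respond. `azasig` implements, as
a tested and reusable library, the baseline-expression analysis used to
separate AZA responders from non-responders in a 23-patient
MDS-with-excess-blasts cohort (14 responders, 9 with primary resistance)
and to carry the resulting signatures into independent cohorts:

1. **Differential expression** — per-gene two-sided Welch t-tests on
   log2(FPKM + 1), DEGs at unadjusted *p* < 0.01, two-way hierarchical
   clustering (1 − Pearson, average linkage) of the DEG submatrix.
2. **Over-representation** — one-sided Fisher's exact tests of the DEG
   list against GO-like gene sets with Bonferroni control, plus a
   category-overlap network whose edges mark significant DEG sharing.
3. **GSEA** — a from-scratch engine: signal-to-noise ranking
   *r* = (μ_R − μ_NR)/(σ_R + σ_NR) with floored σ, weighted
   Kolmogorov–Smirnov running sum (hit increment |r|^p / Σ|r|^p, miss
   decrement 1/(N − N_hits)), ES = signed maximal deviation,
   phenotype-permutation NES / nominal *p* / FDR / FWER, and
   leading-edge extraction at the running-sum peak.
4. **Signature scoring and survival** — gene-set-level scores (mean
   leading-edge log2 expression per sample), clustering of an
   independent cohort into responder-like vs non-responder-like groups,
   prediction accuracy against known labels, Kaplan–Meier curves and the
   two-group log-rank test.
5. **Mechanism of action** — a simplified network-perturbation scorer:
   per network edge, symmetrized KL divergence between the two groups'
   rank-binned joint expression distributions with a permutation *p*;
   Fisher's combination per gene; Benjamini–Hochberg across genes.
6. **Synthetic cohorts** — a first-class generator that plants the
   structure the analysis assumes (respiration/apoptosis modules up in
   responders, Wnt up in non-responders, survival hazard tied to the
   signature, decoy gene sets with controlled overlap, rewired network
   hubs), so the whole pipeline runs and validates itself with no
   external data.

The packaged clinical table (`azasig.load_clinical_table`) transcribes
the published 23-patient cohort; `azasig.summarize_cohort()` applies the
responder definition (CR or marrow CR → responder; primary progression
or stable disease without hematologic improvement → non-responder).

## Worked example

```python
from azasig import (
    SimulationConfig, simulate_discovery_cohort, simulate_validation_cohort,
    t_test_per_gene, select_degs, permute_and_normalize,
    score_samples, classify_cohort, prediction_accuracy, logrank_compare,
)

config = SimulationConfig(seed=1)          # 14 + 9 samples, 5,000 genes
cohort = simulate_discovery_cohort(config)

degs = select_degs(t_test_per_gene(cohort.expression, cohort.phenotypes))
print(len(degs))                            # 243 DEGs at p < 0.01

gsea = permute_and_normalize(cohort.expression, cohort.phenotypes,
                             cohort.gene_sets, n_perm=1000, seed=1)
print(gsea.table.sort_values("nes").iloc[[-1, 0]][["nes"]])
#              nes
# RESPIRATION  1.84   <- top positive NES (up in responders)
# WNT         -1.80   <- most negative NES (up in non-responders)

names = [m.name for m in config.modules]
val = simulate_validation_cohort(config, cohort.gene_sets.subset(names))
scores = score_samples(val.expression, gsea.leading_edge_collection(names),
                       {n: gsea.directions[n] for n in names})
partition = classify_cohort(scores)
print(prediction_accuracy(partition, val.truth["latent_label"]))  # 1.000
print(logrank_compare(val.phenotypes, partition).p_value)         # 7.85e-24
```

The numbers mean: the t-test recovers essentially all 200 planted
differential genes (plus the expected ~1% false positives); GSEA puts
the planted respiration program at the top positive NES and the Wnt
program at the most negative; the leading-edge signature classifies all
123 validation samples into their latent responder-like /
non-responder-like groups; and the log-rank test confirms the two groups
have sharply different survival (the generator ties hazard to the
signature with ratio 3 per SD).

`examples/` holds one short script per capability; each prints the
numbers above and a line on what they mean. A thin CLI mirrors the
stages (`azasig simulate | deg | enrich | gsea | score | survival | moa
| run`); `azasig run --config config.yaml --seed 1` executes the full
pipeline and writes a manifest with per-file checksums.

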