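# pwasforge

Proteome prediction models and proteome-wide association studies (PWAS)
from genotypes and aptamer proteomics — built and validated end to end on
synthetic multi-population data with known ground truth.

## The problem

Plasma proteins sit between genome and disease: cis genetic variation
near a protein's gene shifts its abundance, so protein levels can be
*predicted* from genotypes, and those predictions can be tested against
GWAS summary statistics to nominate proteins that mediate trait
associations. Pipelines of this kind train per-protein SNP weight models
in a reference cohort, check how the models transfer to other
populations, and then run summary-statistic association tests with
colocalization and replication filters to separate credible signals from
LD coincidences and assay artifacts. The cohorts involved are typically
access-controlled, which makes the machinery hard to test; `pwasforge`
pairs the full pipeline with a generative model of such a study so every
stage is exercised against ground truth.

## What it implements

- **Synthetic study generator** (`pwasforge.simdata`): Balding–Nichols
  multi-population genotypes with blockwise LD, sparse cis-genetic
  aptamer abundances at a chosen heritability h², protein-altering-variant
  (PAV) binding artifacts, two noisy timepoints with covariate effects,
  and paired discovery/replication GWAS cohorts whose trait is partially
  mediated by protein abundance.
- **Genotype handling** (`genio`): VCF (DS dosage, GT fallback) and TSV
  dosage IO, MAF/imputation-R² QC filters, PCA, and Hudson /
  Weir–Cockerham F_ST.
- **Abundance preparation** (`phenoprep`): log → per-timepoint age/sex
  residualization → timepoint mean → rank inverse normalization → PC
  residualization.
- **cis-pQTL scan** (`pqtl`): per aptamer–gene window OLS with pooled
  Benjamini–Hochberg FDR.
- **Fine-mapping** (`finemap`): exhaustive Bayesian subset enumeration
  with a Zellner g-prior, PIPs, LD signal clusters, and 1 − PIP penalty
  factors.
- **Prediction models** (`enet`): penalty-factor elastic net (α = 0.5) by
  coordinate descent with KKT verification, nested cross-validation
  (5 outer / 10 inner folds), the ρ > 0.1 & p < 0.05 model filter, PAV
  adjustment, and PredictDB-style SQLite + covariance serialization.
- **Cross-population evaluation** (`xval`): allele-harmonized external
  prediction, Spearman accuracy, Wilcoxon signed-rank model comparisons,
  and the model-F_ST performance-gap analysis.
- **Association testing** (`pwas`, `coloc`, `triage`): the
  summary-statistic protein z-score z = Σ w σ z / √(wᵀΓw), pooled
  Bonferroni significance, Wakefield-ABF colocalization posteriors
  P0–P4, and the three-criteria verdict (discovery + colocalization +
  directional replication).

## Worked example

```python
from pwasforge import run_pipeline

res = run_pipeline(seed=1, n_proteins=10, n_train=300, n_gwas=5000)
print(len(res.models), sorted({m.strategy for m in res.models}))
print(res.summary)
print(res.headline[["aptamer", "verdict", "coloc_p4"]])
```

prints

```
20 ['baseline', 'fine_mapped']
  population     strategy  n_discovered  n_colocalized  n_replicated
0      TRAIN     baseline             1              1             1
1      TRAIN  fine_mapped             1              1             1
    aptamer                            verdict  coloc_p4
0  APT_0000  discovered+colocalized+replicated       1.0
```

Ten synthetic proteins were simulated (h² = 0.5, one trait-mediating
protein, `APT_0000`); both model strategies trained significant models
for all ten, and exactly the mediated protein passed all three
significance criteria — Bonferroni-significant discovery association,
colocalization posterior P4 = 1.0, and a same-direction replication —
while the nine null proteins were correctly left at `not_significant`.

The same pipeline is available from the shell:

```bash
pwasforge simulate --out simdir --seed 1
pwasforge run --config pipeline.yaml --out outdir --seed 1
```

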