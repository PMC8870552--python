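# Methods

`pwasforge` implements a proteome-prediction and proteome-wide association
(PWAS) pipeline: from genotype dosages and aptamer-based protein
abundances it builds per-protein SNP weight models (baseline and
fine-mapping-penalized elastic nets), evaluates how those models transfer
across populations, and tests genetically predicted protein levels
against GWAS summary statistics with colocalization and replication
triage. Because the cohorts such pipelines are normally built on are
access-controlled, the package ships a first-class synthetic-data
generator with full ground truth; every stage is validated against that
truth or against independent oracles.

## Synthetic data generator

**Genotypes.** Population structure follows the Balding–Nichols model:
ancestral allele frequencies are drawn uniformly on [0.05, 0.95] (the
floor avoids monomorphic panels) and each population's frequency at a SNP
is a Beta(p(1−F)/F, (1−p)(1−F)/F) draw, where F controls differentiation.
Note the Hudson F_ST between a population at parameter F and a cohort
fixed at the ancestral frequencies is approximately F/2, while two
populations both at F sit at approximately F from each other; the
transfer study uses this to place training cohorts at chosen distances
from a test cohort. An optional per-locus drift multiplier (Gamma with
mean 1, `fst_locus_shape`) makes differentiation heterogeneous across
loci, as real genomes are; it is off by default and enabled in the
transfer study, where locus-level variation in differentiation is the
phenomenon under test.

Within a locus, haplotypes come from a latent first-order Gaussian chain
(z_j = r·z_{j−1} + √(1−r²)ε, allele = 1 where z < Φ⁻¹(freq)), so pairwise
LD decays geometrically with distance. This is deliberately simpler than
coalescent simulation: it is sufficient to exercise LD clustering,
penalty-factor logic and tag-SNP transfer, and it has a closed-form
neighbour correlation. It does not produce recombination hotspots,
admixture tracts, or allele-age-dependent LD.

**Proteome.** Each aptamer's latent log abundance is genetic value +
person-level noise, scaled so var(genetic)/var(latent) equals the target
cis-heritability h². Observed timepoints (default two, with a 20%
missing-at-second-timepoint rate) add small age and sex effects (0.01 per
year and 0.1 on the log scale; age ~ U(45, 85), sex ~ Bernoulli(0.5)) and
timepoint noise (sd 0.3), then exponentiate to a positive raw scale. A
configurable fraction of aptamers is *artifact-driven*: their only
genetic signal is a protein-altering variant (PAV) dosage times a
N(0, artifact_sd) binding coefficient, emulating assays where a coding
variant changes reagent affinity rather than true abundance; these
aptamers have zero cis-genetic architecture beyond the PAV term.

**GWAS.** Discovery and replication cohorts are drawn independently at
the individual level from the same generative frequencies; the trait is
Σ γ·(true genetic protein value) + N(0, 1), and per-SNP marginal
regressions are summarized exactly (beta, se, z, p, N). Simulating at the
individual level avoids having to specify a summary-level covariance.
The γ values are free study parameters, not estimates of any cohort's
effect sizes.

**What passing tests show.** The generator contains no batch effects,
no trans-QTLs, no relatedness, no genotyping error (imputation R² is a
carried metadata field, exercised by the QC filter on constructed
fixtures), and LD panels are population-homogeneous. Calibration and
power results therefore demonstrate correctness of the statistical
machinery under the stated model, not performance on real cohorts.

## Abundance preparation

The training-cohort chain is: natural log per timepoint → residualize on
age and sex per timepoint → mean across available timepoints (a sample
measured once keeps that value) → rank inverse normalization with offset
(rank − 0.5)/n and average ranks for ties → residualize on the leading
genotypic principal components (default 10). Natural log is used
throughout. An external-cohort convention (different covariate list,
fewer PCs) runs through the same operations with different arguments.
PCA is plain SVD on centered, scaled dosages — synthetic samples are
unrelated, so no kinship-aware variant is needed.

## cis-pQTL scan and FDR

Each aptamer–gene pair is an independent phenotype (an aptamer binding a
complex maps to several genes with identical response values). Variants
within TSS ± 1 Mb (1-based, closed intervals) are tested by simple OLS of
adjusted abundance on dosage; p-values use the t distribution with n − 2
df. Benjamini–Hochberg q-values are pooled across every aptamer-gene ×
variant test in a scan (population-level pooling; per-gene pooling would
be the other defensible choice).

## Fine-mapping

Per locus, all variant subsets up to size K (default 3) are enumerated
and scored with a Zellner g-prior Bayes factor,
log BF = ((n−1−k)/2)·log(1+g) − ((n−1)/2)·log(1+g(1−R²)), with g = n
(unit-information). The g-prior was chosen over an effect-size grid
because it is closed-form and oracle-checkable by exhaustive enumeration;
a grid-averaging hook would be the natural extension. The inclusion prior
is independent Bernoulli with π = 1/p (one causal variant expected per
locus), configurable. Posteriors are normalized over all enumerated
models plus the null; PIPs are summed normalized posteriors. When full
enumeration would exceed the model cap (default 200k), enumeration is
restricted to the strongest marginal variants; excluded variants receive
PIP 0 (documented approximation, not used at default locus sizes).
Signal clusters are greedy: seeds in descending PIP (genomic position
breaks ties), members join at r² ≥ 0.25, each variant joins one cluster.
Penalty factors are 1 − PIP over variants with PIP above a threshold
(0, 0.001 or 0.01); with cluster filtering only the top-PIP member of
each cluster stays eligible. Ineligible variants are excluded from the
design entirely.

## Penalty-factor elastic net

Coordinate descent minimizes (1/2n)‖y − Xβ‖² + λ Σ pf_j[α|β_j| +
((1−α)/2)β_j²] on internally standardized columns (weights are reported
on the dosage scale), with α = 0.5 and per-feature penalty factors; a
factor of 0 exempts a variant from penalization so it always enters.
Convergence: max coefficient change < 1e-7, hard cap 10⁵ sweeps; every
final fit is verified against the KKT subgradient conditions at 1e-4.
The λ path has 100 log-spaced points from λ_max (smallest λ zeroing all
penalized columns) down to 0.01·λ_max. Performance is nested CV: 5 outer
folds; λ chosen per outer fold by 10-fold inner CV on MSE; out-of-fold
predictions pooled into one Spearman ρ with a two-sided t-approximation
p (df = n − 2). Models are kept when ρ > 0.1 and p < 0.05; the final
model refits all data at the 10-fold-CV λ. Fold seeds default to 42.
Single-predictor models are allowed. The training-sample covariance of
the nonzero-weight variants (denominator n − 1) is stored with each model
for summary-statistic association. Serialization uses a single-file
SQLite bundle (`weights` and `extra` tables) and gzipped
`GENE RSID1 RSID2 VALUE` covariance text.

**PAV adjustment.** When the cis window contains protein-altering
variants, abundance is residualized on the smallest set of PAV-genotype
PCs explaining ≥ 95% of PAV-matrix variance, PAV columns are removed from
the design, and the model is retrained. Adjustment outcomes are
categorized as unadjusted (no PAV), marginal (Δρ < 0.1), large but
retained (Δρ ≥ 0.1, still significant; equality binned here), or lost
significance.

## External prediction and comparisons

Model variants are matched to a test cohort by chrom:pos:ref:alt; an
allele-swapped match flips the weight sign; unmatched variants contribute
zero, and a prediction is emitted only when at least one matched variant
is polymorphic (MAF > 0.01) in the test cohort. Strand-ambiguous variants
are kept (synthetic alleles have known strand). Accuracy is Spearman ρ.
Paired model-set comparisons use the Wilcoxon signed-rank test (zeros
dropped; exact null up to 12 nonzero pairs, continuity-corrected normal
beyond); a paired t-test is not used. The allele-frequency analysis
computes, per protein, the difference in mean model F_ST (ratio-of-
averages Hudson estimator over model SNPs, training vs test cohort)
between two training populations, and compares that metric between
proteins with large and small |Δρ| by Mann–Whitney rank-sum (exact for
small tie-free groups). Hudson's estimator is the default (closed form,
robust to unequal n); Weir–Cockerham is available as a cross-check.

## PWAS, colocalization, triage

The protein association statistic is z = Σ w_l σ_l z_l / √(wᵀΓw) with Γ
the training covariance and σ_l its diagonal roots; GWAS z-scores are
sign-aligned to model effect alleles, mismatched allele pairs dropped,
and model variants absent from the GWAS removed from both numerator and
covariance submatrix. Significance uses a Bonferroni threshold of
0.05/n_tests pooled over all populations and traits within one model
strategy. Colocalization uses Wakefield log approximate Bayes factors
(prior effect sd 0.15 for both traits, se-based variances) combined under
the standard one-causal-variant-per-trait enumeration into P0–P4, all in
log space (stable to |z| ≈ 50); priors p1 = p2 = 1e-4, p12 = 1e-5.
P4 > 0.5 is read as colocalized, using the highest P4 when several loci
cover an aptamer. Triage stages: (A) discovery Bonferroni, (B) max
P4 > 0.5, (C) replication — same model-trait association Bonferroni
significant (threshold over the replication test set per strategy) with
the same z sign. Only colocalized discoveries are tested for replication,
so stage counts are monotone. The headline table keeps, per distinct
(aptamer, trait) pair, the record with the lowest discovery p.

## Validation-study conditions

The benchmark studies (`pwasforge.studies`, driven by both the test
suite and `scripts/acceptance.py`) use these problem sizes, chosen to
resolve each property well inside a desktop run:

- Fine-mapping equivalence: 10 loci, p ≤ 10, K ≤ 3, n = 150, vs an
  independent lstsq-based exhaustive enumerator.
- Elastic net: 25 random penalty-factor fits (KKT at 1e-4) plus the
  closed-form univariate and λ = 0 limits.
- Summary/individual equivalence: one cohort of n = 5,000, 200 aptamer
  models, mixed mediated trait; Pearson r and slope between the two
  z-score routes.
- Colocalization: 50 shared-causal and 50 distinct-causal loci, pQTL
  cohort n = 600, GWAS n = 50,000.
- Recovery: 50 proteins, h² = 0.5 spread over 3 causal SNPs, n = 400.
  Three causal variants keep predictions continuous (a single common SNP
  yields a 3-valued predictor whose Spearman ρ is structurally attenuated
  relative to Pearson r). Genotypic-PC adjustment is skipped here: in a
  single unstructured population it removes genuine cis signal and biases
  recovery downward. Null calibration: 100 proteins at h² = 0.
- PAV robustness: 50 artifact-only and 50 cis-with-neutral-PAV
  replicates at n = 300, conditioning on pre-adjustment significance.
- Transfer: 100 proteins, training populations at Hudson F_ST ≈ 0.01 and
  ≈ 0.15 from the test cohort (Balding–Nichols F 0.02 / 0.30 around an
  ancestral test cohort), per-locus drift heterogeneity on, ld 0.85,
  3 causal SNPs, per-training-population MAF QC — the conditions under
  which allele-frequency differentiation visibly degrades transfer.
- End-to-end: 25 pipeline runs, 50 proteins (one mediated, γ = 0.4),
  n_train = 400, GWAS n = 10,000 per cohort.
- FDR: 30 global-null scans of 20 loci.

## Known limitations

Single-configuration colocalization (no multi-signal masking); no
trans-QTLs, conditional analysis, or annotation-based fine-mapping
priors; plain PCA rather than kinship-aware components; greedy
fine-mapping fallback ignores variants outside the candidate set; the
latent-chain LD model cannot reproduce fine-scale haplotype structure.
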