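# Methods

## The question and the design

A species–genetic diversity correlation (SGDC) can arise from neutral
processes (drift, migration and habitat structure acting in parallel on
allele diversity and species richness) or from selection acting on specific
loci.  The package's design partitions both sides of the correlation: SNP
loci into putatively neutral and putatively selected datasets (via two
independent outlier scans), and community diversity into richness,
evenness (α) and compositional dissimilarity (β).  If an SGDC is neutrally
driven, removing outlier loci should strengthen it (r_DS2 ≥ r_DS1) and the
outlier-only datasets should show weaker or null correlations
(r_DS4, r_DS5 ≤ r_DS1); the locus-subset randomization formalizes that
comparison at equal marker number, since Hₑ estimates and correlations are
sensitive to the number of loci.

## QC cascade

Steps run strictly in the order: depth masking (genotype depth < 10 →
missing), locus mean-depth ceiling (> 50 reads dropped, a repeat/paralog
guard), locus missingness (< 40 % kept; a 30 % preset is available as
`QCConfig.stringent()`), MAF ≥ 0.04 over all non-missing genotypes,
biallelic-only (judged from the variant record's allele list, not observed
dosages), observed heterozygosity ≤ 0.5 (paralog guard), individual call
rate ≥ 40 %, and a minimum of 4 genotyped individuals per population.
Reordering the missingness and MAF steps can change the surviving set, so
the order is part of the contract and the cascade is idempotent by
construction.  Boundary behaviour: missingness and call-rate comparisons
keep strictly-less / at-least respectively; the exact boundary is not
documented for the motivating dataset, so the choice is stated here rather
than silently assumed.

Hardy–Weinberg departure is tested per population and locus by a
permutation test: the χ² of observed vs expected genotype counts, with a
null built by re-pairing the 2n allele copies at random (1,000 permutations
by default) and the add-one p-value rule.  The test is conditionally exact,
so its p-values are discrete and conservative (sub-uniform) — the test
suite checks type-I validity rather than two-sided KS uniformity, which no
discrete exact test can pass.  HWE results are reported only; no loci are
dropped on HWE grounds.

Clone detection groups individuals identical at every mutually non-missing
locus, requiring at least 50 shared loci so that sparsely genotyped pairs
cannot be declared clonal by vacuity.

## Structure scan (PCA + Mahalanobis)

Dosages are standardized per locus by centering at 2p̂ and scaling by
√(2p̂(1−p̂)); missing entries become 0 after centering (mean imputation).
Individual scores come from an SVD; each locus is regressed on the first
*k* component scores and the z-vector's Mahalanobis distance D² is computed
with a minimum-covariance-determinant robust covariance (classical variance
when k = 1, where MCD adds nothing).  The genomic inflation factor
λ = median(D²)/median(χ²ₖ) rescales the distances before the χ²ₖ upper-tail
p-value; outliers are Benjamini–Hochberg q ≤ 0.10 by default.  k defaults
to the scree elbow by the maximum-distance-to-chord rule (the component
just before the point farthest below the chord joining the first and last
scree values); the scree is exposed because the choice is conventionally
reviewed by eye, and a flat spectrum degenerates to k = 1 with a warning.

A genuine limit worth knowing: a single differentiated locus among
hundreds of undifferentiated ones produces a variance spike below the
random-matrix (Marchenko–Pastur) bulk edge, so no PCA-based scan can rank
it.  The scan's power tests therefore use weak genome-wide differentiation
so that the leading component recovers the population axis.

## Environment scan (RDA)

Predictors are prescreened by iteratively removing the variable with the
most pairwise |r| > 0.7 partners (ties: larger mean |r|, then name order);
two-level categorical variables enter as a single 0/1 indicator; variance
inflation factors are reported with a warning (not an error) above 5.
Individuals are the observation unit, each carrying its site's predictor
values.  Missing genotypes are imputed to the locus's modal genotype (the
two scans deliberately keep their reference methods' distinct imputation
conventions).  The centered genotype matrix is regressed on the centered
design matrix; an SVD of the fitted values yields the constrained axes.
Axis significance uses permutation of whole predictor rows with forward
conditioning: axis *a* is tested on data residualized on the observed
axes 1…a−1, with a pseudo-F (leading constrained eigenvalue over residual
sum of squares) recomputed per permutation.  Retained axes default to
those both significant at 0.05 and before the eigenvalue scree elbow; both
counts are reported and the precedence is a config option (`axis_rule`),
since the two criteria can disagree.  Loci are flagged when their
standardized loading on a retained axis falls outside
[Q1 − 2·IQR, Q3 + 2·IQR]; the "beyond twice the interquartile range" rule
is ambiguous about its anchor, so the multiplier and anchor
(quartiles vs median) are both configurable, with the Tukey-fence form as
the default reading.

## Diversity

* Hₑ uses the plug-in estimator 1 − Σp̂² (the convention of the tooling
  that produced the packaged reference table); the 2n/(2n−1)-corrected
  variant is a flag.  A locus contributes to a site's Hₑ only when ≥ 4
  individuals are genotyped there, and skipped loci are skipped for that
  site only.  A site with no qualifying locus reports NaN, never 0.
* The chord distance implements
  D_CH = (2/π)·√(2·(1 − (1/L)·ΣₗΣᵤ√(X_lu·Y_lu))) with the per-locus
  average inside the radical, bounded by (2/π)√2 ≈ 0.90; the
  averaged-outside variant is available by flag.  The source formula in
  the motivating study is typographically garbled, so the normalization is
  fixed here by the closed-form bounds and the observed range of the
  published distances (0.03–0.15 at ~1,700 loci).
* Bray–Curtis uses totals of the log₁₀(x+1)-transformed abundances for
  S_i and S_j (the standard abundance-based form).  Reading "total number
  of species" literally would make BC independent of abundances and
  contradict the stated transform, so the abundance reading is used.
* H′ and Hmax = ln S use natural logs; J is undefined (NaN) at S = 1.
  Quadrat biomass is pooled (accumulated) per site before computing
  shares.

## SGDC tests

α-SGDCs: Pearson r with t = r√(n−2)/√(1−r²).  The default tail is
one-sided positive — the published p-values (0.10/0.07/0.09 for
r ≈ 0.33–0.37 at n = 17) match the one-sided Student tail exactly, which
this package reproduces; two-sided is a flag.  β-SGDCs: Mantel r over the
n(n−1)/2 site pairs, null by jointly permuting rows/columns of one matrix,
add-one p-value, 9,999 permutations by default.  The subset randomization
redraws `n_subsets` = 999 equal-size locus subsets from a reference mask
and recomputes the full statistic per subset — per-site Hₑ for α, the
complete D_CH matrix for β (no approximation; at desk scale the cost
999 × O(sites² × loci) is acceptable).  The α comparison uses the lower
tail ("as low as observed" for outlier datasets), the β comparison the
upper tail.  All empirical p-values use (b+1)/(m+1).

## Synthetic scenarios

The generator emulates the study system's structure, not its raw data:

| parameter | default | rationale |
|---|---|---|
| sites × individuals | 17 × 9 | study layout (17 sites, mean 9.3 individuals) |
| loci (neutral + adaptive) | 1,480 + 229 | post-QC and outlier counts of the study |
| drift concentration θ | 10–200, linear in connectivity | strong-to-weak drift across sites |
| cline slope b | 3.0 | clearly detectable genotype–environment signal |
| depth | negative binomial, mean 30, dispersion 5 | study's mean depth ≈ 30 reads |
| missingness | 5 % | study's per-sample missingness 3.8–6 % |
| richness | round(10 + 10·c + N(0, 1.5)), pool 60 | spans the observed 10–21 species |
| frequency clip | [0.01, 0.99] | keeps the realized MAF spectrum compatible with the MAF ≥ 0.04 filter |

Connectivity c_i ~ U(0,1) and the environmental gradient E_i ~ N(0,1) are
independent, so richness (driven by c) and the adaptive cline (driven by
E) are decoupled — the configuration under which the expected dataset
ordering r_DS2 ≥ r_DS1 ≥ r_DS4 holds.  Species occupy niches along the
connectivity gradient so that nearby sites share species and Bray–Curtis
structure is non-trivial.  A single seed drives deterministic per-stage
substreams, so genotypes, community and environment are individually
reproducible.  The generator draws loci independently (no linkage, no
coalescent genealogy, no explicit migration matrix) and its communities
have no true species-interaction structure; passing tests demonstrate that
the pipeline's statistics behave correctly under the assumed generating
model, not that real wetland data satisfy those assumptions.

## Problem sizes in the test and acceptance runs

Simulation-backed checks run at deliberately modest sizes chosen to make
their expectations sharp yet cheap: panmictic null calibration at 60
individuals × 500 loci; RDA null retention over 60 replicates of 9 sites ×
80 loci; Mantel type-I over 200 replicates of 15 sites with 99
permutations; dataset-ordering over 20 seeded scenarios of 15 sites × 480
loci; Hardy–Weinberg validity over 500 loci with 200 permutations.  Scan
permutation counts in tests (49–199) are smaller than the analysis
defaults (999–9,999), which only coarsens the p-value grid.

## Known limitations

* The RDA axis test permutes predictor rows (simple exchangeability);
  residual-permutation schemes are not implemented.
* The BH procedure stands in for smoothed q-value estimation in the
  structure scan; at a 10 % FDR the difference is second-order.
* No latent-factor genotype–environment methods, no LD-aware scans, no
  rarefaction or coverage-standardized richness, and no decomposition of
  SGDCs into shared environmental drivers.
* Multiallelic records are carried only far enough to be excluded by QC;
  downstream statistics assume biallelic dosages.
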