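# sgdc — species–genetic diversity correlation analysis

`sgdc` implements an analysis pipeline for **species–genetic diversity
correlations (SGDCs)**: the covariation between the genetic diversity of a
focal species and the species diversity of its surrounding community.  It is
aimed at population geneticists and community ecologists working on
fragmented habitat systems (the motivating system is a network of high-Andean
wetlands with the sedge *Carex gayana* as focal species), who want to ask
*which evolutionary processes drive an SGDC* by partitioning SNP loci into
putatively neutral and putatively selected datasets and comparing the
correlations each produces.

## What it computes

1. **SNP QC** (`sgdc.qc`): a GBS-style filtering cascade — per-genotype
   depth ≥ 10 reads, locus mean depth ≤ 50, locus missingness < 40 %,
   MAF ≥ 0.04, biallelic only, observed heterozygosity ≤ 0.5 (paralog
   guard), individual call rate ≥ 40 %, ≥ 4 genotyped individuals per
   population — plus a per-population Hardy–Weinberg permutation test and
   multilocus-genotype clone detection.
2. **Dual outlier scans** (`sgdc.scan`, scikit-learn style estimators):
   * `PCAOutlierScan` — population-structure outliers via the Mahalanobis
     distance D² of per-locus z-scores on the first *k* principal
     components, rescaled by the genomic inflation factor
     λ = median(D²)/median(χ²ₖ), with Benjamini–Hochberg FDR calls.
   * `RDAOutlierScan` — genotype–environment association by redundancy
     analysis: loci ~ environmental predictors, permutation tests per
     constrained axis, and an interquartile fence (|z| beyond 2 × IQR from
     the quartiles) on axis loadings.
   The flags combine into five locus datasets: **DS1** (all loci), **DS4**
   (union of scan outliers), **DS5** (intersection), **DS2** = DS1 ∖ DS4,
   **DS3** = DS1 ∖ DS5.
3. **Diversity** (`sgdc.diversity`): per-site expected heterozygosity
   Hₑ = 1 − Σₐ p̂ₐ² averaged over loci; Cavalli-Sforza & Edwards chord
   distance D_CH = (2/π)·√(2·(1 − (1/L)·ΣₗΣᵤ√(X_lu·Y_lu))); species
   richness S, Shannon H′, Pielou J = H′/ln S; Bray–Curtis dissimilarity
   BC_ij = 1 − 2C_ij/(S_i + S_j) on log₁₀(x+1) biomass.
4. **SGDC tests** (`sgdc.stats`): α-SGDCs as Pearson r with a Student-t
   test; β-SGDCs as Mantel tests (9,999 permutations by default); and an
   equal-size locus-subset randomization that asks whether an outlier
   dataset's SGDC is more extreme than 999 random same-size subsets of a
   neutral reference dataset.
5. **Synthetic scenarios** (`sgdc.simulate`): a generator for the habitat
   system the analysis assumes — site connectivity drives both drift
   (Beta-distributed allele frequencies with concentration θ(c)) and
   species richness, while a known subset of loci follows a logistic cline
   in an independent environmental gradient.  Every stage of the pipeline
   is testable against known truth labels.

A per-site reference table for the *C. gayana* system (sample sizes,
richness, Hₑ for DS1–DS5, AFLP Hₑ over 17 sites) is packaged and loadable
with `sgdc.load_carex_sites()`.

## Worked example

Richness α-SGDCs from the packaged per-site table:

```bash
$ sgdc sgdc | head -7
dataset              facet            scope       r  n      p
    DS1           richness              all  0.3337 17 0.0953
    DS1           richness concordant_sites  0.5775 15 0.0121
    DS2           richness              all  0.3703 17 0.0717
    DS2           richness concordant_sites  0.6317 15 0.0058
    DS3           richness              all  0.3435 17 0.0885
    DS3           richness concordant_sites  0.5895 15 0.0104
```

The full and non-outlier datasets (DS1–DS3) correlate moderately with
plant richness over all 17 sites (r ≈ 0.33–0.37, one-sided p ≈ 0.07–0.10)
and strongly once the two marker-discordant sites (S6, S21) are excluded
(r ≈ 0.58–0.63).  The outlier datasets (DS4, DS5) show no positive
richness correlation — the signature of a neutrally driven α-SGDC.

The synthetic pipeline end to end:

```bash
$ sgdc simulate --seed 5 --outdir scen
$ sgdc qc scen/genotypes.vcf --outdir qc1
1552 loci x 153 individuals survive QC
$ sgdc scan qc1/filtered.vcf scen/environment.csv --outdir scan1
{"DS1": 1552, "DS2": 1316, "DS3": 1323, "DS4": 236, "DS5": 229}
```

Here 1,709 simulated loci are reduced to 1,552 by QC, and the scans flag
236 loci (DS4), 229 of them jointly (DS5) — the known adaptive loci carry
a strong environmental cline at the default settings, so the two scans
converge on nearly the same set.

Library use mirrors the CLI: `run_pipeline(config)` takes a nested dict or
YAML config (`scenario`/`inputs`, `qc`, `scan`, `sgdc`, `seed`, `outdir`)
and writes partition membership, diversity tables, distance matrices, SGDC
results and a run log; identical config and seed give byte-identical
outputs.

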