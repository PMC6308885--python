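"""SNP quality-control cascade for GBS-style genotype matrices.

The cascade mirrors standard reduced-representation filtering practice:
per-genotype depth masking, locus-level mean-depth / missingness / MAF /
biallelic / observed-heterozygosity filters, individual call-rate
filtering, and a minimum of genotyped individuals per population.  Steps
are applied strictly in that order; reordering the missingness and MAF
steps can change the surviving set, so the order is part of the contract.

Hardy-Weinberg departures are assessed per population with a permutation
test and *reported*, not used to drop loci.  Clonal ramets are detected as
individuals identical over all shared (mutually non-missing) loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = ["QCConfig", "QCReport", "apply_qc", "hwe_permutation_test",
           "hwe_report", "detect_clones"]


@dataclass
class QCConfig:
    """Thresholds of the filtering cascade (defaults follow the GBS
    filtering protocol used for the wetland sedge dataset)."""

    min_genotype_depth: int = 10
    max_mean_site_depth: float = 50.0
    max_locus_missing_fraction: float = 0.40
    min_maf: float = 0.04
    max_observed_heterozygosity: float = 0.5
    min_individual_call_rate: float = 0.40
    min_genotyped_per_population: int = 4
    hwe_permutations: int = 1000

    def __post_init__(self):
        for name in ("max_locus_missing_fraction", "min_maf",
                     "max_observed_heterozygosity", "min_individual_call_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1]")
        if self.min_genotype_depth < 0 or self.min_genotyped_per_population < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def stringent(cls, **kw) -> "QCConfig":
        """Sensitivity preset with the stricter 30% locus-missingness cap."""
        kw.setdefault("max_locus_missing_fraction", 0.30)
        return cls(**kw)


@dataclass
class QCReport:
    """Locus/individual counts after each step plus per-item exclusion
    reasons.  ``steps`` rows: (step, axis, kept, dropped)."""

    steps: list = field(default_factory=list)
    locus_exclusions: dict = field(default_factory=dict)    # locus_id -> reason
    individual_exclusions: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, step: str, axis: str, kept: int, dropped: int):
        self.steps.append({"step": step, "axis": axis, "kept": kept, "dropped": dropped})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _locus_stats(gm: GenotypeMatrix):
    d = gm.dosage
    called = d != MISSING
    n_called = called.sum(axis=0)
    miss_frac = 1 - n_called / d.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, d, 0).sum(axis=0)
        p = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
        maf = np.minimum(p, 1 - p)
        ho = np.where(n_called > 0, (d == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    return n_called, miss_frac, maf, ho


def apply_qc(gm: GenotypeMatrix, cfg: QCConfig | None = None):
    """Run the full cascade; returns ``(filtered GenotypeMatrix, QCReport)``.

    Steps, in order: (1) mask genotypes with depth < ``min_genotype_depth``;
    (2) drop loci with mean called-genotype depth > ``max_mean_site_depth``;
    (3) drop loci with missing fraction >= ``max_locus_missing_fraction``;
    (4) drop loci with MAF < ``min_maf`` over all remaining individuals;
    (5) keep only biallelic loci (from the variant record's allele list);
    (6) drop loci with observed heterozygosity > ``max_observed_heterozygosity``;
    (7) drop individuals with call rate < ``min_individual_call_rate``;
    (8) drop populations left with fewer than ``min_genotyped_per_population``
    individuals.
    """
    cfg = cfg or QCConfig()
    report = QCReport()
    depth_needed = cfg.min_genotype_depth > 0 or np.isfinite(cfg.max_mean_site_depth)
    if gm.depth is None and depth_needed:
        raise ValueError("depth-based QC steps enabled but no depth in matrix")

    # (1) depth -> missing
    dosage = gm.dosage.copy()
    if gm.depth is not None and cfg.min_genotype_depth > 0:
        dosage[(gm.depth < cfg.min_genotype_depth)] = MISSING
    gm = GenotypeMatrix(gm.individual_ids, gm.locus_ids, gm.populations, dosage,
                        depth=gm.depth, ref=gm.ref, alt=gm.alt, multiallelic=gm.multiallelic)
    report.record("min_genotype_depth", "genotype", int((dosage != MISSING).sum()),
                  int((dosage == MISSING).sum()))

    def drop_loci(g, keep, step, reason):
        for j in np.flatnonzero(~keep):
            report.locus_exclusions.setdefault(g.locus_ids[j], reason)
        report.record(step, "locus", int(keep.sum()), int((~keep).sum()))
        return g.subset(loci=keep)

    # (2) mean site depth
    if gm.depth is not None and np.isfinite(cfg.max_mean_site_depth):
        called = gm.dosage != MISSING
        with np.errstate(invalid="ignore"):
            mean_depth = np.where(called, gm.depth, 0).sum(axis=0) / np.maximum(called.sum(axis=0), 1)
        gm = drop_loci(gm, mean_depth <= cfg.max_mean_site_depth,
                       "max_mean_site_depth", "mean depth too high")

    # (3) locus missingness (strict-less keep rule)
    _, miss_frac, _, _ = _locus_stats(gm)
    gm = drop_loci(gm, miss_frac < cfg.max_locus_missing_fraction,
                   "max_locus_missing_fraction", "too much missing data")

    # (4) MAF
    _, _, maf, _ = _locus_stats(gm)
    gm = drop_loci(gm, ~(maf < cfg.min_maf) & ~np.isnan(maf), "min_maf", "MAF below threshold")

    # (5) biallelic
    gm = drop_loci(gm, ~gm.multiallelic, "biallelic", "multiallelic record")

    # (6) observed heterozygosity
    _, _, _, ho = _locus_stats(gm)
    gm = drop_loci(gm, ~(ho > cfg.max_observed_heterozygosity), "max_observed_heterozygosity",
                   "observed heterozygosity too high (possible paralog)")

    # (7) individual call rate (keep rule: rate >= threshold)
    called = gm.dosage != MISSING
    rate = called.mean(axis=1) if gm.n_loci else np.ones(gm.n_individuals)
    keep_ind = rate >= cfg.min_individual_call_rate
    for i in np.flatnonzero(~keep_ind):
        report.individual_exclusions[gm.individual_ids[i]] = "call rate below threshold"
    report.record("min_individual_call_rate", "individual",
                  int(keep_ind.sum()), int((~keep_ind).sum()))
    gm = gm.subset(individuals=keep_ind)

    # (8) minimum genotyped individuals per population
    sizes = pd.Series(gm.populations).value_counts()
    bad_pops = set(sizes[sizes < cfg.min_genotyped_per_population].index)
    keep_ind = ~np.isin(gm.populations, list(bad_pops))
    for i in np.flatnonzero(~keep_ind):
        report.individual_exclusions[gm.individual_ids[i]] = "population below minimum size"
    report.record("min_genotyped_per_population", "individual",
                  int(keep_ind.sum()), int((~keep_ind).sum()))
    gm = gm.subset(individuals=keep_ind)

    if gm.n_loci == 0 or gm.n_individuals == 0:
        report.warnings.append("matrix empty after QC")
    return gm, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg permutation test
# ---------------------------------------------------------------------------

def _hw_chi2(n0: int, n1: int, n2: int) -> float:
    n = n0 + n1 + n2
    p = (n1 + 2 * n2) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    obs = np.array([n0, n1, n2], dtype=float)
    nz = exp > 0
    return float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())


def hwe_permutation_test(gm: GenotypeMatrix, population: str, locus,
                         n_perm: int = 1000, rng=None) -> float:
    """Permutation p-value for departure from Hardy-Weinberg proportions at
    one locus in one population.

    The observed chi-square of genotype counts against HW expectations is
    compared with a null built by shuffling the 2n allele copies into n
    random genotype pairs; p = (# permuted >= observed + 1) / (n_perm + 1).
    Monomorphic loci return p = 1.
    """
    rng = np.random.default_rng(rng)
    j = gm.locus_ids.index(locus) if isinstance(locus, str) else int(locus)
    d = gm.dosage[gm.populations == str(population), j]
    d = d[d != MISSING]
    if len(d) < 2:
        raise ValueError("need at least 2 non-missing genotypes")
    n0, n1, n2 = int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
    n_alt = n1 + 2 * n2
    if n_alt == 0 or n_alt == 2 * len(d):
        return 1.0
    obs = _hw_chi2(n0, n1, n2)
    alleles = np.concatenate([np.zeros(2 * len(d) - n_alt, dtype=np.int8),
                              np.ones(n_alt, dtype=np.int8)])
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(alleles)
        g = alleles[::2] + alleles[1::2]
        stat = _hw_chi2(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        if stat >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def hwe_report(gm: GenotypeMatrix, n_perm: int = 1000, alpha: float = 0.05,
               min_genotyped: int = 4, rng=None) -> pd.DataFrame:
    """Per-population fraction of loci departing from HW equilibrium at
    ``alpha`` (reported, never used for exclusion)."""
    rng = np.random.default_rng(rng)
    rows = []
    for site in gm.site_ids:
        n_tested = n_sig = 0
        sub = gm.dosage[gm.populations == site]
        for j in range(gm.n_loci):
            d = sub[:, j]
            if (d != MISSING).sum() < min_genotyped:
                continue
            p = hwe_permutation_test(gm, site, j, n_perm=n_perm, rng=rng)
            n_tested += 1
            n_sig += p <= alpha
        rows.append({"population": site, "n_loci_tested": n_tested,
                     "frac_departing": n_sig / n_tested if n_tested else np.nan})
    return pd.DataFrame(rows).set_index("population")


def detect_clones(gm: GenotypeMatrix, min_shared_loci: int = 50) -> list:
    """Group individuals with identical multilocus genotypes.

    A pair is clonal when equal at every mutually non-missing locus and the
    number of shared loci is at least ``min_shared_loci``.  Returns a list
    of groups (lists of individual IDs) of size >= 2.
    """
    n = gm.n_individuals
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d = gm.dosage
    called = d != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[i] & called[j]
            if shared.sum() < min_shared_loci:
                continue
            if np.array_equal(d[i, shared], d[j, shared]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(gm.individual_ids[i])
    return [g for g in groups.values() if len(g) > 1]
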