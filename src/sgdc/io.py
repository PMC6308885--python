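"""Genotype, community and environment data containers and file readers.

The central container is :class:`GenotypeMatrix`: an individuals x loci
matrix of allele-dosage codes (0/1/2 copies of the counted allele, ``-1``
for missing) with per-genotype read depth and a population (site)
assignment per individual.  Community composition and site environment are
plain site-indexed tables with validated invariants.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "CommunityTable",
    "EnvironmentTable",
    "read_vcf",
    "write_vcf",
    "read_community",
    "read_environment",
    "load_carex_sites",
    "read_table",
]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for individuals grouped into populations.

    Parameters
    ----------
    individual_ids : list of str
        Unique sample identifiers (rows).
    locus_ids : list of str
        Unique locus identifiers (columns).
    populations : ndarray of str
        Site/population assignment per individual.
    dosage : ndarray of int8, shape (n_individuals, n_loci)
        Copies of the counted allele in {0, 1, 2}; ``MISSING`` (-1) marks
        genotypes treated as missing (e.g. below the depth filter).
    depth : ndarray of int or None
        Per-genotype read depth, same shape as ``dosage``. Optional;
        required only by depth-based QC steps.
    ref, alt : ndarray of str or None
        Allele labels per locus; ``dosage`` counts ``alt``.
    multiallelic : ndarray of bool or None
        Flags loci whose variant record carried more than one alternate
        allele; such loci are excluded by the biallelic QC step.
    """

    individual_ids: list
    locus_ids: list
    populations: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    multiallelic: np.ndarray | None = None

    def __post_init__(self):
        self.individual_ids = [str(i).strip() for i in self.individual_ids]
        self.locus_ids = [str(l).strip() for l in self.locus_ids]
        self.populations = np.asarray([str(p).strip() for p in self.populations])
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual IDs are not unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus IDs are not unique")
        if self.dosage.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError("dosage shape does not match ID lists")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or missing")
        if len(self.populations) != len(self.individual_ids):
            raise ValueError("populations length does not match individuals")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape does not match dosage")
            if (self.depth < 0).any():
                raise ValueError("negative read depth")
        if self.multiallelic is None:
            self.multiallelic = np.zeros(self.n_loci, dtype=bool)
        else:
            self.multiallelic = np.asarray(self.multiallelic, dtype=bool)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def site_ids(self) -> list:
        """Unique site IDs in order of first appearance."""
        return list(dict.fromkeys(self.populations))

    @property
    def population_of(self) -> dict:
        return dict(zip(self.individual_ids, self.populations))

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    # -- subsetting -------------------------------------------------------
    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given individual / locus
        indices (integer or boolean arrays)."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if loc.dtype == bool:
            loc = np.flatnonzero(loc)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in ind],
            locus_ids=[self.locus_ids[j] for j in loc],
            populations=self.populations[ind],
            dosage=self.dosage[np.ix_(ind, loc)],
            depth=None if self.depth is None else self.depth[np.ix_(ind, loc)],
            ref=None if self.ref is None else np.asarray(self.ref)[loc],
            alt=None if self.alt is None else np.asarray(self.alt)[loc],
            multiallelic=self.multiallelic[loc],
        )

    # -- allele frequencies -----------------------------------------------
    def allele_frequencies(self) -> np.ndarray:
        """Counted-allele frequency per locus over all non-missing genotypes.

        NaN where a locus has no called genotypes.
        """
        d = np.ma.masked_equal(self.dosage, MISSING)
        with np.errstate(invalid="ignore"):
            freq = d.mean(axis=0).filled(np.nan) / 2.0
        return freq

    def site_allele_frequencies(self, min_genotyped: int = 1):
        """Counted-allele frequency per (site, locus).

        Returns ``(site_ids, freq, n_called)`` where ``freq`` is a
        sites x loci array with NaN where fewer than ``min_genotyped``
        individuals are called at that site/locus.
        """
        sites = self.site_ids
        freq = np.full((len(sites), self.n_loci), np.nan)
        n_called = np.zeros((len(sites), self.n_loci), dtype=int)
        for i, s in enumerate(sites):
            rows = self.dosage[self.populations == s]
            called = rows != MISSING
            n = called.sum(axis=0)
            n_called[i] = n
            with np.errstate(invalid="ignore"):
                tot = np.where(called, rows, 0).sum(axis=0)
                f = np.where(n >= max(min_genotyped, 1), tot / np.maximum(2 * n, 1), np.nan)
            f = np.where(n >= min_genotyped, f, np.nan)
            freq[i] = f
        return sites, freq, n_called

    def orient_minor(self) -> "GenotypeMatrix":
        """Recode dosage to count the minor allele (frequency computed over
        all non-missing genotypes).  Ties at 0.5 count the lexicographically
        smaller allele.  Heterozygosity, genetic distances and all SGDCs are
        invariant under this recoding."""
        freq = self.allele_frequencies()
        flip = freq > 0.5
        if self.ref is not None and self.alt is not None:
            ref = np.asarray(self.ref).astype(object)
            alt = np.asarray(self.alt).astype(object)
            tie = np.isclose(freq, 0.5) & (alt > ref)
            flip = flip | tie
        dosage = self.dosage.copy()
        miss = dosage == MISSING
        dosage[:, flip] = 2 - dosage[:, flip]
        dosage[miss] = MISSING
        ref, alt = self.ref, self.alt
        if ref is not None and alt is not None:
            ref = np.asarray(ref).copy()
            alt = np.asarray(alt).copy()
            ref[flip], alt[flip] = np.asarray(self.alt)[flip], np.asarray(self.ref)[flip]
        return replace(self, dosage=dosage, ref=ref, alt=alt)


def _infer_population(sample_id: str) -> str:
    """Default site assignment: sample IDs of the form ``<site>_<k>``."""
    sid = sample_id.strip()
    return sid.rsplit("_", 1)[0] if "_" in sid else sid


def read_vcf(path, min_genotype_depth: int = 10, populations: dict | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Genotypes with per-sample depth below ``min_genotype_depth`` are set to
    missing (depth taken from FORMAT/DP when present; loci without depth
    information are left untouched by the depth filter).  Multiallelic
    records are loaded but flagged for downstream exclusion by QC.

    ``populations`` maps individual ID to site ID; by default the site is
    the sample-name prefix before the last underscore.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = [s.strip() for s in vcf.samples]
    if not samples:
        raise ValueError(f"no samples in VCF {path}")
    if len(set(samples)) != len(samples):
        raise ValueError("sample IDs in VCF are not unique")
    dosage_cols, depth_cols, locus_ids, refs, alts, multi = [], [], [], [], [], []
    any_depth = False
    for v in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = v.gt_types
        col = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = dp.reshape(-1).astype(np.int64)
            dp[dp < 0] = 0
            any_depth = True
        else:
            dp = np.zeros(len(samples), dtype=np.int64)
        dosage_cols.append(col.astype(np.int8))
        depth_cols.append(dp)
        lid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        locus_ids.append(lid)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else "")
        multi.append(len(v.ALT) > 1)
    if not locus_ids:
        raise ValueError(f"no variant records in VCF {path}")
    dosage = np.column_stack(dosage_cols)
    depth = np.column_stack(depth_cols) if any_depth else None
    if depth is not None and min_genotype_depth > 0:
        dosage[depth < min_genotype_depth] = MISSING
    if populations is None:
        pops = [_infer_population(s) for s in samples]
    else:
        try:
            pops = [str(populations[s]).strip() for s in samples]
        except KeyError as e:
            raise ValueError(f"no population assignment for sample {e}") from e
    return GenotypeMatrix(
        individual_ids=samples,
        locus_ids=locus_ids,
        populations=np.asarray(pops),
        dosage=dosage,
        depth=depth,
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        multiallelic=np.asarray(multi),
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF v4.2 with GT and DP.

    Loci without chromosomal coordinates (e.g. tag-pair loci from reference-
    free SNP calling) are written on a placeholder contig, one position per
    locus; re-reading reproduces dosage and missingness exactly.
    """
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("##contig=<ID=un>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individual_ids) + "\n")
        ref = gm.ref if gm.ref is not None else np.repeat("A", gm.n_loci)
        alt = gm.alt if gm.alt is not None else np.repeat("T", gm.n_loci)
        for j, lid in enumerate(gm.locus_ids):
            fields = ["un", str(j + 1), lid, str(ref[j]), str(alt[j]) or "T", ".", "PASS", ".", "GT:DP"]
            for i in range(gm.n_individuals):
                dp = int(gm.depth[i, j]) if gm.depth is not None else 0
                fields.append(f"{code[int(gm.dosage[i, j])]}:{dp}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# site-indexed tables
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Site x species dry-biomass table (g/m^2, pooled over quadrats)."""

    biomass: pd.DataFrame  # index: site IDs, columns: species IDs

    def __post_init__(self):
        df = self.biomass
        df.index = df.index.astype(str).str.strip()
        if df.index.duplicated().any():
            raise ValueError("duplicate site IDs in community table")
        if not np.issubdtype(np.asarray(df.values).dtype, np.number):
            raise ValueError("non-numeric biomass values")
        if (df.values < 0).any():
            raise ValueError("negative biomass values")
        if (df.values.sum(axis=1) <= 0).any():
            bad = df.index[df.values.sum(axis=1) <= 0].tolist()
            raise ValueError(f"sites with no positive biomass: {bad}")
        self.biomass = df.astype(float)

    @property
    def site_ids(self) -> list:
        return list(self.biomass.index)

    @property
    def species_ids(self) -> list:
        return list(self.biomass.columns)


@dataclass
class EnvironmentTable:
    """Site x environmental-variable table.

    ``categorical`` lists variables to be encoded as 0/1 indicator columns
    (two-level factors such as aspect) before any model fitting.
    """

    values: pd.DataFrame
    categorical: list = field(default_factory=list)

    def __post_init__(self):
        df = self.values
        df.index = df.index.astype(str).str.strip()
        if df.index.duplicated().any():
            raise ValueError("duplicate site IDs in environment table")
        if df.isna().any().any():
            raise ValueError("missing values in environment table")
        self.categorical = [c for c in self.categorical if c in df.columns]

    @property
    def site_ids(self) -> list:
        return list(self.values.index)

    @property
    def variables(self) -> list:
        return list(self.values.columns)

    def design_matrix(self) -> pd.DataFrame:
        """Numeric design matrix: continuous variables as-is, each two-level
        categorical as a single 0/1 indicator."""
        cols = {}
        for c in self.values.columns:
            col = self.values[c]
            if c in self.categorical or col.dtype == object:
                levels = sorted(col.astype(str).unique())
                if len(levels) > 2:
                    raise ValueError(f"categorical variable {c!r} has >2 levels")
                cols[c] = (col.astype(str) == levels[-1]).astype(float)
            else:
                cols[c] = col.astype(float)
        return pd.DataFrame(cols, index=self.values.index)

    def drop(self, names) -> "EnvironmentTable":
        keep = [c for c in self.values.columns if c not in set(names)]
        return EnvironmentTable(self.values[keep].copy(),
                                [c for c in self.categorical if c in keep])


def read_community(path, sep=None) -> CommunityTable:
    df = _read_delim(path, sep)
    return CommunityTable(df)


def read_environment(path, categorical=None, sep=None) -> EnvironmentTable:
    df = _read_delim(path, sep, numeric=False)
    return EnvironmentTable(df, list(categorical or []))


def _read_delim(path, sep=None, numeric=True) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    df.index = df.index.astype(str).str.strip()
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate site IDs: {dup}")
    if numeric:
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as e:
            raise ValueError(f"non-numeric cell in numeric table {path}: {e}") from e
    return df


def load_carex_sites() -> pd.DataFrame:
    """Published per-site summary for the Andean wetland *Carex gayana*
    system: sample size ``n``, plant species richness, SNP expected
    heterozygosity for the five locus datasets (DS1-DS5) and AFLP
    heterozygosity, with the two sites discordant between marker systems
    (S6, S21) flagged in the ``discordant`` column."""
    with importlib.resources.files("sgdc.data").joinpath("carex_sites.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    assert len(df) == 17
    he_cols = [c for c in df.columns if c.startswith("he_")]
    if not ((df[he_cols] >= 0) & (df[he_cols] <= 1)).all().all():
        raise ValueError("heterozygosity outside [0,1] in packaged site table")
    if (df["n"] < 4).any():
        raise ValueError("site with fewer than 4 genotyped individuals")
    return df


def read_table(path, kind: str):
    """Read a typed table: ``kind`` in {'community', 'environment', 'fixture'}."""
    if kind == "community":
        return read_community(path)
    if kind == "environment":
        return read_environment(path)
    if kind == "fixture":
        df = pd.read_csv(path, index_col=0)
        if df.index.duplicated().any():
            raise ValueError("duplicate site IDs in fixture table")
        return df
    raise ValueError(f"unknown table kind {kind!r}")
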