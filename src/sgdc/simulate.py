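"""Synthetic genotype / community / environment scenarios.

The generator emulates a fragmented-wetland metapopulation: discrete sites
along an environmental gradient, where site "connectivity" jointly drives
plant species richness (island-biogeographic expectation) and the genetic
diversity retained against drift (population-genetic expectation), so that
a positive species-genetic diversity correlation arises through shared
neutral drivers.  A known subset of loci is made adaptive: their allele
frequencies follow a logistic cline in an environmental variable, which is
what the outlier scans are expected to detect.

Neutral locus ``l`` at site ``i`` draws its frequency from a Beta
distribution with mean equal to the ancestral frequency and concentration
``theta_i = theta_min + c_i * (theta_max - theta_min)``: high-connectivity
sites drift less.  Adaptive loci instead follow
``logit(p_il) = logit(pbar_l) + b * (E_i - mean(E)) + noise``.
Genotypes are Binomial(2, p_il) per individual, depths negative binomial,
and genotypes are masked missing at a fixed rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, CommunityTable, EnvironmentTable

__all__ = [
    "ScenarioConfig",
    "simulate_genotypes",
    "simulate_community",
    "simulate_environment",
    "simulate_scenario",
]


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic SGDC scenario.

    Defaults are sized like the Andean wetland study system: 17 sites with
    4-10 individuals each, ~1,700 biallelic SNPs of which ~13% carry an
    environmental cline, richness spanning roughly 10-21 species, and
    negative-binomial read depth with mean 30.
    """

    n_sites: int = 17
    individuals_per_site: int = 9
    n_neutral_loci: int = 1480
    n_adaptive_loci: int = 229
    theta_min: float = 10.0
    theta_max: float = 200.0
    connectivity: np.ndarray | None = None   # per-site c_i in [0,1]; drawn U(0,1) if None
    environment: np.ndarray | None = None    # per-site E_i; drawn N(0,1) if None
    adaptive_cline_slope: float = 3.0
    adaptive_site_noise: float = 0.25
    species_pool_size: int = 60
    richness_intercept: float = 10.0
    richness_slope: float = 10.0
    richness_noise: float = 1.5
    evenness_shape: float = 1.0              # sd of log-biomass; larger = less even
    niche_width: float = 0.4                 # spatial autocorrelation of composition
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    missingness: float = 0.05
    nuisance_correlations: tuple = (0.9, 0.5, 0.3, 0.0)
    freq_clip: tuple = (0.01, 0.99)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites <= 0 or self.individuals_per_site <= 0:
            raise ValueError("n_sites and individuals_per_site must be positive")
        if self.n_neutral_loci + self.n_adaptive_loci <= 0:
            raise ValueError("scenario must contain at least one locus")
        if not (0 <= self.missingness <= 1):
            raise ValueError("missingness must be in [0,1]")
        if self.theta_min > self.theta_max:
            raise ValueError("theta_min must not exceed theta_max")
        if self.connectivity is not None:
            c = np.asarray(self.connectivity, dtype=float)
            if c.shape != (self.n_sites,) or (c < 0).any() or (c > 1).any():
                raise ValueError("connectivity must be n_sites values in [0,1]")
            self.connectivity = c
        if self.environment is not None:
            e = np.asarray(self.environment, dtype=float)
            if e.shape != (self.n_sites,):
                raise ValueError("environment must have n_sites values")
            self.environment = e

    def site_ids(self) -> list:
        return [f"S{i + 1}" for i in range(self.n_sites)]

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage stream derived from the scenario seed."""
        ss = np.random.SeedSequence([self.seed, _STAGE_KEYS[stage]])
        return np.random.default_rng(ss)


_STAGE_KEYS = {"sites": 0, "genotypes": 1, "community": 2, "environment": 3}


def _site_drivers(config: ScenarioConfig):
    """Connectivity and environmental gradient per site (config override or
    drawn from the 'sites' stream)."""
    rng = config.rng("sites")
    c = rng.uniform(0, 1, config.n_sites)
    e = rng.normal(0, 1, config.n_sites)
    if config.connectivity is not None:
        c = config.connectivity
    if config.environment is not None:
        e = config.environment
    return c, e


def _logit(p):
    return np.log(p / (1 - p))


def simulate_genotypes(config: ScenarioConfig):
    """Draw genotypes, depths and missingness for the scenario.

    Returns
    -------
    gm : GenotypeMatrix
    truth : pandas.DataFrame
        Per-locus ``class`` ('neutral'/'adaptive') and the true per-site
        allele-frequency matrix is attached as ``truth.attrs['site_freq']``
        (sites x loci) for calibration checks on the generating process.
    """
    c, e = _site_drivers(config)
    rng = config.rng("genotypes")
    n_loci = config.n_neutral_loci + config.n_adaptive_loci
    lo, hi = config.freq_clip
    pbar = rng.uniform(0.05, 0.95, n_loci)
    theta = config.theta_min + c * (config.theta_max - config.theta_min)

    freq = np.empty((config.n_sites, n_loci))
    nn = config.n_neutral_loci
    if nn:
        a = pbar[None, :nn] * theta[:, None]
        b = (1 - pbar[None, :nn]) * theta[:, None]
        freq[:, :nn] = rng.beta(a, b)
    if config.n_adaptive_loci:
        shift = config.adaptive_cline_slope * (e - e.mean())[:, None]
        noise = rng.normal(0, config.adaptive_site_noise, (config.n_sites, n_loci - nn))
        logit_p = _logit(np.clip(pbar[None, nn:], lo, hi)) + shift + noise
        freq[:, nn:] = 1 / (1 + np.exp(-logit_p))
    freq = np.clip(freq, lo, hi)

    k = config.individuals_per_site
    site_ids = config.site_ids()
    pops = np.repeat(site_ids, k)
    p_ind = np.repeat(freq, k, axis=0)
    dosage = rng.binomial(2, p_ind).astype(np.int8)

    # negative binomial via gamma-Poisson with mean depth_mean
    r = config.depth_dispersion
    lam = rng.gamma(r, config.depth_mean / r, dosage.shape)
    depth = rng.poisson(lam)
    miss = rng.uniform(size=dosage.shape) < config.missingness
    dosage[miss] = MISSING

    locus_ids = [f"L{j:05d}" for j in range(n_loci)]
    gm = GenotypeMatrix(
        individual_ids=[f"{s}_{i + 1}" for s in site_ids for i in range(k)],
        locus_ids=locus_ids,
        populations=pops,
        dosage=dosage,
        depth=depth,
        ref=np.repeat("A", n_loci).astype(object),
        alt=np.repeat("T", n_loci).astype(object),
    )
    truth = pd.DataFrame(
        {"class": ["neutral"] * nn + ["adaptive"] * config.n_adaptive_loci},
        index=pd.Index(locus_ids, name="locus_id"),
    )
    truth.attrs["site_freq"] = freq
    truth.attrs["connectivity"] = c
    truth.attrs["environment"] = e
    return gm, truth


def simulate_community(config: ScenarioConfig) -> CommunityTable:
    """Site x species biomass with richness increasing in connectivity.

    Each species has a niche centre on the connectivity gradient; the
    species present at a site are drawn without replacement with weights
    decaying in niche distance, so that sites close on the gradient share
    species and Bray-Curtis structure is non-trivial.
    """
    c, _ = _site_drivers(config)
    rng = config.rng("community")
    S = np.rint(config.richness_intercept + config.richness_slope * c
                + rng.normal(0, config.richness_noise, config.n_sites))
    S = np.clip(S, 2, config.species_pool_size).astype(int)
    if (config.richness_intercept + config.richness_slope * np.array([0.0, 1.0]) < 2).all():
        raise ValueError("richness parameters imply fewer than 2 species everywhere")

    centres = rng.uniform(0, 1, config.species_pool_size)
    species = [f"sp{j + 1}" for j in range(config.species_pool_size)]
    biomass = np.zeros((config.n_sites, config.species_pool_size))
    for i in range(config.n_sites):
        w = np.exp(-((c[i] - centres) ** 2) / (2 * config.niche_width ** 2))
        w /= w.sum()
        present = rng.choice(config.species_pool_size, size=S[i], replace=False, p=w)
        biomass[i, present] = np.exp(rng.normal(0, config.evenness_shape, S[i]))
    df = pd.DataFrame(biomass, index=config.site_ids(), columns=species)
    return CommunityTable(df)


def simulate_environment(config: ScenarioConfig) -> EnvironmentTable:
    """Per-site predictors: the true gradient ``E``, correlated nuisance
    variables at the configured target correlations (to exercise the |r|>0.7
    collinearity prescreen), and a two-level categorical (aspect-like)."""
    _, e = _site_drivers(config)
    rng = config.rng("environment")
    z = (e - e.mean()) / (e.std() or 1.0)
    cols = {"E": e}
    for j, rho in enumerate(config.nuisance_correlations):
        noise = rng.normal(0, 1, config.n_sites)
        noise = noise - noise.mean()
        x = rho * z + np.sqrt(max(1 - rho ** 2, 0)) * noise / (noise.std() or 1.0)
        cols[f"nuis{j + 1}"] = x
    cols["aspect"] = np.where(rng.uniform(size=config.n_sites) < 0.5, "N", "S")
    df = pd.DataFrame(cols, index=config.site_ids())
    return EnvironmentTable(df, categorical=["aspect"])


def simulate_scenario(config: ScenarioConfig):
    """All three tables plus truth labels for one scenario."""
    gm, truth = simulate_genotypes(config)
    comm = simulate_community(config)
    env = simulate_environment(config)
    return gm, comm, env, truth
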