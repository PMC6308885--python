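"""Alpha and beta diversity at the genetic and community levels.

Genetic alpha-diversity is the expected heterozygosity He = 1 - sum(p_a^2)
per locus (plug-in estimator, no small-sample correction by default),
averaged over the loci of a dataset mask with at least a minimum number of
genotyped individuals in the population.  Genetic beta-diversity is the
Cavalli-Sforza & Edwards chord distance between per-site allele-frequency
vectors.  Community alpha-diversity is species richness S, Shannon H'
(nats) and Pielou evenness J = H'/ln S from pooled dry biomass; community
beta-diversity is Bray-Curtis dissimilarity of log10(x+1) biomass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import GenotypeMatrix, CommunityTable

__all__ = [
    "expected_heterozygosity", "cavalli_sforza_distance",
    "cavalli_sforza_matrix", "species_alpha", "community_alpha",
    "bray_curtis", "diversity_table",
]


def expected_heterozygosity(gm: GenotypeMatrix, mask=None, min_genotyped: int = 4,
                            unbiased: bool = False) -> pd.Series:
    """Per-site expected heterozygosity over the loci selected by ``mask``.

    At each site, He is averaged over the loci with at least
    ``min_genotyped`` non-missing individuals there; loci failing that at
    one site are skipped for that site only.  With ``unbiased=True`` the
    2n/(2n-1) small-sample correction is applied per locus.  A site with
    no qualifying locus gets NaN (undefined, not zero).
    """
    mask = _as_mask(gm, mask)
    if not mask.any():
        raise ValueError("empty locus mask")
    sites, freq, n_called = gm.site_allele_frequencies(min_genotyped=min_genotyped)
    freq = freq[:, mask]
    n_called = n_called[:, mask]
    he = 2 * freq * (1 - freq)               # biallelic: 1 - p^2 - (1-p)^2
    if unbiased:
        with np.errstate(invalid="ignore"):
            he = he * (2 * n_called) / np.maximum(2 * n_called - 1, 1)
    valid = ~np.isnan(he)
    n_valid = valid.sum(axis=1)
    total = np.where(valid, he, 0.0).sum(axis=1)
    out = np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)
    return pd.Series(out, index=sites, name="He")


def cavalli_sforza_distance(freqs_x, freqs_y, average_inside: bool = True) -> float:
    """Cavalli-Sforza & Edwards chord distance between two populations.

    ``freqs_x``/``freqs_y`` are L x A arrays of allele frequencies (rows
    sum to 1; for biallelic loci pass the counted-allele frequency vector
    and the complement is filled in).  Loci with missing (NaN) frequencies
    in either population are dropped pairwise.

    With ``average_inside=True`` (default):

        D_CH = (2/pi) * sqrt( 2 * (1 - (1/L) * sum_l sum_u sqrt(x_lu * y_lu)) )

    which is bounded by (2/pi)*sqrt(2).  The variant with the per-locus
    average taken outside the radical is available with
    ``average_inside=False``.
    """
    x = _freq_table(freqs_x)
    y = _freq_table(freqs_y)
    if x.shape != y.shape:
        raise ValueError("frequency tables differ in shape")
    ok = ~(np.isnan(x).any(axis=1) | np.isnan(y).any(axis=1))
    x, y = x[ok], y[ok]
    L = len(x)
    if L == 0:
        raise ValueError("no loci with data in both populations")
    cos_l = np.sqrt(x * y).sum(axis=1)
    if average_inside:
        return float(2 / np.pi * np.sqrt(2 * max(1 - cos_l.mean(), 0.0)))
    return float(np.mean(2 / np.pi * np.sqrt(2 * np.clip(1 - cos_l, 0, None))))


def _freq_table(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim == 1:
        f = np.column_stack([f, 1 - f])
    return f


def cavalli_sforza_matrix(gm: GenotypeMatrix, mask=None, min_genotyped: int = 4,
                          average_inside: bool = True) -> pd.DataFrame:
    """Pairwise chord-distance matrix between sites over a locus mask.

    Loci with fewer than ``min_genotyped`` called individuals in either
    member of a pair are dropped for that pair only.
    """
    mask = _as_mask(gm, mask)
    sites, freq, _ = gm.site_allele_frequencies(min_genotyped=min_genotyped)
    freq = freq[:, mask]
    n = len(sites)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = cavalli_sforza_distance(
                freq[i], freq[j], average_inside=average_inside)
    return pd.DataFrame(D, index=sites, columns=sites)


def _as_mask(gm: GenotypeMatrix, mask) -> np.ndarray:
    if mask is None:
        return np.ones(gm.n_loci, dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != (gm.n_loci,):
            raise ValueError("boolean mask length does not match loci")
        return mask
    idx = {l: i for i, l in enumerate(gm.locus_ids)}
    out = np.zeros(gm.n_loci, dtype=bool)
    out[[idx[l] for l in mask]] = True
    return out


# ---------------------------------------------------------------------------
# community diversity
# ---------------------------------------------------------------------------

def species_alpha(biomass_row) -> tuple[int, float, float]:
    """Richness S, Shannon H' (nats) and Pielou J for one site's pooled
    biomass vector.  J is undefined (NaN) for S = 1."""
    b = np.asarray(biomass_row, dtype=float)
    b = b[b > 0]
    if b.size == 0:
        raise ValueError("site has no positive biomass")
    S = int(b.size)
    q = b / b.sum()
    H = float(-(q * np.log(q)).sum())
    J = H / np.log(S) if S >= 2 else float("nan")
    return S, H, J


def community_alpha(community: CommunityTable) -> pd.DataFrame:
    rows = {}
    for site in community.site_ids:
        S, H, J = species_alpha(community.biomass.loc[site].values)
        rows[site] = {"richness": S, "shannon": H, "evenness": J}
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(community: CommunityTable, transform: str = "log10_plus1") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity of the community table.

    Abundances are transformed (default log10(x+1)) before computing
    BC_ij = 1 - 2*C_ij / (S_i + S_j), where C_ij sums the lesser
    transformed abundances of shared species and S_i, S_j are the total
    transformed abundances per site.
    """
    B = community.biomass.values
    if transform == "log10_plus1":
        B = np.log10(B + 1)
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform {transform!r}")
    if (B.sum(axis=1) <= 0).any():
        raise ValueError("site with zero total transformed abundance")
    D = squareform(pdist(B, metric="braycurtis"))
    sites = community.site_ids
    return pd.DataFrame(D, index=sites, columns=sites)


def diversity_table(gm: GenotypeMatrix, community: CommunityTable, partition=None,
                    min_genotyped: int = 4) -> pd.DataFrame:
    """Per-site alpha-diversity table: He per dataset mask, number of loci
    per mask, richness, Shannon, evenness and genotyped sample size."""
    masks = {"DS1": None}
    if partition is not None:
        masks = {name: partition.mask(name) for name in ("ds1", "ds2", "ds3", "ds4", "ds5")}
        masks = {k.upper(): v for k, v in masks.items()}
    he = {f"He_{name}": expected_heterozygosity(gm, m, min_genotyped=min_genotyped)
          for name, m in masks.items()}
    out = pd.DataFrame(he)
    out["n"] = pd.Series(gm.populations).value_counts().reindex(out.index)
    missing_sites = set(out.index) - set(community.site_ids)
    if missing_sites:
        raise ValueError(f"community table missing genotyped sites: {sorted(missing_sites)}")
    out = out.join(community_alpha(community).reindex(out.index))
    for name, m in masks.items():
        out[f"loci_{name}"] = int(gm.n_loci if m is None else np.asarray(m).sum())
    return out
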