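"""Species-genetic diversity correlation (SGDC) estimation and tests.

Alpha-SGDCs are Pearson correlations between per-site genetic diversity
(He) and a community alpha-diversity facet (richness or evenness), tested
with a Student t statistic (one-sided positive by default).  Beta-SGDCs
are Mantel correlations between a pairwise genetic distance matrix and
the Bray-Curtis community dissimilarity matrix, tested by joint row/column
permutation.  The locus-subset randomization asks whether the SGDC of an
outlier dataset is more extreme than expected for an equally sized random
subset of a (putatively neutral) reference dataset, recomputing He (or
the full chord-distance matrix) for every subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import squareform

from .io import GenotypeMatrix
from .diversity import expected_heterozygosity, cavalli_sforza_matrix, _as_mask

__all__ = [
    "SGDCResult", "RandomizationResult",
    "alpha_sgdc", "mantel_test", "subset_randomization",
    "compare_marker_panels",
]


@dataclass
class SGDCResult:
    r: float
    n: int                      # sites (pearson_t) or site pairs (mantel)
    test: str                   # 'pearson_t' | 'mantel'
    tail: str                   # 'one' | 'two' | 'upper' | 'lower'
    p: float
    dataset: str = ""
    facet: str = ""

    def __post_init__(self):
        if not -1 - 1e-9 <= self.r <= 1 + 1e-9:
            raise ValueError("correlation outside [-1, 1]")


@dataclass
class RandomizationResult:
    observed_r: float
    subset_size: int
    reference: str
    n_subsets: int
    null_r: np.ndarray
    p: float
    tail: str
    dataset: str = ""
    facet: str = ""


def alpha_sgdc(he_per_site, facet_values, tail: str = "one",
               dataset: str = "", facet: str = "") -> SGDCResult:
    """Pearson alpha-SGDC with a Student t test on n-2 df.

    ``tail='one'`` tests for a positive correlation (upper tail);
    ``tail='two'`` is two-sided.
    """
    x = np.asarray(he_per_site, dtype=float)
    y = np.asarray(facet_values, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors differ in length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in SGDC inputs")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired sites")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an SGDC input")
    alternative = {"one": "greater", "two": "two-sided"}[tail]
    r, p = sps.pearsonr(x, y, alternative=alternative)
    return SGDCResult(float(r), n, "pearson_t", tail, float(p), dataset, facet)


def _offdiag(D: np.ndarray) -> np.ndarray:
    return squareform(D, checks=False)


def _check_distance(D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix not symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValueError("distance matrix diagonal not zero")
    return D


def mantel_test(D_genetic, D_species, n_perm: int = 9999, tail: str = "upper",
                rng=None, dataset: str = "", facet: str = "beta") -> SGDCResult:
    """Mantel correlation between two site x site distance matrices.

    r is the Pearson correlation over the n(n-1)/2 off-diagonal pairs;
    the null permutes site labels (rows and columns jointly) of the first
    matrix; p uses the add-one rule.  ``tail`` in {'upper','lower','two'}.
    """
    A = _check_distance(D_genetic.values if hasattr(D_genetic, "values") else D_genetic)
    B = _check_distance(D_species.values if hasattr(D_species, "values") else D_species)
    if A.shape != B.shape:
        raise ValueError("distance matrices differ in size")
    if hasattr(D_genetic, "index") and hasattr(D_species, "index"):
        if list(D_genetic.index) != list(D_species.index):
            raise ValueError("distance matrices are over different site sets")
    a, b = _offdiag(A), _offdiag(B)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant distance matrix")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(rng)
    n = A.shape[0]
    hits = 0
    bz = (b - b.mean()) / b.std()
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ap = _offdiag(A[np.ix_(perm, perm)])
        rp = float(np.corrcoef(ap, bz)[0, 1])
        if tail == "upper":
            hits += rp >= r_obs - 1e-12
        elif tail == "lower":
            hits += rp <= r_obs + 1e-12
        else:
            hits += abs(rp) >= abs(r_obs) - 1e-12
    p = (hits + 1) / (n_perm + 1)
    return SGDCResult(r_obs, n * (n - 1) // 2, "mantel", tail, p, dataset, facet)


def subset_randomization(gm: GenotypeMatrix, reference_mask, subset_size: int,
                         facet_values=None, observed_r: float | None = None,
                         n_subsets: int = 999, seed=None, tail: str = "lower",
                         beta: bool = False, species_distance=None,
                         min_genotyped: int = 4, dataset: str = "",
                         facet: str = "") -> RandomizationResult:
    """Equal-size locus-subset randomization for SGDC comparison.

    Draws ``n_subsets`` random subsets of ``subset_size`` loci (without
    replacement within a draw) from ``reference_mask`` and recomputes the
    SGDC for each: per-site He against ``facet_values`` for alpha-SGDCs,
    or the full chord-distance matrix against ``species_distance``
    (Mantel r, no inner permutation) when ``beta=True``.  The empirical p
    locates ``observed_r`` (the outlier dataset's SGDC) in the null at the
    configured tail: lower for "as low as observed" alpha comparisons,
    upper for "as high as observed" beta comparisons.
    """
    if subset_size <= 0:
        raise ValueError("subset_size must be positive")
    ref = np.flatnonzero(_as_mask(gm, reference_mask))
    if subset_size > len(ref):
        raise ValueError("subset_size exceeds reference dataset size")
    rng = np.random.default_rng(seed)
    null = np.empty(n_subsets)
    if beta:
        if species_distance is None:
            raise ValueError("beta randomization needs the species distance matrix")
        B = _offdiag(_check_distance(
            species_distance.values if hasattr(species_distance, "values") else species_distance))
    for t in range(n_subsets):
        pick = rng.choice(ref, size=subset_size, replace=False)
        m = np.zeros(gm.n_loci, dtype=bool)
        m[pick] = True
        if beta:
            Dg = cavalli_sforza_matrix(gm, m, min_genotyped=min_genotyped)
            null[t] = np.corrcoef(_offdiag(Dg.values), B)[0, 1]
        else:
            he = expected_heterozygosity(gm, m, min_genotyped=min_genotyped)
            null[t] = np.corrcoef(he.values, np.asarray(facet_values, float))[0, 1]
    if observed_r is None:
        raise ValueError("observed_r (the outlier dataset's SGDC) is required")
    if tail == "lower":
        hits = int((null <= observed_r + 1e-12).sum())
    elif tail == "upper":
        hits = int((null >= observed_r - 1e-12).sum())
    else:
        med = np.median(null)
        hits = int((np.abs(null - med) >= abs(observed_r - med) - 1e-12).sum())
    p = (hits + 1) / (n_subsets + 1)
    return RandomizationResult(float(observed_r), subset_size, str(reference_mask)[:40],
                               n_subsets, null, p, tail, dataset, facet)


def compare_marker_panels(he_a, he_b, influence_threshold: float = 0.1,
                          exclude=None) -> dict:
    """Concordance of per-site diversity between two marker panels.

    Returns the Pearson r over all paired sites, the r after excluding a
    given site set, and leave-one-out influence diagnostics flagging sites
    whose removal changes r by more than ``influence_threshold`` (how
    discordant sites are identified).
    """
    a = pd.Series(he_a).astype(float)
    b = pd.Series(he_b).astype(float)
    common = a.index.intersection(b.index) if not a.index.equals(b.index) else a.index
    a, b = a.loc[common], b.loc[common]
    if len(a) < 4:
        raise ValueError("need at least 4 paired sites")
    r_all = float(np.corrcoef(a, b)[0, 1])
    influence = {}
    for site in common:
        keep = common != site
        r_wo = float(np.corrcoef(a[keep], b[keep])[0, 1])
        influence[site] = r_wo - r_all
    flagged = [s for s, d in influence.items() if abs(d) > influence_threshold]
    out = {"r": r_all, "n": len(a), "influence": influence, "influential_sites": flagged}
    if exclude is not None:
        keep = ~common.isin(list(exclude))
        if keep.sum() >= 4:
            out["r_excluded"] = float(np.corrcoef(a[keep], b[keep])[0, 1])
            out["n_excluded"] = int(keep.sum())
    return out
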