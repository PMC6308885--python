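"""Outlier-locus detection: population-structure and genotype-environment scans.

Two complementary detectors flag loci deviating from genome-wide neutral
expectations:

``PCAOutlierScan``
    A pcadapt-style scan.  Genotypes are standardized, individuals are
    projected on the first *k* principal components, each locus is
    regressed on the component scores, and the Mahalanobis distance of the
    resulting z-score vector (robust covariance) yields a chi-square
    p-value after genomic-inflation rescaling; outliers are called at a
    false-discovery-rate level via Benjamini-Hochberg.

``RDAOutlierScan``
    A redundancy-analysis genotype-environment association scan.  The
    centered genotype matrix is regressed on site-level environmental
    predictors, the fitted values are eigen-decomposed into constrained
    axes, axis significance is assessed by permuting predictor rows, and
    loci whose loadings on a retained axis fall outside a Tukey-type
    interquartile fence are flagged.

Both follow the scikit-learn estimator protocol (``fit``, fitted
attributes with trailing underscores, ``get_params``/``set_params``).
The flag sets combine into the five locus datasets: DS1 = all post-QC
loci, DS4 = union of the two scans, DS5 = intersection, DS2 = DS1 minus
DS4, DS3 = DS1 minus DS5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import MinCovDet

from .io import MISSING, GenotypeMatrix, EnvironmentTable

__all__ = [
    "PCAOutlierScan", "RDAOutlierScan", "LocusPartition",
    "choose_k", "prescreen_environment", "vif_check",
    "pca_scan", "rda_scan", "build_partition",
]


def _dosage_array(X) -> tuple[np.ndarray, list]:
    if isinstance(X, GenotypeMatrix):
        return X.dosage.astype(float), list(X.locus_ids)
    X = np.asarray(X, dtype=float)
    return X, [f"L{j}" for j in range(X.shape[1])]


def choose_k(values, k_max: int | None = None) -> int:
    """Scree elbow via the maximum-distance-to-chord rule.

    ``values`` are proportions of variance per component, descending.  The
    point of maximum perpendicular distance from the chord joining the
    first and last scree points marks the start of the flat tail; the
    elbow is the component just before it.  A flat spectrum degenerates to
    k=1 with a warning.  At least 3 candidate components are required.
    """
    v = np.asarray(values, dtype=float)
    if k_max is not None:
        v = v[:k_max]
    m = len(v)
    if m < 3:
        raise ValueError("need at least 3 candidate components for the scree elbow")
    if v[0] - v[-1] <= 1e-12:
        warnings.warn("flat scree spectrum; defaulting to k=1")
        return 1
    x = np.arange(m) / (m - 1)
    y = (v - v[-1]) / (v[0] - v[-1])
    # distance from chord joining (0, y0=1) to (1, ym=0): |x + y - 1| / sqrt(2)
    dist = np.abs(x + y - 1)
    return max(int(np.argmax(dist)), 1)


class PCAOutlierScan(BaseEstimator):
    """Population-structure outlier scan (PCA + robust Mahalanobis distance).

    Parameters
    ----------
    k : int or 'auto'
        Number of principal components retained.  ``'auto'`` picks the
        scree elbow (``choose_k``); the scree is exposed so the choice can
        be overridden, as is conventional for this scan.
    k_max : int
        Candidate components examined when ``k='auto'``.
    fdr_level : float
        Benjamini-Hochberg false-discovery-rate level for outlier calls.
    random_state : int
        Seed for the minimum-covariance-determinant subsampling; the scan
        is otherwise deterministic.

    Attributes
    ----------
    k_ : retained components.
    scree_ : proportion of variance per component.
    scores_ : individual scores on the k components.
    tested_ : boolean mask of polymorphic loci actually tested.
    zscores_, d2_, lambda_, pvalues_, qvalues_, outliers_ : per-locus
        results (NaN / False at untested loci).
    """

    def __init__(self, k="auto", k_max=20, fdr_level=0.10, random_state=0):
        self.k = k
        self.k_max = k_max
        self.fdr_level = fdr_level
        self.random_state = random_state

    def fit(self, X, y=None):
        d, locus_ids = _dosage_array(X)
        d[d == MISSING] = np.nan
        n, L = d.shape
        p_hat = np.nanmean(d, axis=0) / 2.0
        poly = (p_hat > 0) & (p_hat < 1) & ~np.isnan(p_hat)
        if not poly.all():
            warnings.warn(f"excluding {int((~poly).sum())} monomorphic loci from the scan")
        self.tested_ = poly
        self.locus_ids_ = locus_ids
        Z = (d - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
        Z[:, ~poly] = 0.0
        Z = np.nan_to_num(Z)  # missing -> 0 after centering (mean imputation)

        k_cap = min(self.k_max, n - 1, L)
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        self.scree_ = (s ** 2 / (s ** 2).sum())[:k_cap]
        k = choose_k(self.scree_) if self.k == "auto" else int(self.k)
        if k >= n:
            raise ValueError("k must be smaller than the number of individuals")
        self.k_ = k
        G = U[:, :k]
        self.scores_ = G * s[:k]

        # per-locus regression on the component scores (G orthonormal)
        beta = G.T @ Z                       # k x L
        resid = Z - G @ beta
        dof = max(n - k - 1, 1)
        sigma = np.sqrt((resid ** 2).sum(axis=0) / dof)
        sigma[sigma == 0] = np.nan
        z = (beta / sigma).T                 # L x k
        self.zscores_ = np.where(poly[:, None], z, np.nan)

        zt = self.zscores_[poly & ~np.isnan(z).any(axis=1)]
        if k >= 2:
            mcd = MinCovDet(random_state=self.random_state).fit(zt)
            loc, cov = mcd.location_, mcd.covariance_
        else:
            loc = np.median(zt, axis=0)
            cov = np.atleast_2d(np.var(zt, axis=0, ddof=1))
        cov_inv = np.linalg.pinv(cov)
        d2 = np.full(L, np.nan)
        ok = poly & ~np.isnan(z).any(axis=1)
        diff = self.zscores_[ok] - loc
        d2[ok] = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
        self.d2_ = d2
        self.lambda_ = float(np.nanmedian(d2) / stats.chi2.median(df=k))
        p = np.full(L, np.nan)
        p[ok] = stats.chi2.sf(d2[ok] / self.lambda_, df=k)
        p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
        self.pvalues_ = p
        q = np.full(L, np.nan)
        q[ok] = stats.false_discovery_control(p[ok])
        self.qvalues_ = q
        self.outliers_ = np.where(ok, q <= self.fdr_level, False)
        return self

    def outlier_loci(self) -> list:
        return [l for l, f in zip(self.locus_ids_, self.outliers_) if f]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d2": self.d2_, "p": self.pvalues_, "q": self.qvalues_,
             "outlier": self.outliers_},
            index=pd.Index(self.locus_ids_, name="locus_id"),
        )


# ---------------------------------------------------------------------------
# environment preparation
# ---------------------------------------------------------------------------

def prescreen_environment(env: EnvironmentTable, r_threshold: float = 0.7) -> EnvironmentTable:
    """Drop collinear predictors until no pairwise |Pearson r| exceeds
    ``r_threshold``.

    Iteratively removes the variable with the most offending partners
    (ties broken by larger mean |r|, then by name order).
    """
    X = env.design_matrix()
    if X.shape[1] < 2:
        return env
    keep = list(X.columns)
    while True:
        C = X[keep].corr().abs().values
        np.fill_diagonal(C, 0.0)
        counts = (C > r_threshold).sum(axis=0)
        if counts.max() == 0:
            break
        worst = counts.max()
        cand = [i for i in range(len(keep)) if counts[i] == worst]
        mean_r = C.mean(axis=0)
        cand.sort(key=lambda i: (-mean_r[i], keep[i]))
        keep.remove(keep[cand[0]])
    return env.drop([c for c in env.variables if c not in keep])


def vif_check(env) -> pd.Series:
    """Variance inflation factor per predictor: VIF_j = 1 / (1 - R^2_j)
    from regressing predictor j on all the others (with intercept).
    Perfect collinearity reports ``inf``.  A VIF above 5 warrants a
    warning, not an error."""
    X = env.design_matrix() if isinstance(env, EnvironmentTable) else pd.DataFrame(env)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors for VIF")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more sites than predictors for VIF")
    vifs = {}
    A = X.values - X.values.mean(axis=0)
    for j, name in enumerate(X.columns):
        yj = A[:, j]
        others = np.delete(A, j, axis=1)
        if np.allclose(yj, 0):
            vifs[name] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        r2 = 1 - ((yj - others @ coef) ** 2).sum() / (yj ** 2).sum()
        vifs[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    out = pd.Series(vifs, name="VIF")
    high = out[out > 5]
    if len(high):
        warnings.warn(f"VIF exceeds 5 for: {', '.join(high.index)}")
    return out


# ---------------------------------------------------------------------------
# RDA genotype-environment scan
# ---------------------------------------------------------------------------

class RDAOutlierScan(BaseEstimator):
    """Genotype-environment association scan by redundancy analysis.

    Individuals are the observation unit; each carries its site's
    (prescreened, indicator-encoded) environmental values.  Missing
    genotypes are imputed to the locus's most common genotype.  Axis
    significance uses permutation of whole predictor rows across
    individuals with forward conditioning on earlier axes; loci are
    flagged when their standardized loading on a retained axis falls
    outside ``[Q1 - m*IQR, Q3 + m*IQR]`` (``loading_anchor='quartile'``,
    the conventional reading of the "beyond m interquartile ranges" rule)
    or ``median +/- m*IQR`` (``'median'``).

    ``axis_rule`` resolves the retained-axis set when the scree elbow and
    the permutation tests disagree: ``'min'`` (default) keeps axes that
    are both significant and before the elbow; ``'significant'`` or
    ``'elbow'`` use a single criterion.  Both counts are reported.
    """

    def __init__(self, n_axes="auto", n_perm=999, alpha=0.05,
                 loading_multiplier=2.0, loading_anchor="quartile",
                 axis_rule="min", random_state=0):
        self.n_axes = n_axes
        self.n_perm = n_perm
        self.alpha = alpha
        self.loading_multiplier = loading_multiplier
        self.loading_anchor = loading_anchor
        self.axis_rule = axis_rule
        self.random_state = random_state

    def fit(self, X, env=None):
        """Fit the scan.  ``X`` is a GenotypeMatrix (or dosage array);
        ``env`` an EnvironmentTable over the matrix's sites, or a
        DataFrame/array of predictor rows aligned to individuals."""
        d, locus_ids = _dosage_array(X)
        self.locus_ids_ = locus_ids
        n, L = d.shape
        E = self._predictor_rows(X, env, n)
        p = E.shape[1]
        n_sites = len(set(map(tuple, np.round(E, 12)))) if not isinstance(X, GenotypeMatrix) \
            else len(set(X.populations))
        if p >= n_sites:
            raise ValueError("more predictors than sites")

        # modal-genotype imputation
        d = d.copy()
        for j in range(L):
            col = d[:, j]
            miss = col == MISSING
            if miss.any():
                vals, counts = np.unique(col[~miss], return_counts=True)
                if len(vals) == 0:
                    raise ValueError(f"locus {locus_ids[j]} has no called genotypes")
                col[miss] = vals[np.argmax(counts)]
        if (d.std(axis=0) == 0).any():
            bad = [locus_ids[j] for j in np.flatnonzero(d.std(axis=0) == 0)]
            raise ValueError(f"constant loci after imputation: {bad[:5]}")
        Y = d - d.mean(axis=0)
        Xc = E - E.mean(axis=0)

        Q, _ = np.linalg.qr(Xc)
        M = Q.T @ Y                                   # p x L
        A, s, Vt = np.linalg.svd(M, full_matrices=False)
        n_con = int((s > 1e-10).sum())
        s = s[:n_con]
        eig = s ** 2 / (n - 1)
        self.eigenvalues_ = eig
        self.axis_share_ = eig / eig.sum()
        self.variance_explained_ = float((s ** 2).sum() / (Y ** 2).sum())
        self.site_scores_ = (Q @ A) * s               # individual scores, n x n_con
        self.loadings_ = Vt.T[:, :n_con]              # L x n_con

        self.axis_pvalues_ = self._axis_permutation_pvalues(Y, Xc)
        sig = self.axis_pvalues_ <= self.alpha
        n_sig = 0
        for flag in sig:                               # consecutive from axis 1
            if not flag:
                break
            n_sig += 1
        self.n_significant_ = n_sig
        self.elbow_ = choose_k(self.axis_share_) if n_con >= 3 else n_con
        if self.n_axes == "auto":
            rule = {"min": min(self.elbow_, n_sig),
                    "significant": n_sig,
                    "elbow": self.elbow_}[self.axis_rule]
            n_ret = max(rule, 0)
        else:
            n_ret = int(self.n_axes)
        self.n_retained_ = min(n_ret, n_con)
        self.retained_axes_ = list(range(self.n_retained_))

        # standardized loadings and the interquartile fence
        self.zscores_ = (self.loadings_ - self.loadings_.mean(axis=0)) \
            / self.loadings_.std(axis=0, ddof=1)
        out = np.zeros(L, dtype=bool)
        m = self.loading_multiplier
        for a in self.retained_axes_:
            z = self.zscores_[:, a]
            q1, med, q3 = np.percentile(z, [25, 50, 75])
            iqr = q3 - q1
            if self.loading_anchor == "quartile":
                lo, hi = q1 - m * iqr, q3 + m * iqr
            elif self.loading_anchor == "median":
                lo, hi = med - m * iqr, med + m * iqr
            else:
                raise ValueError("loading_anchor must be 'quartile' or 'median'")
            out |= (z < lo) | (z > hi)
        self.outliers_ = out

        # strongest environmental correlate per retained axis
        cors = np.zeros((n_con, p))
        for a in range(n_con):
            for j in range(p):
                xj = Xc[:, j]
                if xj.std() == 0 or self.site_scores_[:, a].std() == 0:
                    continue
                cors[a, j] = np.corrcoef(self.site_scores_[:, a], xj)[0, 1]
        self.axis_env_correlations_ = pd.DataFrame(
            cors, columns=self._env_names_, index=[f"RDA{a + 1}" for a in range(n_con)])
        self.top_env_ = {f"RDA{a + 1}": self._env_names_[int(np.argmax(np.abs(cors[a])))]
                         for a in self.retained_axes_}
        return self

    def _predictor_rows(self, X, env, n) -> np.ndarray:
        if isinstance(env, EnvironmentTable):
            if not isinstance(X, GenotypeMatrix):
                raise ValueError("EnvironmentTable input requires a GenotypeMatrix")
            D = env.design_matrix()
            missing = set(X.populations) - set(D.index)
            if missing:
                raise ValueError(f"sites without environment rows: {sorted(missing)}")
            rows = D.loc[list(X.populations)]
            self._env_names_ = list(D.columns)
            return rows.values.astype(float)
        E = pd.DataFrame(env)
        if len(E) != n:
            raise ValueError("predictor rows must align with individuals")
        self._env_names_ = [str(c) for c in E.columns]
        return E.values.astype(float)

    def _axis_permutation_pvalues(self, Y, Xc) -> np.ndarray:
        """Per-axis p-values: permute predictor rows, forward-conditioning
        each axis on the observed earlier axes."""
        rng = np.random.default_rng(self.random_state)
        n = Y.shape[0]
        n_con = len(self.eigenvalues_)
        pvals = np.ones(n_con)
        U_all = self.site_scores_ / np.linalg.norm(self.site_scores_, axis=0)
        for a in range(n_con):
            if a == 0:
                Yr, Xr = Y, Xc
            else:
                P = U_all[:, :a]
                Yr = Y - P @ (P.T @ Y)
                Xr = Xc - P @ (P.T @ Xc)
            Qr, _ = np.linalg.qr(Xr)
            M = Qr.T @ Yr
            s2 = np.linalg.svd(M, compute_uv=False)[0] ** 2
            rss = (Yr ** 2).sum() - (M ** 2).sum()
            f_obs = s2 / max(rss, 1e-300)
            hits = 0
            for _ in range(self.n_perm):
                perm = rng.permutation(n)
                Mp = Qr[perm].T @ Yr
                s2p = np.linalg.svd(Mp, compute_uv=False)[0] ** 2
                rssp = (Yr ** 2).sum() - (Mp ** 2).sum()
                if s2p / max(rssp, 1e-300) >= f_obs - 1e-12:
                    hits += 1
            pvals[a] = (hits + 1) / (self.n_perm + 1)
        return pvals

    def outlier_loci(self) -> list:
        return [l for l, f in zip(self.locus_ids_, self.outliers_) if f]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.zscores_[:, :max(self.n_retained_, 1)],
                          columns=[f"z_RDA{a + 1}" for a in range(max(self.n_retained_, 1))],
                          index=pd.Index(self.locus_ids_, name="locus_id"))
        df["outlier"] = self.outliers_
        return df


# ---------------------------------------------------------------------------
# the five locus datasets
# ---------------------------------------------------------------------------

@dataclass
class LocusPartition:
    """Boolean masks for the five locus datasets over a common locus list.

    DS1: all post-QC loci. DS4: union of the two scans' outliers.
    DS5: intersection. DS2 = DS1 minus DS4. DS3 = DS1 minus DS5.
    """

    locus_ids: list
    ds1: np.ndarray
    ds2: np.ndarray
    ds3: np.ndarray
    ds4: np.ndarray
    ds5: np.ndarray

    def mask(self, name: str) -> np.ndarray:
        return getattr(self, name.lower())

    def sizes(self) -> dict:
        return {k.upper(): int(self.mask(k).sum())
                for k in ("ds1", "ds2", "ds3", "ds4", "ds5")}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k.upper(): self.mask(k) for k in ("ds1", "ds2", "ds3", "ds4", "ds5")},
            index=pd.Index(self.locus_ids, name="locus_id"),
        )


def build_partition(all_loci, pca_flags, rda_flags) -> LocusPartition:
    """Combine the two outlier-flag sets into the DS1-DS5 masks."""
    all_loci = list(all_loci)
    idx = {l: i for i, l in enumerate(all_loci)}
    for src, flags in (("structure scan", pca_flags), ("environment scan", rda_flags)):
        unknown = [l for l in flags if l not in idx]
        if unknown:
            raise ValueError(f"{src} flags unknown loci: {unknown[:5]}")
    pca = np.zeros(len(all_loci), dtype=bool)
    rda = np.zeros(len(all_loci), dtype=bool)
    pca[[idx[l] for l in pca_flags]] = True
    rda[[idx[l] for l in rda_flags]] = True
    ds1 = np.ones(len(all_loci), dtype=bool)
    ds4 = pca | rda
    ds5 = pca & rda
    return LocusPartition(all_loci, ds1, ds1 & ~ds4, ds1 & ~ds5, ds4, ds5)


# thin functional wrappers -------------------------------------------------

def pca_scan(gm, k="auto", fdr_level=0.10, random_state=0, **kw) -> PCAOutlierScan:
    return PCAOutlierScan(k=k, fdr_level=fdr_level, random_state=random_state, **kw).fit(gm)


def rda_scan(gm, env, n_perm=999, random_state=0, **kw) -> RDAOutlierScan:
    return RDAOutlierScan(n_perm=n_perm, random_state=random_state, **kw).fit(gm, env)
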