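"""SGDC estimation: Pearson/t, Mantel, locus-subset randomization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sgdc import (GenotypeMatrix, alpha_sgdc, mantel_test, subset_randomization,
                  compare_marker_panels, expected_heterozygosity, community_alpha,
                  ScenarioConfig, simulate_genotypes, simulate_community)


def _pearson_t_oracle(x, y, tail):
    """Direct-formula oracle: r from the covariance definition, p from the
    Student t distribution on n-2 df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
    p = sps.t.sf(t, n - 2) if tail == "one" else 2 * sps.t.sf(abs(t), n - 2)
    return r, p


class TestAlphaSGDC:
    @pytest.mark.parametrize("tail", ["one", "two"])
    def test_matches_direct_formula_oracle(self, tail):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 40)
            x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
            res = alpha_sgdc(x, y, tail=tail)
            r, p = _pearson_t_oracle(x, y, tail)
            assert res.r == pytest.approx(r, abs=1e-12)
            assert res.p == pytest.approx(p, abs=1e-12)
            assert res.n == n

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = alpha_sgdc(x, 3 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 4"):
            alpha_sgdc([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="zero variance"):
            alpha_sgdc([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="missing"):
            alpha_sgdc([1, np.nan, 3, 4], [1, 2, 3, 4])


def _random_distance(rng, n):
    A = np.abs(rng.normal(0, 1, (n, n)))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    return A


class TestMantel:
    def test_affine_relation_gives_r_one_and_min_p(self):
        rng = np.random.default_rng(1)
        A = _random_distance(rng, 12)
        res = mantel_test(A, 2 * A, n_perm=199, rng=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)
        assert res.n == 12 * 11 // 2

    def test_r_matches_independent_implementation(self):
        from skbio.stats.distance import mantel as skbio_mantel, DistanceMatrix
        rng = np.random.default_rng(2)
        A, B = _random_distance(rng, 10), _random_distance(rng, 10)
        res = mantel_test(A, B, n_perm=99, rng=0)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(A), DistanceMatrix(B),
                                   permutations=0)
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_invariant_to_joint_relabeling_and_affine_transform(self):
        rng = np.random.default_rng(3)
        A, B = _random_distance(rng, 9), _random_distance(rng, 9)
        perm = rng.permutation(9)
        res = mantel_test(A, B, n_perm=99, rng=5)
        res_p = mantel_test(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)],
                            n_perm=99, rng=5)
        assert res.r == pytest.approx(res_p.r)
        B_aff = 0.2 + 3 * B                       # positive-slope affine transform
        np.fill_diagonal(B_aff, 0)
        res_aff = mantel_test(A, B_aff, n_perm=99, rng=5)
        assert res_aff.r == pytest.approx(res.r)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        hits = sum(mantel_test(_random_distance(rng, 15), _random_distance(rng, 15),
                               n_perm=99, rng=rng).p <= 0.05
                   for _ in range(200))
        assert 0.01 <= hits / 200 <= 0.10

    def test_rejects_malformed_matrices(self):
        A = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="not symmetric"):
            mantel_test(A, A.T @ A * 0 + np.eye(2) * 0, n_perm=9)
        B = np.ones((3, 3))
        with pytest.raises(ValueError, match="diagonal"):
            mantel_test(B, B, n_perm=9)


def _he_scenario(seed=0):
    sc = ScenarioConfig(n_sites=12, individuals_per_site=6, n_neutral_loci=150,
                        n_adaptive_loci=30, seed=seed)
    gm, truth = simulate_genotypes(sc)
    rich = community_alpha(simulate_community(sc))["richness"]
    return gm, truth, rich


class TestSubsetRandomization:
    def test_degenerate_full_reference_draw_gives_p_one(self):
        gm, truth, rich = _he_scenario()
        neutral = (truth["class"] == "neutral").values
        he = expected_heterozygosity(gm, neutral)
        obs = float(np.corrcoef(he.values, rich.loc[he.index])[0, 1])
        res = subset_randomization(gm, neutral, int(neutral.sum()),
                                   facet_values=rich.loc[he.index].values,
                                   observed_r=obs, n_subsets=30, seed=0, tail="lower")
        assert res.p == 1.0
        assert np.allclose(res.null_r, obs)

    def test_null_median_observation_has_central_p(self):
        gm, truth, rich = _he_scenario(1)
        neutral = (truth["class"] == "neutral").values
        res = subset_randomization(gm, neutral, 40,
                                   facet_values=rich.values,
                                   observed_r=0.0, n_subsets=199, seed=1, tail="lower")
        med = np.median(res.null_r)
        res2 = subset_randomization(gm, neutral, 40, facet_values=rich.values,
                                    observed_r=float(med), n_subsets=199, seed=1,
                                    tail="lower")
        assert 0.3 <= res2.p <= 0.7

    def test_decoupled_adaptive_loci_fall_in_lower_tail(self):
        """When richness tracks connectivity but adaptive allele frequencies
        track an independent environmental axis, the adaptive-locus SGDC sits
        below the neutral-subset null in most seeds."""
        low = 0
        for seed in range(10):
            sc = ScenarioConfig(n_sites=15, individuals_per_site=8,
                                n_neutral_loci=300, n_adaptive_loci=60,
                                adaptive_cline_slope=3.0, seed=seed)
            gm, truth = simulate_genotypes(sc)
            rich = community_alpha(simulate_community(sc))["richness"]
            neutral = (truth["class"] == "neutral").values
            he_a = expected_heterozygosity(gm, ~neutral)
            obs = float(np.corrcoef(he_a.values, rich.loc[he_a.index])[0, 1])
            res = subset_randomization(gm, neutral, int((~neutral).sum()),
                                       facet_values=rich.loc[he_a.index].values,
                                       observed_r=obs, n_subsets=99, seed=seed,
                                       tail="lower")
            low += res.p < 0.5
        assert low >= 7

    def test_subset_size_validation(self):
        gm, truth, rich = _he_scenario(2)
        with pytest.raises(ValueError, match="positive"):
            subset_randomization(gm, None, 0, facet_values=rich.values,
                                 observed_r=0.0)
        with pytest.raises(ValueError, match="exceeds"):
            subset_randomization(gm, np.zeros(gm.n_loci, bool) | (np.arange(gm.n_loci) < 5),
                                 10, facet_values=rich.values, observed_r=0.0)


class TestMarkerPanelConcordance:
    def test_identical_vectors(self):
        he = pd.Series([0.1, 0.2, 0.3, 0.15, 0.25], index=list("abcde"))
        rep = compare_marker_panels(he, he.copy())
        assert rep["r"] == pytest.approx(1.0)
        assert rep["influential_sites"] == []

    def test_discordant_sites_flagged_in_reference_table(self, carex_table):
        rep = compare_marker_panels(carex_table["he_ds1"], carex_table["he_aflp"],
                                    influence_threshold=0.05,
                                    exclude=["S6", "S21"])
        assert round(rep["r"], 2) == 0.70
        assert round(rep["r_excluded"], 2) == 0.90
        assert {"S6", "S21"} & set(rep["influential_sites"])
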