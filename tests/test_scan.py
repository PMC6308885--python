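"""Outlier scans, scree elbow, collinearity tools, and the locus partition."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sgdc import (GenotypeMatrix, EnvironmentTable, PCAOutlierScan, RDAOutlierScan,
                  choose_k, prescreen_environment, vif_check, build_partition)


class TestChooseK:
    def test_one_dominant_eigenvalue(self):
        assert choose_k([0.9] + [0.01] * 9) == 1

    def test_two_dominant_eigenvalues(self):
        assert choose_k([0.5, 0.3] + [0.02] * 10) == 2

    def test_flat_spectrum_degenerates_to_one(self):
        with pytest.warns(UserWarning, match="flat scree"):
            assert choose_k([0.1] * 10) == 1

    def test_too_few_candidates(self):
        with pytest.raises(ValueError, match="at least 3"):
            choose_k([0.6, 0.4])

    def test_two_deme_structure_recovered(self, two_deme_gm):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = PCAOutlierScan(k="auto", random_state=1).fit(two_deme_gm)
        assert scan.k_ == 1


class TestPCAScan:
    def test_panmictic_null_is_calibrated(self, make_gm):
        """No structure: inflation factor near 1, and the 10% FDR flags at
        most a trivial fraction of loci."""
        rng = np.random.default_rng(42)
        for rep in range(3):
            p = rng.uniform(0.1, 0.9, 400)
            gm = make_gm(rng.binomial(2, p, (60, 400)).astype(np.int8))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scan = PCAOutlierScan(k="auto", random_state=rep).fit(gm)
            assert 0.8 < scan.lambda_ < 1.3
            assert scan.outliers_.mean() <= 0.01

    def test_differentiated_locus_has_max_distance_and_is_flagged(self, two_deme_gm):
        scan = PCAOutlierScan(k=1, random_state=1).fit(two_deme_gm)
        assert int(np.nanargmax(scan.d2_)) == 0
        assert scan.outliers_[0]

    def test_deterministic_given_input_and_seed(self, two_deme_gm):
        a = PCAOutlierScan(k=1, random_state=1).fit(two_deme_gm)
        b = PCAOutlierScan(k=1, random_state=1).fit(two_deme_gm)
        np.testing.assert_array_equal(a.outliers_, b.outliers_)
        np.testing.assert_allclose(a.d2_, b.d2_)

    def test_k_must_be_less_than_individuals(self, make_gm):
        rng = np.random.default_rng(0)
        gm = make_gm(rng.integers(0, 3, (5, 30)).astype(np.int8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="smaller than the number"):
                PCAOutlierScan(k=5).fit(gm)

    def test_monomorphic_loci_excluded_with_warning(self, make_gm):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, (30, 20)).astype(np.int8)
        dosage[:, 3] = 0
        with pytest.warns(UserWarning, match="monomorphic"):
            scan = PCAOutlierScan(k=2, random_state=0).fit(make_gm(dosage))
        assert not scan.tested_[3] and np.isnan(scan.pvalues_[3])


class TestEnvironmentPrep:
    def _env(self, df):
        return EnvironmentTable(df)

    def test_duplicate_variable_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        env = self._env(pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 20)},
                                     index=[f"S{i}" for i in range(20)]))
        kept = prescreen_environment(env, 0.7)
        assert len(kept.variables) == 2 and "c" in kept.variables

    def test_uncorrelated_set_untouched(self):
        rng = np.random.default_rng(1)
        env = self._env(pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"),
                                     index=[f"S{i}" for i in range(30)]))
        assert prescreen_environment(env, 0.7).variables == list("abcd")

    def test_mutually_correlated_triple_loses_two(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 40)
        df = pd.DataFrame({
            "a": base,
            "b": 0.95 * base + 0.05 * rng.normal(0, 1, 40),
            "c": 0.9 * base + 0.1 * rng.normal(0, 1, 40),
            "d": rng.normal(0, 1, 40),
        }, index=[f"S{i}" for i in range(40)])
        kept = prescreen_environment(self._env(df), 0.7)
        assert len(kept.variables) == 2 and "d" in kept.variables

    def test_vif_closed_forms(self):
        n = 20
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(0, 1, (n, 3)))
        z1, z2, z3 = Q.T                              # exactly orthogonal, centered-ish
        z1, z2, z3 = (z - z.mean() for z in (z1, z2, z3))
        Q2, _ = np.linalg.qr(np.column_stack([z1, z2, z3]))
        z1, z2, z3 = Q2.T
        idx = [f"S{i}" for i in range(n)]
        ortho = self._env(pd.DataFrame({"a": z1, "b": z2, "c": z3}, index=idx))
        assert np.allclose(vif_check(ortho).values, 1.0)

        dup = self._env(pd.DataFrame({"a": z1, "b": z1, "c": z3}, index=idx))
        with pytest.warns(UserWarning, match="VIF exceeds 5"):
            vifs = vif_check(dup)
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

        # |r| = 0.6 pair with an orthogonal third: VIF = 1/(1-0.36) = 1.5625
        pair = self._env(pd.DataFrame({"a": z1, "b": 0.6 * z1 + 0.8 * z2, "c": z3}, index=idx))
        vifs = vif_check(pair)
        assert vifs["a"] == pytest.approx(1.5625)
        assert vifs["b"] == pytest.approx(1.5625)
        assert vifs["c"] == pytest.approx(1.0)


def _noise_gm(rng, n_sites=9, k_ind=5, L=80):
    p = rng.uniform(0.2, 0.8, L)
    d = rng.binomial(2, p, (n_sites * k_ind, L)).astype(np.int8)
    return GenotypeMatrix(
        [f"S{s}_{i}" for s in range(n_sites) for i in range(k_ind)],
        [f"L{j}" for j in range(L)],
        np.repeat([f"S{s}" for s in range(n_sites)], k_ind), d)


class TestRDAScan:
    def test_null_rarely_retains_axes(self):
        """Pure-noise genotypes: the permutation tests retain an axis at
        alpha=0.05 in no more than ~10% of replicates."""
        rng = np.random.default_rng(5)
        retained = 0
        reps = 60
        for rep in range(reps):
            gm = _noise_gm(rng)
            env = EnvironmentTable(pd.DataFrame(
                {"E": rng.normal(0, 1, 9), "X": rng.normal(0, 1, 9)},
                index=[f"S{s}" for s in range(9)]))
            scan = RDAOutlierScan(n_perm=99, random_state=rep).fit(gm, env)
            retained += scan.n_retained_ > 0
        assert retained / reps <= 0.10

    def test_environment_linear_locus_is_top_outlier(self):
        rng = np.random.default_rng(1)
        n_sites, k_ind, L = 10, 6, 200
        E = np.linspace(-1, 1, n_sites)
        gm = _noise_gm(rng, n_sites, k_ind, L)
        dosage = gm.dosage.copy().astype(float)
        dosage[:, 0] = np.clip(np.round(1 + np.repeat(E, k_ind)
                                        + rng.normal(0, 0.2, n_sites * k_ind)), 0, 2)
        gm = GenotypeMatrix(gm.individual_ids, gm.locus_ids, gm.populations,
                            dosage.astype(np.int8))
        env = EnvironmentTable(pd.DataFrame(
            {"E": E, "X2": rng.normal(0, 1, n_sites)},
            index=[f"S{s}" for s in range(n_sites)]))
        scan = RDAOutlierScan(n_perm=199, random_state=2).fit(gm, env)
        assert scan.n_retained_ >= 1
        assert int(np.argmax(np.abs(scan.zscores_[:, 0]))) == 0
        assert scan.outliers_[0]
        assert scan.top_env_["RDA1"] == "E"
        assert 0 < scan.variance_explained_ < 1

    def test_modal_imputation_and_missing_handling(self):
        rng = np.random.default_rng(3)
        gm = _noise_gm(rng)
        dosage = gm.dosage.copy()
        dosage[rng.uniform(size=dosage.shape) < 0.1] = -1
        gm2 = GenotypeMatrix(gm.individual_ids, gm.locus_ids, gm.populations, dosage)
        env = EnvironmentTable(pd.DataFrame(
            {"E": rng.normal(0, 1, 9), "X": rng.normal(0, 1, 9)},
            index=[f"S{s}" for s in range(9)]))
        scan = RDAOutlierScan(n_perm=49, random_state=0).fit(gm2, env)
        assert scan.loadings_.shape[0] == gm2.n_loci

    def test_more_predictors_than_sites_rejected(self):
        rng = np.random.default_rng(4)
        gm = _noise_gm(rng, n_sites=4, k_ind=5, L=30)
        env = EnvironmentTable(pd.DataFrame(
            rng.normal(0, 1, (4, 5)), columns=list("abcde"),
            index=[f"S{s}" for s in range(4)]))
        with pytest.raises(ValueError, match="more predictors than sites"):
            RDAOutlierScan(n_perm=9).fit(gm, env)


class TestPartition:
    def test_published_dataset_sizes(self):
        """1,709 post-QC loci with 229 union / 39 joint outliers give the
        published non-outlier dataset sizes 1,480 and 1,670."""
        loci = [f"L{j}" for j in range(1709)]
        rng = np.random.default_rng(0)
        pca = list(rng.choice(loci, 173, replace=False))
        joint = set(rng.choice(pca, 39, replace=False))
        others = [l for l in loci if l not in set(pca)]
        rda = list(joint) + list(rng.choice(others, 95 - 39, replace=False))
        part = build_partition(loci, pca, rda)
        sizes = part.sizes()
        assert sizes == {"DS1": 1709, "DS2": 1480, "DS3": 1670, "DS4": 229, "DS5": 39}

    def test_disjoint_and_identical_flag_sets(self):
        loci = list("abcdef")
        part = build_partition(loci, ["a"], ["b"])
        assert part.sizes() == {"DS1": 6, "DS2": 4, "DS3": 6, "DS4": 2, "DS5": 0}
        part = build_partition(loci, ["a", "b"], ["a", "b"])
        assert (part.ds4 == part.ds5).all() and (part.ds2 == part.ds3).all()

    def test_unknown_locus_rejected(self):
        with pytest.raises(ValueError, match="unknown loci"):
            build_partition(["a", "b"], ["z"], [])

    @given(st.integers(5, 60), st.data())
    @settings(max_examples=50, deadline=None)
    def test_partition_arithmetic_invariants(self, n, data):
        """|DS2| = |DS1| - |DS4|, |DS3| = |DS1| - |DS5|, DS5 subset of DS4,
        for arbitrary flag configurations."""
        loci = [f"L{j}" for j in range(n)]
        pca = data.draw(st.sets(st.sampled_from(loci)))
        rda = data.draw(st.sets(st.sampled_from(loci)))
        part = build_partition(loci, sorted(pca), sorted(rda))
        s = part.sizes()
        assert s["DS2"] == s["DS1"] - s["DS4"]
        assert s["DS3"] == s["DS1"] - s["DS5"]
        assert not (part.ds5 & ~part.ds4).any()
        assert (part.ds4 == (part.ds1 & ~part.ds2)).all()
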