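"""Null-allele estimation, heterozygosity, and F_ST estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import nichescan as ns
from nichescan.popgen import fst_from_frequencies


def qhat_quadrature(n, x):
    """Independent oracle: posterior mean of q by numerical quadrature of
    (q^2)^x (1-q^2)^(n-x) under a uniform prior."""
    like = lambda q: q ** (2 * x) * (1 - q**2) ** (n - x)
    num, _ = integrate.quad(lambda q: q * like(q), 0, 1)
    den, _ = integrate.quad(like, 0, 1)
    return num / den


class TestNullAlleleEstimator:
    def test_all_absent_closed_form(self):
        # all 10 individuals band-absent: posterior mean is 10.5/11
        assert ns.estimate_null_allele_freq(10, 10) == pytest.approx(10.5 / 11, abs=1e-12)

    @pytest.mark.parametrize("n,x", [(10, 0), (10, 3), (10, 10), (18, 5), (50, 25), (7, 1)])
    def test_matches_quadrature(self, n, x):
        assert ns.estimate_null_allele_freq(n, x) == pytest.approx(
            qhat_quadrature(n, x), abs=1e-8)

    def test_none_absent_small_sample(self):
        # prior keeps the estimate well away from 0
        assert ns.estimate_null_allele_freq(10, 0) == pytest.approx(0.168, abs=0.001)

    def test_asymptotic_consistency(self):
        # x/n = c fixed, n large: q_hat -> sqrt(c)
        assert ns.estimate_null_allele_freq(10000, 2500) == pytest.approx(0.5, abs=0.01)

    @given(st.integers(1, 200), st.data())
    @settings(max_examples=50, deadline=None)
    def test_interior_and_monotone(self, n, data):
        x = data.draw(st.integers(0, n))
        q = ns.estimate_null_allele_freq(n, x)
        assert 0 < q < 1
        if x < n:
            assert ns.estimate_null_allele_freq(n, x + 1) > q

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ns.estimate_null_allele_freq(0, 0)
        with pytest.raises(ValueError):
            ns.estimate_null_allele_freq(5, 6)

    def test_posterior_variance_positive(self):
        m, v = ns.null_allele_posterior_moments(18, 9)
        assert v > 0
        assert m == pytest.approx(ns.estimate_null_allele_freq(18, 9))


class TestFst:
    def test_two_site_hand_example(self):
        # q = 0.2 and 0.8 known exactly: G_ST = (0.5 - 0.32)/0.5 = 0.36
        q = np.array([[0.2], [0.8]])
        fst, he = fst_from_frequencies(q)
        assert fst[0] == pytest.approx(0.36, abs=1e-12)
        assert he[0] == pytest.approx(0.5, abs=1e-12)

    def test_identical_frequencies_zero(self):
        q = np.full((5, 3), 0.4)
        fst, _ = fst_from_frequencies(q)
        assert np.allclose(fst, 0.0)

    def test_monomorphic_locus_is_nan(self):
        q = np.zeros((3, 1))
        fst, _ = fst_from_frequencies(q)
        assert np.isnan(fst[0])

    def test_trimming_rule_hand_arithmetic(self):
        # symmetric 30% trim on 10 values keeps the middle four
        vals = [0.00, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.30, 0.50]
        assert stats.trim_mean(vals, 0.30) == pytest.approx(0.045)

    def test_global_is_trimmed_mean_of_per_locus(self, tiny_matrix):
        matrix, _, _ = tiny_matrix
        res = ns.fst_per_locus(matrix)
        vals = res.per_locus_fst[~np.isnan(res.per_locus_fst)]
        assert res.global_fst == pytest.approx(
            stats.trim_mean(vals, res.trim_fraction))
        assert res.global_fst_untrimmed == pytest.approx(vals.mean())

    def test_per_locus_range(self, tiny_matrix):
        matrix, _, _ = tiny_matrix
        res = ns.fst_per_locus(matrix)
        ok = res.per_locus_fst[~np.isnan(res.per_locus_fst)]
        assert np.all((ok >= 0) & (ok <= 1))


class TestPairwiseFst:
    def test_identical_sites_zero(self):
        bands = np.tile([1, 1, 0, 1, 0, 1], (12, 1)).astype(np.int8)
        m = ns.MarkerMatrix(bands, [f"i{k}" for k in range(12)],
                            np.array(["a"] * 6 + ["b"] * 6),
                            [f"L{j}" for j in range(6)])
        d = ns.pairwise_fst(m)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_shape_and_symmetry(self, tiny_matrix):
        matrix, _, _ = tiny_matrix
        d = ns.pairwise_fst(matrix)
        n = len(d.ids)
        assert d.values.shape == (n, n)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_low_count_site_dropped(self, tiny_matrix):
        matrix, _, _ = tiny_matrix
        # fabricate a 2-individual site by truncation
        keep = np.ones(matrix.n_individuals, dtype=bool)
        first_site = matrix.sites[0]
        idx = np.where(matrix.site_ids == first_site)[0]
        keep[idx[2:]] = False
        m2 = ns.MarkerMatrix(matrix.bands[keep],
                             [matrix.individual_ids[i] for i in np.where(keep)[0]],
                             matrix.site_ids[keep], matrix.locus_ids)
        with pytest.warns(UserWarning, match="below min_n"):
            d = ns.pairwise_fst(m2, min_n=4)
        assert first_site not in d.ids

    def test_differentiation_ordering(self):
        # higher simulated F_ST yields higher mean pairwise estimates
        rng_seeds = range(6)
        wins = 0
        for s in rng_seeds:
            land = ns.LandscapeSpec(n_sites=10, n_variables=1, seed=s)
            sites = ns.generate_sites(land)
            niche = ns.NicheSpec("sp", "env01", niche_width=5.0, baseline_occupancy=1.0)
            pres = ns.generate_presence(sites, [niche], seed=s)
            means = {}
            for fst_true in (0.02, 0.20):
                model = ns.GenotypeModel(n_loci=80, n_selected=0,
                                         neutral_fst=fst_true,
                                         n_individuals_per_site=15)
                mat, _ = ns.generate_aflp(sites, pres, niche, model,
                                          seed=s + int(fst_true * 1000))
                d = ns.pairwise_fst(mat)
                means[fst_true] = d.condensed().mean()
            wins += means[0.20] > means[0.02]
        assert wins >= 5


class TestDiversity:
    def test_max_heterozygosity_at_half(self):
        # q = 0.5 gives per-locus H = 0.5; engineered via x/n = 0.25
        bands = np.zeros((100, 1), dtype=np.int8)
        bands[:75] = 1  # 25 band-absent of 100 -> q_hat ~ 0.5
        m = ns.MarkerMatrix(bands, [f"i{k}" for k in range(100)],
                            np.array(["a"] * 50 + ["b"] * 50), ["L1"])
        div = ns.diversity_summary(m)
        assert div.h_t == pytest.approx(0.5, abs=0.01)

    def test_monomorphic_band_present_low_h(self):
        # prior keeps q_hat off zero, so H stays small but positive and
        # matches 2*q_hat*(1-q_hat) at the quadrature-checked estimate
        bands = np.ones((100, 1), dtype=np.int8)
        m = ns.MarkerMatrix(bands, [f"i{k}" for k in range(100)],
                            np.array(["a"] * 50 + ["b"] * 50), ["L1"])
        div = ns.diversity_summary(m)
        q = qhat_quadrature(100, 0)
        assert div.h_t == pytest.approx(2 * q * (1 - q), abs=1e-8)
        assert 0 < div.h_t < 0.15
        # shrinks toward zero as the sample grows
        big = ns.MarkerMatrix(np.ones((1000, 1), dtype=np.int8),
                              [f"i{k}" for k in range(1000)],
                              np.array(["a"] * 500 + ["b"] * 500), ["L1"])
        assert ns.diversity_summary(big).h_t < div.h_t

    def test_random_subsets_exchangeable(self, tiny_matrix):
        matrix, _, _ = tiny_matrix
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(50):
            pick = rng.choice(matrix.n_loci, 20, replace=False)
            a = [matrix.locus_ids[i] for i in pick[:10]]
            b = [matrix.locus_ids[i] for i in pick[10:]]
            diffs.append(ns.diversity_summary(matrix, a).h_t
                         - ns.diversity_summary(matrix, b).h_t)
        assert abs(np.mean(diffs)) < 0.02

    def test_empty_subset_rejected(self, tiny_matrix):
        matrix, _, _ = tiny_matrix
        with pytest.raises(ValueError):
            ns.diversity_summary(matrix, [])


class TestReplicateErrorRate:
    def test_study_scale_arithmetic(self):
        # 41 mismatches over 14670 scored fragments -> 0.28%
        a = np.zeros(14670, dtype=int)
        b = a.copy()
        b[:41] = 1
        assert ns.replicate_error_rate([(a, b)]) == pytest.approx(0.2795, abs=1e-4)

    def test_identical_pairs(self):
        a = np.array([0, 1, 1, 0])
        assert ns.replicate_error_rate([(a, a), (a, a)]) == 0.0

    def test_one_in_hundred(self):
        a = np.zeros(100, dtype=int)
        b = a.copy()
        b[0] = 1
        assert ns.replicate_error_rate([(a, b)]) == pytest.approx(1.0)

    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            ns.replicate_error_rate([])
        with pytest.raises(ValueError):
            ns.replicate_error_rate([(np.zeros(3), np.zeros(4))])
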