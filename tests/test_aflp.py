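import numpy as np
import pytest
from scipy import integrate

from refugia import simulate as sim
from refugia.aflp import (
    _bayes_posterior_mean,
    _sqrt_estimate,
    estimate_allele_frequencies,
    nei_gene_diversity,
    percent_polymorphic,
    population_diversity,
    private_bands,
    repeatability,
)
from refugia.datatypes import BinaryMarkerMatrix


def matrix_from(calls, pops):
    calls = np.asarray(calls, dtype=float)
    ids = [f"i{k}" for k in range(calls.shape[0])]
    return BinaryMarkerMatrix(
        ids, [f"L{j + 1}" for j in range(calls.shape[1])], calls,
        dict(zip(ids, pops)))


class TestSqrtEstimator:
    def test_interior_value(self):
        q = _sqrt_estimate(np.array([4.0]), np.array([10.0]))
        assert q[0] == pytest.approx(np.sqrt(0.4))

    def test_zero_class_correction_below_bound(self):
        n = 12.0
        q = _sqrt_estimate(np.array([0.0]), np.array([n]))
        assert 0 < q[0] < np.sqrt(1 / (2 * n))


class TestBayesEstimator:
    def test_matches_quadrature_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = int(rng.integers(0, n + 1))
            a, b = rng.uniform(0.3, 4.0, size=2)

            def integrand(q, pw=0):
                return (q ** (a - 1 + pw) * (1 - q) ** (b - 1)
                        * (q**2) ** x * (1 - q**2) ** (n - x))

            num, _ = integrate.quad(integrand, 0, 1, args=(1,), limit=200)
            den, _ = integrate.quad(integrand, 0, 1, limit=200)
            got = _bayes_posterior_mean(np.array([float(x)]), np.array([float(n)]),
                                        a, b)[0]
            assert got == pytest.approx(num / den, abs=1e-6)

    def test_shrinks_toward_prior_relative_to_sqrt(self, rng):
        # with a common prior fitted across loci, small-sample estimates
        # move toward the prior mean
        env = sim.simulate_env(sim.EnvSimConfig(n_populations=4), rng)
        markers, _ = sim.simulate_aflp(
            sim.AflpSimConfig(n_populations=4, n_per_population=8, n_loci=150),
            env, rng)
        bayes = estimate_allele_frequencies(markers, method="bayes")
        sqrt = estimate_allele_frequencies(markers, method="sqrt")
        for pi, pop in enumerate(bayes.populations):
            prior_a, prior_b = bayes.prior_params[pop]
            prior_mean = prior_a / (prior_a + prior_b)
            d_bayes = np.nanmean(np.abs(bayes.q_hat[pi] - prior_mean))
            d_sqrt = np.nanmean(np.abs(sqrt.q_hat[pi] - prior_mean))
            assert d_bayes < d_sqrt


class TestDiversity:
    def test_maximal_at_even_frequencies(self):
        est = estimate_allele_frequencies(
            matrix_from([[1, 1], [1, 1], [0, 0], [0, 0]], ["p1"] * 4),
            method="sqrt")
        # absence fraction 0.5 -> q = sqrt(0.5), h = 2pq ~ 0.414
        h = nei_gene_diversity(est)
        q = np.sqrt(0.5)
        assert h.H_E[0] == pytest.approx(2 * q * (1 - q))

    def test_monomorphic_loci_zero(self):
        m = matrix_from([[0, 0], [0, 0], [0, 0]], ["p1"] * 3)
        est = estimate_allele_frequencies(m, method="sqrt",
                                          drop_empty_loci=False)
        h = nei_gene_diversity(est)
        assert h.H_E[0] == pytest.approx(0.0)

    def test_matches_per_locus_recount(self, markers_small):
        est = estimate_allele_frequencies(markers_small, method="sqrt")
        h = nei_gene_diversity(est)
        brute = np.nanmean(2 * est.q_hat * (1 - est.q_hat), axis=1)
        np.testing.assert_allclose(h.H_E, brute)

    def test_percent_polymorphic_arithmetic(self):
        q = np.array([[0.5, 0.99, 0.5, 0.5, 0.5, 0.99, 0.99, 0.99, 0.99, 0.99]])
        est = type("E", (), {})()
        from refugia.aflp import AlleleFreqEstimate
        est = AlleleFreqEstimate(
            populations=["p1"], locus_ids=[f"L{i}" for i in range(10)],
            q_hat=q, band_freq=1 - q, n_scored=np.full((1, 10), 10))
        assert percent_polymorphic(est)[0] == pytest.approx(40.0)


class TestPrivateBands:
    def test_partial_and_fixed_private(self):
        calls = [
            [1, 1], [1, 1], [0, 1], [0, 1], [0, 1],   # pop A
            [0, 0], [0, 0], [0, 0], [0, 0], [0, 0],   # pop B
        ]
        m = matrix_from(calls, ["A"] * 5 + ["B"] * 5)
        res = private_bands(m)
        # L1: band in 2/5 of A only -> private, not fixed
        # L2: band in all of A only -> private and fixed
        assert res.loc["A", "N_p"] == 2
        assert res.loc["A", "N_fp"] == 1
        assert res.loc["B", "N_p"] == 0

    def test_matches_bruteforce_scan(self, markers_small):
        res = private_bands(markers_small)
        pops = markers_small.populations
        ix = markers_small.population_indices()
        brute_np = dict.fromkeys(pops, 0)
        brute_fp = dict.fromkeys(pops, 0)
        for j in range(markers_small.n_loci):
            present = [p for p in pops
                       if np.nansum(markers_small.calls[ix[p], j]) > 0]
            if len(present) == 1:
                p = present[0]
                brute_np[p] += 1
                vals = markers_small.calls[ix[p], j]
                vals = vals[~np.isnan(vals)]
                if len(vals) and (vals == 1).all():
                    brute_fp[p] += 1
        for p in pops:
            assert res.loc[p, "N_p"] == brute_np[p]
            assert res.loc[p, "N_fp"] == brute_fp[p]


class TestRepeatability:
    def test_identical_profiles(self):
        a = np.array([0, 1, 1, 0])
        assert repeatability([(a, a.copy())]) == 100.0

    def test_five_mismatches_in_hundred(self):
        a = np.zeros(100)
        b = a.copy()
        b[:5] = 1
        assert repeatability([(a, b)]) == 95.0

    def test_pooled_equals_weighted_mean(self):
        a1, b1 = np.zeros(50), np.zeros(50)
        b1[:10] = 1                       # pair 1: 80%
        a2, b2 = np.ones(100), np.ones(100)
        b2[:5] = 0                        # pair 2: 95%
        pooled = repeatability([(a1, b1), (a2, b2)])
        assert pooled == pytest.approx((40 + 95) / 150 * 100)

    def test_mismatched_locus_sets_rejected(self):
        with pytest.raises(ValueError):
            repeatability([(np.zeros(5), np.zeros(6))])


def test_population_diversity_table_shape(markers_small):
    table = population_diversity(markers_small)
    assert list(table.columns) == ["N", "percent_polymorphic", "N_p", "N_fp",
                                   "H_E", "SE_H_E"]
    assert (table["N"] == 15).all()
    assert ((table["H_E"] >= 0) & (table["H_E"] <= 0.5)).all()
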