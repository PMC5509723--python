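import math

import numpy as np
import pytest

from refugia import demography as dm
from refugia import simulate as sim
from refugia.seq_diversity import MismatchSpectrum


def tajima_oracle(n, S, k_bar):
    """Independent evaluation of the normalizing coefficients."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (k_bar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_matches_independent_coefficients(self):
        for n, S, k in [(4, 2, 1.0), (10, 7, 2.3), (25, 30, 9.1)]:
            assert dm.tajimas_d(n, S, k) == pytest.approx(tajima_oracle(n, S, k))

    def test_small_sample_example(self):
        assert dm.tajimas_d(4, 2, 1.0) == pytest.approx(-0.710, abs=5e-4)

    def test_zero_when_estimators_agree(self):
        a1 = sum(1.0 / i for i in range(1, 10))
        assert dm.tajimas_d(10, 5, 5 / a1) == pytest.approx(0.0)

    def test_undefined_without_segregating_sites(self):
        with pytest.raises(ValueError):
            dm.tajimas_d(10, 0, 0.0)


def ewens_pmf_oracle(n, theta):
    """Ewens P(K=k) via the explicit Stirling recursion on exact ints."""
    rows = [[1]]
    for m in range(1, n + 1):
        prev = rows[-1]
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = (prev[k - 1] if k - 1 < len(prev) else 0) + \
                (m - 1) * (prev[k] if k < len(prev) else 0)
        rows.append(row)
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    return [rows[n][k] * theta**k / rising for k in range(n + 1)]


class TestFusFs:
    def test_closed_form_n2(self):
        assert dm.fus_fs(2, 2, 1.0) == pytest.approx(0.0)
        assert dm.fus_fs(2, 2, math.e) == pytest.approx(1.0)

    def test_matches_exhaustive_ewens(self):
        pmf = ewens_pmf_oracle(5, 0.8)
        sp = sum(pmf[3:])
        expected = math.log(sp / (1 - sp))
        assert dm.fus_fs(5, 3, 0.8) == pytest.approx(expected, abs=1e-12)

    def test_ewens_probabilities_small_n_high_precision(self):
        for n in range(2, 9):
            for theta in (0.3, 1.0, 2.7):
                ours = np.exp(dm.ewens_log_pmf(n, theta))
                oracle = ewens_pmf_oracle(n, theta)
                assert np.max(np.abs(ours - oracle)) < 1e-10

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            dm.fus_fs(5, 6, 1.0)


class TestR2:
    def test_hand_evaluated_example(self):
        r2 = dm.r2_statistic(np.array([0, 0, 0, 2]), 1.0, 2, 4)
        assert r2 == pytest.approx(math.sqrt(0.75) / 2)

    def test_zero_when_singletons_match_half_kbar(self):
        assert dm.r2_statistic(np.full(6, 1.5), 3.0, 4, 6) == 0.0

    def test_inverse_scaling_in_s(self):
        U = np.array([0, 1, 0, 3])
        one = dm.r2_statistic(U, 2.0, 5, 4)
        two = dm.r2_statistic(U, 2.0, 10, 4)
        assert two == pytest.approx(one / 2)


class TestMismatchModels:
    def test_sudden_model_tau_zero_is_stationary(self):
        j = np.arange(11)
        got = dm.expected_mismatch_sudden(0.0, 0.7, 30.0, 10)
        want = dm.stationary_mismatch(0.7, j)
        np.testing.assert_allclose(got, want / want.sum(), rtol=1e-10)

    def test_spatial_model_tau_zero_is_stationary(self):
        j = np.arange(11)
        got = dm.expected_mismatch_spatial(0.0, 2.0, 5.0, 10)
        want = dm.stationary_mismatch(2.0, j)
        np.testing.assert_allclose(got, want / want.sum(), rtol=1e-8)

    def test_self_fit_has_zero_ssd(self):
        probs = dm.expected_mismatch_sudden(2.0, 0.5, 50.0, 15)
        fit = dm.fit_mismatch_expansion(MismatchSpectrum(counts=probs * 4950))
        assert fit.SSD < 1e-10

    def test_flat_spectrum_raggedness_zero(self):
        assert dm.raggedness(np.array([0.25, 0.25, 0.25, 0.25])) == 0.0

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError):
            dm.fit_mismatch_expansion(MismatchSpectrum(counts=np.array([10.0])))

    def test_spatial_fit_runs(self, rng):
        sets, lens = sim.sim_tree(30, rng, (0.1, 50.0))
        muts = sim.drop_mutations_theta(sets, lens, 20.0, rng)
        spec = MismatchSpectrum(counts=sim.mismatch_counts_from_mutations(muts, 30))
        fit = dm.fit_mismatch_expansion(spec, model="spatial")
        assert fit.SSD >= 0 and fit.M is not None


class TestKsTest:
    def test_zero_distance_when_identical(self):
        probs = dm.expected_mismatch_sudden(1.5, 0.3, 20.0, 12)
        spec = MismatchSpectrum(counts=probs * 1000)
        fit = dm.fit_mismatch_expansion(spec)
        d, _ = dm.mismatch_ks_test(spec, fit)
        assert d < 1e-6

    def test_distance_matches_bruteforce_cdf_scan(self, rng):
        sets, lens = sim.sim_tree(12, rng)
        muts = sim.drop_mutations_theta(sets, lens, 4.0, rng)
        spec = MismatchSpectrum(counts=sim.mismatch_counts_from_mutations(muts, 12))
        fit = dm.fit_mismatch_expansion(spec)
        d, _ = dm.mismatch_ks_test(spec, fit)
        brute = max(
            abs(spec.frequencies[: k + 1].sum() - fit.expected[: k + 1].sum())
            for k in range(len(spec.frequencies))
        )
        assert d == pytest.approx(brute)

    def test_bootstrap_p_in_range(self, rng):
        sets, lens = sim.sim_tree(15, rng, (0.05, 80.0))
        muts = sim.drop_mutations_theta(sets, lens, 15.0, rng)
        spec = MismatchSpectrum(counts=sim.mismatch_counts_from_mutations(muts, 15))
        fit = dm.fit_mismatch_expansion(spec, bootstrap_B=30, rng=rng)
        assert 0 < fit.p_SSD <= 1 and 0 < fit.p_rg <= 1


class TestDating:
    def test_zero_tau_gives_zero_time(self):
        assert dm.date_expansion(0.0, 1e-8, 2.0, 1000).t_generations == 0.0

    def test_linear_in_tau_inverse_in_mu_and_k(self, rng):
        for _ in range(10):
            tau = float(rng.uniform(0.1, 5))
            mu = float(rng.uniform(1e-9, 1e-7))
            g = float(rng.uniform(1, 20))
            k = int(rng.integers(100, 5000))
            base = dm.date_expansion(tau, mu, g, k).t_generations
            assert dm.date_expansion(2 * tau, mu, g, k).t_generations == \
                pytest.approx(2 * base)
            assert dm.date_expansion(tau, 2 * mu, g, k).t_generations == \
                pytest.approx(base / 2)
            assert dm.date_expansion(tau, mu, g, 2 * k).t_generations == \
                pytest.approx(base / 2)

    def test_years_equals_generations_times_generation_time(self):
        d = dm.date_expansion(1.5, 1e-8, 3.0, 1200)
        assert d.t_years == pytest.approx(d.t_generations * 3.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dm.date_expansion(1.0, 0.0, 2.0, 100)


class TestNullPvalues:
    def test_observed_median_gives_half_p(self, rng):
        cfg = dm.CoalescentNullConfig(replicates=400, pool_size=1500)
        table = dm.null_statistic_table(20, cfg, S=10, rng=rng)
        med = np.median(table[:, 0])
        p = (np.sum(table[:, 0] <= med) + 1) / (len(table) + 1)
        assert 0.4 < p < 0.6

    def test_expansion_data_gives_small_p(self, rng):
        # strong expansion: D should be clearly negative vs the null
        hits = 0
        for _ in range(10):
            sets, lens = sim.sim_tree(50, rng, (2.0 / 50.0, 100.0))
            muts = sim.drop_mutations_theta(sets, lens, 50.0, rng)
            s = sim.summarize_mutations(muts, 50)
            res = dm.neutrality_tests(
                50, s.S, s.k_bar, s.n_haplotypes, s.singletons,
                dm.CoalescentNullConfig(replicates=200, pool_size=1000), rng)
            hits += res.p_D < 0.05
        assert hits >= 8

    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError):
            dm.CoalescentNullConfig(replicates=50)
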