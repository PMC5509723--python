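import numpy as np
import pandas as pd
import pytest

from refugia import simulate as sim
from refugia.aflp import estimate_allele_frequencies
from refugia.datatypes import AlignedSequenceSet, BinaryMarkerMatrix
from refugia.differentiation import (
    PairwiseFstMatrix,
    _amova_from_d2,
    amova_phist,
    dapc_axes,
    find_clusters,
    mean_population_fst,
    multilocus_fst,
    pairwise_fst_dominant,
    pairwise_phist_sequences,
)


class TestDominantFst:
    def test_identical_frequencies_zero(self):
        q = np.tile(np.linspace(0.2, 0.8, 20), (2, 1))
        v = np.zeros_like(q)
        m = np.full_like(q, 1e5)
        assert multilocus_fst(q, v, m) == pytest.approx(0.0, abs=1e-9)

    def test_near_fixed_differences_high(self):
        q = np.vstack([np.full(100, 0.02), np.full(100, 0.98)])
        v = (1 - q**2) / (4 * 200)
        m = np.full_like(q, 200.0)
        assert multilocus_fst(q, v, m) > 0.9

    def test_population_order_invariance(self, markers_small):
        freqs = estimate_allele_frequencies(markers_small, method="sqrt")
        mat = pairwise_fst_dominant(freqs).matrix
        perm = list(mat.index)[::-1]
        mat2 = mat.loc[perm, perm]
        np.testing.assert_allclose(mat.to_numpy(),
                                   mat2.loc[mat.index, mat.columns].to_numpy())

    def test_estimator_recovers_target(self, env8, rng):
        vals = []
        for _ in range(10):
            markers, _ = sim.simulate_aflp(
                sim.AflpSimConfig(background_fst=0.15), env8, rng)
            freqs = estimate_allele_frequencies(markers, method="sqrt")
            from refugia.differentiation import lynch_milligan_mask
            mask = lynch_milligan_mask(freqs.band_freq, freqs.n_scored)
            vals.append(multilocus_fst(freqs.q_hat, freqs.sampling_variance(),
                                       freqs.n_scored, mask))
        assert np.mean(vals) == pytest.approx(0.15, abs=0.02)


class TestRefugiumScore:
    def test_arithmetic_example(self):
        m = pd.DataFrame([[0, .1, .3], [.1, 0, .2], [.3, .2, 0]],
                         index=list("abc"), columns=list("abc"))
        score = mean_population_fst(PairwiseFstMatrix(matrix=m, source="dominant"))
        np.testing.assert_allclose(score.scores.to_numpy(), [0.2, 0.15, 0.25])
        assert score.candidate == "c" and not score.tied

    def test_tie_flagged(self):
        m = pd.DataFrame([[0, .2, .2], [.2, 0, .2], [.2, .2, 0]],
                         index=list("abc"), columns=list("abc"))
        score = mean_population_fst(PairwiseFstMatrix(matrix=m, source="dominant"))
        assert score.tied and score.candidate is None

    def test_mean_identity_on_random_matrices(self, rng):
        for _ in range(5):
            r = int(rng.integers(3, 8))
            a = rng.uniform(0, 0.5, size=(r, r))
            m = (a + a.T) / 2
            np.fill_diagonal(m, 0)
            df = pd.DataFrame(m)
            score = mean_population_fst(
                PairwiseFstMatrix(matrix=df, source="dominant"))
            off_diag_mean = m.sum() / (r * (r - 1))
            assert score.scores.mean() == pytest.approx(off_diag_mean)


class TestAmova:
    def test_perfect_separation_phi_one(self):
        calls = np.vstack([np.zeros((6, 20)), np.ones((6, 20))])
        ids = [f"i{k}" for k in range(12)]
        m = BinaryMarkerMatrix(ids, [f"L{j}" for j in range(20)], calls,
                               {i: ("A" if int(i[1:]) < 6 else "B") for i in ids})
        res = amova_phist(m, n_permutations=99,
                          rng=np.random.default_rng(0))
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_components_match_hand_decomposition(self):
        # 6 individuals, 2 groups; squared Euclidean on scalar profiles
        x = np.array([0.0, 1.0, 0.0, 3.0, 4.0, 3.0])[:, None]
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        d2 = (x - x.T) ** 2
        sig_a, sig_w, phi = _amova_from_d2(d2, labels)
        # hand computation: SS_total = sum (x - grand)^2; SS_within per group
        ss_tot = ((x - x.mean()) ** 2).sum()
        ss_w = sum(((x[labels == g] - x[labels == g].mean()) ** 2).sum()
                   for g in "ab")
        ms_w = ss_w / 4
        ms_a = (ss_tot - ss_w) / 1
        n_c = (6 - (9 + 9) / 6) / 1
        exp_sig_a = (ms_a - ms_w) / n_c
        assert sig_w == pytest.approx(ms_w)
        assert sig_a == pytest.approx(exp_sig_a)
        assert phi == pytest.approx(exp_sig_a / (exp_sig_a + ms_w))

    def test_shuffled_labels_phi_near_zero(self, markers_small, rng):
        labels = rng.permutation(
            [markers_small.population_of[i] for i in markers_small.individual_ids])
        res = amova_phist(markers_small, labels=labels, n_permutations=99,
                          rng=rng)
        assert abs(res.phi_st) < 0.05

    def test_refuses_too_few_permutations(self, markers_small):
        with pytest.raises(ValueError):
            amova_phist(markers_small, n_permutations=5)

    def test_sequence_pairwise_matches_two_pop_amova(self, rng):
        aln = sim.simulate_coalescent_alignment(
            sim.CoalescentConfig(n=12, theta=5.0, sites=200), rng)
        pops = {sid: ("A" if i < 6 else "B")
                for i, sid in enumerate(aln.sample_ids)}
        aln2 = AlignedSequenceSet(aln.sample_ids, aln.sequences, pops)
        mat = pairwise_phist_sequences(aln2).matrix
        res = amova_phist(aln2, n_permutations=0)
        assert mat.loc["A", "B"] == pytest.approx(res.phi_st)


class TestDapc:
    def test_two_blobs_recovered(self, rng):
        env = sim.simulate_env(sim.EnvSimConfig(n_populations=2), rng)
        markers, _ = sim.simulate_aflp(
            sim.AflpSimConfig(n_populations=2, n_per_population=30,
                              n_loci=200, background_fst=0.5), env, rng)
        res = find_clusters(markers, K_range=range(1, 5), seed=0)
        assert res.best_K == 2
        truth = np.array([0] * 30 + [1] * 30)
        acc = max((res.assignments == truth).mean(),
                  (res.assignments == 1 - truth).mean())
        assert acc >= 0.95

    def test_duplicated_rows_same_assignment(self, markers_small):
        calls = np.vstack([markers_small.calls, markers_small.calls[:1]])
        ids = markers_small.individual_ids + ["dup"]
        popmap = dict(markers_small.population_of)
        popmap["dup"] = popmap[markers_small.individual_ids[0]]
        m = BinaryMarkerMatrix(ids, markers_small.locus_ids, calls, popmap)
        res = find_clusters(m, K_range=range(1, 5), seed=0)
        assert res.assignments[0] == res.assignments[-1]

    def test_k_max_bound(self, markers_small):
        with pytest.raises(ValueError):
            find_clusters(markers_small, K_range=range(1, 400))

    def test_axes_separate_clusters_and_fractions_sum(self, rng):
        env = sim.simulate_env(sim.EnvSimConfig(n_populations=3), rng)
        markers, _ = sim.simulate_aflp(
            sim.AflpSimConfig(n_populations=3, n_per_population=20,
                              n_loci=150, background_fst=0.5), env, rng)
        truth = np.repeat([0, 1, 2], 20)
        res = dapc_axes(markers, truth)
        assert res.ld_var_fractions.sum() == pytest.approx(1.0)
        ld1 = res.ld_coords[:, 0]
        # group means on LD1 should be well separated relative to spread
        means = [ld1[truth == g].mean() for g in range(3)]
        within = max(ld1[truth == g].std() for g in range(3))
        assert (max(means) - min(means)) > 3 * within

    def test_small_cluster_rejected(self, markers_small):
        labels = np.zeros(markers_small.n_individuals, dtype=int)
        labels[0] = 1
        with pytest.raises(ValueError):
            dapc_axes(markers_small, labels)
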