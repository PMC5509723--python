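import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from conftest import plant_high_fst_locus
from refugia import simulate as sim
from refugia.datatypes import BinaryMarkerMatrix
from refugia.selection_scan import (
    FdistConfig,
    McmcConfig,
    adaptive_call_table,
    bayescan_lite,
    benjamini_hochberg,
    call_adaptive_loci,
    fdist_scan,
    trimmed_mean_fst,
)


def test_benjamini_hochberg_matches_statsmodels(rng):
    p = rng.uniform(size=50)
    p[:5] = rng.uniform(0, 1e-3, size=5)
    ours = benjamini_hochberg(p)
    _, sm_q, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(ours, sm_q)


def test_trimmed_mean_drops_both_tails():
    f = np.concatenate([np.full(30, 0.15), [0.9] * 3, [0.0] * 3])
    assert trimmed_mean_fst(f, 0.30) == pytest.approx(0.15)


class TestFdist:
    def test_monomorphic_never_flagged(self, env8, rng):
        markers, _ = sim.simulate_aflp(
            sim.AflpSimConfig(n_loci=80), env8, rng)
        calls = markers.calls.copy()
        calls[:, 0] = 1.0  # monomorphic presence
        m = BinaryMarkerMatrix(markers.individual_ids, markers.locus_ids,
                               calls, markers.population_of)
        scan, _ = fdist_scan(
            m, FdistConfig(n_sim_loci=3000, n_calib_loci=1500), rng)
        assert not scan.loc["L1", "outlier_fdist"]
        assert not scan.loc["L1", "polymorphic"]

    def test_envelope_quantiles_monotone(self, env8, rng):
        markers, _ = sim.simulate_aflp(sim.AflpSimConfig(n_loci=150), env8, rng)
        _, env = fdist_scan(
            markers, FdistConfig(n_sim_loci=8000, n_calib_loci=2000), rng)
        bins = np.digitize(env.het, env.bin_edges) - 1
        for b in np.unique(bins):
            cloud = env.fst[bins == b]
            if len(cloud) < 50:
                continue
            qs = np.quantile(cloud, [0.5, 0.75, 0.9, 0.95, 0.99])
            assert np.all(np.diff(qs) >= 0)

    def test_planted_locus_detected_at_95_level(self, env8, rng):
        hits = 0
        runs = 8
        for _ in range(runs):
            markers, _ = sim.simulate_aflp(
                sim.AflpSimConfig(background_fst=0.15), env8, rng)
            planted = plant_high_fst_locus(markers, rng, fst=0.6)
            scan, _ = fdist_scan(
                planted, FdistConfig(n_sim_loci=30000, n_calib_loci=3000), rng)
            hits += bool(scan.loc["L1", "outlier_95"])
        assert hits >= 6


class TestBayescanLite:
    def test_prior_recovered_without_data(self):
        ids = [f"i{k}" for k in range(16)]
        calls = np.full((16, 12), np.nan)
        popmap = {i: f"p{int(i[1:]) // 4}" for i in ids}
        m = BinaryMarkerMatrix(ids, [f"L{j}" for j in range(12)], calls, popmap)
        res = bayescan_lite(
            m, McmcConfig(burn_in=200, samples=800, seed=1))
        # posterior odds should sit near the 10:1 neutral prior
        assert np.median(res.table["log10_PO"]) == pytest.approx(-1.0, abs=0.35)

    def test_planted_locus_strong_evidence(self, env8, rng):
        markers, _ = sim.simulate_aflp(
            sim.AflpSimConfig(n_loci=80, background_fst=0.15), env8, rng)
        calls = markers.calls.copy()
        # extreme differentiation: band frequency alternates 0.95 / 0.05
        # between populations (informative on both phenotype classes)
        band = np.tile([0.95, 0.05], 4)
        calls[:, 0] = np.concatenate([
            (rng.random(15) < band[j]).astype(float) for j in range(8)])
        planted = BinaryMarkerMatrix(markers.individual_ids, markers.locus_ids,
                                     calls, markers.population_of)
        res = bayescan_lite(planted, McmcConfig(burn_in=500, samples=2000), rng)
        assert res.table.loc["L1", "log10_PO"] > 1.5
        others = res.table.drop("L1")
        assert (others["log10_PO"] > 1.5).mean() <= 0.05


class TestAdaptiveCalls:
    def flags(self):
        loci = ["P1_17", "P1_19", "P2_15", "P3_23", "P3_24", "P4_35",
                "P6_12", "P6_17", "P6_25", "P6_30", "P12_29", "P12_49"]
        fdist = pd.Series(
            [True, False, False, True, True, False, True, True, False,
             False, False, True], index=loci)
        bayes = pd.Series(
            [False, False, False, True, True, False, True, True, True,
             False, False, False], index=loci)
        assoc = pd.DataFrame([
            ("P1_17", "TMI", True), ("P1_17", "wet_days", True),
            ("P1_19", "BIO1", True), ("P2_15", "TMI", True),
            ("P2_15", "wet_days", True), ("P3_23", "NDVI", True),
            ("P3_24", "BIO12", True), ("P3_24", "NDVI", True),
            ("P4_35", "soil_pH", True), ("P6_12", "BIO1", True),
            ("P6_30", "WS_mean", True), ("P12_29", "BIO1", True),
            ("P6_17", "BIO1", False), ("P6_25", "BIO1", False),
            ("P12_49", "BIO1", False),
        ], columns=["locus", "variable", "significant"])
        return fdist, bayes, assoc

    def test_published_flag_pattern_yields_four_adaptive_loci(self):
        calls = call_adaptive_loci(*self.flags())
        adaptive = {c.locus for c in calls if c.adaptive}
        assert adaptive == {"P1_17", "P3_23", "P3_24", "P6_12"}

    def test_outlier_without_association_not_adaptive(self):
        calls = {c.locus: c for c in call_adaptive_loci(*self.flags())}
        assert calls["P6_17"].fdist_outlier and not calls["P6_17"].adaptive

    def test_empty_flags_empty_calls(self):
        fdist, bayes, assoc = self.flags()
        none = pd.Series(False, index=fdist.index)
        assoc = assoc.assign(significant=False)
        calls = call_adaptive_loci(none, none.copy(), assoc)
        assert not any(c.adaptive for c in calls)

    def test_monotone_in_flags(self):
        fdist, bayes, assoc = self.flags()
        base = {c.locus for c in call_adaptive_loci(fdist, bayes, assoc)
                if c.adaptive}
        more = fdist.copy()
        more["P2_15"] = True
        bigger = {c.locus for c in call_adaptive_loci(more, bayes, assoc)
                  if c.adaptive}
        assert base <= bigger

    def test_locus_set_mismatch_rejected(self):
        fdist, bayes, assoc = self.flags()
        with pytest.raises(ValueError):
            call_adaptive_loci(fdist.iloc[:5], bayes, assoc)

    def test_table_export(self):
        table = adaptive_call_table(call_adaptive_loci(*self.flags()))
        assert table.loc["P1_17", "adaptive"]
        assert table.loc["P1_17", "associated_variables"] == "TMI;wet_days"
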