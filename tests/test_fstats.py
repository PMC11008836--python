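"""Weir-Cockerham estimators against an independent ANOVA oracle, and the
randomization machinery built on them."""

import itertools

import numpy as np
import pandas as pd
import pytest

from msatqc import (
    SimulationConfig,
    bootstrap_ci,
    combine_p_generalized_binomial,
    fis_permutation_test,
    gtest_subdivision,
    inject_artifacts,
    jackknife_se,
    sex_linkage_screen,
    simulate_dataset,
    wc_fstats,
)
from msatqc.fstats import _locus_components, two_sided_from_one_sided

from conftest import anova_components, make_dataset


class TestWcEstimators:
    def test_matches_anova_oracle_exhaustive_tiny(self):
        # all 2-allele genotype assignments for 2 pops x 3 individuals
        genos = [(100, 100), (100, 102), (102, 102)]
        codes = np.repeat([0, 1], 3)
        checked = 0
        for combo in itertools.product(range(3), repeat=6):
            pair = np.array([genos[i] for i in combo])
            res = _locus_components(pair, codes)
            oracle = anova_components(pair, codes)
            if oracle is None:
                assert res[0].size == 0
                continue
            a, b, c = res[1].sum(), res[2].sum(), res[3].sum()
            assert np.allclose((a, b, c), oracle, atol=1e-12)
            checked += 1
        assert checked > 500

    def test_matches_anova_oracle_random_multiallelic(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            npop = rng.integers(2, 5)
            n = rng.integers(3, 9)
            codes = np.repeat(np.arange(npop), n)
            pair = rng.choice([100, 102, 104, 106], size=(npop * n, 2))
            res = _locus_components(pair, codes)
            oracle = anova_components(pair, codes)
            if oracle is None:
                continue
            assert np.allclose(
                (res[1].sum(), res[2].sum(), res[3].sum()), oracle, atol=1e-10
            )

    def test_hand_computed_single_population_fis(self, hw_single_pop):
        # 4 AA / 2 AB / 4 BB: p = 0.5, Ho = 0.2, n = 10
        # b = (10/9)(0.25 - (19/40) 0.2) per allele, c = 0.1
        # F_IS = 1 - 0.2/(2*(0.1722... + 0.1)/2 ... ) = 31/49
        res = wc_fstats(hw_single_pop)
        assert res.per_locus["fis"].iloc[0] == pytest.approx(31 / 49, abs=1e-12)
        assert np.isnan(res.multilocus["fst"])  # one population

    def test_complete_differentiation(self, two_pop_fixed):
        assert wc_fstats(two_pop_fixed).multilocus["fst"] == pytest.approx(1.0)

    def test_monomorphic_locus_undefined(self):
        pairs = np.array([[[100, 100], [200, 202]]] * 6)
        ds = make_dataset(pairs, populations=["a"] * 3 + ["b"] * 3)
        res = wc_fstats(ds)
        assert not res.per_locus["defined"].iloc[0]
        assert np.isnan(res.per_locus["fis"].iloc[0])
        assert res.per_locus["defined"].iloc[1]

    def test_multilocus_is_ratio_of_sums(self):
        cfg = SimulationConfig(n_pops=3, n_per_pop=30, n_loci=5, seed=4)
        ds, _ = simulate_dataset(cfg)
        res = wc_fstats(ds)
        comp = res.components()
        a, b, c = comp.sum(axis=0)
        assert res.multilocus["fst"] == pytest.approx(a / (a + b + c), rel=1e-12)
        # and differs from the mean of per-locus ratios in general
        assert res.multilocus["fst"] != pytest.approx(
            res.per_locus.loc[res.per_locus["defined"], "fst"].mean(), abs=1e-6
        )


class TestPermutationTests:
    def test_two_sided_doubling_rule(self):
        assert two_sided_from_one_sided(0.2, 0.5) == pytest.approx(0.4)
        assert two_sided_from_one_sided(0.9, -0.5) == pytest.approx(0.2)
        assert two_sided_from_one_sided(0.8, 0.5) == 1.0

    def test_fis_permutation_detects_deficit(self):
        rng = np.random.default_rng(0)
        # strong heterozygote deficit: mostly homozygotes from a diverse pool
        sizes = np.array([100, 102, 104, 106])
        hom = rng.choice(sizes, size=60)
        pair = np.stack([hom, hom], axis=1)
        pair[:6, 1] = np.where(pair[:6, 0] == 100, 102, 100)
        tab = fis_permutation_test(make_dataset(pair), n_perm=300, seed=1)
        assert tab[tab["locus"] == "overall"]["p_one_sided"].iloc[0] < 0.01

    def test_all_heterozygote_locus_excess(self):
        pair = np.array([[100, 102]] * 20)
        tab = fis_permutation_test(make_dataset(pair), n_perm=200, seed=1)
        row = tab[tab["locus"] == "L1"].iloc[0]
        assert row["p_one_sided"] > 0.95  # no deficit at all
        assert row["p_two_sided"] < 0.2  # strong excess two-sided

    def test_invariant_to_allele_relabeling(self):
        cfg = SimulationConfig(n_pops=2, n_per_pop=25, n_loci=3, seed=8)
        ds, _ = simulate_dataset(cfg)
        relab = ds.copy()
        relab.alleles = relab.alleles * 3 + 7  # order-preserving relabel
        t1 = fis_permutation_test(ds, n_perm=100, seed=5)
        t2 = fis_permutation_test(relab, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        g1 = gtest_subdivision(ds, n_perm=100, seed=5)
        g2 = gtest_subdivision(relab, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(g1, g2)

    def test_type_i_error_calibrated(self):
        # panmictic data: rejection rate at alpha = 0.05 within [0.03, 0.07]
        rej_fis = rej_g = 0
        R = 150
        for s in range(R):
            cfg = SimulationConfig(n_pops=3, n_per_pop=24, n_loci=8,
                                   target_fst=0.0, seed=8000 + s)
            ds, _ = simulate_dataset(cfg)
            t = fis_permutation_test(ds, n_perm=200, seed=s)
            rej_fis += t[t["locus"] == "overall"]["p_one_sided"].iloc[0] < 0.05
            g = gtest_subdivision(ds, n_perm=100, seed=s)
            rej_g += g[g["locus"] == "overall"]["p"].iloc[0] < 0.05
        assert 0.02 <= rej_fis / R <= 0.08
        assert 0.02 <= rej_g / R <= 0.09

    def test_gtest_requires_two_populations(self, hw_single_pop):
        with pytest.raises(ValueError):
            gtest_subdivision(hw_single_pop, n_perm=10, seed=0)

    def test_gtest_duplicated_population_is_null(self):
        cfg = SimulationConfig(n_pops=1, n_per_pop=30, n_loci=4, seed=2)
        ds, _ = simulate_dataset(cfg)
        dup = make_dataset(
            np.concatenate([ds.alleles, ds.alleles]),
            populations=["a"] * 30 + ["b"] * 30,
            loci=ds.loci,
        )
        tab = gtest_subdivision(dup, n_perm=100, seed=1)
        row = tab[tab["locus"] == "overall"].iloc[0]
        assert row["g"] == pytest.approx(0.0, abs=1e-9)
        assert row["p"] == 1.0


class TestResampling:
    def test_bootstrap_ci_contains_estimate(self):
        hits = 0
        for s in range(20):
            cfg = SimulationConfig(n_pops=3, n_per_pop=30, n_loci=10,
                                   target_fst=0.05, seed=40 + s)
            ds, _ = simulate_dataset(cfg)
            res = wc_fstats(ds)
            lo, hi = bootstrap_ci(res.components(), "fst", n_boot=500, seed=s)
            hits += lo <= res.multilocus["fst"] <= hi
        assert hits >= 18

    def test_identical_loci_zero_width(self):
        comp = np.tile([[0.1, 0.3, 0.6]], (5, 1))
        lo, hi = bootstrap_ci(comp, "fst", n_boot=200, seed=0)
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(0.1)

    def test_too_few_loci_undefined(self):
        assert np.isnan(bootstrap_ci(np.array([[0.1, 0.3, 0.6]]), "fst")[0])

    def test_jackknife_degenerate_identical_loci(self):
        comp = np.tile([[0.1, 0.3, 0.6]], (5, 1))
        jk = jackknife_se(comp)
        assert jk["se_fis"] == pytest.approx(0.0)
        assert np.isinf(jk["r_ratio"])

    def test_null_alleles_raise_se_ratio(self):
        hits = 0
        for s in range(15):
            cfg = SimulationConfig(n_pops=3, n_per_pop=30, n_loci=10,
                                   target_fst=0.03, null_freq=0.2, seed=200 + s)
            ds, truth = simulate_dataset(cfg)
            ds = inject_artifacts(ds, truth, cfg)
            hits += jackknife_se(ds)["r_ratio"] > 2
        assert hits >= 10  # the classical null-allele signature, most runs


class TestGeneralizedBinomial:
    def test_single_p_returned(self):
        p = combine_p_generalized_binomial([0.3], n_mc=20000, seed=0)
        assert p == pytest.approx(0.3, abs=0.02)

    def test_unanimous_signal(self):
        assert combine_p_generalized_binomial([0.001] * 3, n_mc=20000, seed=0) < 0.01

    def test_uniform_inputs_stay_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        combined = [
            combine_p_generalized_binomial(rng.random(5), n_mc=2000, seed=s)
            for s in range(150)
        ]
        assert stats.kstest(combined, "uniform").pvalue > 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_p_generalized_binomial([])


class TestSexLinkageScreen:
    def test_z_linked_locus_flagged(self):
        cfg = SimulationConfig(n_pops=3, n_per_pop=40, n_loci=6,
                               target_fst=0.03, sex_linked_loci=["L02"], seed=11)
        ds, truth = simulate_dataset(cfg)
        ds = inject_artifacts(ds, truth, cfg)
        rep = sex_linkage_screen(ds, n_perm=300, seed=1)
        tab = rep.fis_by_sex.set_index("locus")
        assert tab.loc["L02", "fis_female"] > tab.loc["L02", "fis_male"] + 0.5
        assert "L02" in rep.flagged

    def test_random_sexes_rarely_flagged(self):
        flags = 0
        for s in range(10):
            cfg = SimulationConfig(n_pops=3, n_per_pop=30, n_loci=6,
                                   target_fst=0.03, seed=700 + s)
            ds, _ = simulate_dataset(cfg)
            rep = sex_linkage_screen(ds, n_perm=200, seed=s)
            flags += len(rep.flagged) > 0
        assert flags <= 2
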