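"""LD permutation tests, SAD and stuttering screens, FDR, outlier rules."""

import numpy as np
import pandas as pd
import pytest

from msatqc import (
    Locus,
    SimulationConfig,
    fdr_adjust,
    inject_artifacts,
    ld_gtest_all_pairs,
    outlier_locus_rules,
    qc_battery,
    sad_test,
    simulate_dataset,
    stuttering_test,
    wc_fstats,
)

from conftest import make_dataset


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.04], "BH")[0] == pytest.approx(0.04)
        assert fdr_adjust([0.04], "BY")[0] == pytest.approx(0.04)  # c(1) = 1

    def test_bh_step_up_hand_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04], "BH")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_by_dominates_bh(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.random(8)
            assert np.all(fdr_adjust(p, "BY") >= fdr_adjust(p, "BH") - 1e-12)

    def test_monotone_in_raw_p(self):
        p = np.array([0.001, 0.5, 0.03, 0.2, 0.9])
        adj = fdr_adjust(p, "BH")
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_input(self):
        assert fdr_adjust([], "BH").size == 0


class TestLd:
    def test_duplicated_locus_detected(self):
        cfg = SimulationConfig(n_pops=3, n_per_pop=24, n_loci=4,
                               target_fst=0.05, seed=7)
        ds, _ = simulate_dataset(cfg)
        alleles = np.concatenate([ds.alleles, ds.alleles[:, [0], :] + 1000], axis=1)
        ds_dup = make_dataset(
            alleles, populations=list(ds.individuals["population"]),
            loci=ds.loci + [Locus("DUP")],
        )
        n_perm = 300
        res = ld_gtest_all_pairs(ds_dup, n_perm=n_perm, seed=1)
        t = res["table"].set_index(["locus1", "locus2"])
        assert t.loc[("L01", "DUP"), "p"] == pytest.approx(1 / (n_perm + 1))

    def test_independent_loci_rarely_significant_after_by(self):
        sig = tot = 0
        for s in range(6):
            cfg = SimulationConfig(n_pops=3, n_per_pop=24, n_loci=6,
                                   target_fst=0.05, seed=60 + s)
            ds, _ = simulate_dataset(cfg)
            res = ld_gtest_all_pairs(ds, n_perm=200, seed=s)
            t = res["table"].dropna(subset=["by_p"])
            sig += (t["by_p"] < 0.05).sum()
            tot += len(t)
        assert sig / tot <= 0.01

    def test_pair_order_invariance(self):
        cfg = SimulationConfig(n_pops=2, n_per_pop=20, n_loci=3, seed=3)
        ds, _ = simulate_dataset(cfg)
        rev = ds.subset_loci(ds.locus_names[::-1])
        r1 = ld_gtest_all_pairs(ds, n_perm=150, seed=9)["table"]
        r2 = ld_gtest_all_pairs(rev, n_perm=150, seed=9)["table"]

        def norm(t):
            return {
                tuple(sorted((a, b))): g
                for a, b, g in zip(t["locus1"], t["locus2"], t["g"])
            }
        assert norm(r1).keys() == norm(r2).keys()
        for k in norm(r1):
            assert norm(r1)[k] == pytest.approx(norm(r2)[k], abs=1e-9)


class TestSad:
    def test_injected_sad_detected(self):
        det = 0
        R = 40
        for s in range(R):
            cfg = SimulationConfig(n_pops=3, n_per_pop=50, n_loci=1,
                                   target_fst=0.02, sad_strength=0.02,
                                   seed=400 + s)
            ds, truth = simulate_dataset(cfg)
            ds = inject_artifacts(ds, truth, cfg)
            r = sad_test(ds, ds.locus_names[0])
            det += r["testable"] and np.isfinite(r["spearman_p"]) and r["spearman_p"] < 0.05
        assert det / R >= 0.5

    def test_too_few_alleles_untestable(self):
        pairs = np.array([[100, 102]] * 10 + [[100, 100]] * 5)
        r = sad_test(make_dataset(pairs), "L1")
        assert not r["testable"]

    def test_clean_locus_not_flagged_often(self):
        hits = 0
        for s in range(20):
            cfg = SimulationConfig(n_pops=3, n_per_pop=50, n_loci=1,
                                   target_fst=0.02, seed=800 + s)
            ds, _ = simulate_dataset(cfg)
            r = sad_test(ds, ds.locus_names[0])
            hits += r["testable"] and np.isfinite(r["spearman_p"]) and r["spearman_p"] < 0.05
        assert hits <= 4


class TestStuttering:
    def test_injected_stuttering_detected(self):
        det = 0
        R = 40
        for s in range(R):
            cfg = SimulationConfig(n_pops=3, n_per_pop=200, n_loci=1,
                                   target_fst=0.02, stutter_rate=0.3,
                                   seed=10_000 + s)
            ds, truth = simulate_dataset(cfg)
            ds = inject_artifacts(ds, truth, cfg)
            r = stuttering_test(ds, ds.locus_names[0], seed=s)
            det += r["testable"] and r["p"] < 0.05
        assert det / R >= 0.5

    def test_no_one_step_pairs_untestable(self):
        # alleles two motif units apart everywhere
        pairs = np.array([[100, 104], [104, 108], [100, 108], [104, 104]] * 5)
        r = stuttering_test(make_dataset(pairs), "L1")
        assert not r["testable"]

    def test_share_bounded_and_conserved(self):
        cfg = SimulationConfig(n_pops=2, n_per_pop=60, n_loci=1, seed=5)
        ds, _ = simulate_dataset(cfg)
        r = stuttering_test(ds, ds.locus_names[0], seed=0)
        for d in r["per_population"]:
            assert 0 < d["expected_share"] < 1
            assert d["observed_onestep"] <= d["observed_het"]


class TestOutlierRules:
    def _fstats(self, fis, fst):
        n = len(fis)
        per_locus = pd.DataFrame(
            {"locus": [f"L{i}" for i in range(n)], "a": 0.1, "b": 0.1, "c": 0.1,
             "fis": fis, "fst": fst, "fit": 0.1, "defined": True}
        )
        from msatqc.fstats import FStatsResult
        return FStatsResult(per_locus, pd.DataFrame(), {}, 3)

    def test_all_inside_ci_nothing_excluded(self):
        f = self._fstats([0.1, 0.12, 0.11], [0.05, 0.06, 0.055])
        out = outlier_locus_rules(f, (0.0, 0.2), (0.04, 0.07))
        assert not out["exclude"].any()

    def test_fst_outlier_needs_corroboration(self):
        f = self._fstats([0.1, 0.1, 0.1], [0.5, 0.05, 0.05])
        out = outlier_locus_rules(f, (0.0, 0.2), (0.04, 0.07)).set_index("locus")
        assert out.loc["L0", "fst_outlier"]
        assert not out.loc["L0", "exclude"]  # no F_IS outlier, no LD

    def test_fst_plus_fis_outlier_excluded(self):
        f = self._fstats([0.9, 0.1, 0.1], [0.5, 0.05, 0.05])
        out = outlier_locus_rules(f, (0.0, 0.2), (0.04, 0.07)).set_index("locus")
        assert out.loc["L0", "exclude"]

    def test_fst_plus_ld_membership_excluded(self):
        f = self._fstats([0.1, 0.1, 0.1], [0.5, 0.05, 0.05])
        ld = pd.DataFrame({"locus1": ["L0"], "locus2": ["L1"], "by_p": [0.001]})
        out = outlier_locus_rules(f, (0.0, 0.2), (0.04, 0.07), ld_table=ld)
        assert out.set_index("locus").loc["L0", "exclude"]


class TestBattery:
    def test_disruptive_locus_flagged(self):
        # one locus at 5x the background differentiation
        hits = 0
        for s in range(10):
            cfg = SimulationConfig(n_pops=3, n_per_pop=40, n_loci=8,
                                   target_fst=0.03, seed=900 + s)
            ds, _ = simulate_dataset(cfg)
            cfg_hi = SimulationConfig(n_pops=3, n_per_pop=40, n_loci=1,
                                      target_fst=0.3, seed=950 + s)
            hi, _ = simulate_dataset(cfg_hi)
            alleles = np.concatenate([ds.alleles, hi.alleles + 2000], axis=1)
            merged = make_dataset(
                alleles, populations=list(ds.individuals["population"]),
                loci=ds.loci + [Locus("HI")],
            )
            res = wc_fstats(merged)
            from msatqc import bootstrap_ci
            fst_ci = bootstrap_ci(res.components(), "fst", n_boot=300, seed=s)
            fis_ci = bootstrap_ci(res.components(), "fis", n_boot=300, seed=s)
            out = outlier_locus_rules(res, fis_ci, fst_ci).set_index("locus")
            hits += bool(out.loc["HI", "fst_outlier"])
        assert hits >= 8

    def test_clean_data_low_false_flag_rate(self):
        flagged = total = 0
        for s in range(6):
            cfg = SimulationConfig(n_pops=3, n_per_pop=24, n_loci=6,
                                   target_fst=0.05, seed=7000 + s)
            ds, _ = simulate_dataset(cfg)
            rep = qc_battery(ds, n_perm=150, n_boot=300, seed=s)
            flags = rep.flags[["sad", "stuttering", "excess_missing"]]
            flagged += int(flags.to_numpy().sum())
            total += flags.size
        assert flagged / total <= 0.05

    def test_excess_missing_flagged(self):
        cfg = SimulationConfig(n_pops=2, n_per_pop=30, n_loci=3, seed=1)
        ds, _ = simulate_dataset(cfg)
        ds.alleles[: int(0.6 * ds.n_individuals), 0, :] = -1
        ds.alleles = ds.alleles  # re-validate not needed; MISSING is -1
        rep = qc_battery(ds, n_perm=100, n_boot=100, seed=0, run_ld=False)
        assert rep.flags.set_index("locus").loc["L01", "excess_missing"]
        assert "L01" in rep.excluded
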