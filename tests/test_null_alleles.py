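"""EM null-frequency estimation, blank consistency, diagnostics, ENA F_ST."""

import numpy as np
import pandas as pd
import pytest

from msatqc import (
    MISSING,
    NULL_CODE,
    SimulationConfig,
    blanks_consistency_test,
    em_null_frequency,
    em_null_table,
    fst_ena,
    inject_artifacts,
    null_diagnostics,
    simulate_dataset,
    wc_fstats,
)
from msatqc.null_alleles import EmResult



def _null_locus(rng, n, q, p_vis=None, sizes=None):
    """Genotypes at a locus segregating a null at frequency q."""
    sizes = sizes if sizes is not None else np.array([100, 102, 104, 106, 108])
    p_vis = p_vis if p_vis is not None else np.full(sizes.size, (1 - q) / sizes.size)
    full = np.append(sizes, NULL_CODE)
    p = np.append(p_vis, q)
    draws = rng.choice(full, size=(n, 2), p=p / p.sum())
    obs = draws.copy()
    is_null = obs == NULL_CODE
    both = is_null.all(axis=1)
    one = is_null.any(axis=1) & ~both
    obs[both] = MISSING
    vis = np.where(obs[one, 0] == NULL_CODE, obs[one, 1], obs[one, 0])
    obs[one, 0] = vis
    obs[one, 1] = vis
    return np.sort(obs, axis=1)


class TestEm:
    def test_clean_locus_near_zero(self):
        rng = np.random.default_rng(0)
        draws = rng.choice([100, 102, 104, 106], size=(300, 2))
        freqs, _ = em_null_frequency(draws, include_blanks=True)
        assert freqs[NULL_CODE] < 0.01

    @pytest.mark.parametrize("q", [0.05, 0.1, 0.2])
    def test_recovery_bias_small_at_n500(self, q):
        rng = np.random.default_rng(17)
        errs = [
            float(em_null_frequency(_null_locus(rng, 500, q))[0][NULL_CODE]) - q
            for _ in range(12)
        ]
        assert np.mean(np.abs(errs)) < 0.03

    def test_truncated_model_without_blanks(self):
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(10):
            obs = _null_locus(rng, 500, 0.2)
            obs = obs[obs[:, 0] != MISSING]  # blanks unavailable
            freqs, _ = em_null_frequency(obs, include_blanks=False)
            errs.append(float(freqs[NULL_CODE]) - 0.2)
        assert np.mean(np.abs(errs)) < 0.05

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            freqs, _ = em_null_frequency(_null_locus(rng, 80, 0.15))
            assert freqs.sum() == pytest.approx(1.0, abs=1e-9)
            assert (freqs >= 0).all()

    def test_loglik_monotone_enforced(self):
        # the EM asserts monotonicity internally on every run; exercise it
        rng = np.random.default_rng(9)
        for _ in range(30):
            em_null_frequency(_null_locus(rng, 60, 0.25))


class TestBlanksConsistency:
    def test_zero_expected_zero_observed(self):
        table = pd.DataFrame(
            [{"locus": "L1", "population": "p", "null_freq": 0.0, "n": 50,
              "observed_blanks": 0, "expected_blanks": 0.0}]
        )
        out = blanks_consistency_test(table)
        assert out["binom_p"].iloc[0] == 1.0

    def test_observed_matching_expected_not_significant(self):
        table = pd.DataFrame(
            [{"locus": "L1", "population": "p", "null_freq": 0.2, "n": 100,
              "observed_blanks": 4, "expected_blanks": 4.0}]
        )
        out = blanks_consistency_test(table)
        assert out["binom_p"].iloc[0] > 0.4

    def test_fewer_blanks_than_nulls_predict_is_significant(self):
        table = pd.DataFrame(
            [{"locus": "L1", "population": "p", "null_freq": 0.3, "n": 200,
              "observed_blanks": 2, "expected_blanks": 18.0}]
        )
        out = blanks_consistency_test(table)
        assert out["binom_p"].iloc[0] < 0.01


class TestDiagnostics:
    def test_constant_fis_undefined(self):
        comp = pd.DataFrame(
            {"locus": [f"L{i + 1:02d}" for i in range(4)], "a": 0.01, "b": 0.2,
             "c": 0.3, "fis": 0.25, "fst": [0.01, 0.02, 0.03, 0.04],
             "fit": 0.3, "defined": True}
        )
        from msatqc.fstats import FStatsResult

        fres = FStatsResult(comp, pd.DataFrame(), {"fis": 0.25}, 2)
        cfg = SimulationConfig(n_pops=2, n_per_pop=10, n_loci=4, seed=0)
        ds, _ = simulate_dataset(cfg)
        diag = null_diagnostics(fres, ds)
        assert np.isnan(diag["spearman_fis_fst"]["rho"])

    def test_null_gradient_produces_positive_correlations(self):
        # loci with increasing null frequency: F_IS and blanks co-vary
        qs = [0.0, 0.05, 0.1, 0.15, 0.2, 0.3]
        cfg = SimulationConfig(
            n_pops=3, n_per_pop=50, n_loci=len(qs), target_fst=0.02,
            null_freq={f"L{j + 1:02d}": q for j, q in enumerate(qs)}, seed=21,
        )
        ds, truth = simulate_dataset(cfg)
        ds = inject_artifacts(ds, truth, cfg)
        diag = null_diagnostics(wc_fstats(ds), ds)
        assert diag["spearman_fis_blanks"]["rho"] > 0.5
        assert diag["regression_fis_blanks"]["slope"] > 0

    def test_exclusion_list_reruns_regression(self):
        cfg = SimulationConfig(n_pops=3, n_per_pop=40, n_loci=6,
                               null_freq=0.1, missing_rate=0.02, seed=3)
        ds, truth = simulate_dataset(cfg)
        ds = inject_artifacts(ds, truth, cfg)
        diag = null_diagnostics(wc_fstats(ds), ds,
                                exclude_from_regression=["L01", "L02"])
        assert "regression_fis_blanks_excl" in diag
        assert diag["excluded"] == ["L01", "L02"]


class TestEna:
    def test_reduces_to_wc_with_zero_nulls(self):
        cfg = SimulationConfig(n_pops=3, n_per_pop=30, n_loci=5,
                               target_fst=0.06, seed=13)
        ds, _ = simulate_dataset(cfg)
        # explicit zero-null EM: bit-level agreement with plain WC
        table = em_null_table(ds).table.assign(null_freq=0.0, expected_blanks=0.0)
        zero_em = EmResult(table=table, freqs={})
        res = fst_ena(ds, em=zero_em, n_boot=0)
        assert res["fst_multilocus"] == wc_fstats(ds).multilocus["fst"]

    def test_corrects_toward_true_fst_under_nulls(self):
        # oracle: the realized full-system F_ST of each replicate (null
        # allele visible in the truth genotypes); ENA should cut the upward
        # bias that apparent homozygote excess puts into the uncorrected
        # estimate on null-recoded data
        from msatqc import GenotypeDataset, recode_missing_as_null

        err_raw, err_ena, closer = [], [], 0
        R = 30
        for s in range(R):
            cfg = SimulationConfig(n_pops=3, n_per_pop=50, n_loci=10,
                                   target_fst=0.05, null_freq=0.2, seed=3000 + s)
            ds, truth = simulate_dataset(cfg)
            noisy = inject_artifacts(ds, truth, cfg)
            fullsys = GenotypeDataset(
                ds.loci, ds.individuals.copy(), truth.full_system_alleles.copy()
            )
            tru = wc_fstats(fullsys).multilocus["fst"]
            rec = recode_missing_as_null(noisy, noisy.locus_names)
            raw = wc_fstats(rec).multilocus["fst"]
            ena = fst_ena(rec, blank_loci=rec.locus_names, n_boot=0)[
                "fst_multilocus"
            ]
            err_raw.append(raw - tru)
            err_ena.append(ena - tru)
            closer += abs(err_ena[-1]) <= abs(err_raw[-1])
        assert abs(np.mean(err_ena)) < abs(np.mean(err_raw))
        assert np.mean(np.abs(err_ena)) < np.mean(np.abs(err_raw))
        assert closer > R / 2

    def test_recoded_null_locus_handled(self):
        from msatqc import recode_missing_as_null

        cfg = SimulationConfig(n_pops=3, n_per_pop=30, n_loci=4,
                               null_freq=0.15, seed=6)
        ds, truth = simulate_dataset(cfg)
        ds = inject_artifacts(ds, truth, cfg)
        rec = recode_missing_as_null(ds, [ds.locus_names[0]])
        res = fst_ena(rec, blank_loci=[ds.locus_names[0]], n_boot=0)
        assert np.isfinite(res["fst_multilocus"])
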