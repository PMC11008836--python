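"""Locus-level artifact tests and the consolidated QC verdict.

The battery screens each locus for linkage disequilibrium (G-based
permutation tests over all pairs, BY-adjusted), short-allele dominance
(negative trend of per-allele F_IT with allele size), stuttering (deficit
of one-repeat-step heterozygotes), F_IS/F_ST outlier status against the
multilocus bootstrap CI, excess missing data and sex linkage, and combines
the flags into a retained-locus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .fstats import (
    FStatsResult,
    _g_stat,
    bootstrap_ci,
    combine_p_generalized_binomial,
    wc_fstats,
)
from .genotype_io import MISSING, NULL_CODE, GenotypeDataset

__all__ = [
    "QCReport",
    "ld_gtest_all_pairs",
    "sad_test",
    "stuttering_test",
    "outlier_locus_rules",
    "fdr_adjust",
    "qc_battery",
]


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def fdr_adjust(p_values, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg (independent series) or Benjamini-Yekutieli
    (dependent series) step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    c = np.sum(1.0 / np.arange(1, m + 1)) if method == "BY" else 1.0
    if method not in ("BH", "BY"):
        raise ValueError(f"unknown FDR method {method!r}")
    adj = ranked * m * c / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def _genotype_codes(pair: np.ndarray) -> np.ndarray:
    """Integer code per individual for the (sorted) genotype; -1 = blank."""
    ok = pair[:, 0] != MISSING
    codes = np.full(pair.shape[0], -1)
    if ok.sum() == 0:
        return codes
    uniq, inv = np.unique(pair[ok], axis=0, return_inverse=True)
    codes[ok] = inv
    return codes


def ld_gtest_all_pairs(
    dataset: GenotypeDataset, n_perm: int = 10000, seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """G-based LD permutation test for every locus pair.

    Per pair, the statistic sums over subsamples the G statistic of the
    two-locus genotype contingency table; the null permutes one locus's
    genotypes among individuals within each subsample.  Raw p-values are
    BY-adjusted over all pairs (they share loci, hence are dependent), and
    the per-site proportions of significant raw tests are compared with a
    Fisher exact test (chi-square contingency test for >2 sites).
    """
    if len(dataset.loci) < 2:
        raise ValueError("need >= 2 loci")
    rng = np.random.default_rng(seed)
    codes, labels = dataset.population_codes()
    L = len(dataset.loci)
    gcodes = [ _genotype_codes(dataset.alleles[:, j, :]) for j in range(L) ]

    rows = []
    site_sig = {lab: 0 for lab in labels}
    site_tot = {lab: 0 for lab in labels}
    for j1, j2 in combinations(range(L), 2):
        g_obs = 0.0
        per_pop = []
        for pi in range(len(labels)):
            sel = (codes == pi) & (gcodes[j1] >= 0) & (gcodes[j2] >= 0)
            c1, c2 = gcodes[j1][sel], gcodes[j2][sel]
            if sel.sum() < 2 or np.unique(c1).size < 2 or np.unique(c2).size < 2:
                continue
            per_pop.append((pi, c1, c2))
        if not per_pop:
            rows.append((dataset.loci[j1].name, dataset.loci[j2].name,
                         np.nan, np.nan, False))
            continue
        k1 = {pi: c1.max() + 1 for pi, c1, _ in per_pop}
        k2 = {pi: c2.max() + 1 for pi, _, c2 in per_pop}

        def g_of(pair_list):
            tot = 0.0
            for pi, c1, c2 in pair_list:
                tab = np.zeros((k1[pi], k2[pi]))
                np.add.at(tab, (c1, c2), 1.0)
                tot += _g_stat(tab)
            return tot

        g_obs = g_of(per_pop)
        exceed = 0
        for _ in range(n_perm):
            permed = [(pi, c1, rng.permutation(c2)) for pi, c1, c2 in per_pop]
            if g_of(permed) >= g_obs - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        rows.append((dataset.loci[j1].name, dataset.loci[j2].name, g_obs, p, True))
        # per-site significance bookkeeping on raw per-pop tests
        for pi, c1, c2 in per_pop:
            site_tot[labels[pi]] += 1
            tab = np.zeros((k1[pi], k2[pi]))
            np.add.at(tab, (c1, c2), 1.0)
            g_site = _g_stat(tab)
            ex = sum(
                1 for _ in range(min(n_perm, 400))
                if _g_stat(_count_tab(c1, rng.permutation(c2), k1[pi], k2[pi]))
                >= g_site - 1e-12
            )
            if (ex + 1) / (min(n_perm, 400) + 1) < alpha:
                site_sig[labels[pi]] += 1

    table = pd.DataFrame(rows, columns=["locus1", "locus2", "g", "p", "tested"])
    tested = table["tested"] & table["p"].notna()
    table["by_p"] = np.nan
    if tested.any():
        table.loc[tested, "by_p"] = fdr_adjust(table.loc[tested, "p"], method="BY")

    # Fisher exact comparison of per-site significant-test proportions
    counts = np.array(
        [[site_sig[lab], site_tot[lab] - site_sig[lab]] for lab in labels]
    )
    fisher_p = np.nan
    if counts.shape[0] == 2 and counts.sum() > 0:
        fisher_p = float(stats.fisher_exact(counts).pvalue)
    elif counts.shape[0] > 2 and np.all(counts.sum(axis=1) > 0):
        ok_cols = counts.sum(axis=0) > 0
        if ok_cols.all():
            fisher_p = float(stats.chi2_contingency(counts).pvalue)
        else:
            fisher_p = 1.0
    return {"table": table, "site_proportion_p": fisher_p,
            "site_significant": site_sig, "site_total": site_tot}


def _count_tab(c1, c2, k1, k2):
    tab = np.zeros((k1, k2))
    np.add.at(tab, (c1, c2), 1.0)
    return tab


# ---------------------------------------------------------------------------
# Short-allele dominance
# ---------------------------------------------------------------------------


def sad_test(dataset: GenotypeDataset, locus: str,
             fstats: FStatsResult | None = None) -> dict:
    """Short-allele dominance tests for one locus.

    Primary: one-sided (negative) Spearman rank correlation between
    per-allele F_IT and allele size — preferential amplification of the
    shorter allele in heterozygotes produces a size trend in the per-allele
    fixation index.  Secondary (confirmation): weighted least squares of
    per-allele F_IS on size with weights p_i (1 - p_i), one-sided
    negative-slope p.

    With a single population F_IT is unavailable and per-allele F_IS is
    used for the Spearman arm as well.
    """
    if fstats is None:
        fstats = wc_fstats(dataset)
    sub = fstats.per_allele.query("locus == @locus")
    sub = sub[sub["allele"] != NULL_CODE]
    if len(sub) < 3:
        return {"testable": False, "spearman_rho": np.nan, "spearman_p": np.nan,
                "wls_slope": np.nan, "wls_p": np.nan}
    sizes = sub["allele"].to_numpy(dtype=float)
    stat_col = "fit" if fstats.n_populations > 1 else "fis"
    y = sub[stat_col].to_numpy(dtype=float)
    ok = np.isfinite(y)
    rho = p_s = np.nan
    if ok.sum() >= 3 and np.unique(y[ok]).size > 1:
        res = stats.spearmanr(sizes[ok], y[ok], alternative="less")
        rho, p_s = float(res.statistic), float(res.pvalue)
    elif ok.sum() >= 3:
        rho, p_s = 0.0, 1.0  # constant F_IT: no signal

    yis = sub["fis"].to_numpy(dtype=float)
    w = sub["pbar"].to_numpy() * (1.0 - sub["pbar"].to_numpy())
    okw = np.isfinite(yis) & (w > 0)
    slope = p_w = np.nan
    if okw.sum() >= 3 and np.unique(sizes[okw]).size > 1:
        slope, p_w = _wls_negative_slope(sizes[okw], yis[okw], w[okw])
    return {"testable": True, "spearman_rho": rho, "spearman_p": p_s,
            "wls_slope": slope, "wls_p": p_w}


def _wls_negative_slope(x, y, w):
    """Weighted OLS slope with one-sided p for slope < 0 (t distribution)."""
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    sxy = np.sum(w * (x - xb) * (y - yb))
    slope = sxy / sxx
    resid = y - (yb + slope * (x - xb))
    dof = x.size - 2
    if dof <= 0 or sxx <= 0:
        return float(slope), np.nan
    s2 = np.sum(w * resid**2) / dof
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return float(slope), 0.5 if slope >= 0 else np.nan
    t = slope / se
    return float(slope), float(stats.t.cdf(t, dof))


# ---------------------------------------------------------------------------
# Stuttering
# ---------------------------------------------------------------------------


def stuttering_test(dataset: GenotypeDataset, locus: str,
                    seed: int | None = None) -> dict:
    """Deficit of one-repeat-step heterozygotes (stuttering signature).

    Stuttering miscalls heterozygotes whose alleles differ by exactly one
    motif unit as homozygotes, so those heterozygotes go missing relative
    to random-mating expectations while other heterozygote classes do not.
    Within each population the expected share of one-step pairs among all
    heterozygous pairs is computed from the allele frequencies; the
    observed one-step count among observed heterozygotes is compared by a
    one-sided (deficit) exact binomial test, and per-population p-values
    are combined with the generalized binomial procedure.
    """
    j = dataset.locus_index(locus)
    motif_len = dataset.loci[j].motif_length
    codes, labels = dataset.population_codes()
    pair = dataset.alleles[:, j, :]

    p_values = []
    any_expected = False
    details = []
    for pi, lab in enumerate(labels):
        sub = pair[codes == pi]
        ok = (sub[:, 0] != MISSING) & (sub[:, 0] != NULL_CODE) & (sub[:, 1] != NULL_CODE)
        sub = sub[ok]
        if sub.shape[0] < 2:
            continue
        vals, counts = np.unique(sub.ravel(), return_counts=True)
        p = counts / counts.sum()
        onestep = np.abs(vals[:, None] - vals[None, :]) == motif_len
        pairmat = np.outer(p, p)
        het_total = pairmat.sum() - np.sum(p**2)
        het_onestep = pairmat[onestep].sum()
        if het_total <= 0 or het_onestep <= 0:
            continue
        any_expected = True
        share = het_onestep / het_total
        hets = sub[sub[:, 0] != sub[:, 1]]
        n_het = hets.shape[0]
        n_one = int(np.sum(np.abs(hets[:, 0] - hets[:, 1]) == motif_len))
        if n_het == 0:
            continue
        pv = stats.binomtest(n_one, n_het, share, alternative="less").pvalue
        p_values.append(float(pv))
        details.append({"population": lab, "expected_share": float(share),
                        "observed_onestep": n_one, "observed_het": n_het,
                        "p": float(pv)})

    if not any_expected or not p_values:
        return {"testable": False, "p": np.nan, "per_population": details}
    if len(p_values) == 1:
        return {"testable": True, "p": p_values[0], "per_population": details}
    combined = combine_p_generalized_binomial(p_values, seed=seed)
    return {"testable": True, "p": combined, "per_population": details}


# ---------------------------------------------------------------------------
# Outlier rules and verdict
# ---------------------------------------------------------------------------


def outlier_locus_rules(
    fstats: FStatsResult,
    fis_ci: tuple[float, float],
    fst_ci: tuple[float, float],
    ld_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag loci outside the multilocus bootstrap CIs and apply the
    exclusion rule.

    A locus is marked for exclusion when it is an F_ST outlier AND (an F_IS
    outlier OR a member of a BY-significant LD pair) — behaviour consistent
    with discarding loci whose differentiation is shaped by selection or
    shared artifacts rather than demography.
    """
    ld_loci: set[str] = set()
    if ld_table is not None and "by_p" in ld_table:
        sig = ld_table[ld_table["by_p"] < alpha]
        ld_loci = set(sig["locus1"]) | set(sig["locus2"])
    rows = []
    for _, r in fstats.per_locus.iterrows():
        if not r["defined"]:
            rows.append((r["locus"], False, False, False, False))
            continue
        fis_out = bool(
            np.isfinite(r["fis"])
            and not (fis_ci[0] <= r["fis"] <= fis_ci[1])
        )
        fst_out = bool(
            np.isfinite(r["fst"])
            and np.isfinite(fst_ci[0])
            and not (fst_ci[0] <= r["fst"] <= fst_ci[1])
        )
        in_ld = r["locus"] in ld_loci
        exclude = fst_out and (fis_out or in_ld)
        rows.append((r["locus"], fis_out, fst_out, in_ld, exclude))
    return pd.DataFrame(
        rows, columns=["locus", "fis_outlier", "fst_outlier", "ld_member", "exclude"]
    )


@dataclass
class QCReport:
    """Consolidated per-locus QC decision."""

    flags: pd.DataFrame  # one row per locus, boolean flag columns
    retained: list
    excluded: list
    ld: dict
    decisions: list = field(default_factory=list)


def qc_battery(
    dataset: GenotypeDataset,
    n_perm: int = 10000,
    n_boot: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
    missing_threshold: float = 0.5,
    sad_alpha: float = 0.05,
    run_ld: bool = True,
) -> QCReport:
    """Run the full locus-QC battery and produce the retained-locus set.

    Flags per locus: ``excess_missing`` (> ``missing_threshold`` blanks),
    ``sad`` (Spearman arm significant after BH and confirmed by the
    weighted regression), ``stuttering`` (BH-adjusted), ``ld_member``,
    ``fis_outlier`` / ``fst_outlier`` (outside the multilocus bootstrap
    CIs) and the combined ``exclude`` rule.
    """
    rng = np.random.default_rng(seed)
    fres = wc_fstats(dataset)
    comp = fres.components()
    fis_ci = bootstrap_ci(comp, "fis", n_boot=n_boot, seed=int(rng.integers(2**31 - 1)))
    fst_ci = bootstrap_ci(comp, "fst", n_boot=n_boot, seed=int(rng.integers(2**31 - 1)))

    ld = {"table": None, "site_proportion_p": np.nan}
    if run_ld and len(dataset.loci) >= 2:
        ld = ld_gtest_all_pairs(
            dataset, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)), alpha=alpha
        )

    n = dataset.n_individuals
    blanks = dataset.n_blanks()
    sad_p, stut_p = {}, {}
    for locus in dataset.locus_names:
        s = sad_test(dataset, locus, fstats=fres)
        sad_p[locus] = s
        stut_p[locus] = stuttering_test(
            dataset, locus, seed=int(rng.integers(2**31 - 1))
        )
    sad_raw = {k: v["spearman_p"] for k, v in sad_p.items()
               if v["testable"] and np.isfinite(v["spearman_p"])}
    sad_bh = dict(zip(sad_raw, fdr_adjust(list(sad_raw.values()), "BH"))) if sad_raw else {}
    stut_raw = {k: v["p"] for k, v in stut_p.items()
                if v["testable"] and np.isfinite(v["p"])}
    stut_bh = dict(zip(stut_raw, fdr_adjust(list(stut_raw.values()), "BH"))) if stut_raw else {}

    out_rules = outlier_locus_rules(
        fres, fis_ci, fst_ci, ld_table=ld.get("table"), alpha=alpha
    ).set_index("locus")

    rows, decisions = [], []
    for locus in dataset.locus_names:
        excess = blanks[locus] / n > missing_threshold
        sad_flag = bool(
            sad_bh.get(locus, 1.0) < sad_alpha
            and sad_p[locus]["wls_p"] is not None
            and np.isfinite(sad_p[locus]["wls_p"])
            and sad_p[locus]["wls_p"] < sad_alpha
        )
        stut_flag = bool(stut_bh.get(locus, 1.0) < alpha)
        r = out_rules.loc[locus]
        exclude = bool(r["exclude"] or excess or sad_flag or stut_flag)
        rows.append((locus, excess, sad_flag, stut_flag, bool(r["ld_member"]),
                     bool(r["fis_outlier"]), bool(r["fst_outlier"]), exclude))
        if exclude:
            why = []
            if excess:
                why.append(f"missing fraction {blanks[locus] / n:.2f} > {missing_threshold}")
            if r["exclude"]:
                why.append("F_ST outlier combined with F_IS outlier or LD membership")
            if sad_flag:
                why.append("short-allele dominance (both tests)")
            if stut_flag:
                why.append("stuttering signature")
            decisions.append(f"{locus}: excluded ({'; '.join(why)})")

    flags = pd.DataFrame(
        rows,
        columns=["locus", "excess_missing", "sad", "stuttering", "ld_member",
                 "fis_outlier", "fst_outlier", "exclude"],
    )
    retained = list(flags.loc[~flags["exclude"], "locus"])
    excluded = list(flags.loc[flags["exclude"], "locus"])
    return QCReport(flags=flags, retained=retained, excluded=excluded,
                    ld=ld, decisions=decisions)
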