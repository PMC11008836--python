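"""Weir & Cockerham (1984) F-statistics and their randomization tests.

The estimators partition allele-indicator variance into components among
populations (a), among individuals within populations (b) and within
individuals (c).  Per locus and overall, components are *summed* over
alleles and loci before taking ratios (ratio of sums, not mean of ratios),
matching the behaviour of the classical Fstat program:

    F_ST = a / (a + b + c)
    F_IT = 1 - c / (a + b + c)
    F_IS = 1 - c / (b + c)

Monomorphic (or all-missing) loci have undefined statistics and are
excluded from multilocus sums.

Permutation tests follow the classical scheme: F_IS by permuting alleles
among individuals within subsamples (one-sided heterozygote deficit by
default, two-sided by the doubling rule); subdivision by the G-based test
permuting whole individuals among subsamples.  All p-values use the
(k + 1) / (n + 1) convention so a permutation test never returns zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "FStatsResult",
    "SexLinkageReport",
    "wc_fstats",
    "fis_permutation_test",
    "gtest_subdivision",
    "bootstrap_ci",
    "jackknife_se",
    "sex_linkage_screen",
    "combine_p_generalized_binomial",
    "two_sided_from_one_sided",
]


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------


def _locus_components(pair: np.ndarray, codes: np.ndarray):
    """WC84 per-allele variance components for one locus.

    ``pair``: (n, 2) allele sizes with MISSING; ``codes``: population code
    per individual.  Returns (alleles, a, b, c) arrays; empty when the locus
    is uninformative (monomorphic or <1 typed individual).
    """
    ok = pair[:, 0] != MISSING
    pair = pair[ok]
    codes = codes[ok]
    if pair.shape[0] == 0:
        return np.array([]), np.array([]), np.array([]), np.array([])
    alleles = np.unique(pair)
    if alleles.size < 2:
        return np.array([]), np.array([]), np.array([]), np.array([])

    pops, inv = np.unique(codes, return_inverse=True)
    r = pops.size
    n_i = np.bincount(inv).astype(float)  # individuals per pop
    N = n_i.sum()
    nbar = N / r
    het = pair[:, 0] != pair[:, 1]

    # per pop x allele counts and het counts
    k = alleles.size
    aidx0 = np.searchsorted(alleles, pair[:, 0])
    aidx1 = np.searchsorted(alleles, pair[:, 1])
    counts = np.zeros((r, k))
    np.add.at(counts, (inv, aidx0), 1.0)
    np.add.at(counts, (inv, aidx1), 1.0)
    hets = np.zeros((r, k))
    np.add.at(hets, (inv[het], aidx0[het]), 1.0)
    np.add.at(hets, (inv[het], aidx1[het]), 1.0)

    p_iu = counts / (2.0 * n_i[:, None])
    pbar = counts.sum(axis=0) / (2.0 * N)
    hbar = hets.sum(axis=0) / N

    if r > 1:
        nc = (N - (n_i**2).sum() / N) / (r - 1.0)
        s2 = (n_i[:, None] * (p_iu - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        term = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = (nbar / nc) * (s2 - (term - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (term - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    else:
        if nbar <= 1:
            return np.array([]), np.array([]), np.array([]), np.array([])
        a = np.zeros(k)
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
    c = hbar / 2.0
    return alleles, a, b, c


def _ratios(a: float, b: float, c: float) -> tuple[float, float, float]:
    tot = a + b + c
    fst = a / tot if tot != 0 else np.nan
    fit = 1.0 - c / tot if tot != 0 else np.nan
    fis = 1.0 - c / (b + c) if (b + c) != 0 else np.nan
    return fis, fst, fit


@dataclass
class FStatsResult:
    """Per-locus, per-allele and multilocus Weir-Cockerham statistics."""

    per_locus: pd.DataFrame  # locus, a, b, c, fis, fst, fit, defined
    per_allele: pd.DataFrame  # locus, allele, a, b, c, fis, fst, fit, pbar
    multilocus: dict  # fis, fst, fit
    n_populations: int
    ci_95: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)

    def components(self) -> np.ndarray:
        """(L, 3) summed components for defined loci, in locus order."""
        d = self.per_locus[self.per_locus["defined"]]
        return d[["a", "b", "c"]].to_numpy()


def wc_fstats(dataset: GenotypeDataset) -> FStatsResult:
    """Weir-Cockerham F-statistics for every locus and overall.

    With a single population only F_IS is defined (F_ST/F_IT need >=2
    subsamples).  All-missing or monomorphic loci yield undefined (NaN)
    entries rather than raising.
    """
    codes, labels = dataset.population_codes()
    rows, allele_rows = [], []
    for j, locus in enumerate(dataset.loci):
        alleles, a, b, c = _locus_components(dataset.alleles[:, j, :], codes)
        if alleles.size == 0:
            rows.append((locus.name, 0.0, 0.0, 0.0, np.nan, np.nan, np.nan, False))
            continue
        fis, fst, fit = _ratios(a.sum(), b.sum(), c.sum())
        rows.append((locus.name, a.sum(), b.sum(), c.sum(), fis, fst, fit, True))
        ok = dataset.alleles[:, j, 0] != MISSING
        flat = dataset.alleles[ok, j, :].ravel()
        tot = flat.size
        for u, au, bu, cu in zip(alleles, a, b, c):
            fis_u, fst_u, fit_u = _ratios(au, bu, cu)
            allele_rows.append(
                (locus.name, int(u), au, bu, cu, fis_u, fst_u, fit_u,
                 float((flat == u).sum()) / tot)
            )
    per_locus = pd.DataFrame(
        rows, columns=["locus", "a", "b", "c", "fis", "fst", "fit", "defined"]
    )
    per_allele = pd.DataFrame(
        allele_rows,
        columns=["locus", "allele", "a", "b", "c", "fis", "fst", "fit", "pbar"],
    )
    d = per_locus[per_locus["defined"]]
    fis, fst, fit = _ratios(d["a"].sum(), d["b"].sum(), d["c"].sum())
    if len(labels) < 2:
        fst = np.nan
        fit = np.nan
    multilocus = {"fis": fis, "fst": fst, "fit": fit}
    return FStatsResult(per_locus, per_allele, multilocus, n_populations=len(labels))


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------


def two_sided_from_one_sided(p_one: float, estimate: float) -> float:
    """Two-sided p by the doubling rule: 2p for positive estimates,
    2(1 - p) otherwise, capped at 1."""
    if np.isnan(p_one) or np.isnan(estimate):
        return np.nan
    p = 2.0 * p_one if estimate > 0 else 2.0 * (1.0 - p_one)
    return min(p, 1.0)


def fis_permutation_test(
    dataset: GenotypeDataset, n_perm: int = 10000, seed: int | None = None
) -> pd.DataFrame:
    """Permutation test of F_IS (alleles shuffled within subsamples).

    Returns a DataFrame with rows per locus plus ``overall``: observed F_IS,
    one-sided p (heterozygote deficit: Pr(F_IS_perm >= F_IS_obs)) and the
    two-sided doubling-rule p.

    Shuffling alleles within subsamples keeps allele frequencies fixed, so
    the per-allele components depend on a permutation only through the
    heterozygote counts H_u; summed over alleles, sum_u H_u = 2 x (number of
    heterozygous individuals), so each permuted F_IS is a monotone function
    of the locus's total heterozygote count:

        sum b = B0 - kappa * 2H / N,   sum c = H / N,
        kappa = (nbar / (nbar - 1)) (2 nbar - 1) / (4 nbar)

    with B0 the frequency-only part, H the heterozygote count, N the typed
    individuals and nbar = N / r.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    codes, _ = dataset.population_codes()
    L = len(dataset.loci)

    obs_bc = np.zeros((L, 2))
    perm_bc = np.zeros((n_perm, L, 2))
    defined = np.zeros(L, dtype=bool)

    for j in range(L):
        pair = dataset.alleles[:, j, :]
        alleles, a, b, c = _locus_components(pair, codes)
        if alleles.size == 0:
            continue
        defined[j] = True
        obs_bc[j] = (b.sum(), c.sum())

        ok = pair[:, 0] != MISSING
        sub = pair[ok]
        sub_codes = codes[ok]
        N = sub.shape[0]
        r = np.unique(sub_codes).size
        nbar = N / r
        if nbar <= 1:
            defined[j] = False
            continue
        kappa = (nbar / (nbar - 1.0)) * (2.0 * nbar - 1.0) / (4.0 * nbar)
        h_obs = float(np.sum(sub[:, 0] != sub[:, 1]))
        # frequency-only part of sum(b): add back the het part at observed H
        b0 = obs_bc[j, 0] + kappa * 2.0 * h_obs / N

        h_perm = np.zeros(n_perm)
        for pc_code in np.unique(sub_codes):
            flat = sub[sub_codes == pc_code].ravel()
            if flat.size < 2:
                continue
            order = np.argsort(rng.random((n_perm, flat.size)), axis=1)
            shuffled = flat[order].reshape(n_perm, -1, 2)
            h_perm += (shuffled[:, :, 0] != shuffled[:, :, 1]).sum(axis=1)
        perm_bc[:, j, 0] = b0 - kappa * 2.0 * h_perm / N
        perm_bc[:, j, 1] = h_perm / N

    rows = []
    for j, locus in enumerate(dataset.loci):
        if not defined[j]:
            rows.append((locus.name, np.nan, np.nan, np.nan))
            continue
        b, c = obs_bc[j]
        fis = 1.0 - c / (b + c) if (b + c) != 0 else np.nan
        pb, pc = perm_bc[:, j, 0], perm_bc[:, j, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            fis_perm = 1.0 - pc / (pb + pc)
        k = int(np.sum(fis_perm >= fis - 1e-12))
        p_one = (k + 1) / (n_perm + 1)
        rows.append((locus.name, fis, p_one, two_sided_from_one_sided(p_one, fis)))

    b_all, c_all = obs_bc[defined, 0].sum(), obs_bc[defined, 1].sum()
    fis_all = 1.0 - c_all / (b_all + c_all) if (b_all + c_all) != 0 else np.nan
    pb = perm_bc[:, defined, 0].sum(axis=1)
    pc = perm_bc[:, defined, 1].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fis_perm = 1.0 - pc / (pb + pc)
    k = int(np.sum(fis_perm >= fis_all - 1e-12))
    p_one = (k + 1) / (n_perm + 1)
    rows.append(("overall", fis_all, p_one, two_sided_from_one_sided(p_one, fis_all)))
    return pd.DataFrame(rows, columns=["locus", "fis", "p_one_sided", "p_two_sided"])


def _g_stat(counts: np.ndarray) -> float:
    """G log-likelihood-ratio statistic of a contingency table of counts."""
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.size == 0:
        return 0.0
    total = counts.sum()
    exp = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    obs = counts[counts > 0]
    return float(2.0 * np.sum(obs * np.log(obs / exp[counts > 0])))


def gtest_subdivision(
    dataset: GenotypeDataset, n_perm: int = 10000, seed: int | None = None
) -> pd.DataFrame:
    """G-based randomization test of subdivision (individuals permuted
    among subsamples, whole multilocus genotypes travelling together).

    Returns per-locus rows plus ``overall`` (G summed over loci), with
    one-sided (k + 1)/(n + 1) p-values.
    """
    codes, labels = dataset.population_codes()
    if len(labels) < 2:
        raise ValueError("subdivision test requires >= 2 populations")
    rng = np.random.default_rng(seed)
    L = len(dataset.loci)
    r = len(labels)

    # precompute allele index per locus
    locus_alleles, locus_idx = [], []
    for j in range(L):
        pair = dataset.alleles[:, j, :]
        ok = pair[:, 0] != MISSING
        alleles = np.unique(pair[ok])
        locus_alleles.append(alleles)
        idx = np.full((dataset.n_individuals, 2), -1)
        idx[ok] = np.searchsorted(alleles, pair[ok])
        locus_idx.append(idx)

    def g_per_locus(perm_codes):
        gs = np.zeros(L)
        for j in range(L):
            k = locus_alleles[j].size
            if k < 2:
                gs[j] = np.nan
                continue
            idx = locus_idx[j]
            ok = idx[:, 0] >= 0
            tab = np.zeros((r, k))
            np.add.at(tab, (perm_codes[ok], idx[ok, 0]), 1.0)
            np.add.at(tab, (perm_codes[ok], idx[ok, 1]), 1.0)
            gs[j] = _g_stat(tab)
        return gs

    g_obs = g_per_locus(codes)
    exceed = np.zeros(L)
    exceed_all = 0
    g_obs_all = np.nansum(g_obs)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        g = g_per_locus(perm)
        exceed += (g >= g_obs - 1e-12) & ~np.isnan(g)
        if np.nansum(g) >= g_obs_all - 1e-12:
            exceed_all += 1

    rows = []
    for j, locus in enumerate(dataset.loci):
        if np.isnan(g_obs[j]):
            rows.append((locus.name, np.nan, np.nan))
        else:
            rows.append((locus.name, g_obs[j], (exceed[j] + 1) / (n_perm + 1)))
    rows.append(("overall", g_obs_all, (exceed_all + 1) / (n_perm + 1)))
    return pd.DataFrame(rows, columns=["locus", "g", "p"])


# ---------------------------------------------------------------------------
# Resampling over loci
# ---------------------------------------------------------------------------


def _stat_from_components(comp: np.ndarray, statistic: str) -> float:
    a, b, c = comp.sum(axis=0)
    fis, fst, fit = _ratios(a, b, c)
    return {"fis": fis, "fst": fst, "fit": fit}[statistic]


def bootstrap_ci(
    dataset_or_components,
    statistic: str = "fst",
    n_boot: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap-over-loci CI of a multilocus statistic.

    Accepts a dataset or a precomputed (L, 3) component matrix.  Requires
    >= 2 informative loci; returns (nan, nan) otherwise.
    """
    comp = (
        wc_fstats(dataset_or_components).components()
        if isinstance(dataset_or_components, GenotypeDataset)
        else np.asarray(dataset_or_components, dtype=float)
    )
    L = comp.shape[0]
    if L < 2:
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_boot, L))
    sums = comp[idx].sum(axis=1)  # (n_boot, 3)
    a, b, c = sums[:, 0], sums[:, 1], sums[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "fst":
            vals = a / (a + b + c)
        elif statistic == "fis":
            vals = 1.0 - c / (b + c)
        elif statistic == "fit":
            vals = 1.0 - c / (a + b + c)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return (np.nan, np.nan)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def jackknife_se(dataset_or_components) -> dict:
    """Delete-one-locus jackknife SEs of multilocus F_IS and F_ST.

    Returns ``{"se_fis", "se_fst", "r_ratio"}``; ``r_ratio`` =
    se_fis / se_fst is the classical null-allele signature (values above 2
    point to null alleles).  With zero F_ST variance the ratio is inf.
    """
    comp = (
        wc_fstats(dataset_or_components).components()
        if isinstance(dataset_or_components, GenotypeDataset)
        else np.asarray(dataset_or_components, dtype=float)
    )
    L = comp.shape[0]
    if L < 3:
        return {"se_fis": np.nan, "se_fst": np.nan, "r_ratio": np.nan}
    fis_i = np.empty(L)
    fst_i = np.empty(L)
    for i in range(L):
        rest = np.delete(comp, i, axis=0)
        fis_i[i] = _stat_from_components(rest, "fis")
        fst_i[i] = _stat_from_components(rest, "fst")
    se_fis = float(np.sqrt((L - 1) / L * np.sum((fis_i - fis_i.mean()) ** 2)))
    se_fst = float(np.sqrt((L - 1) / L * np.sum((fst_i - fst_i.mean()) ** 2)))
    r = se_fis / se_fst if se_fst > 0 else float("inf")
    return {"se_fis": se_fis, "se_fst": se_fst, "r_ratio": r}


# ---------------------------------------------------------------------------
# Generalized binomial p-value combination
# ---------------------------------------------------------------------------


def combine_p_generalized_binomial(
    p_values, n_mc: int = 10000, seed: int | None = None
) -> float:
    """Combine k one-sided p-values with the generalized binomial procedure.

    The statistic is S = min over ranks r of Pr(Binomial(k, p_(r)) >= r),
    i.e. the most surprising count of small p-values at any threshold among
    the observed order statistics; its null distribution is obtained by
    Monte-Carlo over k iid uniforms, and the combined p is
    Pr(S_null <= S_obs) with the (m + 1)/(n + 1) convention.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    ranks = np.arange(1, k + 1)

    def stat(sorted_p):
        return stats.binom.sf(ranks - 1, k, sorted_p).min(axis=-1)

    s_obs = stat(np.sort(p))
    rng = np.random.default_rng(seed)
    null = np.sort(rng.random((n_mc, k)), axis=1)
    s_null = stats.binom.sf(ranks[None, :] - 1, k, null).min(axis=1)
    return float((np.sum(s_null <= s_obs + 1e-15) + 1) / (n_mc + 1))


# ---------------------------------------------------------------------------
# Sex-linkage screen
# ---------------------------------------------------------------------------


@dataclass
class SexLinkageReport:
    """Heterozygosity and divergence comparisons between sexes.

    In female-heterogametic (WZ/ZZ) species a Z-linked locus shows a strong
    female heterozygote deficit (hemizygous females read as homozygotes) and
    sex-divergent allele frequencies; autosomal loci show neither.
    """

    fis_by_sex: pd.DataFrame  # locus, fis_female, fis_male, delta
    wilcoxon: pd.DataFrame  # locus, p (top-k loci by |delta|)
    divergence: pd.DataFrame  # locus, mean_fst, combined_p, bh_p
    per_country: pd.DataFrame  # locus, country, fst, g_p
    flagged: list


def _fis_by_sex(dataset: GenotypeDataset, sex: str) -> FStatsResult:
    mask = (dataset.individuals["sex"] == sex).to_numpy()
    return wc_fstats(dataset.subset_individuals(mask))


def sex_linkage_screen(
    dataset: GenotypeDataset,
    top_k: int = 3,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SexLinkageReport:
    """Screen loci for sex-chromosome linkage.

    Arm 1: per-locus F_IS in females vs males; the ``top_k`` loci with the
    biggest |difference| get a Wilcoxon signed-rank test paired by allele on
    per-allele F_IS.  Arm 2: per-locus F_ST between sexes within each
    country (G-test by permutation), F_ST averaged and p-values combined
    across countries with the generalized binomial procedure, then
    BH-adjusted across loci.  A locus is flagged when either arm is
    significant after adjustment.
    """
    from .marker_qc import fdr_adjust

    rng = np.random.default_rng(seed)
    res_f = _fis_by_sex(dataset, "female")
    res_m = _fis_by_sex(dataset, "male")
    tab = pd.DataFrame(
        {
            "locus": dataset.locus_names,
            "fis_female": res_f.per_locus["fis"].to_numpy(),
            "fis_male": res_m.per_locus["fis"].to_numpy(),
        }
    )
    tab["delta"] = (tab["fis_female"] - tab["fis_male"]).abs()

    top = tab.dropna(subset=["delta"]).nlargest(top_k, "delta")["locus"].tolist()
    wil_rows = []
    for name in top:
        af = res_f.per_allele.query("locus == @name").set_index("allele")["fis"]
        am = res_m.per_allele.query("locus == @name").set_index("allele")["fis"]
        shared = af.index.intersection(am.index)
        diffs = (af[shared] - am[shared]).dropna()
        diffs = diffs[diffs != 0]
        if len(diffs) < 2:
            wil_rows.append((name, np.nan))
            continue
        wil_rows.append((name, float(stats.wilcoxon(diffs).pvalue)))
    wilcoxon = pd.DataFrame(wil_rows, columns=["locus", "p"])
    okw = wilcoxon["p"].notna()
    wilcoxon["bh_p"] = np.nan
    if okw.any():
        wilcoxon.loc[okw, "bh_p"] = fdr_adjust(
            wilcoxon.loc[okw, "p"].to_numpy(), method="BH"
        )

    countries = dataset.population_labels
    pc_rows = []
    for country in countries:
        mask = (
            (dataset.individuals["population"] == country)
            & dataset.individuals["sex"].isin(["female", "male"])
        ).to_numpy()
        sub = dataset.subset_individuals(mask)
        if sub.individuals["sex"].nunique() < 2:
            continue  # a sex absent: country excluded
        sub = GenotypeDataset(
            loci=sub.loci,
            individuals=sub.individuals.assign(population=sub.individuals["sex"]),
            alleles=sub.alleles,
        )
        fres = wc_fstats(sub)
        gtab = gtest_subdivision(
            sub, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        ).set_index("locus")
        for name, fst in zip(fres.per_locus["locus"], fres.per_locus["fst"]):
            pc_rows.append((name, country, fst, gtab.loc[name, "p"]))
    per_country = pd.DataFrame(pc_rows, columns=["locus", "country", "fst", "g_p"])

    div_rows = []
    for name in dataset.locus_names:
        sub = per_country.query("locus == @name").dropna(subset=["g_p"])
        if len(sub) == 0:
            div_rows.append((name, np.nan, np.nan))
            continue
        combined = combine_p_generalized_binomial(
            sub["g_p"].to_numpy(), seed=int(rng.integers(2**31 - 1))
        )
        div_rows.append((name, float(np.nanmean(sub["fst"])), combined))
    divergence = pd.DataFrame(div_rows, columns=["locus", "mean_fst", "combined_p"])
    ok = divergence["combined_p"].notna()
    divergence["bh_p"] = np.nan
    divergence.loc[ok, "bh_p"] = fdr_adjust(
        divergence.loc[ok, "combined_p"].to_numpy(), method="BH"
    )

    flagged = sorted(
        set(wilcoxon.loc[wilcoxon["bh_p"] < alpha, "locus"])
        | set(divergence.loc[divergence["bh_p"] < alpha, "locus"])
    )
    return SexLinkageReport(tab, wilcoxon, divergence, per_country, flagged)
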