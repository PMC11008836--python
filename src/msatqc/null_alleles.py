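"""Null-allele estimation and corrections.

A null allele fails to amplify: heterozygotes carrying one null are read as
homozygotes for the visible allele, and null homozygotes come out as blanks
(missing data).  Nulls therefore inflate apparent homozygosity and F_IS.

This module provides

* an EM estimator of the per-population null-allele frequency from the
  visible genotype counts (with blanks either modelled as putative null
  homozygotes or excluded, per locus);
* the one-sided exact binomial consistency test of expected vs observed
  blanks;
* the classical diagnostic battery (se(F_IS)/se(F_ST) ratio, one-sided
  Spearman correlations of F_IS with F_ST and with blank counts, and the
  F_IS ~ N_Blanks regression whose intercept estimates the null-free F_IS);
* the ENA ("excluding null alleles") corrected F_ST, where the null is
  carried as an extra allele class with its EM frequency and dropped from
  the component sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fstats import FStatsResult, _ratios, jackknife_se
from .genotype_io import MISSING, NULL_CODE, GenotypeDataset

__all__ = [
    "NullAlleleReport",
    "null_allele_report",
    "em_null_frequency",
    "em_null_table",
    "blanks_consistency_test",
    "null_diagnostics",
    "fst_ena",
]

EM_TOL = 1e-9
EM_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _genotype_counts(pair: np.ndarray):
    """Visible genotype counts at one locus for one population.

    Blanks and explicit 999999 homozygotes both count as ``n_blank``
    (putative null homozygotes); a 999999/visible heterozygote cannot be
    observed and is rejected.
    """
    blank = (pair[:, 0] == MISSING) | (
        (pair[:, 0] == NULL_CODE) & (pair[:, 1] == NULL_CODE)
    )
    if np.any((pair == NULL_CODE).sum(axis=1) == 1):
        raise ValueError("explicit null heterozygote is not observable")
    vis = pair[~blank]
    alleles, inv = np.unique(vis, return_inverse=True)
    inv = inv.reshape(vis.shape)
    k = alleles.size
    hom = np.zeros(k)
    het = np.zeros((k, k))
    for (i0, i1) in inv:
        if i0 == i1:
            hom[i0] += 1
        else:
            het[i0, i1] += 1
            het[i1, i0] += 1
    return alleles, hom, het, int(blank.sum()), int(vis.shape[0])


def em_null_frequency(
    pair: np.ndarray, include_blanks: bool = True
) -> tuple[pd.Series, float]:
    """EM estimate of allele frequencies including a null class.

    ``pair`` is the (n, 2) genotype column of one locus for one population.
    Observed homozygotes i/i are mixtures of true i/i and i/null; blanks are
    null/null when ``include_blanks`` (the model used when the locus's
    blanks are read as null homozygotes).  When blanks are excluded the
    likelihood is conditioned on the genotype being visible (truncated EM:
    an expected count of unobserved null homozygotes is imputed each step).

    Returns (frequency Series indexed by allele size with ``NULL_CODE`` for
    the null class, final log-likelihood).  The log-likelihood is checked to
    be non-decreasing across iterations.
    """
    alleles, hom, het, n_blank, n_vis = _genotype_counts(np.asarray(pair))
    k = alleles.size
    if k == 0 and n_blank == 0:
        raise ValueError("no genotypes at all")
    if k == 0:
        # only blanks: everything is null under the blank model
        return pd.Series([1.0], index=[NULL_CODE]), 0.0

    # initial frequencies: observed counts, nulls from blanks (or tiny)
    counts0 = 2.0 * hom + het.sum(axis=1)
    if include_blanks:
        total0 = counts0.sum() + 2.0 * n_blank
        p = np.append(counts0 / total0, max(2.0 * n_blank / total0, 1e-6))
    else:
        p = np.append(counts0 / counts0.sum(), 1e-3)
    p /= p.sum()

    def loglik(p):
        pv, pn = p[:k], p[k]
        ll = 0.0
        # visible homozygote i: p_i^2 + 2 p_i pn
        prob_hom = pv**2 + 2.0 * pv * pn
        with np.errstate(divide="ignore"):
            ll += np.sum(hom * np.where(hom > 0, np.log(np.maximum(prob_hom, 1e-300)), 0.0))
            iu, ju = np.nonzero(np.triu(het, 1))
            if iu.size:
                ll += np.sum(het[iu, ju] * np.log(2.0 * pv[iu] * pv[ju]))
        if include_blanks:
            if n_blank:
                ll += n_blank * np.log(max(pn**2, 1e-300))
        else:
            ll -= (n_vis) * np.log(max(1.0 - pn**2, 1e-300))
        return ll

    ll_prev = loglik(p)
    for _ in range(EM_MAX_ITER):
        pv, pn = p[:k], p[k]
        prob_hom = pv**2 + 2.0 * pv * pn
        with np.errstate(divide="ignore", invalid="ignore"):
            w_true = np.where(prob_hom > 0, pv**2 / prob_hom, 0.0)
        # expected allele counts
        cnt_vis = 2.0 * hom * w_true + hom * (1.0 - w_true) + het.sum(axis=1)
        cnt_null = np.sum(hom * (1.0 - w_true))
        n_total = n_vis
        if include_blanks:
            cnt_null += 2.0 * n_blank
            n_total += n_blank
        else:
            # truncated model: impute unobserved null homozygotes
            n_nn = n_vis * pn**2 / max(1.0 - pn**2, 1e-300)
            cnt_null += 2.0 * n_nn
            n_total += n_nn
        new = np.append(cnt_vis, cnt_null) / (2.0 * n_total)
        new /= new.sum()
        delta = np.max(np.abs(new - p))
        p = new
        ll = loglik(p)
        if ll < ll_prev - 1e-6:
            raise AssertionError(
                f"EM log-likelihood decreased ({ll_prev} -> {ll})"
            )
        ll_prev = ll
        if delta < EM_TOL:
            break

    # no polymorphism and no homozygote excess signal: clamp tiny estimates
    freqs = pd.Series(np.append(p[:k], p[k]), index=list(alleles) + [NULL_CODE])
    if freqs[NULL_CODE] < 1e-8:
        freqs[NULL_CODE] = 0.0
        freqs /= freqs.sum()
    return freqs, float(ll_prev)


@dataclass
class EmResult:
    """EM output: summary table plus full frequency vectors.

    ``table`` has one row per locus x population (null_freq, n, observed and
    expected blanks); ``freqs[(locus, pop)]`` is the full EM frequency
    Series over visible allele sizes plus :data:`NULL_CODE`.
    """

    table: pd.DataFrame
    freqs: dict[tuple[str, str], pd.Series]

    def mean_null_freq(self) -> pd.Series:
        return self.table.groupby("locus", sort=False)["null_freq"].mean()


def em_null_table(
    dataset: GenotypeDataset, blank_loci: list[str] | None = None
) -> EmResult:
    """EM null frequencies per locus x population.

    ``blank_loci`` lists the loci whose blanks are modelled as null
    homozygotes (e.g. the loci that were 999999-recoded); loci carrying
    explicit 999999 alleles are always treated that way.  Elsewhere blanks
    are excluded and only the homozygote-excess signal drives the EM.
    """
    blank_loci = set(blank_loci or [])
    codes, labels = dataset.population_codes()
    rows = []
    freqs: dict[tuple[str, str], pd.Series] = {}
    for j, locus in enumerate(dataset.loci):
        has_null_code = bool(np.any(dataset.alleles[:, j, :] == NULL_CODE))
        include = locus.name in blank_loci or has_null_code
        for pi, pop in enumerate(labels):
            pair = dataset.alleles[codes == pi, j, :]
            n_tot = pair.shape[0]
            blank = np.sum(
                (pair[:, 0] == MISSING)
                | ((pair[:, 0] == NULL_CODE) & (pair[:, 1] == NULL_CODE))
            )
            if n_tot == 0 or blank == n_tot:
                rows.append((locus.name, pop, np.nan, n_tot, int(blank), np.nan,
                             include))
                continue
            fr, _ = em_null_frequency(pair, include_blanks=include)
            freqs[(locus.name, pop)] = fr
            nf = float(fr.get(NULL_CODE, 0.0))
            rows.append(
                (locus.name, pop, nf, n_tot, int(blank), n_tot * nf**2, include)
            )
    table = pd.DataFrame(
        rows,
        columns=["locus", "population", "null_freq", "n", "observed_blanks",
                 "expected_blanks", "blank_model"],
    )
    return EmResult(table=table, freqs=freqs)


# ---------------------------------------------------------------------------
# Blank consistency
# ---------------------------------------------------------------------------


def blanks_consistency_test(table: pd.DataFrame) -> pd.DataFrame:
    """One-sided exact binomial test of observed vs expected blanks.

    Under the blanks-as-null-homozygotes model each individual is a blank
    with probability null_freq^2; the alternative is *fewer* observed blanks
    than expected (blanks not explained by nulls would go the other way and
    are tested by the regression diagnostics instead).  Rows are aggregated
    per locus over populations.
    """
    rows = []
    for locus, grp in table.groupby("locus", sort=False):
        grp = grp.dropna(subset=["null_freq"])
        n = int(grp["n"].sum())
        if n == 0:
            rows.append((locus, np.nan, np.nan, np.nan))
            continue
        obs = int(grp["observed_blanks"].sum())
        # pooled success probability: expectation-preserving
        p_null2 = float(grp["expected_blanks"].sum()) / n
        p_null2 = min(max(p_null2, 0.0), 1.0)
        if p_null2 == 0.0 and obs == 0:
            rows.append((locus, 0.0, 0, 1.0))
            continue
        p = stats.binomtest(obs, n, p_null2, alternative="less").pvalue
        rows.append((locus, n * p_null2, obs, float(p)))
    return pd.DataFrame(rows, columns=["locus", "expected", "observed", "binom_p"])


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


@dataclass
class NullAlleleReport:
    """Null-allele evidence for a dataset."""

    em_table: pd.DataFrame  # locus x population null frequencies
    mean_null_freq: pd.Series  # per locus
    blanks_test: pd.DataFrame
    diagnostics: dict


def null_allele_report(
    dataset: GenotypeDataset,
    fstats: FStatsResult | None = None,
    blank_loci: list[str] | None = None,
    exclude_from_regression: list[str] | None = None,
) -> NullAlleleReport:
    """Assemble the full null-allele evidence: EM table, blank-consistency
    tests (BH-adjustable), and the correlation/regression diagnostics."""
    from .fstats import wc_fstats

    if fstats is None:
        fstats = wc_fstats(dataset)
    em = em_null_table(dataset, blank_loci=blank_loci)
    return NullAlleleReport(
        em_table=em.table,
        mean_null_freq=em.mean_null_freq(),
        blanks_test=blanks_consistency_test(em.table),
        diagnostics=null_diagnostics(
            fstats, dataset, exclude_from_regression=exclude_from_regression
        ),
    )


def _spearman_one_sided(x, y, positive: bool = True):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
        return np.nan, np.nan
    res = stats.spearmanr(x[ok], y[ok], alternative="greater" if positive else "less")
    return float(res.statistic), float(res.pvalue)


def null_diagnostics(
    fstats: FStatsResult,
    dataset: GenotypeDataset,
    exclude_from_regression: list[str] | None = None,
) -> dict:
    """Correlation/regression diagnostics for null alleles.

    One-sided (positive) Spearman tests of F_IS ~ F_ST and F_IS ~ N_Blanks
    across loci; OLS regression of F_IS on N_Blanks giving the slope, the
    intercept F_IS_0 (the F_IS expected with no null alleles) and R^2.
    ``exclude_from_regression`` drops loci whose blanks are known not to be
    null homozygotes (negative-F_IS loci with blanks) and re-runs the
    correlation and regression on the remainder.
    """
    per_locus = fstats.per_locus.set_index("locus")
    blanks = dataset.n_blanks()
    loci = [n for n in per_locus.index if per_locus.loc[n, "defined"]]
    fis = np.array([per_locus.loc[n, "fis"] for n in loci])
    fst = np.array([per_locus.loc[n, "fst"] for n in loci])
    nb = np.array([blanks[n] for n in loci], dtype=float)

    out: dict = {"r_ratio": jackknife_se(fstats.components())["r_ratio"]}
    rho, p = _spearman_one_sided(fis, fst)
    out["spearman_fis_fst"] = {"rho": rho, "p": p}
    rho, p = _spearman_one_sided(fis, nb)
    out["spearman_fis_blanks"] = {"rho": rho, "p": p}
    out["regression_fis_blanks"] = _ols(nb, fis)

    if exclude_from_regression:
        keep = [i for i, n in enumerate(loci) if n not in exclude_from_regression]
        rho, p = _spearman_one_sided(fis[keep], nb[keep])
        out["spearman_fis_blanks_excl"] = {"rho": rho, "p": p}
        out["regression_fis_blanks_excl"] = _ols(nb[keep], fis[keep])
        out["excluded"] = list(exclude_from_regression)
    return out


def _ols(x, y) -> dict:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]):
        return {"slope": np.nan, "intercept": np.nan, "r2": np.nan}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
    }


# ---------------------------------------------------------------------------
# ENA-corrected F_ST
# ---------------------------------------------------------------------------


def _ena_components(dataset: GenotypeDataset, em: EmResult):
    """Per-locus WC components with the null class excluded (ENA).

    The genotype table is EM-completed before the variance components are
    taken: per-population allele frequencies come from the EM (visible
    alleles plus null), and apparent homozygotes i/i are split into true
    homozygotes and i/null heterozygotes with the EM posterior weight
    w_i = p_i^2 / (p_i^2 + 2 p_i q), which corrects the per-allele
    heterozygote counts that null alleles deflate.  Components are computed
    over all classes, then the null class's terms are dropped from the
    sums.  When every null frequency at a locus is exactly zero the
    completed table is the observed one and the result equals the
    uncorrected components, bit for bit.
    """
    codes, labels = dataset.population_codes()
    comp_rows = []
    blank_model = {}
    if len(em.table):
        blank_model = {
            (r["locus"], r["population"]): bool(r.get("blank_model", True))
            for _, r in em.table.iterrows()
        }

    for j, locus in enumerate(dataset.loci):
        pair = dataset.alleles[:, j, :]
        blank = (pair[:, 0] == MISSING) | (
            (pair[:, 0] == NULL_CODE) & (pair[:, 1] == NULL_CODE)
        )
        ok = ~blank
        if ok.sum() == 0:
            comp_rows.append((locus.name, 0.0, 0.0, 0.0, False))
            continue
        sub = pair[ok]
        sub_codes = codes[ok]
        vis_alleles = np.unique(sub[sub != NULL_CODE])
        if vis_alleles.size < 2:
            comp_rows.append((locus.name, 0.0, 0.0, 0.0, False))
            continue
        k = vis_alleles.size

        pops_present = np.unique(sub_codes)
        freq = np.zeros((pops_present.size, k + 1))
        n_i = np.zeros(pops_present.size)
        hets = np.zeros((pops_present.size, k + 1))
        for pi, pc in enumerate(pops_present):
            sel = sub_codes == pc
            n_vis = int(sel.sum())
            spair = sub[sel]
            n_blank_pop = int(np.sum(blank & (codes == pc)))
            is_het = spair[:, 0] != spair[:, 1]
            hom_obs = np.zeros(k)
            het_obs = np.zeros(k + 1)
            for row, het_row in zip(spair, is_het):
                for v in row[: 2 if het_row else 1]:
                    ai = k if v == NULL_CODE else int(np.searchsorted(vis_alleles, v))
                    if het_row:
                        het_obs[ai] += 1
                    elif ai < k:
                        hom_obs[ai] += 1

            fr = em.freqs.get((locus.name, labels[pc]))
            q = float(fr.get(NULL_CODE, 0.0)) if fr is not None else 0.0
            if q > 0:
                include = blank_model.get((locus.name, labels[pc]), True)
                n_i[pi] = n_vis + (n_blank_pop if include else 0)
                p_vis = np.array([float(fr.get(u, 0.0)) for u in vis_alleles])
                freq[pi, :k] = p_vis
                freq[pi, k] = q
                with np.errstate(divide="ignore", invalid="ignore"):
                    w_true = np.where(
                        p_vis > 0, p_vis**2 / (p_vis**2 + 2.0 * p_vis * q), 1.0
                    )
                hets[pi, :k] = het_obs[:k] + hom_obs * (1.0 - w_true)
                hets[pi, k] = het_obs[k] + float(np.sum(hom_obs * (1.0 - w_true)))
            else:
                # zero null frequency: observed counts, exactly
                n_i[pi] = n_vis
                vals, counts = np.unique(spair.ravel(), return_counts=True)
                for v, cnt in zip(vals, counts):
                    ai = k if v == NULL_CODE else int(np.searchsorted(vis_alleles, v))
                    freq[pi, ai] = cnt / (2.0 * n_vis)
                hets[pi] = het_obs

        N = n_i.sum()
        r = pops_present.size
        nbar = N / r
        if r < 2 or nbar <= 1:
            comp_rows.append((locus.name, 0.0, 0.0, 0.0, False))
            continue
        nc = (N - (n_i**2).sum() / N) / (r - 1.0)
        pbar = (n_i[:, None] * freq).sum(axis=0) / N
        s2 = (n_i[:, None] * (freq - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = hets.sum(axis=0) / N
        term = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = (nbar / nc) * (s2 - (term - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (term - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        # ENA: drop the null class from the sums
        comp_rows.append(
            (locus.name, a[:k].sum(), b[:k].sum(), c[:k].sum(), True)
        )
    return pd.DataFrame(comp_rows, columns=["locus", "a", "b", "c", "defined"])


def fst_ena(
    dataset: GenotypeDataset,
    em: EmResult | None = None,
    blank_loci: list[str] | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
) -> dict:
    """ENA-corrected multilocus F_ST with a bootstrap-over-loci CI.

    ``em`` is the EM result (computed if omitted).  When all null
    frequencies are zero this equals the uncorrected Weir-Cockerham F_ST on
    the same data.
    """
    if em is None:
        em = em_null_table(dataset, blank_loci=blank_loci)
    comp = _ena_components(dataset, em)
    d = comp[comp["defined"]]
    per_locus = {}
    for _, row in d.iterrows():
        _, fst, _ = _ratios(row["a"], row["b"], row["c"])
        per_locus[row["locus"]] = fst
    _, fst_all, _ = _ratios(d["a"].sum(), d["b"].sum(), d["c"].sum())
    from .fstats import bootstrap_ci

    ci = bootstrap_ci(
        d[["a", "b", "c"]].to_numpy(), statistic="fst", n_boot=n_boot, seed=seed
    )
    return {
        "fst_per_locus": per_locus,
        "fst_multilocus": fst_all,
        "ci_95": ci,
        "components": d[["a", "b", "c"]].to_numpy(),
        "loci": list(d["locus"]),
        "em_table": em,
    }
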