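"""Individual-level genetic distances, trees, and standardized differentiation.

Cavalli-Sforza & Edwards' chord distance compares allele-frequency profiles
on the unit sphere; for individuals the per-locus profile is the genotype
vector (0, 0.5 or 1 per allele).  The INA ("including null alleles")
correction inserts the EM-estimated null frequency as an extra allele class
in each profile at affected loci, damping the artefactual distance inflation
that apparent homozygotes cause.

The chord distance per locus is

    d_l(x, y) = (2 / pi) * sqrt( 2 * (1 - sum_i sqrt(x_i * y_i)) )

and individual distances average d_l over the loci typed in both
individuals (this normalization matches Cavalli-Sforza & Edwards 1967 as
used for null-corrected distances; conventions differ across software, so
it is stated explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .fstats import _ratios
from .genotype_io import MISSING, NULL_CODE, GenotypeDataset
from .null_alleles import EmResult, em_null_table, fst_ena

__all__ = [
    "DistanceMatrix",
    "StandardizedFst",
    "chord_distance_ina",
    "nj_tree",
    "diagnostic_alleles",
    "fst_standardized",
]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def chord_distance_ina(
    dataset: GenotypeDataset,
    em: EmResult | None = None,
    blank_loci: list[str] | None = None,
    correct: bool = True,
) -> DistanceMatrix:
    """Chord distance between individuals, null-corrected (INA).

    At a locus where the EM null frequency for an individual's population is
    q > 0, the individual's profile over visible alleles is scaled by
    (1 - q) and a null class with mass q is appended, so two apparent
    homozygotes are no longer treated as identical with certainty.  Blanks
    (and explicit 999999 homozygotes) at such loci are profiles concentrated
    on the null class.  Loci with q = 0 are untouched.  Pairs sharing no
    typed locus get NaN.  ``correct=False`` computes the plain chord
    distance (all q = 0).
    """
    if not correct:
        em = EmResult(table=pd.DataFrame(
            columns=["locus", "population", "null_freq", "n",
                     "observed_blanks", "expected_blanks"]), freqs={})
    elif em is None:
        em = em_null_table(dataset, blank_loci=blank_loci)
    codes, labels = dataset.population_codes()
    n = dataset.n_individuals
    L = len(dataset.loci)

    # per locus: matrix of profiles (n x k+1) and typed mask
    dist_sum = np.zeros((n, n))
    dist_cnt = np.zeros((n, n))
    for j, locus in enumerate(dataset.loci):
        pair = dataset.alleles[:, j, :]
        vis = np.unique(pair[(pair != MISSING) & (pair != NULL_CODE)])
        if vis.size == 0:
            continue
        k = vis.size
        prof = np.zeros((n, k + 1))
        typed = np.zeros(n, dtype=bool)
        q_by_pop = {}
        for c, lab in enumerate(labels):
            fr = em.freqs.get((locus.name, lab))
            q_by_pop[c] = float(fr.get(NULL_CODE, 0.0)) if fr is not None else 0.0
        for i in range(n):
            a, b = pair[i]
            q = q_by_pop[codes[i]]
            if a == MISSING or (a == NULL_CODE and b == NULL_CODE):
                if q > 0:
                    prof[i, k] = 1.0
                    typed[i] = True
                continue
            typed[i] = True
            for v in (a, b):
                prof[i, int(np.searchsorted(vis, v))] += 0.5
            if q > 0:
                prof[i, :k] *= 1.0 - q
                prof[i, k] = q
        # chord distance between all typed pairs at this locus
        root = np.sqrt(prof[typed])
        cos = root @ root.T
        np.clip(cos, 0.0, 1.0, out=cos)
        d = (2.0 / np.pi) * np.sqrt(2.0 * (1.0 - cos))
        idx = np.flatnonzero(typed)
        dist_sum[np.ix_(idx, idx)] += d
        dist_cnt[np.ix_(idx, idx)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        values = dist_sum / dist_cnt
    values[dist_cnt == 0] = np.nan
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=list(dataset.individuals["id"]), values=values)


def nj_tree(matrix: DistanceMatrix):
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Negative branch lengths are set to zero with the difference moved to the
    adjacent branch.  Returns a ``skbio.TreeNode``; serialize with
    ``str(tree)`` or ``tree.write(path)`` (Newick).
    """
    if len(matrix.labels) < 3:
        raise ValueError("need >= 3 labels")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("distance matrix has undefined entries")
    dm = _SkbioDM(matrix.values, ids=[str(l) for l in matrix.labels])
    return _skbio_nj(dm)


def diagnostic_alleles(
    dataset: GenotypeDataset, group_a: np.ndarray, group_b: np.ndarray
) -> pd.DataFrame:
    """Alleles private to each of two disjoint individual groups.

    ``group_a``/``group_b`` are boolean masks over individuals.  A locus is
    ``diagnostic`` when every typed individual in both groups carries at
    least one private allele of its own group, i.e. the genotype alone
    classifies it.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if not group_a.any() or not group_b.any():
        raise ValueError("empty group")
    if np.any(group_a & group_b):
        raise ValueError("groups overlap")
    rows = []
    for j, locus in enumerate(dataset.loci):
        pair = dataset.alleles[:, j, :]

        def observed(mask):
            sub = pair[mask]
            sub = sub[(sub[:, 0] != MISSING)]
            return set(int(v) for v in np.unique(sub)) - {NULL_CODE}

        seen_a, seen_b = observed(group_a), observed(group_b)
        priv_a = sorted(seen_a - seen_b)
        priv_b = sorted(seen_b - seen_a)

        def classifiable(mask, private):
            sub = pair[mask]
            sub = sub[sub[:, 0] != MISSING]
            if sub.shape[0] == 0:
                return False
            return bool(np.all(np.isin(sub, list(private)).any(axis=1)))

        diagnostic = (
            bool(priv_a) and bool(priv_b)
            and classifiable(group_a, priv_a)
            and classifiable(group_b, priv_b)
        )
        rows.append((locus.name, priv_a, priv_b, diagnostic))
    return pd.DataFrame(
        rows, columns=["locus", "private_a", "private_b", "diagnostic"]
    )


# ---------------------------------------------------------------------------
# Standardized F'ST
# ---------------------------------------------------------------------------


@dataclass
class StandardizedFst:
    fst_freena: float
    fst_max: float
    fst_prime: float
    ci_95: tuple[float, float]
    per_locus: pd.DataFrame


def _recode_private(dataset: GenotypeDataset) -> GenotypeDataset:
    """Meirmans recoding: relabel each population's alleles so that no
    allele is shared between populations (maximal differentiation given the
    within-population structure).  Blanks and the reserved null code are
    left untouched."""
    out = dataset.copy()
    codes, labels = out.population_codes()
    for j in range(len(out.loci)):
        pair = out.alleles[:, j, :]
        for pi in range(len(labels)):
            sel = (codes == pi)[:, None] & (pair != MISSING) & (pair != NULL_CODE)
            # unique code: size * n_pops + pop index keeps sizes distinct per pop
            pair[sel] = pair[sel] * len(labels) + pi
        out.alleles[:, j, :] = np.sort(pair, axis=1)
    return out


def _recode_em(em: EmResult, labels: list[str]) -> EmResult:
    """EM result under Meirmans recoding: same estimates, relabeled."""
    r = len(labels)
    pop_index = {lab: i for i, lab in enumerate(labels)}
    freqs = {}
    for (locus, pop), fr in em.freqs.items():
        pi = pop_index[pop]
        new_idx = [v if v == NULL_CODE else v * r + pi for v in fr.index]
        freqs[(locus, pop)] = pd.Series(fr.to_numpy(), index=new_idx)
    return EmResult(table=em.table, freqs=freqs)


def fst_standardized(
    dataset: GenotypeDataset,
    em: EmResult | None = None,
    blank_loci: list[str] | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
) -> StandardizedFst:
    """Standardized differentiation F'ST = F_ST(ENA) / F_ST_max.

    F_ST_max is the ENA-corrected multilocus F_ST after recoding the data so
    populations share no alleles (the maximum achievable divergence given
    the observed within-population diversity); using the same null-allele
    correction in numerator and denominator keeps the ratio exactly 1 for
    populations that already share nothing, and reduces to the plain
    Weir-Cockerham maximum when all null frequencies are zero.  The ratio's
    CI is a bootstrap over loci pairing each locus's corrected and maximal
    components.
    """
    if em is None:
        em = em_null_table(dataset, blank_loci=blank_loci)
    ena = fst_ena(dataset, em=em, n_boot=0, seed=seed)
    recoded = _recode_private(dataset)
    from .null_alleles import _ena_components

    max_df = _ena_components(
        recoded, _recode_em(em, dataset.population_labels)
    )
    max_comp = max_df.set_index("locus")

    rows = []
    for locus, (a, b, c) in zip(ena["loci"], ena["components"]):
        if locus not in max_comp.index or not max_comp.loc[locus, "defined"]:
            continue
        rows.append(
            (locus, a, b, c, max_comp.loc[locus, "a"], max_comp.loc[locus, "b"],
             max_comp.loc[locus, "c"])
        )
    tab = pd.DataFrame(
        rows, columns=["locus", "a_ena", "b_ena", "c_ena", "a_max", "b_max", "c_max"]
    )
    if tab.empty:
        return StandardizedFst(np.nan, np.nan, np.nan, (np.nan, np.nan), tab)

    comp = tab[["a_ena", "b_ena", "c_ena", "a_max", "b_max", "c_max"]].to_numpy()

    def prime(sums: np.ndarray) -> tuple[float, float, float]:
        _, f_ena, _ = _ratios(sums[0], sums[1], sums[2])
        _, f_max, _ = _ratios(sums[3], sums[4], sums[5])
        ratio = f_ena / f_max if np.isfinite(f_max) and f_max != 0 else np.nan
        return f_ena, f_max, ratio

    f_ena, f_max, ratio = prime(comp.sum(axis=0))
    rng = np.random.default_rng(seed)
    ci = (np.nan, np.nan)
    L = len(tab)
    if L >= 2 and n_boot > 0:
        idx = rng.integers(0, L, size=(n_boot, L))
        sums = comp[idx].sum(axis=1)  # (n_boot, 6)
        with np.errstate(divide="ignore", invalid="ignore"):
            fe = sums[:, 0] / (sums[:, 0] + sums[:, 1] + sums[:, 2])
            fm = sums[:, 3] / (sums[:, 3] + sums[:, 4] + sums[:, 5])
            rb = fe / fm
        rb = rb[np.isfinite(rb)]
        if rb.size:
            ci = tuple(float(v) for v in np.percentile(rb, [2.5, 97.5]))
    return StandardizedFst(
        fst_freena=f_ena, fst_max=f_max, fst_prime=ratio, ci_95=ci, per_locus=tab
    )
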