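"""Effective size, migration and dispersal calculus.

Two effective-size estimators are provided:

* ``ne_from_fis`` — a heterozygote-excess method: in a dioecious population
  of effective size Ne, random union of distinct parents produces a small
  expected heterozygote *excess*, F_IS ~ -1/(2Ne); inverting gives
  Ne = -1/(2 F_IS) - F_IS / (2 (1 + F_IS)), applicable only to loci with
  negative F_IS.
* ``ne_ld`` — the linkage-disequilibrium method (Burrows composite
  correlation between unlinked locus pairs, sample-size bias subtracted,
  random mating assumed), with a low-frequency allele cutoff and a
  missing-data adjustment through pairwise sample sizes.

Migration uses the infinite island model at equilibrium:
Nem = (1 - F'ST) / (4 F'ST) effective immigrants per generation, from the
standardized differentiation F'ST.  The immigration rate is m = Nem / Ne
and the dispersal distance per generation is delta = m x D_geo, with
geographic distances on the WGS84 ellipsoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, NULL_CODE, GenotypeDataset
from .pop_structure import DistanceMatrix

__all__ = [
    "DemographyEstimates",
    "ne_from_fis",
    "ne_ld",
    "nem_from_fst",
    "geodesic_km",
    "dispersal",
]


# ---------------------------------------------------------------------------
# Ne
# ---------------------------------------------------------------------------


def ne_from_fis(fis_per_locus: dict | pd.Series) -> dict:
    """Heterozygote-excess Ne per locus and mean.

    Only loci with F_IS < 0 carry the signal (positive F_IS is dominated by
    null alleles and other artifacts); others are skipped and logged.
    """
    if isinstance(fis_per_locus, pd.Series):
        fis_per_locus = fis_per_locus.to_dict()
    per_locus, skipped = {}, []
    for name, fis in fis_per_locus.items():
        if fis is None or not np.isfinite(fis) or fis >= 0:
            skipped.append(name)
            continue
        per_locus[name] = -1.0 / (2.0 * fis) - fis / (2.0 * (1.0 + fis))
    mean = float(np.mean(list(per_locus.values()))) if per_locus else np.nan
    return {"per_locus": per_locus, "mean": mean, "skipped": skipped}


def _burrows_r2(pair1: np.ndarray, pair2: np.ndarray, pcrit: float):
    """Mean squared Burrows composite correlation between two loci.

    Returns (weighted sum of r^2, weighted sum of E[r^2 | drift-free],
    total weight, harmonic-sample-size contribution) over allele pairs with
    both frequencies above ``pcrit``; individuals missing either locus are
    dropped (the missing-data adjustment: S is pairwise).
    """
    ok = (pair1[:, 0] != MISSING) & (pair2[:, 0] != MISSING)
    ok &= (pair1[:, 0] != NULL_CODE) & (pair2[:, 0] != NULL_CODE)
    g1, g2 = pair1[ok], pair2[ok]
    S = g1.shape[0]
    if S < 10:
        return 0.0, 0.0, 0, S

    def usable(g):
        vals, counts = np.unique(g.ravel(), return_counts=True)
        p = counts / counts.sum()
        keep = (p >= pcrit) & (p <= 1 - pcrit)
        return vals[keep], dict(zip(vals, p))

    a1, p1 = usable(g1)
    a2, p2 = usable(g2)
    if a1.size < 1 or a2.size < 1:
        return 0.0, 0.0, 0, S
    # drop one allele per locus to avoid the redundant (compositional) df
    if a1.size > 1:
        a1 = a1[:-1]
    if a2.size > 1:
        a2 = a2[:-1]

    if S >= 30:
        exp_r2 = 1.0 / S + 3.19 / S**2
    else:
        exp_r2 = 0.0018 + 0.907 / S + 4.44 / S**2

    sum_r2 = 0.0
    n_pairs = 0
    x1 = {u: (g1 == u).sum(axis=1).astype(float) for u in a1}
    x2 = {v: (g2 == v).sum(axis=1).astype(float) for v in a2}
    for u in a1:
        for v in a2:
            xu, xv = x1[u], x2[v]
            pu, pv = np.mean(xu) / 2.0, np.mean(xv) / 2.0
            # Burrows composite disequilibrium and Weir's composite
            # variances v = E[x^2]/2 - 2 p^2 = p(1-p) + D_A
            d = (S / (S - 1.0)) * (np.mean(xu * xv) / 2.0 - 2.0 * pu * pv)
            vu = np.mean(xu**2) / 2.0 - 2.0 * pu**2
            vv = np.mean(xv**2) / 2.0 - 2.0 * pv**2
            if vu <= 0 or vv <= 0:
                continue
            sum_r2 += d**2 / (vu * vv)
            n_pairs += 1
    return sum_r2, exp_r2 * n_pairs, n_pairs, S


def ne_ld(dataset: GenotypeDataset, pcrit: float = 0.05,
          population: str | None = None) -> dict:
    """LD-based effective size for one population.

    Unlinked loci in a closed population of size Ne carry r^2 above the
    pure-sampling expectation by ~1/(3Ne); after subtracting the sampling
    expectation the random-mating quadratic inversion gives Ne.  Alleles
    rarer than ``pcrit`` are dropped; sample size is pairwise (individuals
    typed at both loci), which is the missing-data adjustment.  Negative
    drift signal yields an infinite estimate (flagged).  The parametric CI
    treats the allele-pair comparisons as chi-square degrees of freedom.
    """
    if population is not None:
        mask = (dataset.individuals["population"] == population).to_numpy()
        dataset = dataset.subset_individuals(mask)
    L = len(dataset.loci)
    if L < 2:
        raise ValueError("need >= 2 loci")

    tot_r2 = tot_exp = 0.0
    tot_pairs = 0
    s_list = []
    for j1, j2 in combinations(range(L), 2):
        r2, e2, npair, S = _burrows_r2(
            dataset.alleles[:, j1, :], dataset.alleles[:, j2, :], pcrit
        )
        if npair == 0:
            continue
        tot_r2 += r2
        tot_exp += e2
        tot_pairs += npair
        s_list.extend([S] * npair)
    if tot_pairs == 0:
        return {"ne": np.nan, "ci": (np.nan, np.nan), "flag": "undefined",
                "r2_mean": np.nan, "n_comparisons": 0}

    r2_mean = tot_r2 / tot_pairs
    exp_mean = tot_exp / tot_pairs
    S_harm = len(s_list) / np.sum(1.0 / np.asarray(s_list, dtype=float))
    r2_drift = r2_mean - exp_mean

    def invert(r2d):
        if r2d <= 0:
            return float("inf")
        if S_harm >= 30:
            disc = 1.0 / 9.0 - 2.76 * r2d
            if disc < 0:
                return float("inf") if r2d < 0 else max(
                    (1.0 / 3.0) / (2.0 * r2d), 0.0
                )
            return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2d)
        disc = 0.308**2 - 2.08 * r2d
        if disc < 0:
            return max(0.308 / (2.0 * r2d), 0.0)
        return (0.308 + np.sqrt(disc)) / (2.0 * r2d)

    ne = invert(r2_drift)
    # parametric CI: chi-square on the number of comparisons
    df = tot_pairs
    lo_r2 = r2_mean * df / stats.chi2.ppf(0.975, df)
    hi_r2 = r2_mean * df / stats.chi2.ppf(0.025, df)
    ci = (invert(lo_r2 - exp_mean), invert(hi_r2 - exp_mean))
    ci = (min(ci), max(ci))
    return {
        "ne": float(ne),
        "ci": (float(ci[0]), float(ci[1])),
        "flag": "infinite" if np.isinf(ne) else "ok",
        "r2_mean": float(r2_mean),
        "expected_r2": float(exp_mean),
        "n_comparisons": int(tot_pairs),
        "harmonic_s": float(S_harm),
    }


# ---------------------------------------------------------------------------
# Migration
# ---------------------------------------------------------------------------


def nem_from_fst(fst_prime: float) -> float:
    """Effective immigrants per generation under the infinite island model:
    Nem = (1 - F'ST) / (4 F'ST).  Undefined (infinite) for F'ST <= 0."""
    if not np.isfinite(fst_prime) or fst_prime <= 0:
        return float("inf")
    if fst_prime > 1:
        raise ValueError("F'ST must be <= 1")
    return (1.0 - fst_prime) / (4.0 * fst_prime)


# ---------------------------------------------------------------------------
# Geodesics (WGS84)
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563


def _vincenty_m(lat1, lon1, lat2, lon2, tol=1e-12, max_iter=200) -> float:
    """Vincenty inverse geodesic distance in metres on the WGS84 ellipsoid."""
    a, f = _WGS84_A, _WGS84_F
    b = (1.0 - f) * a
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1, U2 = np.arctan((1 - f) * np.tan(phi1)), np.arctan((1 - f) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)
    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sm = (
            cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        )
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1.0 + 2.0 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    u2 = cos2_alpha * (a**2 - b**2) / b**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    dsig = B * sin_sigma * (
        cos_2sm
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sm**2)
            - B / 6.0 * cos_2sm * (-3.0 + 4.0 * sin_sigma**2)
            * (-3.0 + 4.0 * cos_2sm**2)
        )
    )
    return float(b * A * (sigma - dsig))


def geodesic_km(coords: dict) -> DistanceMatrix:
    """Pairwise WGS84 geodesic distances in km.

    ``coords`` maps label -> (lat, lon) decimal degrees; labels with None
    coordinates are omitted (flagged by their absence from the output).
    """
    labels = [k for k, v in coords.items() if v is not None]
    for lab in labels:
        lat, lon = coords[lab]
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"{lab}: invalid coordinates ({lat}, {lon})")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _vincenty_m(*coords[labels[i]], *coords[labels[j]]) / 1000.0
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Dispersal
# ---------------------------------------------------------------------------


@dataclass
class DemographyEstimates:
    ne_fis: dict
    ne_ld: dict
    ne_summary: dict  # per method: {"avg", "min", "max"}; plus grand average
    nem: float
    nem_ci: tuple[float, float]
    m: dict
    dgeo: DistanceMatrix | None
    delta: dict
    yearly_migrants: float
    generations_per_year: int


def dispersal(
    nem: float,
    ne_summary: dict,
    dgeo: DistanceMatrix | None,
    generations_per_year: int = 12,
) -> dict:
    """Immigration rate m = Nem / Ne and dispersal delta = m x D_geo.

    ``ne_summary`` must carry ``avg``/``min``/``max`` Ne values; m and
    delta are reported for each.  ``delta`` covers every subsample pair and
    the mean pairwise distance; ``yearly_migrants`` = Nem x generations per
    year.  Ne -> infinity sends m and delta to 0.
    """
    out: dict = {"m": {}, "delta": {}, "yearly_migrants": nem * generations_per_year}
    for key in ("min", "avg", "max"):
        ne = ne_summary.get(key)
        if ne is None or not np.isfinite(ne) and not np.isinf(ne):
            out["m"][key] = np.nan
            continue
        if ne == 0:
            out["m"][key] = np.nan
        elif np.isinf(ne):
            out["m"][key] = 0.0
        else:
            out["m"][key] = nem / ne
    if dgeo is not None and len(dgeo.labels) >= 2:
        n = len(dgeo.labels)
        iu = np.triu_indices(n, 1)
        pair_d = dgeo.values[iu]
        mean_d = float(pair_d.mean())
        for key, m in out["m"].items():
            if not np.isfinite(m):
                out["delta"][key] = {"mean": np.nan, "pairs": {}}
                continue
            pairs = {
                f"{dgeo.labels[i]}~{dgeo.labels[j]}": float(m * dgeo.values[i, j])
                for i, j in zip(*iu)
            }
            out["delta"][key] = {"mean": m * mean_d, "pairs": pairs}
        out["mean_dgeo_km"] = mean_d
    return out
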