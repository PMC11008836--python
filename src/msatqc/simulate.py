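"""Synthetic genotype datasets with controlled structure and artifacts.

The generator draws an island-model multi-population sample under the
Balding-Nichols construction: ancestral allele frequencies from a symmetric
Dirichlet, per-population frequencies from Dirichlet(p * (1 - F) / F) with
F the target F_ST, and genotypes at Hardy-Weinberg equilibrium within
populations.  Allele states map to fragment sizes on the motif lattice
(adapter tail included), so repeat-step arithmetic works exactly as on
real fragment calls.

Genotyping artifacts are injected post hoc, each with its generative model:

* null alleles — a hidden allele at frequency q per locus x population;
  visible/null heterozygotes are recorded as visible homozygotes and
  null/null as missing;
* stuttering — heterozygotes one motif step apart miscalled as homozygous
  for the longer allele with a fixed probability;
* short-allele dominance — in heterozygotes the longer allele drops with
  probability min(1, strength x size difference in bp), recording a
  short-allele homozygote;
* random technical missingness, applied last;
* sex linkage — at chosen loci females (the heterogametic sex here) carry
  one copy and are recorded as homozygous.

A discrete Wright-Fisher mode provides drift/LD structure for
effective-size estimator checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, Locus

__all__ = [
    "SimulationConfig",
    "simulate_dataset",
    "inject_artifacts",
    "reference_fixture",
    "wright_fisher_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the field-study layout this package models: three
    subsamples of 24 moths (12 female / 12 male), 11 dinucleotide-dominated
    loci, allele sizes in the 130-310 bp range including the 19 bp adapter
    tail.
    """

    n_pops: int = 3
    n_per_pop: int = 24
    sex_ratio: float = 0.5  # fraction female
    n_loci: int = 11
    motifs: list[str] | None = None  # default: 8 "AC" + 3 "CCG"
    allele_size_range: tuple[int, int] = (130, 310)
    target_fst: float = 0.05
    ancestral_allele_count: int = 12
    dirichlet_alpha: float = 1.0
    null_freq: float | dict = 0.0  # per locus name or scalar
    stutter_rate: float = 0.0
    sad_strength: float = 0.0  # dropout prob per bp of size difference
    missing_rate: float = 0.0
    sex_linked_loci: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in ("stutter_rate", "sad_strength", "missing_rate", "sex_ratio"):
            v = getattr(self, r)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{r} must be in [0, 1]")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        if self.motifs is None:
            base = ["AC"] * self.n_loci
            for i in range(2, self.n_loci, 4):
                base[i] = "CCG"
            self.motifs = base


#: Visible stand-in for the hidden null allele in the full-system truth
#: genotypes recorded by :func:`inject_artifacts` (distinct from the
#: dataset-level reserved ``NULL_CODE``).
TRUTH_NULL = 888888


@dataclass
class TruthRecord:
    """Latent parameters behind a simulated dataset."""

    config: SimulationConfig
    ancestral_freqs: dict  # locus -> Series allele size -> freq
    pop_freqs: dict  # (locus, pop) -> Series
    null_freq: dict  # locus -> {pop code -> realized q}
    true_genotypes: np.ndarray | None = None  # pre-artifact alleles
    full_system_alleles: np.ndarray | None = None  # null visible as TRUTH_NULL


def _locus_sizes(rng, motif_len: int, k: int, size_range, adapter: int = 19):
    """k allele sizes on the motif lattice inside the size range.

    Stepwise mutation keeps real microsatellite ladders near-contiguous, so
    consecutive alleles are mostly one repeat apart with occasional
    two-repeat gaps.
    """
    lo, hi = size_range
    steps = rng.choice([1, 2], size=k - 1, p=[0.8, 0.2]) if k > 1 else np.array([], int)
    offsets = np.concatenate([[0], np.cumsum(steps)])
    span = (hi - lo) // motif_len
    if offsets[-1] > span:
        raise ValueError("size range too narrow for allele count")
    start = int(rng.integers(0, span - offsets[-1] + 1))
    base = lo + int(rng.integers(0, motif_len))
    return np.sort(base + (start + offsets) * motif_len)


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeDataset, TruthRecord]:
    """Draw an island-model dataset (no artifacts; see
    :func:`inject_artifacts`)."""
    rng = np.random.default_rng(config.seed)
    F = config.target_fst
    loci = [
        Locus(name=f"L{j + 1:02d}", motif=m)
        for j, m in enumerate(config.motifs[: config.n_loci])
    ]
    n_total = config.n_pops * config.n_per_pop
    pops = [f"pop{i + 1}" for i in range(config.n_pops)]

    ids, pop_col, sex_col = [], [], []
    for pi, pop in enumerate(pops):
        n_f = int(round(config.n_per_pop * config.sex_ratio))
        for i in range(config.n_per_pop):
            ids.append(f"{pop}_{i + 1:03d}")
            pop_col.append(pop)
            sex_col.append("female" if i < n_f else "male")
    individuals = pd.DataFrame({"id": ids, "population": pop_col, "sex": sex_col})

    alleles = np.zeros((n_total, len(loci), 2), dtype=np.int64)
    anc_freqs, pop_freqs = {}, {}
    for j, locus in enumerate(loci):
        sizes = _locus_sizes(
            rng, locus.motif_length, config.ancestral_allele_count,
            config.allele_size_range,
        )
        p_anc = rng.dirichlet([config.dirichlet_alpha] * sizes.size)
        anc_freqs[locus.name] = pd.Series(p_anc, index=sizes)
        for pi, pop in enumerate(pops):
            if F > 0:
                p_pop = rng.dirichlet(p_anc * (1.0 - F) / F)
            else:
                p_pop = p_anc
            pop_freqs[(locus.name, pop)] = pd.Series(p_pop, index=sizes)
            rows = slice(pi * config.n_per_pop, (pi + 1) * config.n_per_pop)
            draws = rng.choice(sizes, size=(config.n_per_pop, 2), p=p_pop)
            alleles[rows, j, :] = draws

    dataset = GenotypeDataset(loci, individuals, alleles)
    truth = TruthRecord(
        config=config,
        ancestral_freqs=anc_freqs,
        pop_freqs=pop_freqs,
        null_freq={},
        true_genotypes=dataset.alleles.copy(),
    )
    return dataset, truth


def inject_artifacts(
    dataset: GenotypeDataset, truth: TruthRecord, config: SimulationConfig | None = None
) -> GenotypeDataset:
    """Apply the configured genotyping artifacts to a clean dataset.

    Order: sex linkage, null alleles, stuttering, SAD, random missingness.
    Artifacts never act on already-missing genotypes.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1_000_003)
    out = dataset.copy()
    n, L, _ = out.alleles.shape
    female = (out.individuals["sex"] == "female").to_numpy()
    motif_len = np.array([loc.motif_length for loc in out.loci])

    for j, locus in enumerate(out.loci):
        if locus.name in config.sex_linked_loci:
            # females hemizygous: one copy read as homozygous
            keep = rng.integers(0, 2, size=n)
            vals = out.alleles[np.arange(n), j, keep]
            out.alleles[female, j, 0] = vals[female]
            out.alleles[female, j, 1] = vals[female]

    # null alleles: a hidden allele whose per-population frequency varies
    # across populations like any other allele (Balding-Nichols marginal
    # Beta around the ancestral null frequency)
    codes, _ = out.population_codes()
    F = config.target_fst
    full_alleles = out.alleles.copy()
    for j, locus in enumerate(out.loci):
        q = (
            config.null_freq.get(locus.name, 0.0)
            if isinstance(config.null_freq, dict)
            else config.null_freq
        )
        if q <= 0:
            truth.null_freq[locus.name] = {}
            continue
        q_pop = {}
        carrier = np.zeros((n, 2), dtype=bool)
        for pc in np.unique(codes):
            if 0 < F < 1:
                qp = float(rng.beta(q * (1 - F) / F, (1 - q) * (1 - F) / F))
            else:
                qp = q
            q_pop[int(pc)] = qp
            sel = codes == pc
            carrier[sel] = rng.random((int(sel.sum()), 2)) < qp
        truth.null_freq[locus.name] = q_pop
        fp = full_alleles[:, j, :]
        fp[carrier & (fp[:, 0] != MISSING)[:, None]] = TRUTH_NULL
        pair = out.alleles[:, j, :]
        ok = pair[:, 0] != MISSING
        both = carrier.all(axis=1) & ok
        one = carrier.any(axis=1) & ~carrier.all(axis=1) & ok
        pair[both] = MISSING
        # visible/null heterozygote: recorded homozygous for the visible one
        vis_idx = np.where(carrier[one][:, 0], 1, 0)
        rows = np.flatnonzero(one)
        vis = pair[rows, vis_idx]
        pair[rows, 0] = vis
        pair[rows, 1] = vis

    truth.full_system_alleles = np.sort(full_alleles, axis=2)

    # stuttering: one-motif-step heterozygotes miscalled as long-homozygote
    if config.stutter_rate > 0:
        for j in range(L):
            pair = out.alleles[:, j, :]
            ok = pair[:, 0] != MISSING
            diff = np.abs(pair[:, 1] - pair[:, 0])
            onestep = ok & (diff == motif_len[j])
            hit = onestep & (rng.random(n) < config.stutter_rate)
            longer = pair[hit].max(axis=1)
            pair[hit, 0] = longer
            pair[hit, 1] = longer

    # SAD: longer allele drops with probability ~ size difference
    if config.sad_strength > 0:
        for j in range(L):
            pair = out.alleles[:, j, :]
            ok = (pair[:, 0] != MISSING) & (pair[:, 0] != pair[:, 1])
            diff = np.abs(pair[:, 1] - pair[:, 0]).astype(float)
            p_drop = np.minimum(1.0, config.sad_strength * diff)
            hit = ok & (rng.random(n) < p_drop)
            shorter = pair[hit].min(axis=1)
            pair[hit, 0] = shorter
            pair[hit, 1] = shorter

    # random technical failures last
    if config.missing_rate > 0:
        miss = rng.random((n, L)) < config.missing_rate
        out.alleles[miss] = MISSING

    out.alleles = np.sort(out.alleles, axis=2)
    return out


def reference_fixture(seed: int = 20240411) -> GenotypeDataset:
    """Golden regression fixture mimicking the study layout.

    3 populations x 24 individuals (12 F / 12 M) plus one related outgroup
    population of 22, 11 loci (AC/CCG motifs), moderate differentiation,
    mild null alleles and missingness.  Deterministic for a given seed.
    """
    cfg = SimulationConfig(
        n_pops=3, n_per_pop=24, n_loci=11, target_fst=0.05,
        null_freq=0.08, missing_rate=0.01, seed=seed,
    )
    ds, truth = simulate_dataset(cfg)
    ds = inject_artifacts(ds, truth, cfg)

    # distinct outgroup population of 22 (11 F / 11 M): its own allele pools
    rng = np.random.default_rng(seed + 7)
    n_og = 22
    alleles = np.zeros((n_og, len(ds.loci), 2), dtype=np.int64)
    for j, locus in enumerate(ds.loci):
        sizes = _locus_sizes(rng, locus.motif_length, 8, (131, 311))
        p = rng.dirichlet([1.0] * sizes.size)
        alleles[:, j, :] = rng.choice(sizes, size=(n_og, 2), p=p)
    og = GenotypeDataset(
        loci=ds.loci,
        individuals=pd.DataFrame(
            {
                "id": [f"pop4_{i + 1:03d}" for i in range(n_og)],
                "population": ["pop4"] * n_og,
                "sex": ["female"] * 11 + ["male"] * 11,
            }
        ),
        alleles=alleles,
    )
    combined = GenotypeDataset(
        loci=ds.loci,
        individuals=pd.concat([ds.individuals, og.individuals], ignore_index=True),
        alleles=np.concatenate([ds.alleles, og.alleles], axis=0),
        populations={
            "pop1": (-2.51029, 120.80766),
            "pop2": (3.97197, 100.753445),
            "pop3": (7.14839, 124.85229),
            "pop4": None,
        },
    )
    return combined


def wright_fisher_dataset(
    ne: int,
    n_loci: int = 20,
    n_sample: int = 50,
    generations: int = 100,
    n_alleles: int = 8,
    seed: int = 0,
) -> GenotypeDataset:
    """Discrete Wright-Fisher simulation of one isolated population.

    ``ne`` diploids reproduce with random mating for ``generations``
    (enough for LD among unlinked loci to reach quasi-equilibrium at
    E[r^2] ~ 1/(3Ne) + 1/S); ``n_sample`` individuals are then drawn.
    Used to exercise effective-size estimators.
    """
    rng = np.random.default_rng(seed)
    loci = [Locus(name=f"L{j + 1:02d}", motif="AC") for j in range(n_loci)]
    sizes = [
        _locus_sizes(rng, 2, n_alleles, (130, 310)) for _ in range(n_loci)
    ]
    # population: (ne, n_loci, 2) allele states
    pop = np.stack(
        [
            rng.choice(s, size=(ne, 2), p=rng.dirichlet([2.0] * s.size))
            for s in sizes
        ],
        axis=1,
    )
    for _ in range(generations):
        mothers = rng.integers(0, ne, size=ne)
        fathers = rng.integers(0, ne, size=ne)
        m_g = pop[mothers, :, :]
        f_g = pop[fathers, :, :]
        pick_m = rng.integers(0, 2, size=(ne, n_loci))
        pick_f = rng.integers(0, 2, size=(ne, n_loci))
        child = np.empty_like(pop)
        rows = np.arange(ne)[:, None]
        cols = np.arange(n_loci)[None, :]
        child[:, :, 0] = m_g[rows, cols, pick_m]
        child[:, :, 1] = f_g[rows, cols, pick_f]
        pop = child
    take = rng.choice(ne, size=min(n_sample, ne), replace=False)
    sample = pop[take]
    individuals = pd.DataFrame(
        {
            "id": [f"wf_{i + 1:03d}" for i in range(sample.shape[0])],
            "population": ["wf"] * sample.shape[0],
            "sex": ["unknown"] * sample.shape[0],
        }
    )
    return GenotypeDataset(loci, individuals, np.sort(sample, axis=2))
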