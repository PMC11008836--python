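"""End-to-end analysis pipeline: genotype table in, report bundle out.

Stages, in the order the analysis is meant to run:

1. load (CSV/GenePop) and validate;
2. sex-linkage screen;
3. outlier individuals: INA-corrected chord distances, NJ tree, diagnostic
   alleles between labelled groups;
4. locus QC battery (LD, null alleles, SAD, stuttering, outliers) and
   locus selection;
5. diversity table (N_A, %amplification, size range, H_o, H_s, H_t);
6. ENA-corrected and standardized F_ST;
7. effective sizes, migrants, immigration rate, dispersal.

Every stage is re-runnable on its own through the library functions; the
pipeline records the seed of each stochastic stage so a bundle is
reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import demography as dem
from . import fstats as fs
from . import marker_qc as qc
from . import null_alleles as na
from . import pop_structure as ps
from .genotype_io import MISSING, NULL_CODE, GenotypeDataset

__all__ = ["PipelineConfig", "run_pipeline", "diversity_table"]


@dataclass
class PipelineConfig:
    """Pipeline settings; the defaults are the study-protocol values
    (10,000 permutations, 5,000 bootstraps, BY FDR for the dependent LD
    series, BH elsewhere, 12 generations per year)."""

    n_perm: int = 10_000
    n_boot: int = 5_000
    alpha: float = 0.05
    recode_null_loci: list[str] = field(default_factory=list)
    exclude_individuals: list[str] = field(default_factory=list)
    exclude_loci: list[str] = field(default_factory=list)  # overrides auto QC
    auto_locus_qc: bool = True
    run_sex_screen: bool = True
    run_tree: bool = True
    generations_per_year: int = 12
    pcrit: float = 0.05
    seed: int = 0


def diversity_table(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-locus diversity summary.

    N_A counts distinct visible alleles; %amplification is the non-missing
    fraction; H_o is observed heterozygosity; H_s and H_t are Nei &
    Chesser's sample-size-corrected gene diversities within and across
    subsamples.
    """
    codes, labels = dataset.population_codes()
    r = len(labels)
    rows = []
    for j, locus in enumerate(dataset.loci):
        pair = dataset.alleles[:, j, :]
        vis_mask = pair[:, 0] != MISSING
        n_all = pair.shape[0]
        if vis_mask.sum() == 0:
            rows.append((locus.name, locus.motif, 0.0, None, 0, np.nan, np.nan, np.nan))
            continue
        vis = pair[vis_mask]
        alleles = np.unique(vis[vis != NULL_CODE])
        size_range = (
            f"{alleles.min()}-{alleles.max()}" if alleles.size else None
        )
        # per-pop frequencies and heterozygosity
        n_i, ho_i, sum_p2 = [], [], []
        for pi in range(r):
            sel = (codes == pi) & vis_mask
            sub = pair[sel]
            if sub.shape[0] == 0:
                continue
            n_i.append(sub.shape[0])
            ho_i.append(np.mean(sub[:, 0] != sub[:, 1]))
            vals, counts = np.unique(sub.ravel(), return_counts=True)
            p = counts / counts.sum()
            sum_p2.append(np.sum(p**2))
        n_i = np.asarray(n_i, dtype=float)
        if n_i.size == 0:
            rows.append((locus.name, locus.motif, 0.0, size_range,
                         int(alleles.size), np.nan, np.nan, np.nan))
            continue
        ntilde = n_i.size / np.sum(1.0 / n_i)  # harmonic mean sample size
        ho = float(np.mean(ho_i))
        hs_raw = 1.0 - float(np.mean(sum_p2))
        if ntilde > 1:
            hs = ntilde / (ntilde - 1.0) * (hs_raw - ho / (2.0 * ntilde))
        else:
            hs = np.nan
        # Ht from mean frequencies across subsamples (Nei & Chesser 1983)
        freq_mats = []
        all_vals = np.unique(vis.ravel())
        for pi in range(r):
            sel = (codes == pi) & vis_mask
            sub = pair[sel]
            if sub.shape[0] == 0:
                continue
            vals, counts = np.unique(sub.ravel(), return_counts=True)
            row = np.zeros(all_vals.size)
            row[np.searchsorted(all_vals, vals)] = counts / counts.sum()
            freq_mats.append(row)
        pbar = np.mean(np.vstack(freq_mats), axis=0)
        s = len(freq_mats)
        ht_raw = 1.0 - float(np.sum(pbar**2))
        if s >= 1 and ntilde > 1 and np.isfinite(hs):
            ht = ht_raw + hs / (ntilde * s) - ho / (2.0 * ntilde * s)
        else:
            ht = np.nan
        rows.append(
            (locus.name, locus.motif, 100.0 * vis_mask.mean(), size_range,
             int(alleles.size), ho, hs, ht)
        )
    return pd.DataFrame(
        rows,
        columns=["locus", "motif", "pct_amplification", "size_range", "n_alleles",
                 "ho", "hs", "ht"],
    )


def run_pipeline(dataset: GenotypeDataset, config: PipelineConfig | None = None) -> dict:
    """Run the full analysis; returns the report bundle (JSON-serialisable
    summaries plus the intermediate result objects)."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    bundle: dict = {"config": asdict(config), "stages": {}}

    if config.exclude_individuals:
        keep = ~dataset.individuals["id"].isin(config.exclude_individuals).to_numpy()
        dataset = dataset.subset_individuals(keep)
    bundle["n_individuals"] = dataset.n_individuals
    bundle["n_blanks"] = dataset.n_blanks()

    # 1. sex-linkage screen
    if config.run_sex_screen and dataset.individuals["sex"].isin(
        ["female", "male"]
    ).any():
        screen = fs.sex_linkage_screen(
            dataset, n_perm=max(200, config.n_perm // 10),
            seed=int(rng.integers(2**31 - 1)),
        )
        bundle["sex_screen"] = screen
        bundle["stages"]["sex_screen"] = {
            "flagged": screen.flagged,
            "min_wilcoxon_p": float(np.nanmin(screen.wilcoxon["p"]))
            if len(screen.wilcoxon) and screen.wilcoxon["p"].notna().any()
            else None,
            "min_combined_p": float(np.nanmin(screen.divergence["combined_p"]))
            if screen.divergence["combined_p"].notna().any()
            else None,
        }

    # 2. outlier individuals: chord distances + NJ tree
    em_all = na.em_null_table(dataset, blank_loci=config.recode_null_loci)
    if config.run_tree and dataset.n_individuals >= 3:
        dm = ps.chord_distance_ina(dataset, em=em_all)
        finite = np.all(np.isfinite(dm.values))
        bundle["chord_matrix"] = dm
        if finite:
            tree = ps.nj_tree(dm)
            bundle["nj_newick"] = str(tree).strip()
        bundle["stages"]["tree"] = {"computed": bool(finite)}

    # 3. QC battery and locus selection
    if config.auto_locus_qc and len(dataset.loci) >= 2:
        report = qc.qc_battery(
            dataset,
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            seed=int(rng.integers(2**31 - 1)),
            alpha=config.alpha,
        )
        bundle["qc"] = report
        retained = [l for l in report.retained if l not in config.exclude_loci]
        bundle["stages"]["qc"] = {
            "retained": retained,
            "excluded": report.excluded + list(config.exclude_loci),
            "decisions": report.decisions,
        }
    else:
        retained = [l for l in dataset.locus_names if l not in config.exclude_loci]
        bundle["stages"]["qc"] = {"retained": retained, "excluded": list(config.exclude_loci)}
    selected = dataset.subset_loci(retained)

    # 4. diversity table on the retained loci
    div = diversity_table(selected)
    bundle["diversity"] = div
    bundle["stages"]["diversity"] = {
        "mean_n_alleles": float(div["n_alleles"].mean()) if len(div) else np.nan,
        "mean_ht": float(div["ht"].mean()) if len(div) else np.nan,
    }

    # 5. F-statistics with null recoding where configured
    from .genotype_io import recode_missing_as_null

    recoded = (
        recode_missing_as_null(selected, config.recode_null_loci)
        if config.recode_null_loci
        else selected
    )
    fres = fs.wc_fstats(recoded)
    bundle["fstats"] = fres
    multi = dict(fres.multilocus)
    comp = fres.components()
    multi["fis_ci"] = fs.bootstrap_ci(comp, "fis", n_boot=config.n_boot,
                                      seed=int(rng.integers(2**31 - 1)))
    multi["fst_ci"] = fs.bootstrap_ci(comp, "fst", n_boot=config.n_boot,
                                      seed=int(rng.integers(2**31 - 1)))
    bundle["stages"]["fstats"] = multi

    several_pops = len(dataset.population_labels) >= 2
    if several_pops:
        em_sel = na.em_null_table(recoded, blank_loci=config.recode_null_loci)
        prime = ps.fst_standardized(
            recoded, em=em_sel, n_boot=config.n_boot,
            seed=int(rng.integers(2**31 - 1)),
        )
        bundle["fst_standardized"] = prime
        bundle["stages"]["fst_standardized"] = {
            "fst_freena": prime.fst_freena,
            "fst_max": prime.fst_max,
            "fst_prime": prime.fst_prime,
            "ci_95": prime.ci_95,
        }

    # 6. effective sizes
    ne_fis = dem.ne_from_fis(fres.per_locus.set_index("locus")["fis"])
    ne_estimates: dict = {"fis": ne_fis}
    ld_values = []
    for pop in dataset.population_labels:
        try:
            est = dem.ne_ld(selected, pcrit=config.pcrit, population=pop)
        except ValueError:
            continue
        ne_estimates.setdefault("ld", {})[pop] = est
        if np.isfinite(est["ne"]):
            ld_values.append(est["ne"])
    method_stats = {}
    if np.isfinite(ne_fis["mean"]):
        vals = list(ne_fis["per_locus"].values())
        method_stats["fis"] = {"avg": float(np.mean(vals)), "min": float(np.min(vals)),
                               "max": float(np.max(vals))}
    if ld_values:
        method_stats["ld"] = {"avg": float(np.mean(ld_values)),
                              "min": float(np.min(ld_values)),
                              "max": float(np.max(ld_values))}
    if method_stats:
        ne_summary = {
            k: float(np.mean([m[k] for m in method_stats.values()]))
            for k in ("avg", "min", "max")
        }
    else:
        ne_summary = {"avg": np.nan, "min": np.nan, "max": np.nan}
    ne_summary["per_method"] = method_stats
    bundle["stages"]["ne"] = ne_summary

    # 7. migration and dispersal
    if several_pops and "fst_standardized" in bundle:
        fprime = bundle["fst_standardized"].fst_prime
        nem = dem.nem_from_fst(fprime)
        lo, hi = bundle["fst_standardized"].ci_95
        nem_ci = (dem.nem_from_fst(hi), dem.nem_from_fst(lo))
        coords = {k: v for k, v in dataset.populations.items() if v is not None}
        dgeo = dem.geodesic_km(coords) if len(coords) >= 2 else None
        disp = dem.dispersal(nem, ne_summary, dgeo,
                             generations_per_year=config.generations_per_year)
        bundle["stages"]["demography"] = {
            "nem": nem, "nem_ci": nem_ci, **disp,
            "dgeo_km": dgeo.to_frame().to_dict() if dgeo else None,
        }
        bundle["dgeo"] = dgeo
    return bundle


def bundle_summary_json(bundle: dict) -> str:
    """Machine-readable stage summary of a pipeline bundle."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = {
        "config": bundle.get("config"),
        "n_individuals": bundle.get("n_individuals"),
        "n_blanks": bundle.get("n_blanks"),
        "stages": bundle.get("stages"),
    }
    return json.dumps(payload, indent=2, default=default)
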