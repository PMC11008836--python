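"""Codominant microsatellite genotype datasets: containers, readers, writers.

Alleles are identified by their reported fragment size in base pairs,
including any adapter tail added during PCR (the M13 tail adds 19 bp to
every call in the study design this package targets).  Repeat-unit
arithmetic (stuttering tests, allele pooling) uses the locus motif length.

Missing data (amplification failure, a "blank") is a dataset-level concept
distinct from the reserved null-allele code 999999: a blank *may* be a null
homozygote, and :func:`recode_missing_as_null` makes that interpretation
explicit, per locus, when the analyst decides it is warranted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Sentinel for a missing (blank) genotype in the allele array.
MISSING = -1

#: Reserved allele value for an explicit null allele.
NULL_CODE = 999999

_MISSING_TOKENS = {"", "0", "na", "nan", "none", "-", "?"}

SEXES = ("female", "male", "unknown")


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    ``motif`` is the repeat unit (e.g. ``"AC"``, ``"CCG"``); ``adapter_bp``
    is the constant number of bases added to every reported allele size by
    the labelled adapter tail.
    """

    name: str
    motif: str = "AC"
    expected_size: int | None = None
    adapter_bp: int = 19

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise ValueError(f"locus {self.name}: empty motif")
        if self.adapter_bp < 0:
            raise ValueError(f"locus {self.name}: adapter_bp < 0")

    @property
    def motif_length(self) -> int:
        return len(self.motif)


@dataclass
class GenotypeDataset:
    """Individuals x loci codominant allele-size genotypes with metadata.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)`` (dtype int64) with
    :data:`MISSING` marking blanks; both alleles of a genotype are missing
    or both present, and the pair is unordered (stored sorted).
    ``individuals`` is a DataFrame with columns ``id``, ``population``,
    ``sex``.  ``populations`` maps population label to an optional
    ``(lat, lon)`` in decimal degrees (WGS84).
    """

    loci: list[Locus]
    individuals: pd.DataFrame
    alleles: np.ndarray
    populations: dict[str, tuple[float, float] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n_ind = len(self.individuals)
        if self.alleles.shape != (n_ind, len(self.loci), 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{n_ind} individuals x {len(self.loci)} loci x 2"
            )
        for label in self.individuals["population"].unique():
            if label not in self.populations:
                self.populations[label] = None
        bad_sex = set(self.individuals["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        half = (self.alleles == MISSING).sum(axis=2)
        if np.any(half == 1):
            ind, loc = np.argwhere(half == 1)[0]
            raise ValueError(
                f"single-allele genotype for individual "
                f"{self.individuals['id'].iloc[ind]!r} at locus {self.loci[loc].name!r}"
            )
        if np.any((self.alleles <= 0) & (self.alleles != MISSING)):
            raise ValueError("allele sizes must be positive")
        self.alleles = np.sort(self.alleles, axis=2)  # unordered-pair canonical form
        self.individuals = self.individuals.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def locus_index(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"locus {name!r} not in dataset") from None

    @property
    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for p in self.individuals["population"]:
            if p not in seen:
                seen.append(p)
        return seen

    def population_codes(self) -> tuple[np.ndarray, list[str]]:
        """Integer population code per individual, plus label order."""
        labels = self.population_labels
        lut = {p: i for i, p in enumerate(labels)}
        codes = np.array([lut[p] for p in self.individuals["population"]])
        return codes, labels

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): genotype is blank."""
        return self.alleles[:, :, 0] == MISSING

    def n_blanks(self) -> dict[str, int]:
        """Count of blank genotypes per locus."""
        counts = self.missing_mask().sum(axis=0)
        return dict(zip(self.locus_names, (int(c) for c in counts)))

    # -- transforms --------------------------------------------------------

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            loci=list(self.loci),
            individuals=self.individuals.copy(),
            alleles=self.alleles.copy(),
            populations=dict(self.populations),
        )

    def subset_loci(self, names: list[str]) -> "GenotypeDataset":
        idx = [self.locus_index(n) for n in names]
        return GenotypeDataset(
            loci=[self.loci[i] for i in idx],
            individuals=self.individuals.copy(),
            alleles=self.alleles[:, idx, :].copy(),
            populations=dict(self.populations),
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, dtype=bool)
        sub = self.individuals.loc[mask].reset_index(drop=True)
        pops = {p: self.populations.get(p) for p in sub["population"].unique()}
        return GenotypeDataset(
            loci=list(self.loci),
            individuals=sub,
            alleles=self.alleles[mask].copy(),
            populations=pops,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.loci == other.loci
            and self.individuals[["id", "population", "sex"]].equals(
                other.individuals[["id", "population", "sex"]]
            )
            and np.array_equal(self.alleles, other.alleles)
        )


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Per stratum x locus allele frequencies.

    ``freqs[(stratum, locus_name)]`` is a Series indexed by allele size,
    summing to 1; ``n[(stratum, locus_name)]`` is the number of individuals
    with data.  Strata with no data at a locus are listed in ``empty``.
    """

    freqs: dict[tuple[str, str], pd.Series]
    n: dict[tuple[str, str], int]
    empty: list[tuple[str, str]]

    def alleles(self, locus_name: str) -> np.ndarray:
        sizes: set[int] = set()
        for (_, loc), s in self.freqs.items():
            if loc == locus_name:
                sizes.update(int(a) for a in s.index)
        return np.array(sorted(sizes))


def allele_frequencies(dataset: GenotypeDataset, by: str = "population") -> FrequencyTable:
    """Allele frequencies per stratum (``population``, ``sex`` or ``global``).

    Blanks are excluded from the counts; an explicit :data:`NULL_CODE`
    allele, when present, counts as an ordinary allele.
    """
    if dataset.n_individuals == 0:
        raise ValueError("empty dataset")
    if by == "population":
        strata = dataset.individuals["population"].to_numpy()
    elif by == "sex":
        strata = dataset.individuals["sex"].to_numpy()
    elif by == "global":
        strata = np.array(["all"] * dataset.n_individuals)
    else:
        raise ValueError(f"unknown stratification {by!r}")

    freqs: dict[tuple[str, str], pd.Series] = {}
    n: dict[tuple[str, str], int] = {}
    empty: list[tuple[str, str]] = []
    for stratum in pd.unique(strata):
        sel = strata == stratum
        for j, locus in enumerate(dataset.loci):
            pair = dataset.alleles[sel, j, :]
            ok = pair[:, 0] != MISSING
            n_ok = int(ok.sum())
            key = (str(stratum), locus.name)
            if n_ok == 0:
                empty.append(key)
                continue
            vals, counts = np.unique(pair[ok].ravel(), return_counts=True)
            freqs[key] = pd.Series(counts / counts.sum(), index=vals)
            n[key] = n_ok
    return FrequencyTable(freqs=freqs, n=n, empty=empty)


# ---------------------------------------------------------------------------
# Recoding and pooling
# ---------------------------------------------------------------------------


def recode_missing_as_null(dataset: GenotypeDataset, loci: list[str]) -> GenotypeDataset:
    """Recode blanks as explicit null homozygotes (999999/999999).

    Applied only to the listed loci; the input dataset is not modified.
    """
    out = dataset.copy()
    for name in loci:
        j = out.locus_index(name)
        blank = out.alleles[:, j, 0] == MISSING
        out.alleles[blank, j, :] = NULL_CODE
    return out


def pool_alleles(
    dataset: GenotypeDataset, locus: str, max_step_bases: int = 2
) -> GenotypeDataset:
    """Merge alleles differing by at most ``max_step_bases`` into size classes.

    Classes form by single linkage along the sorted size list and each class
    is relabelled by its smallest member.  This is the remediation step for
    stuttering artifacts (miscalls between one-repeat neighbours).
    """
    out = dataset.copy()
    j = out.locus_index(locus)
    col = out.alleles[:, j, :]
    sizes = np.unique(col[col != MISSING])
    sizes = sizes[sizes != NULL_CODE]
    if sizes.size == 0:
        return out
    # single-linkage chaining on sorted sizes
    class_rep = {int(sizes[0]): int(sizes[0])}
    rep = int(sizes[0])
    for prev, cur in zip(sizes[:-1], sizes[1:]):
        if cur - prev > max_step_bases:
            rep = int(cur)
        class_rep[int(cur)] = rep
    flat = col.ravel()
    pooled = flat.copy()
    for size, r in class_rep.items():
        pooled[flat == size] = r
    out.alleles[:, j, :] = np.sort(pooled.reshape(col.shape), axis=1)
    return out


# ---------------------------------------------------------------------------
# Allele-matrix CSV
# ---------------------------------------------------------------------------


def _parse_allele(token) -> int:
    s = str(token).strip()
    if s.lower() in _MISSING_TOKENS:
        return MISSING
    v = int(float(s))
    if v == 0:
        return MISSING
    return v


def load_schema(path) -> dict:
    """Load a YAML column-mapping schema for :func:`read_allele_matrix`."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_allele_matrix(path, schema: dict) -> GenotypeDataset:
    """Read a one-row-per-individual CSV allele matrix.

    ``schema`` declares the layout rather than sniffing it::

        id: Individual
        population: Population
        sex: Sex                      # optional
        populations: {Indo: [lat, lon], ...}   # optional GPS
        loci:
          Cpb54: {columns: [Cpb54_a, Cpb54_b], motif: AC}
          Cpb62: {column: Cpb62, sep: "/"}     # single "a/b" column

    Blank, ``0`` or ``NA`` cells are missing; a genotype with exactly one
    missing allele is a hard error naming the row.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    id_col = schema.get("id")
    pop_col = schema["population"]
    sex_col = schema.get("sex")

    loci: list[Locus] = []
    allele_cols: list[tuple[str, ...]] = []
    for name, spec in schema["loci"].items():
        loci.append(
            Locus(
                name=name,
                motif=spec.get("motif", "AC"),
                expected_size=spec.get("expected_size"),
                adapter_bp=spec.get("adapter_bp", 19),
            )
        )
        if "columns" in spec:
            a, b = spec["columns"]
            allele_cols.append(("pair", a, b))
        else:
            allele_cols.append(("single", spec["column"], spec.get("sep", "/")))

    n = len(df)
    alleles = np.full((n, len(loci), 2), MISSING, dtype=np.int64)
    for j, (loc, cols) in enumerate(zip(loci, allele_cols)):
        for i in range(n):
            row_name = df[id_col].iloc[i] if id_col else f"row {i + 2}"
            if cols[0] == "pair":
                a = _parse_allele(df[cols[1]].iloc[i])
                b = _parse_allele(df[cols[2]].iloc[i])
            else:
                raw = str(df[cols[1]].iloc[i]).strip()
                if raw.lower() in _MISSING_TOKENS:
                    a = b = MISSING
                else:
                    parts = raw.split(cols[2])
                    if len(parts) != 2:
                        raise ValueError(
                            f"{row_name}, locus {loc.name}: expected two alleles, "
                            f"got {raw!r}"
                        )
                    a, b = _parse_allele(parts[0]), _parse_allele(parts[1])
            if (a == MISSING) != (b == MISSING):
                raise ValueError(
                    f"{row_name}, locus {loc.name}: single-allele entry"
                )
            alleles[i, j] = (a, b)

    ids = df[id_col] if id_col else pd.Series([f"ind{i + 1}" for i in range(n)])
    sexes = (
        df[sex_col].str.strip().str.lower().replace({"f": "female", "m": "male", "": "unknown"})
        if sex_col
        else pd.Series(["unknown"] * n)
    )
    individuals = pd.DataFrame(
        {"id": ids.to_numpy(), "population": df[pop_col].to_numpy(), "sex": sexes.to_numpy()}
    )
    populations: dict[str, tuple[float, float] | None] = {}
    for label, coords in (schema.get("populations") or {}).items():
        populations[label] = tuple(coords) if coords else None
    known = set(individuals["population"].unique())
    declared = set(populations)
    if declared and not known <= declared:
        raise ValueError(f"unknown population label(s): {sorted(known - declared)}")
    return GenotypeDataset(loci, individuals, alleles, populations)


def write_allele_matrix(dataset: GenotypeDataset, path) -> dict:
    """Write the CSV layout read by :func:`read_allele_matrix`.

    Returns the matching schema dict (also serialisable to YAML), making the
    write -> read round trip lossless.
    """
    cols = {"Individual": dataset.individuals["id"],
            "Population": dataset.individuals["population"],
            "Sex": dataset.individuals["sex"]}
    schema: dict = {"id": "Individual", "population": "Population", "sex": "Sex",
                    "populations": {}, "loci": {}}
    for j, loc in enumerate(dataset.loci):
        a = dataset.alleles[:, j, 0].astype(object)
        b = dataset.alleles[:, j, 1].astype(object)
        a[a == MISSING] = ""
        b[b == MISSING] = ""
        cols[f"{loc.name}_a"] = a
        cols[f"{loc.name}_b"] = b
        schema["loci"][loc.name] = {
            "columns": [f"{loc.name}_a", f"{loc.name}_b"],
            "motif": loc.motif,
            "adapter_bp": loc.adapter_bp,
        }
        if loc.expected_size is not None:
            schema["loci"][loc.name]["expected_size"] = loc.expected_size
    for label, gps in dataset.populations.items():
        schema["populations"][label] = list(gps) if gps else None
    pd.DataFrame(cols).to_csv(path, index=False)
    return schema


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------


def write_genepop(dataset: GenotypeDataset, path, digits: int = 3) -> None:
    """Write GenePop format (``digits`` in {2, 3} per allele).

    Allele sizes above the code capacity (notably the 999999 null code) are
    assigned free compact codes; the mapping is embedded in the title line so
    :func:`read_genepop` restores the original sizes.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    cap = 10**digits - 1
    mapping: dict[int, int] = {}
    all_sizes = np.unique(dataset.alleles[dataset.alleles != MISSING])
    used = set(int(s) for s in all_sizes if 0 < s <= cap)
    free = (c for c in range(cap, 0, -1) if c not in used)
    for s in all_sizes:
        s = int(s)
        mapping[s] = s if 0 < s <= cap else next(free)
    inverse = ";".join(f"{v}={k}" for k, v in mapping.items() if v != k)
    title = "msatqc genepop export" + (f" [codes:{inverse}]" if inverse else "")

    lines = [title]
    lines.extend(dataset.locus_names)
    pops = dataset.population_labels
    codes, _ = dataset.population_codes()
    for pi, pop in enumerate(pops):
        lines.append("Pop")
        for i in np.flatnonzero(codes == pi):
            gts = []
            for j in range(len(dataset.loci)):
                a, b = dataset.alleles[i, j]
                if a == MISSING:
                    gts.append("0" * (2 * digits))
                else:
                    gts.append(f"{mapping[int(a)]:0{digits}d}{mapping[int(b)]:0{digits}d}")
            lines.append(f"{dataset.individuals['id'].iloc[i]} ,  " + " ".join(gts))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypeDataset:
    """Read GenePop (4- or 6-digit genotype coding; mixed widths rejected)."""
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    title = raw[0]
    mapping: dict[int, int] = {}
    if "[codes:" in title:
        spec = title.split("[codes:", 1)[1].rstrip("]")
        for pair in spec.split(";"):
            if pair:
                code, size = pair.split("=")
                mapping[int(code)] = int(size)

    locus_names: list[str] = []
    i = 1
    while i < len(raw) and raw[i].strip().lower() != "pop":
        # locus names may be one per line or comma separated
        locus_names.extend(s.strip() for s in raw[i].split(",") if s.strip())
        i += 1
    loci = [Locus(name=n) for n in locus_names]

    ids: list[str] = []
    pops: list[str] = []
    genos: list[list[tuple[int, int]]] = []
    pop_idx = 0
    width: int | None = None
    while i < len(raw):
        line = raw[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        name, _, rest = line.partition(",")
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise ValueError(f"individual {name.strip()!r}: {len(tokens)} genotypes "
                             f"for {len(loci)} loci")
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) not in (4, 6):
                raise ValueError(f"genotype {tok!r}: not 4- or 6-digit coding")
            d = len(tok) // 2
            if width is None:
                width = d
            elif d != width:
                raise ValueError("mixed GenePop coding widths")
            a, b = int(tok[:d]), int(tok[d:])
            a = MISSING if a == 0 else mapping.get(a, a)
            b = MISSING if b == 0 else mapping.get(b, b)
            if (a == MISSING) != (b == MISSING):
                raise ValueError(f"individual {name.strip()!r}: single-allele entry")
            row.append((a, b))
        ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
        genos.append(row)

    individuals = pd.DataFrame({"id": ids, "population": pops,
                                "sex": ["unknown"] * len(ids)})
    alleles = np.array(genos, dtype=np.int64) if genos else np.empty((0, len(loci), 2), np.int64)
    return GenotypeDataset(loci, individuals, alleles)
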