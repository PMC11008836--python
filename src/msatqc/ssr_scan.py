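"""Microsatellite (SSR) discovery: motif scanning and candidate filtering.

Finds maximal perfect tandem runs of di-/tri-nucleotide motifs in an
assembly and pushes them through the marker-design funnel: a minimum repeat
count, a feasible PCR product window given the flanking sequence, and
removal of candidates whose flanks occur at multiple genomic positions
(primers would not be locus-specific).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = ["SsrCandidate", "find_ssrs", "filter_candidates", "canonical_motif"]

_VALID = set("ACGT")


def canonical_motif(motif: str) -> str:
    """Canonical representative over rotations and reverse complement.

    (AC, CA, GT, TG) all map to "AC".  Lexicographically smallest rotation
    of the motif or its reverse complement.
    """
    motif = motif.upper()
    rc = str(Seq(motif).reverse_complement())
    forms = [motif[i:] + motif[:i] for i in range(len(motif))]
    forms += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(forms)


def _is_homopolymer_equivalent(motif: str) -> bool:
    return len(set(motif)) == 1


@dataclass(frozen=True)
class SsrCandidate:
    """A perfect tandem repeat: 0-based half-open coordinates on ``contig``."""

    contig: str
    start: int
    end: int
    motif: str  # canonical
    n_repeats: int
    flank_left: int = 0
    flank_right: int = 0
    flank_ok: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start != self.n_repeats * len(self.motif):
            raise ValueError("span does not equal n_repeats x motif length")


def _scan_sequence(name: str, seq: str, motif_lengths, min_repeats):
    """Maximal non-overlapping perfect runs in one sequence."""
    seq = seq.upper()
    n = len(seq)
    found: list[SsrCandidate] = []
    taken_until = 0
    i = 0
    # prefer longer total runs; scan left to right taking the longest run
    # starting at each position across allowed motif lengths
    while i < n:
        best = None
        for m in sorted(motif_lengths):
            if i + 2 * m > n:
                continue
            unit = seq[i : i + m]
            if not set(unit) <= _VALID or _is_homopolymer_equivalent(unit):
                continue
            j = i + m
            while j + m <= n and seq[j : j + m] == unit:
                j += m
            reps = (j - i) // m
            if reps >= min_repeats:
                span = reps * m
                if best is None or span > best[0]:
                    best = (span, m, reps)
        if best is not None:
            span, m, reps = best
            found.append(
                SsrCandidate(
                    contig=name,
                    start=i,
                    end=i + span,
                    motif=canonical_motif(seq[i : i + m]),
                    n_repeats=reps,
                    flank_left=i,
                    flank_right=n - (i + span),
                )
            )
            i += span
        else:
            i += 1
    return found


def find_ssrs(fasta_path, motif_lengths=(2, 3), min_repeats: int = 11):
    """Scan a FASTA assembly for perfect di-/tri-nucleotide tandem repeats.

    Ambiguous bases break runs; homopolymer-equivalent motifs ("AA",
    "CCC") are excluded; motifs are canonicalized over rotations and
    reverse complement.  Returns a list of :class:`SsrCandidate`.
    """
    out: list[SsrCandidate] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.extend(_scan_sequence(rec.id, str(rec.seq), motif_lengths, min_repeats))
    return out


def filter_candidates(
    candidates,
    product_window: tuple[int, int] = (180, 300),
    drop_duplicates: bool = True,
    fasta_path=None,
    flank_kmer: int = 50,
):
    """Marker-design funnel: product-window feasibility, then duplicates.

    A candidate passes the window stage when the repeat tract plus its
    available flanks can host a product of ``product_window`` length
    (tract length <= window max and total available span >= window min).
    Duplicate detection needs the assembly (``fasta_path``): candidates
    whose flanking ``flank_kmer``-mers occur at more than one genomic
    position are removed, standing in for primer pairs hitting multiple
    sites.  Returns ``(filtered, funnel_counts)`` with counts after each
    stage.
    """
    lo, hi = product_window
    stage0 = list(candidates)
    stage1 = []
    for c in stage0:
        tract = c.end - c.start
        feasible = tract <= hi and tract + c.flank_left + c.flank_right >= lo
        if feasible:
            stage1.append(c)

    stage2 = stage1
    if drop_duplicates and fasta_path is not None and stage1:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        kmer_counts: dict[str, int] = {}

        def flank_kmers(c):
            s = seqs[c.contig]
            left = s[max(0, c.start - flank_kmer) : c.start]
            right = s[c.end : c.end + flank_kmer]
            return [k for k in (left, right) if len(k) == flank_kmer]

        for c in stage1:
            for k in flank_kmers(c):
                kmer_counts[k] = 0
        # count occurrences (forward and reverse complement) across contigs
        for k in list(kmer_counts):
            rc = str(Seq(k).reverse_complement())
            tot = 0
            for s in seqs.values():
                tot += s.count(k)
                if rc != k:
                    tot += s.count(rc)
            kmer_counts[k] = tot
        stage2 = []
        for c in stage1:
            ks = flank_kmers(c)
            if ks and all(kmer_counts[k] <= 1 for k in ks):
                stage2.append(c)

    funnel = {
        "input": len(stage0),
        "product_window": len(stage1),
        "unique": len(stage2),
    }
    return stage2, funnel
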