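"""Promoter extraction and IUPAC degenerate motif scanning.

Promoters are the ``length`` bases immediately upstream of a gene locus
(default 2,000 bp): for a + strand gene the slice ends at the feature
start; for a - strand gene it begins at the feature end and is
reverse-complemented, so every promoter reads 5'->3' toward the gene.
Windows truncated by a contig edge are flagged as clipped.

Matching uses the 15-letter IUPAC alphabet on the pattern side only: a
genome base outside {A, C, G, T} (e.g. an N run) never matches, which
keeps degenerate-pattern counts conservative.  Overlapping sites are all
counted, and a palindromic site scanned on both strands yields two hits
(distinct (start, strand) pairs) unless collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import GeneLocus

__all__ = [
    "Promoter",
    "MotifHit",
    "extract_promoters",
    "compile_iupac",
    "reverse_complement",
    "scan",
    "rank_elements",
]

IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Promoter:
    """One extracted promoter window."""

    gene_id: str
    sequence: str
    requested_length: int
    clipped: bool

    @property
    def actual_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence at a 0-based promoter offset.

    ``matched`` is always the forward-strand promoter substring at
    [start, start + pattern length), also for - strand hits.
    """

    gene_id: str
    start: int
    strand: str
    matched: str


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_promoters(
    genome: Mapping[str, str],
    loci: Iterable[GeneLocus],
    length: int = 2000,
) -> dict[str, Promoter]:
    """Extract upstream windows of ``length`` bp for every locus."""
    if length <= 0:
        raise ValueError("promoter length must be positive")
    out: dict[str, Promoter] = {}
    for locus in loci:
        if locus.seq_id not in genome:
            raise KeyError(f"sequence {locus.seq_id!r} missing from genome")
        contig = genome[locus.seq_id]
        if locus.strand == "+":
            lo = max(0, locus.start - length)
            seq = contig[lo : locus.start]
        else:
            hi = min(len(contig), locus.end + length)
            seq = reverse_complement(contig[locus.end : hi])
        out[locus.gene_id] = Promoter(locus.gene_id, seq, length, len(seq) < length)
    return out


def compile_iupac(pattern: str) -> tuple[frozenset[str], ...]:
    """Compile an IUPAC pattern into per-position base sets."""
    if not pattern:
        raise ValueError("empty pattern")
    sets = []
    for ch in pattern.upper():
        if ch not in IUPAC_CLASSES:
            raise ValueError(f"illegal IUPAC character {ch!r} in pattern {pattern!r}")
        sets.append(IUPAC_CLASSES[ch])
    return tuple(sets)


def _matches_at(seq: str, pos: int, sets: tuple[frozenset[str], ...]) -> bool:
    return all(seq[pos + k] in s for k, s in enumerate(sets))


def scan(
    promoters: Mapping[str, Promoter] | Mapping[str, str],
    pattern: str,
    strands: str = "both",
    collapse_palindromes: bool = False,
) -> tuple[list[MotifHit], dict[str, int]]:
    """Find all pattern occurrences in every promoter.

    Returns the hit list plus per-gene counts (every gene appears in
    the counts, hit or not).  With ``strands='both'`` the reverse strand
    is scanned as well; those hits carry strand '-' and forward-
    coordinate starts.  ``collapse_palindromes`` keeps only the + hit
    when both strands match at the same start.
    """
    if strands not in ("plus", "both"):
        raise ValueError(f"unknown strands mode {strands!r}")
    fwd = compile_iupac(pattern)
    # A reverse-strand occurrence at forward position i is a forward
    # match of the reverse-complemented pattern classes.
    rev = tuple(
        frozenset(b.translate(_COMPLEMENT) for b in s) for s in reversed(fwd)
    )
    k = len(fwd)
    hits: list[MotifHit] = []
    counts: dict[str, int] = {}
    for gene_id, prom in promoters.items():
        seq = prom.sequence if isinstance(prom, Promoter) else str(prom)
        n = 0
        for i in range(len(seq) - k + 1):
            plus = _matches_at(seq, i, fwd)
            if plus:
                hits.append(MotifHit(gene_id, i, "+", seq[i : i + k]))
                n += 1
            if strands == "both" and _matches_at(seq, i, rev):
                if not (plus and collapse_palindromes):
                    hits.append(MotifHit(gene_id, i, "-", seq[i : i + k]))
                    n += 1
        counts[gene_id] = n
    return hits, counts


def rank_elements(
    promoters: Mapping[str, Promoter] | Mapping[str, str],
    pattern_library: Mapping[str, str],
    strands: str = "both",
) -> pd.DataFrame:
    """Rank library patterns by genes hit, then total sites, then name.

    Returns a DataFrame indexed by pattern name with columns
    ``pattern``, ``genes_hit`` and ``total_sites``, sorted descending on
    (genes_hit, total_sites) with ascending-name tie-break.
    """
    if not pattern_library:
        raise ValueError("empty pattern library")
    rows = []
    for name, pattern in pattern_library.items():
        _, counts = scan(promoters, pattern, strands=strands)
        rows.append(
            {
                "name": name,
                "pattern": pattern,
                "genes_hit": sum(1 for c in counts.values() if c > 0),
                "total_sites": sum(counts.values()),
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["genes_hit", "total_sites", "name"], ascending=[False, False, True]
    ).set_index("name")
    return frame
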