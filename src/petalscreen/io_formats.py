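"""Readers and writers for the external formats the pipeline touches.

Expression matrices travel as plain tab-separated tables (header row of
organ labels, first column of gene identifiers), homology hits as
12-column BLAST tabular output (outfmt 6), sequences as FASTA and gene
coordinates as GFF3.  GFF3 coordinates (1-based inclusive) are converted
on input to 0-based half-open, the convention used everywhere else in
the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "HomologHit",
    "GeneLocus",
    "read_expression_table",
    "write_expression_table",
    "read_blast_tabular",
    "read_fasta",
    "read_gene_loci",
]

# 15-letter IUPAC nucleotide alphabet (after U -> T mapping).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """A malformed input file; the message names the offending element."""


@dataclass(frozen=True)
class HomologHit:
    """One BLAST tabular hit (only the fields the pipeline consumes)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"negative E-value for {self.query_id}: {self.evalue}")
        if self.bitscore < 0:
            raise FormatError(f"negative bitscore for {self.query_id}: {self.bitscore}")


@dataclass(frozen=True)
class GeneLocus:
    """A gene location in 0-based half-open coordinates."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionMatrix:
    """Gene x organ abundance matrix (RPKM units).

    Rows are genes, columns are organs; every value is finite and
    non-negative, identifiers are unique and ordered.
    """

    gene_ids: list[str]
    organ_labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.organ_labels = list(self.organ_labels)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise FormatError(f"duplicate gene id {dup!r}")
        if len(set(self.organ_labels)) != len(self.organ_labels):
            raise FormatError("duplicate organ label")
        if self.values.shape != (len(self.gene_ids), len(self.organ_labels)):
            raise FormatError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.organ_labels)} organs"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression value")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative expression for gene {self.gene_ids[i]!r}, "
                f"organ {self.organ_labels[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def column(self, organ: str) -> np.ndarray:
        try:
            j = self.organ_labels.index(organ)
        except ValueError:
            raise KeyError(f"unknown organ {organ!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.organ_labels
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            list(map(str, frame.index)),
            list(map(str, frame.columns)),
            frame.to_numpy(dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.organ_labels == other.organ_labels
            and np.array_equal(self.values, other.values)
        )


def read_expression_table(text: str) -> ExpressionMatrix:
    """Parse a tab-separated expression table.

    The header row carries organ labels; a leading header cell for the
    gene-id column (e.g. ``gene_id``) is accepted and ignored.  Row and
    column order are preserved.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty expression table (no header)")
    header = lines[0].split("\t")
    first_row = lines[1].split("\t") if len(lines) > 1 else None
    if first_row is not None and len(header) == len(first_row):
        organs = header[1:]  # header names the gene-id column
    elif first_row is not None and len(header) == len(first_row) - 1:
        organs = header[:]
    else:
        organs = header[1:] if len(header) > 1 else header
    if not organs:
        raise FormatError("expression table header declares no organ labels")

    gene_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(organs) + 1:
            raise FormatError(
                f"line {lineno}: expected {len(organs) + 1} fields, got {len(fields)}"
            )
        gid = fields[0]
        if gid in seen:
            raise FormatError(f"duplicate gene id {gid!r}")
        seen.add(gid)
        row: list[float] = []
        for organ, cell in zip(organs, fields[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"gene {gid!r}, organ {organ!r}: non-numeric value {cell!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise FormatError(
                    f"gene {gid!r}, organ {organ!r}: invalid value {cell!r}"
                )
            row.append(v)
        gene_ids.append(gid)
        rows.append(row)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(organs)))
    return ExpressionMatrix(gene_ids, organs, values)


def write_expression_table(matrix: ExpressionMatrix) -> str:
    """Serialize to the canonical tab-separated dialect (6 significant digits)."""
    out = ["\t".join(["gene_id", *matrix.organ_labels])]
    for gid, row in zip(matrix.gene_ids, matrix.values):
        out.append("\t".join([gid, *(format(v, ".6g") for v in row)]))
    return "\n".join(out) + "\n"


def read_blast_tabular(text: str) -> list[HomologHit]:
    """Parse BLAST outfmt-6 lines into hits (query, subject, evalue, bitscore).

    Comment lines starting with ``#`` and blank lines are skipped; extra
    trailing columns are ignored.
    """
    hits: list[HomologHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise FormatError(
                f"line {lineno}: expected >= 12 tab-separated columns, got {len(fields)}"
            )
        try:
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError:
            raise FormatError(
                f"line {lineno}: unparseable evalue/bitscore "
                f"{fields[10]!r}/{fields[11]!r}"
            ) from None
        hits.append(HomologHit(fields[0], fields[1], evalue, bitscore))
    return hits


def read_fasta(text: str) -> dict[str, str]:
    """Parse FASTA into ``{id: uppercase DNA}``.

    Sequence ids are the first whitespace-delimited token after ``>``.
    U is mapped to T; any character outside the 15-letter IUPAC DNA
    alphabet is an error.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"sequence {record.id!r}: illegal character {sorted(bad)[0]!r}"
            )
        sequences[record.id] = seq
    return sequences


def _gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gene_loci(text: str, feature_type: str = "gene") -> list[GeneLocus]:
    """Extract ``feature_type`` rows from GFF3 as 0-based half-open loci."""
    loci: list[GeneLocus] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise FormatError(f"line {lineno}: GFF3 row has {len(fields)} columns")
        if fields[2] != feature_type:
            continue
        attrs = _gff3_attributes(fields[8])
        if "ID" not in attrs:
            raise FormatError(f"line {lineno}: {feature_type} feature without ID")
        try:
            gff_start, gff_end = int(fields[3]), int(fields[4])
        except ValueError:
            raise FormatError(f"line {lineno}: non-integer coordinates") from None
        if gff_end < gff_start:
            raise FormatError(
                f"line {lineno}: end {gff_end} precedes start {gff_start}"
            )
        loci.append(
            GeneLocus(attrs["ID"], fields[0], gff_start - 1, gff_end, fields[6])
        )
    return loci
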