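"""Sequence/annotation/read I/O and circular-coordinate primitives.

Plant mitochondrial genomes are (conceptually) circular molecules, so every
coordinate operation here is wrap-around aware.  Two coordinate systems are
used and converted losslessly:

* **internal**: 0-based, half-open, ascending (``start0 < end0`` unless the
  feature wraps the origin) — all computation happens here;
* **reported**: 1-based, inclusive; minus-oriented units are printed with
  descending coordinates (``419510-419000``), the convention used in organelle
  recombination tables.

Sequences are restricted to the alphabet ``{A, C, G, T, N}``.  ``U`` on input
is mapped to ``T``; ``N`` never counts as a match anywhere downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file (empty FASTA, bad alphabet, missing GFF IDs...)."""


class CoordinateError(ValueError):
    """Out-of-range or inconsistent genome coordinates."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genome interval with orientation.

    For orientation ``-`` the reported ``start`` is *greater* than ``end``
    (descending), mirroring the minus-unit convention of recombination
    tables.  :meth:`to_internal` / :meth:`from_internal` convert to and from
    the 0-based half-open ascending form used internally.
    """

    start: int
    end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise CoordinateError(f"bad orientation {self.orientation!r}")
        if self.orientation == "+" and self.start > self.end:
            raise CoordinateError("plus-oriented interval must ascend")
        if self.orientation == "-" and self.start < self.end:
            raise CoordinateError("minus-oriented interval must descend")

    @property
    def length(self) -> int:
        return abs(self.end - self.start) + 1

    def to_internal(self) -> tuple[int, int, str]:
        """Return (start0, end0, strand) in 0-based half-open ascending form."""
        if self.orientation == "+":
            return self.start - 1, self.end, "+"
        return self.end - 1, self.start, "-"

    @classmethod
    def from_internal(cls, start0: int, end0: int, strand: str = "+") -> "Interval":
        if end0 <= start0:
            raise CoordinateError("internal interval must be ascending, non-empty")
        if strand == "+":
            return cls(start0 + 1, end0, "+")
        return cls(end0, start0 + 1, "-")


@dataclass
class CircularGenome:
    """A genome sequence with optional wrap-around coordinate semantics."""

    id: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-IUPAC/unsupported characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coordinate helpers -------------------------------------------------

    def slice0(self, start0: int, end0: int) -> str:
        """Extract [start0, end0) with wrap-around when circular.

        ``end0`` may exceed the genome length (or ``start0`` may be negative)
        by at most one full turn; the extracted length is ``end0 - start0``.
        """
        n = len(self.sequence)
        if end0 < start0:
            raise CoordinateError("end0 < start0")
        if end0 - start0 > n:
            raise CoordinateError("cannot extract more than one full turn")
        if not self.is_circular:
            if start0 < 0 or end0 > n:
                raise CoordinateError(
                    f"[{start0}, {end0}) out of range on linear sequence of length {n}"
                )
            return self.sequence[start0:end0]
        length = end0 - start0
        start0 %= n
        stop = start0 + length
        if stop <= n:
            return self.sequence[start0:stop]
        return self.sequence[start0:] + self.sequence[: stop - n]


def normalize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise FormatError(
            f"record {record_id!r} contains unsupported characters: {sorted(bad)}"
        )
    return s


@dataclass
class GeneAnnotation:
    """A gene with its exon structure on the genome.

    ``exon_intervals`` are 1-based inclusive ascending (start, end) pairs in
    genome coordinates, sorted ascending regardless of strand; the transcript
    of a minus-strand gene is the reverse complement of the concatenated
    exons.
    """

    gene_id: str
    strand: str
    exon_intervals: list[tuple[int, int]]
    feature_type: str = "CDS"
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        ivs = sorted(self.exon_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
        self.exon_intervals = ivs

    @property
    def span(self) -> tuple[int, int]:
        """Full genomic span (1-based inclusive) from first to last exon."""
        return self.exon_intervals[0][0], self.exon_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exon_intervals)

    def transcript(self, genome: CircularGenome) -> str:
        """Spliced transcript-strand sequence (introns removed)."""
        parts = [genome.slice0(s - 1, e) for s, e in self.exon_intervals]
        joined = "".join(parts)
        return revcomp(joined) if self.strand == "-" else joined

    def cds_to_genome(self, cds_pos: int) -> int:
        """Map a 1-based transcript position to its 1-based genome position."""
        if not 1 <= cds_pos <= self.cds_length:
            raise CoordinateError(
                f"cds position {cds_pos} outside gene {self.gene_id}"
            )
        offsets: list[int] = []
        for s, e in self.exon_intervals:
            offsets.extend(range(s, e + 1))
        if self.strand == "-":
            offsets.reverse()
        return offsets[cds_pos - 1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction over {A,C,G,T}; N excluded from the denominator."""
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined on all-N sequence")
    return gc / acgt


def circular_substring(genome: CircularGenome, start: int, end: int) -> str:
    """Extract 1-based inclusive [start, end], wrapping when start > end.

    On a circular genome ``start > end`` wraps through the origin and the
    result has length ``(end - start) mod n + 1``.  On a linear genome the
    wrap case is a coordinate error.
    """
    n = len(genome)
    if not (1 <= start <= n and 1 <= end <= n):
        raise CoordinateError(f"positions ({start}, {end}) outside 1..{n}")
    if start <= end:
        return genome.sequence[start - 1 : end]
    if not genome.is_circular:
        raise CoordinateError("wrap-around extraction on a linear sequence")
    return genome.sequence[start - 1 :] + genome.sequence[:end]


def extract_interval(genome: CircularGenome, interval: Interval) -> str:
    """Oriented sequence of an interval (revcomp for minus orientation)."""
    s0, e0, strand = interval.to_internal()
    seq = circular_substring(genome, s0 + 1, e0)
    return revcomp(seq) if strand == "-" else seq


def read_fasta(
    path: str | os.PathLike, circular: bool = False
) -> list[CircularGenome]:
    """Read a (multi-)FASTA file into :class:`CircularGenome` records.

    Circularity is a property of the molecule, not of the file format, so it
    is taken from the ``circular`` argument.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), rec.id)
        records.append(CircularGenome(rec.id, seq, is_circular=circular))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Iterable[CircularGenome | tuple[str, str]],
    path: str | os.PathLike,
    width: int = 70,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, CircularGenome) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTQ as (id, sequence) pairs; qualities are not retained."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, normalize_sequence(str(rec.seq), rec.id)))
    return out


def write_fastq(
    reads: Iterable[tuple[str, str]], path: str | os.PathLike, quality_char: str = "I"
) -> None:
    """Write (id, seq) reads as 4-line FASTQ with a constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_gff_genes(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Parse GFF3 CDS/tRNA/rRNA features into per-gene annotations.

    CDS segments are grouped by their gene identifier (``Parent`` or
    ``gene_id``/``ID`` attribute) and sorted; features without any usable
    identifier are a format error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneAnnotation] = {}
    pseudo_flags: dict[str, bool] = {}
    for ftype in ("CDS", "tRNA", "rRNA"):
        for feat in db.features_of_type(ftype):
            gid = (
                feat.attributes.get("Parent", [None])[0]
                or feat.attributes.get("gene_id", [None])[0]
                or feat.attributes.get("ID", [None])[0]
            )
            if gid is None:
                raise FormatError(f"{ftype} feature at {feat.start} lacks an ID")
            gid = gid.removeprefix("gene-").removesuffix(".cds")
            pseudo = feat.attributes.get("pseudo", ["false"])[0].lower() == "true"
            pseudo_flags[gid] = pseudo_flags.get(gid, False) or pseudo
            if gid in genes:
                genes[gid].exon_intervals.append((feat.start, feat.end))
            else:
                genes[gid] = GeneAnnotation(
                    gene_id=gid,
                    strand=feat.strand,
                    exon_intervals=[(feat.start, feat.end)],
                    feature_type=ftype,
                )
    out = []
    for gid, gene in genes.items():
        gene.pseudogene = pseudo_flags.get(gid, False)
        gene.exon_intervals.sort()
        if (
            gene.feature_type == "CDS"
            and not gene.pseudogene
            and gene.cds_length % 3 != 0
        ):
            raise FormatError(
                f"gene {gid}: CDS length {gene.cds_length} not divisible by 3 "
                "(mark pseudo=true if intentional)"
            )
        out.append(gene)
    out.sort(key=lambda g: g.span)
    return out


def write_gff_genes(
    genes: Sequence[GeneAnnotation], path: str | os.PathLike, seqid: str
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            attrs = f"ID=gene-{g.gene_id}"
            if g.pseudogene:
                attrs += ";pseudo=true"
            fh.write(
                f"{seqid}\tmitorec\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (xs, xe) in enumerate(g.exon_intervals, 1):
                fh.write(
                    f"{seqid}\tmitorec\t{g.feature_type}\t{xs}\t{xe}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}.cds{i};Parent={g.gene_id}"
                    + (";pseudo=true" if g.pseudogene else "")
                    + "\n"
                )
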