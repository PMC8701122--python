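"""RNA-editing site detection in mitochondrial protein-coding transcripts.

Plant mitochondrial transcripts are post-transcriptionally edited,
predominantly C-to-U.  Sites are called from per-position pileups of RNA
reads aligned to the spliced coding sequences (transcript strand), after
excluding genomic variation seen in DNA reads:

* depth filter: at least ``min_depth`` reads (default 10) at the site;
* support filter: the alternative base in at least ``min_fraction`` of the
  reads (default 10%, inclusive);
* editing efficiency: edited reads / depth.

All twelve ordered substitution types over {A, C, G, U} are classified on
the transcript strand, so a genomic G-to-A mismatch on a minus-strand gene
is reported as C-to-U.  Start-codon events (e.g. genomic ACG edited to AUG)
are scanned separately, including sub-threshold-depth sites, which are then
flagged rather than silently dropped.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam
from Bio.Seq import Seq

from .io import CircularGenome, GeneAnnotation
from .recombination import round_half_up

BASES = "ACGT"
EDIT_TYPES = tuple(
    f"{a}-to-{b}".replace("T", "U")
    for a in BASES
    for b in BASES
    if a != b
)


def _to_rna(base: str) -> str:
    return "U" if base == "T" else base


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


@dataclass
class PileupSite:
    """Per-position base tally on the transcript strand."""

    gene_id: str
    cds_pos: int  # 1-based position in the spliced transcript
    genome_pos: int  # 1-based genome position (0 when unmapped)
    ref_base: str  # transcript-strand base (DNA alphabet)
    depth: int
    base_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ReadAlignment:
    """Minimal alignment record: a read placed on a spliced CDS reference."""

    gene_id: str
    seq: str
    ref_start: int  # 0-based
    aligned_pairs: list[tuple[int, int]]  # (query_pos, ref_pos), matches only
    mapq: int = 60
    quals: Sequence[int] | None = None


def alignments_from_sam(path: str) -> list[ReadAlignment]:
    """Load read-vs-CDS alignments from a SAM file (pysam)."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            pairs = [
                (q, r)
                for q, r in rec.get_aligned_pairs()
                if q is not None and r is not None
            ]
            out.append(
                ReadAlignment(
                    gene_id=rec.reference_name,
                    seq=rec.query_sequence,
                    ref_start=rec.reference_start,
                    aligned_pairs=pairs,
                    mapq=rec.mapping_quality,
                    quals=rec.query_qualities,
                )
            )
    return out


def pileup_from_alignments(
    alignments: Iterable[ReadAlignment] | str,
    genes: Sequence[GeneAnnotation],
    transcripts: Mapping[str, str],
    min_baseq: int = 20,
    min_mapq: int = 20,
) -> list[PileupSite]:
    """Per-CDS-position base counts on the transcript strand.

    ``alignments`` may be a SAM path or ReadAlignment records; reference
    space is the spliced transcript of each gene.  Bases below ``min_baseq``
    and reads below ``min_mapq`` are excluded; a read deleted at a position
    simply does not contribute to that position's depth.  Alignments to
    genes absent from the annotation are skipped with a warning.
    """
    if isinstance(alignments, str):
        alignments = alignments_from_sam(alignments)
    by_gene = {g.gene_id: g for g in genes}
    counts: dict[str, dict[int, Counter]] = defaultdict(lambda: defaultdict(Counter))
    skipped: set[str] = set()
    for aln in alignments:
        if aln.gene_id not in by_gene:
            if aln.gene_id not in skipped:
                warnings.warn(f"alignment to unannotated gene {aln.gene_id!r}; skipped")
                skipped.add(aln.gene_id)
            continue
        if aln.mapq < min_mapq:
            continue
        for qpos, rpos in aln.aligned_pairs:
            if aln.quals is not None and aln.quals[qpos] < min_baseq:
                continue
            base = aln.seq[qpos]
            if base not in BASES:
                continue
            counts[aln.gene_id][rpos][base] += 1

    sites = []
    for gid, per_pos in counts.items():
        gene = by_gene[gid]
        tseq = transcripts[gid]
        for rpos in sorted(per_pos):
            if rpos >= len(tseq):
                continue
            tally = per_pos[rpos]
            sites.append(
                PileupSite(
                    gene_id=gid,
                    cds_pos=rpos + 1,
                    genome_pos=gene.cds_to_genome(rpos + 1),
                    ref_base=tseq[rpos],
                    depth=sum(tally.values()),
                    base_counts={b: tally.get(b, 0) for b in BASES},
                )
            )
    return sites


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


@dataclass
class EditingSite:
    """One transcript-strand editing event."""

    gene_id: str
    cds_pos: int
    genome_pos: int
    edit_type: str  # e.g. "C-to-U"
    edited_count: int
    depth: int
    efficiency: float
    codon_position: int  # 1..3
    aa_change: str  # e.g. "P->L" or "P->P"
    ref_base: str = ""
    alt_base: str = ""
    dna_verified: bool = True


def classify_edit(ref_base: str, alt_base: str) -> str:
    """Ordered-pair edit label on the transcript strand (T reported as U)."""
    r, a = _to_rna(ref_base.upper()), _to_rna(alt_base.upper())
    if r == a:
        raise ValueError("ref and alt base are identical")
    label = f"{r}-to-{a}"
    if label not in EDIT_TYPES:
        raise ValueError(f"bases must be in ACGU, got {ref_base}/{alt_base}")
    return label


def _aa_change(transcript: str, cds_pos: int, alt_base: str) -> tuple[int, str]:
    codon_pos = (cds_pos - 1) % 3 + 1
    codon_start = cds_pos - codon_pos
    codon = transcript[codon_start : codon_start + 3]
    if len(codon) < 3:
        return codon_pos, "?"
    edited = codon[: codon_pos - 1] + alt_base + codon[codon_pos:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(edited).translate())
    return codon_pos, f"{aa_ref}->{aa_alt}"


def call_editing_sites(
    pileup: Sequence[PileupSite],
    transcripts: Mapping[str, str],
    min_depth: int = 10,
    min_fraction: float = 0.10,
) -> list[EditingSite]:
    """Editing sites passing the depth and support filters (both inclusive).

    One record is emitted per (site, alternative base); a site with two
    alternative bases above threshold yields two records.
    """
    out = []
    for site in pileup:
        if site.depth < min_depth:
            continue
        for alt in BASES:
            if alt == site.ref_base:
                continue
            cnt = site.base_counts.get(alt, 0)
            if cnt == 0 or cnt / site.depth < min_fraction:
                continue
            codon_pos, aa = _aa_change(transcripts[site.gene_id], site.cds_pos, alt)
            out.append(
                EditingSite(
                    gene_id=site.gene_id,
                    cds_pos=site.cds_pos,
                    genome_pos=site.genome_pos,
                    edit_type=classify_edit(site.ref_base, alt),
                    edited_count=cnt,
                    depth=site.depth,
                    efficiency=cnt / site.depth,
                    codon_position=codon_pos,
                    aa_change=aa,
                    ref_base=_to_rna(site.ref_base),
                    alt_base=_to_rna(alt),
                )
            )
    return out


def filter_genomic_variants(
    dna_pileup: Sequence[PileupSite],
    candidate_sites: Sequence[EditingSite],
    max_dna_alt_fraction: float = 0.05,
) -> list[EditingSite]:
    """Drop candidates that look like DNA-level variation, not editing.

    A candidate is removed when WGS reads support its alternative base above
    ``max_dna_alt_fraction`` at the same transcript coordinate.  Sites with
    no DNA coverage are retained but flagged unverified.
    """
    dna = {(p.gene_id, p.cds_pos): p for p in dna_pileup}
    kept = []
    for site in candidate_sites:
        p = dna.get((site.gene_id, site.cds_pos))
        if p is None or p.depth == 0:
            site.dna_verified = False
            kept.append(site)
            continue
        alt_dna = p.base_counts.get(site.alt_base.replace("U", "T"), 0)
        if alt_dna / p.depth > max_dna_alt_fraction:
            continue
        kept.append(site)
    return kept


# ---------------------------------------------------------------------------
# start-codon events
# ---------------------------------------------------------------------------


@dataclass
class StartCodonEvent:
    gene_id: str
    genomic_codon: str  # RNA alphabet, e.g. "ACG"
    edited_codon: str  # "AUG" when an event is found
    status: str  # "edited-start" | "unedited-non-canonical-start"
    efficiency: float | None = None
    depth: int | None = None
    depth_below_threshold: bool = False


def detect_start_codon_editing(
    gene: GeneAnnotation,
    transcript: str,
    candidate_sites: Sequence[EditingSite],
    min_depth: int = 10,
) -> StartCodonEvent | None:
    """Start-codon creation by editing (e.g. ACG -> AUG via C-to-U).

    ``candidate_sites`` should include sub-threshold-depth calls (pass the
    output of :func:`call_editing_sites` with ``min_depth=1``); events whose
    depth is below ``min_depth`` are reported with a flag rather than
    dropped.  Genes starting with AUG return None; genes with a non-AUG
    start and no converting edit are reported as unedited.
    """
    codon = transcript[:3].replace("T", "U")
    if codon == "AUG" or len(codon) < 3:
        return None
    for site in candidate_sites:
        if site.gene_id != gene.gene_id or site.cds_pos > 3:
            continue
        pos = site.cds_pos
        edited = codon[: pos - 1] + site.alt_base + codon[pos:]
        if edited == "AUG":
            return StartCodonEvent(
                gene_id=gene.gene_id,
                genomic_codon=codon,
                edited_codon="AUG",
                status="edited-start",
                efficiency=site.efficiency,
                depth=site.depth,
                depth_below_threshold=site.depth < min_depth,
            )
    return StartCodonEvent(
        gene_id=gene.gene_id,
        genomic_codon=codon,
        edited_codon=codon,
        status="unedited-non-canonical-start",
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class EditingSummary:
    total: int
    per_gene: dict[str, int]
    per_type: dict[str, int]
    per_type_pct: dict[str, float]
    efficiency_bins: dict[str, int]  # below50 / at_least50 / near100
    efficiency_bin_pct: dict[str, float]


def share_pct(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage share rounded half-up (the table-formatting convention)."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def summarize_editing(
    sites: Sequence[EditingSite], near100_cutoff: float = 0.99
) -> EditingSummary:
    """Per-gene counts, 12-type histogram and efficiency bins.

    ``near100`` (efficiency >= ``near100_cutoff``) is a subset of
    ``at_least50``; percentages are rounded half-up to one decimal.
    """
    total = len(sites)
    per_gene = Counter(s.gene_id for s in sites)
    per_type = Counter(s.edit_type for s in sites)
    bins = {
        "below50": sum(1 for s in sites if s.efficiency < 0.5),
        "at_least50": sum(1 for s in sites if s.efficiency >= 0.5),
        "near100": sum(1 for s in sites if s.efficiency >= near100_cutoff),
    }
    return EditingSummary(
        total=total,
        per_gene=dict(per_gene),
        per_type={t: per_type.get(t, 0) for t in EDIT_TYPES},
        per_type_pct={t: share_pct(per_type.get(t, 0), total) for t in EDIT_TYPES},
        efficiency_bins=bins,
        efficiency_bin_pct={k: share_pct(v, total) for k, v in bins.items()},
    )
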