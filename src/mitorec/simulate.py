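"""Synthetic data with the statistical structure the analyses assume.

Generates a random circular genome at a target GC with planted repeat pairs
and protein-coding genes, then reads of the three kinds the study design
relies on:

* ONT-like long reads (lognormal lengths, substitution + indel errors),
  drawn from a mixture of the master circle and explicitly constructed
  recombinant molecules at planted per-repeat alternative fractions;
* Illumina-like paired short reads (~150 bp, insert ~350 bp) from the same
  conformational mixture;
* strand-aware RNA-seq reads from spliced transcripts carrying planted
  edits, each read independently edited with probability equal to the
  planted efficiency.

Every generator is driven by a single :class:`numpy.random.Generator` seeded
from the config, so a fixed config reproduces byte-identical outputs.  A
:class:`TruthTable` records the planted coordinates, fractions and
efficiencies for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil, log
from typing import Sequence

import numpy as np

from .editing import ReadAlignment
from .io import CircularGenome, GeneAnnotation, Interval, revcomp
from .recombination import ConformationPair, build_alternative_molecules
from .repeats import RepeatPair, hamming

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


class ConfigError(ValueError):
    """Infeasible simulation configuration (placement, edit positions...)."""


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedRepeat:
    length: int
    orientation: str  # "direct" | "inverted"
    mismatches: int = 0
    alt_fraction: float = 0.0
    positions: tuple[int, int] | None = None  # 0-based unit starts

    def __post_init__(self):
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ConfigError("alt_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    n_codons: int = 100  # including start and stop
    strand: str = "+"
    start_codon: str = "ATG"
    n_exons: int = 1
    intron_length: int = 120
    position: int | None = None  # 0-based locus start


@dataclass(frozen=True)
class PlantedEdit:
    gene_id: str
    cds_pos: int  # 1-based transcript position
    ref_base: str = "C"
    alt_base: str = "T"
    efficiency: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.efficiency <= 1.0:
            raise ConfigError("efficiency must be in [0, 1]")


@dataclass
class SimConfig:
    """All simulation knobs, with the study's data properties as defaults.

    The genome default is 50 kb (desk scale) rather than the ~0.5 Mb of a
    real plum mitogenome; GC, read lengths and depths default to the real
    data set's summary statistics.
    """

    seed: int = 0
    genome_length: int = 50_000
    gc_target: float = 0.4543
    planted_repeats: tuple[PlantedRepeat, ...] = ()
    planted_genes: tuple[PlantedGene, ...] = ()
    planted_edits: tuple[PlantedEdit, ...] = ()
    long_read_mean_len: int = 13_430
    long_read_sigma: float = 0.6  # lognormal shape
    long_read_sub_rate: float = 0.05
    long_read_indel_rate: float = 0.03
    long_read_depth: float = 178.0
    short_read_len: int = 150
    short_read_depth: float = 48.0
    short_read_sub_rate: float = 0.001
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    rna_read_len: int = 150
    rna_depth: float = 100.0
    rna_sub_rate: float = 0.001
    placement_margin: int = 1_200


@dataclass
class TruthTable:
    """Planted ground truth, spot-checkable against the emitted sequences."""

    repeats: list[RepeatPair] = field(default_factory=list)
    alt_fractions: dict[str, float] = field(default_factory=dict)
    genes: list[GeneAnnotation] = field(default_factory=list)
    edits: list[PlantedEdit] = field(default_factory=list)
    long_read_n50: int | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return bytes(_BASES[rng.choice(4, size=n, p=probs)]).decode()


def mutate_read(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
) -> str:
    """Uniform substitutions plus balanced insertions/deletions."""
    if not seq or (sub_rate == 0 and indel_rate == 0):
        return seq
    code = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr = lut[code]
    n = arr.size
    if sub_rate > 0:
        hit = rng.random(n) < sub_rate
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    if indel_rate > 0:
        u = rng.random(n)
        counts = np.ones(n, dtype=np.int64)
        counts[u < indel_rate / 2] = 0  # deletion
        ins = (u >= indel_rate / 2) & (u < indel_rate)
        counts[ins] = 2  # insertion after the base
        out = np.repeat(arr, counts)
        ins_slots = np.cumsum(counts)[ins] - 1
        out[ins_slots] = rng.integers(0, 4, size=ins_slots.size)
        arr = out
    return bytes(_BASES[arr]).decode()


def _nonoverlapping_positions(
    rng: np.random.Generator,
    n: int,
    lengths: Sequence[int],
    margin: int,
    fixed: Sequence[tuple[int, int]] = (),
) -> list[int]:
    """Random starts for elements of the given lengths, margin apart."""
    taken = [(s, s + l) for s, l in fixed]
    out = []
    for length in lengths:
        if n - length - margin <= 0:
            raise ConfigError(
                f"element of length {length} cannot fit a {n} bp genome "
                f"with margin {margin}"
            )
        for _ in range(2000):
            start = int(rng.integers(0, n - length - margin))
            lo, hi = start - margin, start + length + margin
            if all(hi <= s or lo >= e for s, e in taken):
                taken.append((start, start + length))
                out.append(start)
                break
        else:
            raise ConfigError("could not place planted elements without overlap")
    return out


def _mismatched_copy(seq: str, n_mm: int, rng: np.random.Generator) -> str:
    s = list(seq)
    if n_mm > len(s):
        raise ConfigError("more mismatches than repeat length")
    for p in rng.choice(len(s), size=n_mm, replace=False):
        alts = [b for b in "ACGT" if b != s[p]]
        s[p] = alts[int(rng.integers(0, 3))]
    return "".join(s)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _build_cds(gene: PlantedGene, edits: Sequence[PlantedEdit], rng) -> str:
    codons = [gene.start_codon]
    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ]
    for _ in range(gene.n_codons - 2):
        codons.append(non_stop[int(rng.integers(0, len(non_stop)))])
    codons.append("TAA")
    cds = list("".join(codons))
    for e in edits:
        if e.gene_id != gene.gene_id:
            continue
        if e.cds_pos > len(cds):
            raise ConfigError(
                f"edit position {e.cds_pos} exceeds CDS of {gene.gene_id}"
            )
        cds[e.cds_pos - 1] = e.ref_base.replace("U", "T")
        ci = (e.cds_pos - 1) // 3
        codon = "".join(cds[3 * ci : 3 * ci + 3])
        if codon in _STOPS and 3 * ci + 3 < len(cds):
            # repair a premature stop introduced by forcing the edited base
            for off in range(3):
                if 3 * ci + off == e.cds_pos - 1:
                    continue
                for b in "ACGT":
                    trial = list(codon)
                    trial[off] = b
                    if "".join(trial) not in _STOPS:
                        cds[3 * ci + off] = b
                        codon = "".join(trial)
                        break
                if codon not in _STOPS:
                    break
    return "".join(cds)


def simulate_genome(
    config: SimConfig,
) -> tuple[CircularGenome, list[GeneAnnotation], TruthTable]:
    """Random circular genome with planted repeats and genes, plus truth."""
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    seq = list(random_sequence(rng, n, config.gc_target))
    truth = TruthTable(edits=list(config.planted_edits))

    # --- repeats ---
    auto = [pr for pr in config.planted_repeats if pr.positions is None]
    fixed = [
        (pr.positions[i], pr.length)
        for pr in config.planted_repeats
        if pr.positions is not None
        for i in (0, 1)
    ]
    lengths = [pr.length for pr in auto for _ in (0, 1)]
    starts = _nonoverlapping_positions(
        rng, n, lengths, config.placement_margin, fixed=fixed
    )
    it = iter(starts)
    repeat_pairs: list[tuple[PlantedRepeat, int, int]] = []
    for pr in config.planted_repeats:
        if pr.positions is not None:
            a1, a2 = pr.positions
        else:
            a1, a2 = next(it), next(it)
        if a1 > a2:
            a1, a2 = a2, a1
        repeat_pairs.append((pr, a1, a2))

    occupied = [(a, a + pr.length) for pr, a1, a2 in repeat_pairs for a in (a1, a2)]

    for i, (pr, a1, a2) in enumerate(repeat_pairs):
        unit = random_sequence(rng, pr.length, config.gc_target)
        copy = _mismatched_copy(unit, pr.mismatches, rng)
        if pr.orientation == "inverted":
            copy = revcomp(copy)
        seq[a1 : a1 + pr.length] = list(unit)
        seq[a2 : a2 + pr.length] = list(copy)
        rid = f"rep{i + 1:04d}"
        strand2 = "-" if pr.orientation == "inverted" else "+"
        unit2 = (
            Interval(a2 + pr.length, a2 + 1, "-")
            if strand2 == "-"
            else Interval(a2 + 1, a2 + pr.length, "+")
        )
        rp = RepeatPair(
            repeat_id=rid,
            unit1=Interval(a1 + 1, a1 + pr.length, "+"),
            unit2=unit2,
            orientation=pr.orientation,
            length=pr.length,
            mismatches=pr.mismatches,
            evalue=0.0,
            unit1_seq=unit,
            unit2_seq="".join(seq[a2 : a2 + pr.length]),
        )
        assert hamming(rp.unit1_seq, rp.oriented_unit2_seq()) == pr.mismatches
        truth.repeats.append(rp)
        truth.alt_fractions[rid] = pr.alt_fraction

    # --- genes ---
    gene_loci: list[tuple[PlantedGene, str, int]] = []  # (gene, locus_seq, locus_len)
    for pg in config.planted_genes:
        cds = _build_cds(pg, config.planted_edits, rng)
        if pg.n_exons == 1:
            locus = cds
            exon_rel = [(0, len(cds))]
        elif pg.n_exons == 2:
            half = (len(cds) // 2) // 3 * 3
            intron = random_sequence(rng, pg.intron_length, config.gc_target)
            locus = cds[:half] + intron + cds[half:]
            exon_rel = [(0, half), (half + pg.intron_length, len(locus))]
        else:
            raise ConfigError("only 1 or 2 exons supported")
        if pg.strand == "-":
            L = len(locus)
            locus = revcomp(locus)
            exon_rel = sorted((L - e, L - s) for s, e in exon_rel)
        gene_loci.append((pg, locus, exon_rel))

    locus_lengths = [len(locus) for pg, locus, _ in gene_loci if pg.position is None]
    gene_starts = iter(
        _nonoverlapping_positions(
            rng,
            n,
            locus_lengths,
            config.placement_margin,
            fixed=[(s, e - s) for s, e in occupied],
        )
    )
    genes: list[GeneAnnotation] = []
    for pg, locus, exon_rel in gene_loci:
        start = pg.position if pg.position is not None else next(gene_starts)
        seq[start : start + len(locus)] = list(locus)
        genes.append(
            GeneAnnotation(
                gene_id=pg.gene_id,
                strand=pg.strand,
                exon_intervals=[(start + s + 1, start + e) for s, e in exon_rel],
                feature_type="CDS",
            )
        )
    truth.genes = genes

    genome = CircularGenome("sim_mito", "".join(seq), is_circular=True)
    # planted repeat copies may be perturbed if a later element overlapped;
    # placement margins make that impossible, but verify cheaply
    for rp in truth.repeats:
        a1, a2 = rp.unit_starts0()
        assert genome.slice0(a1, a1 + rp.length) == rp.unit1_seq
    return genome, genes, truth


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------


def _lognormal_lengths(rng, n, mean, sigma):
    mu = log(mean) - sigma**2 / 2.0
    return np.maximum(200, rng.lognormal(mu, sigma, size=n).astype(np.int64))


def _read_from_circle(mol: str, start: int, length: int, rng, strand_random, sub, indel):
    cl = len(mol)
    length = min(length, cl)
    start %= cl
    stop = start + length
    raw = mol[start:stop] if stop <= cl else mol[start:] + mol[: stop - cl]
    if strand_random and rng.random() < 0.5:
        raw = revcomp(raw)
    return mutate_read(raw, rng, sub, indel)


def simulate_long_reads(
    genome: CircularGenome,
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_reads: int | None = None,
) -> list[tuple[str, str]]:
    """Whole-genome long reads from the conformational mixture.

    Each read is drawn from a repeat's recombinant molecules with the
    planted per-repeat alternative fraction, else from the master circle.
    Returns (read_id, sequence) pairs; ids carry the source molecule.  The
    realized N50 is stored on the truth table.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = len(genome)
    if n_reads is None:
        # reads are truncated at one molecule turn, so size the read count by
        # the realized (capped) lengths to actually hit the target depth
        target = config.long_read_depth * n
        probe = np.minimum(
            _lognormal_lengths(rng, 4096, config.long_read_mean_len, config.long_read_sigma),
            n,
        )
        n_reads = max(1, int(np.searchsorted(np.cumsum(probe), target)) + 1)
    alt_mols = {
        rp.repeat_id: [m for m, _ in build_alternative_molecules(genome, rp)]
        for rp in truth.repeats
        if truth.alt_fractions.get(rp.repeat_id, 0) > 0
    }
    rids = list(alt_mols)
    probs = np.array([truth.alt_fractions[r] for r in rids])
    if probs.sum() > 1:
        raise ConfigError("alternative fractions sum above 1")
    lengths = _lognormal_lengths(rng, n_reads, config.long_read_mean_len, config.long_read_sigma)
    reads = []
    for i in range(n_reads):
        u = rng.random()
        acc = 0.0
        source = "master"
        mol = genome.sequence
        for rid, p in zip(rids, probs):
            acc += p
            if u < acc:
                mols = alt_mols[rid]
                if len(mols) == 2 and mols[0] is not mols[1]:
                    w = len(mols[0]) / (len(mols[0]) + len(mols[1]))
                    mol = mols[0] if rng.random() < w else mols[1]
                else:
                    mol = mols[0]
                source = rid
                break
        start = int(rng.integers(0, len(mol)))
        seq = _read_from_circle(
            mol, start, int(lengths[i]), rng, True,
            config.long_read_sub_rate, config.long_read_indel_rate,
        )
        reads.append((f"lr{i:06d}|{source}", seq))
    truth.long_read_n50 = _n50([len(s) for _, s in reads])
    return reads


def simulate_spanning_reads(
    genome: CircularGenome,
    rp: RepeatPair,
    conf: ConformationPair,
    n_reads: int,
    alt_fraction: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Long reads conditioned on fully covering one junction of a repeat.

    A thin wrapper over the same molecule/error model as
    :func:`simulate_long_reads` that samples read start positions only from
    the window where the read covers a (randomly chosen) junction, which is
    the subpopulation the recombination frequency is estimated from.
    Returns (reads, true_labels).
    """
    n = len(genome)
    f = conf.flank
    L = rp.length
    jlen = L + 2 * f
    a = rp.unit_starts0()
    alt = build_alternative_molecules(genome, rp)
    reads, labels = [], []
    for i in range(n_reads):
        is_alt = rng.random() < alt_fraction
        j = int(rng.integers(0, 2))
        if is_alt:
            mol, unit_start = alt[j]
            jstart = (unit_start - f) % len(mol)
        else:
            mol, jstart = genome.sequence, (a[j] - f) % n
        length = int(
            _lognormal_lengths(rng, 1, config.long_read_mean_len, config.long_read_sigma)[0]
        )
        pad = 60  # indel slack so errors cannot shrink the read below the junction
        length = max(length, jlen + 2 * pad)
        length = min(length, len(mol))
        lo = jstart + jlen + pad - length
        hi = jstart - pad
        start = int(rng.integers(lo, hi + 1)) if hi >= lo else jstart - pad
        seq = _read_from_circle(
            mol, start % len(mol), length, rng, True,
            config.long_read_sub_rate, config.long_read_indel_rate,
        )
        reads.append(seq)
        labels.append("alternative" if is_alt else "master")
    return reads, labels


def _n50(lengths: Sequence[int]) -> int:
    xs = sorted(lengths, reverse=True)
    half = sum(xs) / 2
    acc = 0
    for x in xs:
        acc += x
        if acc >= half:
            return x
    return 0


# ---------------------------------------------------------------------------
# short reads
# ---------------------------------------------------------------------------


def simulate_short_reads(
    genome: CircularGenome,
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_pairs: int | None = None,
) -> list[tuple[str, str]]:
    """Paired ~150 bp reads (insert ~350 bp) from the conformational mixture.

    Returns (read1, read2) with read2 reverse-complemented (FR layout).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = len(genome)
    rl = config.short_read_len
    if n_pairs is None:
        n_pairs = ceil(config.short_read_depth * n / (2 * rl))
    alt_mols = {
        rp.repeat_id: [m for m, _ in build_alternative_molecules(genome, rp)]
        for rp in truth.repeats
        if truth.alt_fractions.get(rp.repeat_id, 0) > 0
    }
    rids = list(alt_mols)
    probs = [truth.alt_fractions[r] for r in rids]
    pairs = []
    for _ in range(n_pairs):
        u = rng.random()
        acc = 0.0
        mol = genome.sequence
        for rid, p in zip(rids, probs):
            acc += p
            if u < acc:
                mols = alt_mols[rid]
                w = len(mols[0]) / sum(len(m) for m in mols) if len(mols) == 2 else 1.0
                mol = mols[0] if rng.random() < w else mols[-1]
                break
        insert = max(2 * rl, int(rng.normal(config.insert_mean, config.insert_sd)))
        insert = min(insert, len(mol))
        start = int(rng.integers(0, len(mol)))
        frag = _read_from_circle(mol, start, insert, rng, False, 0.0, 0.0)
        r1 = mutate_read(frag[:rl], rng, config.short_read_sub_rate, 0.0)
        r2 = mutate_read(revcomp(frag[-rl:]), rng, config.short_read_sub_rate, 0.0)
        pairs.append((r1, r2))
    return pairs


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------


def simulate_rnaseq_reads(
    genes: Sequence[GeneAnnotation],
    transcripts: dict[str, str],
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    depth_override: dict[str, int] | None = None,
) -> list[ReadAlignment]:
    """Strand-aware transcript reads with planted edits, as alignments.

    Reads are emitted in transcript orientation (a strand-specific library);
    at each planted edit the alternative base appears independently with
    probability equal to the planted efficiency, then substitution errors
    are layered on top.  Reads are returned as alignment records on the
    spliced CDS references, directly consumable by the pileup.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    edits_by_gene: dict[str, list[PlantedEdit]] = {}
    for e in truth.edits:
        if e.cds_pos > len(transcripts[e.gene_id]):
            raise ConfigError(f"edit beyond CDS length for {e.gene_id}")
        edits_by_gene.setdefault(e.gene_id, []).append(e)
    out = []
    for gene in genes:
        tseq = transcripts[gene.gene_id]
        tlen = len(tseq)
        rl = min(config.rna_read_len, tlen)
        depth = (
            depth_override.get(gene.gene_id, config.rna_depth)
            if depth_override
            else config.rna_depth
        )
        n_reads = ceil(depth * tlen / rl)
        for i in range(n_reads):
            start = int(rng.integers(0, tlen - rl + 1))
            read = list(tseq[start : start + rl])
            for e in edits_by_gene.get(gene.gene_id, []):
                p = e.cds_pos - 1
                if start <= p < start + rl and rng.random() < e.efficiency:
                    read[p - start] = e.alt_base.replace("U", "T")
            seq = mutate_read("".join(read), rng, config.rna_sub_rate, 0.0)
            out.append(
                ReadAlignment(
                    gene_id=gene.gene_id,
                    seq=seq,
                    ref_start=start,
                    aligned_pairs=[(q, start + q) for q in range(len(seq))],
                    mapq=60,
                )
            )
    return out


def simulate_dna_pileup(
    genes: Sequence[GeneAnnotation],
    transcripts: dict[str, str],
    depth: int = 50,
):
    """Clean WGS pileup over the CDS coordinates (no variation planted).

    The study's DNA control found no SNPs in coding regions; this emulates
    that situation for the variant-exclusion filter.
    """
    from .editing import PileupSite

    sites = []
    for gene in genes:
        tseq = transcripts[gene.gene_id]
        for i, base in enumerate(tseq, 1):
            counts = {b: 0 for b in "ACGT"}
            counts[base] = depth
            sites.append(
                PileupSite(
                    gene_id=gene.gene_id,
                    cds_pos=i,
                    genome_pos=gene.cds_to_genome(i),
                    ref_base=base,
                    depth=depth,
                    base_counts=counts,
                )
            )
    return sites
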