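"""Repeat-mediated recombination: conformations, read votes, frequencies.

Homologous recombination between the two units of a dispersed repeat
rearranges a circular genome:

* a **direct** repeat subdivides the master circle into two subcircles, each
  carrying one (hybrid) repeat copy;
* an **inverted** repeat inverts the arc between the two units, yielding a
  single circle of unchanged length.

For each repeat pair we build *junction references*: the repeat unit plus
its two flanking regions (default 1000 bp) cut from the master circle and
from the explicitly constructed recombinant molecule(s).  A long read votes
for a conformation only when it completely covers one of that conformation's
junctions — repeat plus both full flanks — at sufficient identity, and beats
the best junction of the other conformation by a clear edit-distance margin.
The recombination frequency of a repeat is the fraction of informative
spanning reads supporting the alternative conformation.

Crossover breakpoints inside mismatched repeat copies are placed at the
repeat midpoint; the breakpoint is unobservable within identical sequence,
and any choice inside the repeat yields the same junction flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import edlib

from .io import CircularGenome, Interval, revcomp
from .repeats import RepeatPair

MASTER = "master"
ALTERNATIVE = "alternative"
AMBIGUOUS = "ambiguous"
UNINFORMATIVE = "uninformative"


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# conformation construction
# ---------------------------------------------------------------------------


@dataclass
class ConformationPair:
    """Master and alternative junction references for one repeat pair."""

    repeat_id: str
    flank: int
    master_junctions: tuple[str, str]
    alternative_junctions: tuple[str, str]
    informative: bool
    alternative_molecules: list[str] = field(default_factory=list)
    kind: str = ""  # "subdivision" (direct) | "inversion" (inverted)
    truncated: bool = False
    unit_seq: str = ""


def _extract_junction(molecule: str, unit_start: int, unit_len: int, flank: int) -> tuple[str, bool]:
    """Cut flank+unit+flank around a unit on a circular molecule.

    Returns (sequence, truncated); the junction is truncated when the
    molecule is shorter than the requested window.
    """
    cl = len(molecule)
    want = unit_len + 2 * flank
    take = min(want, cl)
    start = (unit_start - flank) % cl
    stop = start + take
    seq = molecule[start:stop] if stop <= cl else molecule[start:] + molecule[: stop - cl]
    return seq, take < want


def build_alternative_molecules(
    genome: CircularGenome, rp: RepeatPair
) -> list[tuple[str, int]]:
    """Explicit recombinant molecules for a repeat pair.

    Returns ``[(molecule_sequence, hybrid_unit_start), ...]`` — two
    subcircles for a direct repeat, one inverted-arc circle (with both
    hybrid unit starts, emitted as two entries sharing the sequence) for an
    inverted repeat.  Molecule sequences are linearized circles.
    """
    s = genome.sequence
    n = len(s)
    a1, a2 = rp.unit_starts0()
    L = rp.length
    mid = L // 2

    def circ(start: int, stop_unwrapped: int) -> str:
        arc = (stop_unwrapped - start) % n
        return genome.slice0(start, start + arc) if arc else ""

    b1, b2 = a1 + L, a2 + L
    if rp.orientation == "direct":
        hybrid1 = circ(a1, a1 + mid) + circ(a2 + mid, b2)
        hybrid2 = circ(a2, a2 + mid) + circ(a1 + mid, b1)
        circle1 = hybrid1 + circ(b2, a1)
        circle2 = hybrid2 + circ(b1, a2)
        return [(circle1, 0), (circle2, 0)]
    # inverted: reverse-complement the arc between the two crossover points
    c1 = a1 + mid
    c2 = (a2 + L - mid) % n if a2 + L - mid >= n else a2 + L - mid
    # build on a rotation starting at b2 (end of unit2) so the inverted arc
    # never straddles the string boundary even for origin-spanning repeats
    rot = b2 % n
    rs = genome.slice0(rot, rot + n)  # rotated master
    ra1 = (a1 - rot) % n
    rc1 = (c1 - rot) % n
    rc2 = (c2 - rot) % n
    alt = rs[:rc1] + revcomp(rs[rc1:rc2]) + rs[rc2:]
    # hybrid units sit at the original unit positions in rotated coordinates
    ra2 = (a2 - rot) % n
    return [(alt, ra1), (alt, ra2)]


def build_conformations(
    genome: CircularGenome, rp: RepeatPair, flank: int = 1000
) -> ConformationPair:
    """Master and alternative junction references for one repeat pair.

    Master junctions are cut straight from the circular genome around each
    unit; alternative junctions are cut from the explicitly constructed
    recombinant molecule(s).  When flanks do not fit on the available arcs
    the junctions are truncated and flagged.  The pair is uninformative when
    any alternative junction equals a master junction (e.g. identical
    flanks on both units).
    """
    n = len(genome)
    a1, a2 = rp.unit_starts0()
    L = rp.length

    mj = []
    truncated = False
    for a in (a1, a2):
        want = L + 2 * flank
        take = min(want, n)
        truncated |= take < want
        mj.append(genome.slice0((a - flank) % n, (a - flank) % n + take))

    molecules = build_alternative_molecules(genome, rp)
    aj = []
    for mol, unit_start in molecules:
        j, trunc = _extract_junction(mol, unit_start, L, flank)
        truncated |= trunc
        aj.append(j)

    informative = not (set(aj) & set(mj))
    if truncated:
        warnings.warn(
            f"{rp.repeat_id}: flank {flank} truncated to fit molecule arcs",
            stacklevel=2,
        )
    return ConformationPair(
        repeat_id=rp.repeat_id,
        flank=flank,
        master_junctions=(mj[0], mj[1]),
        alternative_junctions=(aj[0], aj[1]),
        informative=informative,
        alternative_molecules=[m for m, _ in molecules],
        kind="subdivision" if rp.orientation == "direct" else "inversion",
        truncated=truncated,
        unit_seq=rp.unit1_seq,
    )


# ---------------------------------------------------------------------------
# read classification
# ---------------------------------------------------------------------------


def _junction_distance(junction: str, read: str, k: int) -> int | None:
    """Semiglobal edit distance of the whole junction inside the read.

    None when the distance exceeds ``k`` (edlib band abandoned).
    """
    res = edlib.align(junction, read, mode="HW", task="distance", k=k)
    d = res["editDistance"]
    return None if d == -1 else d


def classify_read(
    read: str,
    conf: ConformationPair,
    min_identity: float = 0.75,
    min_margin: int = 5,
    _accelerate: bool = True,
) -> str:
    """Vote of one long read: master / alternative / ambiguous / uninformative.

    The read (either strand) is aligned semiglobally against all four
    junction references.  A junction counts as *covered* only when the whole
    reference aligns within the read at identity >= ``min_identity`` (the
    complete-coverage rule: repeat plus both full flanks).  The read votes
    for the conformation of its best junction when that beats the other
    conformation's best by at least ``min_margin`` edit distance; otherwise
    it is ambiguous.  Reads covering no junction are uninformative.

    ``_accelerate`` first locates the repeat unit in the read and aligns the
    junctions only against a window around it (plus slack); it falls back to
    whole-read alignment when the unit is not found.  Results are identical
    to whole-read alignment (checked in the test suite).
    """
    if not conf.informative:
        return UNINFORMATIVE

    junctions = list(conf.master_junctions) + list(conf.alternative_junctions)
    jlen = max(len(j) for j in junctions)
    k_cov = int((1.0 - min_identity) * jlen)
    k = k_cov + min_margin

    strands = [read, revcomp(read)]

    def measure(windows):
        best: dict[str, int | None] = {MASTER: None, ALTERNATIVE: None}
        cov = {MASTER: False, ALTERNATIVE: False}
        sides = ((MASTER, conf.master_junctions), (ALTERNATIVE, conf.alternative_junctions))
        for side, js in sides:
            for j in js:
                k_cov_j = int((1.0 - min_identity) * len(j))
                for w in windows:
                    d = _junction_distance(j, w, k_cov_j + min_margin)
                    if d is None:
                        continue
                    if d <= k_cov_j:
                        cov[side] = True
                    if best[side] is None or d < best[side]:
                        best[side] = d
        return best, cov

    windows = strands
    accel_used = False
    if _accelerate and conf.unit_seq and len(read) > 3 * len(conf.unit_seq):
        # find the repeat unit (either orientation) and align the junctions
        # only around it; both orientations of the window are kept so every
        # junction is still tested against both read strands
        slack = conf.flank + max(200, int(0.3 * len(conf.unit_seq)))
        unit = conf.unit_seq
        uk = max(10, int((1.0 - min_identity) * len(unit)))
        hits = []
        for strand_seq in strands:
            res = edlib.align(unit, strand_seq, mode="HW", task="locations", k=uk)
            if res["editDistance"] != -1 and res["locations"]:
                hits.append((res["editDistance"], strand_seq, res["locations"]))
        if hits:
            _, strand_seq, locations = min(hits, key=lambda h: h[0])
            lo = min(loc[0] for loc in locations if loc[0] is not None)
            hi = max(loc[1] for loc in locations)
            w = strand_seq[max(0, lo - slack) : hi + 1 + slack]
            windows = [w, revcomp(w)]
            accel_used = True

    best, cov = measure(windows)
    if accel_used and not (cov[MASTER] or cov[ALTERNATIVE]):
        # the unit hit may have been spurious; retry against the whole read
        best, cov = measure(strands)
    cov_m, cov_a = cov[MASTER], cov[ALTERNATIVE]
    if not cov_m and not cov_a:
        return UNINFORMATIVE
    dm = best[MASTER] if best[MASTER] is not None else k + 1
    da = best[ALTERNATIVE] if best[ALTERNATIVE] is not None else k + 1
    if cov_m and dm + min_margin <= da:
        return MASTER
    if cov_a and da + min_margin <= dm:
        return ALTERNATIVE
    return AMBIGUOUS


def classify_reads(
    reads: Iterable[str | tuple[str, str]],
    conf: ConformationPair,
    min_identity: float = 0.75,
    min_margin: int = 5,
) -> dict[str, int]:
    """Tally of classify_read votes over a read set."""
    counts = {MASTER: 0, ALTERNATIVE: 0, AMBIGUOUS: 0, UNINFORMATIVE: 0}
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        counts[classify_read(seq, conf, min_identity, min_margin)] += 1
    return counts


# ---------------------------------------------------------------------------
# frequency table
# ---------------------------------------------------------------------------


@dataclass
class RecombinationRecord:
    """One row of the recombination-frequency table."""

    repeat_id: str
    length: int
    orientation: str
    unit1: Interval
    unit2: Interval
    master_count: int
    alt_count: int
    master_pct: float
    alt_pct: float


def recombination_table(
    counts: Mapping[str, tuple[int, int]],
    repeats: Sequence[RepeatPair] | None = None,
) -> list[RecombinationRecord]:
    """Frequency table from per-repeat (master, alternative) read counts.

    Percentages use the informative-read denominator (master + alternative)
    and are rounded half-up to two decimals.  Rows are sorted by repeat
    length descending and renamed R1..Rn; rows with zero informative reads
    are suppressed with a warning.
    """
    by_id = {rp.repeat_id: rp for rp in repeats} if repeats else {}
    rows = []
    for rid, (m, a) in counts.items():
        if m < 0 or a < 0:
            raise ValueError("negative read counts")
        total = m + a
        if total == 0:
            warnings.warn(f"{rid}: no informative reads; row suppressed", stacklevel=2)
            continue
        rp = by_id.get(rid)
        rows.append(
            RecombinationRecord(
                repeat_id=rid,
                length=rp.length if rp else 0,
                orientation=rp.orientation if rp else "",
                unit1=rp.unit1 if rp else Interval(1, 1),
                unit2=rp.unit2 if rp else Interval(1, 1),
                master_count=m,
                alt_count=a,
                master_pct=round_half_up(100.0 * m / total, 2),
                alt_pct=round_half_up(100.0 * a / total, 2),
            )
        )
    rows.sort(key=lambda r: (-r.length, r.repeat_id))
    for i, row in enumerate(rows, 1):
        row.repeat_id = f"R{i}"
    return rows


# ---------------------------------------------------------------------------
# short-read screening
# ---------------------------------------------------------------------------


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def screen_short_reads(
    genome: CircularGenome,
    repeats: Sequence[RepeatPair],
    read_pairs: Sequence[tuple[str, str]],
    min_flank_evidence: int = 2,
    kmer: int = 21,
    flank_window: int = 250,
    max_insert: int = 600,
) -> list[str]:
    """Repeats whose short-read context shows non-master flank combinations.

    Each read pair is treated as one fragment.  For a repeat with units U1,
    U2 and flanks L1/R1, L2/R2, a fragment is assigned a left flank (via
    k-mers unique to the ``flank_window`` bases of L1 vs L2 adjacent to the
    unit) and a right flank likewise.  Master fragments combine (L1, R1) or
    (L2, R2); combinations (L1, R2) / (L2, R1) indicate an additional
    structure.  A repeat is flagged when any extra combination is supported
    by at least ``min_flank_evidence`` fragments.

    Repeats whose units lie closer than ``max_insert`` on the circle are
    skipped (a master fragment could bridge between the units, mimicking a
    recombinant combination), as are repeats with indistinguishable flanks.
    """
    n = len(genome)
    flagged = []
    for rp in repeats:
        a1, a2 = rp.unit_starts0()
        L = rp.length
        gap12 = (a2 - (a1 + L)) % n
        gap21 = (a1 - (a2 + L)) % n
        if min(gap12, gap21) < max_insert:
            continue
        w = min(flank_window, gap12, gap21)
        lf1 = genome.slice0((a1 - w) % n, (a1 - w) % n + w)
        lf2 = genome.slice0((a2 - w) % n, (a2 - w) % n + w)
        rf1 = genome.slice0((a1 + L) % n, (a1 + L) % n + w)
        rf2 = genome.slice0((a2 + L) % n, (a2 + L) % n + w)
        if rp.orientation == "inverted":
            # unit2's neighborhood in unit1's oriented frame
            lf2, rf2 = revcomp(rf2), revcomp(lf2)
        k1l, k2l = _kmers(lf1, kmer), _kmers(lf2, kmer)
        k1r, k2r = _kmers(rf1, kmer), _kmers(rf2, kmer)
        uniq = {
            ("L", 1): k1l - k2l,
            ("L", 2): k2l - k1l,
            ("R", 1): k1r - k2r,
            ("R", 2): k2r - k1r,
        }
        if not all(uniq.values()):
            continue  # indistinguishable flanks: overhangs carry no signal
        combos: dict[tuple[int, int], int] = {}
        for r1, r2 in read_pairs:
            frag_kmers = set()
            for seq in (r1, r2):
                frag_kmers |= _kmers(seq, kmer) | _kmers(revcomp(seq), kmer)
            left = [i for i in (1, 2) if frag_kmers & uniq[("L", i)]]
            right = [i for i in (1, 2) if frag_kmers & uniq[("R", i)]]
            if len(left) == 1 and len(right) == 1:
                combos[(left[0], right[0])] = combos.get((left[0], right[0]), 0) + 1
        extra = combos.get((1, 2), 0), combos.get((2, 1), 0)
        if max(extra) >= min_flank_evidence:
            flagged.append(rp.repeat_id)
    return flagged


# ---------------------------------------------------------------------------
# isomer enumeration
# ---------------------------------------------------------------------------


@dataclass
class IsomerSet:
    """Alternative configuration of the genome for one repeat pair.

    ``configurations`` is a list of molecules; each molecule is a list of
    oriented genome segments (0-based half-open, strand) whose total length
    over all molecules equals the genome length.
    """

    repeat_id: str
    kind: str  # "inversion" | "subdivision"
    configurations: list[list[tuple[int, int, str]]]


def enumerate_isomers(
    genome: CircularGenome, repeats: Sequence[RepeatPair]
) -> list[IsomerSet]:
    """Segment-level description of each repeat's alternative configuration."""
    n = len(genome)
    out = []
    for rp in repeats:
        a1, a2 = rp.unit_starts0()
        L = rp.length
        mid = L // 2
        if rp.orientation == "direct":
            # crossover at the midpoints subdivides the circle
            cut1 = (a1 + mid) % n
            cut2 = (a2 + mid) % n
            circle1 = [(cut2, cut1, "+")]
            circle2 = [(cut1, cut2, "+")]
            out.append(IsomerSet(rp.repeat_id, "subdivision", [circle1, circle2]))
        else:
            c1 = (a1 + mid) % n
            c2 = (a2 + L - mid) % n
            out.append(
                IsomerSet(
                    rp.repeat_id,
                    "inversion",
                    [[(c2, c1, "+"), (c1, c2, "-")]],
                )
            )
    return out


def segment_length(seg: tuple[int, int, str], n: int) -> int:
    start, stop, _ = seg
    return (stop - start) % n or n


def isomer_total_length(iso: IsomerSet, n: int) -> int:
    return sum(
        segment_length(seg, n) for mol in iso.configurations for seg in mol
    )
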