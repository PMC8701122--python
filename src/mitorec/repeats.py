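"""Dispersed repeat discovery with a mismatch budget.

Finds all *maximal* repeat pairs — forward ("direct") and palindromic
("inverted") — whose two units match under a Hamming-distance budget
(default 3) at a minimum length (default 30 bp), the classic settings used
for organelle-genome repeat surveys.  A pair is maximal when extending either
end by one base would exceed the mismatch budget or leave the genome arc.

The scan works diagonal-by-diagonal on the (doubled, for circular genomes)
sequence: along each alignment diagonal the mismatch positions are located
with numpy, and every maximal window containing at most ``max_mismatch``
mismatches falls out of simple index arithmetic on those positions.  This
enumerates exactly the maximal ≤k-mismatch stretches and vectorizes well;
it is O(n²) overall and intended for the ≤100 kb genomes this package
simulates and analyzes.

Statistical filtering uses the expected number of chance occurrences of a
length-L, m-mismatch match in a genome of length n:

    E = C(L, m) · 3^m · n² · 4^(−L)

computed in log space; pairs with E above ``evalue_max`` are discarded.
Pairs whose units overlap each other (tandem arrays) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .io import CircularGenome, GeneAnnotation, Interval, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 4  # sentinel; paired array uses 5 so N never matches


def _encode(seq: str, n_code: int = 4) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    arr[arr == 4] = n_code
    return arr


@dataclass
class RepeatPair:
    """Two repeat units with orientation, mismatch count and significance.

    ``unit1`` is the leftmost unit (ascending, plus orientation).  For
    inverted repeats ``unit2`` is reported minus-oriented (descending
    coordinates); ``unit2_seq`` is stored in genome-forward orientation and
    :meth:`oriented_unit2_seq` applies the orientation, so that
    ``hamming(unit1_seq, oriented_unit2_seq) == mismatches`` exactly.
    """

    repeat_id: str
    unit1: Interval
    unit2: Interval
    orientation: str  # "direct" | "inverted"
    length: int
    mismatches: int
    evalue: float
    unit1_seq: str
    unit2_seq: str
    wraps_origin: bool = False

    def oriented_unit2_seq(self) -> str:
        return revcomp(self.unit2_seq) if self.orientation == "inverted" else self.unit2_seq

    def unit_starts0(self) -> tuple[int, int]:
        """0-based starts of the two units in genome-forward coordinates."""
        s1, _, _ = self.unit1.to_internal()
        s2, _, _ = self.unit2.to_internal()
        return s1, s2


@dataclass(frozen=True)
class GeneCapture:
    """A gene whose full CDS span lies inside both units of a repeat pair."""

    gene_id: str
    repeat_id: str
    copy_number: int


def repeat_evalue(length: int, mismatches: int, genome_length: int) -> float:
    """Expected chance occurrences of a (length, mismatches) match.

    Monotone decreasing in length, increasing in mismatches.  Evaluated in
    log space so that long repeats do not underflow to spurious zeros before
    the comparison (exact zeros are still possible and simply pass any
    threshold).
    """
    if length < 1 or mismatches < 0:
        raise ValueError("length >= 1 and mismatches >= 0 required")
    log_choose = (
        gammaln(length + 1) - gammaln(mismatches + 1) - gammaln(length - mismatches + 1)
    )
    log_e = (
        log_choose
        + mismatches * log(3.0)
        + 2.0 * log(genome_length)
        - length * log(4.0)
    )
    if log_e < -700:
        return 0.0
    return float(exp(log_e))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y or x == "N" for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# diagonal scan
# ---------------------------------------------------------------------------


def _seed_run_length(min_len: int, k: int) -> int:
    """Pigeonhole: a ≥min_len window with ≤k mismatches has an exact run
    of at least ceil((min_len - k) / (k + 1))."""
    return max(1, -(-(min_len - k) // (k + 1)))


def _walk_mismatches(a, b, c, pos, direction, k, diag_len):
    """Up to k+1 mismatch positions on diagonal c from pos going one way.

    Returns (positions, hit_boundary); positions ordered away from pos.
    """
    out = []
    step = 128
    p = pos
    if direction < 0:
        while p >= 0 and len(out) <= k:
            lo = max(0, p - step + 1)
            seg = a[lo : p + 1] != b[lo + c : p + 1 + c]
            for q in np.flatnonzero(seg)[::-1]:
                out.append(lo + int(q))
                if len(out) > k:
                    break
            p = lo - 1
        return out[: k + 1], len(out) <= k
    while p < diag_len and len(out) <= k:
        hi = min(diag_len, p + step)
        seg = a[p:hi] != b[p + c : hi + c]
        for q in np.flatnonzero(seg):
            out.append(p + int(q))
            if len(out) > k:
                break
        p = hi
    return out[: k + 1], len(out) <= k


def _windows_at_run(a, b, c, run_start, k, min_len, diag_len):
    """All maximal ≤k-mismatch windows containing the exact run at run_start.

    Expands left/right to the blocking mismatches and enumerates every split
    of the budget across the two sides; a window is maximal when it holds
    exactly k mismatches or spans the whole diagonal within budget.
    """
    # extend the exact run itself (cheap, vectorized in chunks)
    re_ = run_start
    step = 256
    while re_ < diag_len:
        hi = min(diag_len, re_ + step)
        seg = a[re_:hi] != b[re_ + c : hi + c]
        nz = np.flatnonzero(seg)
        if nz.size:
            re_ += int(nz[0])
            break
        re_ = hi
    left, left_open = _walk_mismatches(a, b, c, run_start - 1, -1, k, diag_len)
    right, right_open = _walk_mismatches(a, b, c, re_, +1, k, diag_len)
    results = []
    for l in range(k + 1):
        r = k - l
        if l < len(left):
            lb = left[l]
            l_inc = l
        elif left_open:
            lb = -1
            l_inc = len(left)
        else:
            continue
        if r < len(right):
            rb = right[r]
            r_inc = r
        elif right_open:
            rb = diag_len
            r_inc = len(right)
        else:
            continue
        mm = l_inc + r_inc
        if mm == k or (lb == -1 and rb == diag_len):
            length = rb - lb - 1
            if length >= min_len:
                results.append((lb + 1, length, mm))
    return results, re_


def _scan_pair(a, b, c_lo, c_hi, k, min_len, emit, block=64):
    """Emit maximal windows for diagonals c in [c_lo, c_hi).

    Diagonal c aligns a[i] with b[i + c].  The block scan screens for exact
    seed runs (pigeonhole length) across ``block`` diagonals at once, then
    enumerates maximal windows only around the rare seed hits.
    """
    la, lb = a.size, b.size
    seed = min(_seed_run_length(min_len, k), 12)
    bp = np.concatenate([b, np.full(c_hi + la - lb + 1, 255, dtype=np.uint8)])
    for c0 in range(c_lo, c_hi, block):
        nb = min(block, c_hi - c0)
        width = min(la, max(lb - c0, 1))  # longest diagonal in this block
        rows = np.lib.stride_tricks.sliding_window_view(bp, width)[c0 : c0 + nb]
        m = a[None, :width] == rows
        # positions starting an exact run of >= seed matches (binary doubling)
        r = m
        got = 1
        while got < seed:
            shift = min(got, seed - got)
            r = r[:, : r.shape[1] - shift] & r[:, shift:]
            got += shift
        memo_hi = {}
        for t, i in np.argwhere(r):
            c = c0 + int(t)
            i = int(i)
            if i < memo_hi.get(c, 0):
                continue
            diag_len = min(la, lb - c)
            if i >= diag_len:
                continue
            wins, run_end = _windows_at_run(a, b, c, i, k, min_len, diag_len)
            memo_hi[c] = run_end
            for start, length, mm in wins:
                emit(c, start, length, mm)


def find_maximal_repeats(
    genome: CircularGenome,
    min_length: int = 30,
    max_mismatch: int = 3,
    evalue_max: float | None = 1e-5,
    kinds: Iterable[str] = ("direct", "inverted"),
    circular: bool | None = None,
) -> list[RepeatPair]:
    """All maximal repeat pairs meeting the length/mismatch/e-value thresholds.

    Pairs are deduplicated so each {unit1, unit2} set is reported once with
    ``unit1`` leftmost; pairs whose units overlap each other are excluded.
    When ``circular`` (default: the genome's flag), repeats spanning the
    origin are found by scanning the doubled sequence capped at one wrap and
    are flagged via ``wraps_origin``.
    """
    if circular is None:
        circular = genome.is_circular
    s = genome.sequence
    n = len(s)
    kinds = set(kinds)

    x = s + s if circular else s
    a_dir = _encode(x, n_code=4)
    b_dir = _encode(x, n_code=5)
    r = revcomp(x)
    b_inv = _encode(r, n_code=5)
    m_scan = len(x)

    found: dict[tuple, tuple] = {}

    def _add(u1: int, u2: int, length: int, mm: int, orientation: str) -> None:
        # u1, u2: genome-forward 0-based starts (may exceed n when circular)
        u1 %= n
        u2 %= n
        wraps = u1 + length > n or u2 + length > n
        if u1 == u2:
            return
        d = (u2 - u1) % n if circular else u2 - u1
        if circular:
            if min(d, n - d) < length:  # units overlap on the circle
                return
        else:
            if abs(u2 - u1) < length:
                return
        key = (min(u1, u2), max(u1, u2), length, orientation)
        if key not in found:
            found[key] = (u1, u2, length, mm, orientation, wraps)

    if "direct" in kinds:

        def emit_direct(c, w0, wlen, mm):
            if circular and (w0 >= n or wlen > n):
                return
            _add(w0, w0 + c, wlen, mm, "direct")

        _scan_pair(a_dir, b_dir, 1, n, max_mismatch, min_length, emit_direct)

    if "inverted" in kinds:
        # align x against r = revcomp(x): pair (i, q) in (x, r) space means
        # a unit at x position i matching the reverse complement of the unit
        # whose x start is m_scan - q - L.  Nonnegative (x, r) diagonals are
        # scanned directly; negative ones via the swapped pair (r, x).
        def emit_inv1(c, w0, wlen, mm):
            i, q = w0, w0 + c
            _emit_inverted(i, q, wlen, mm)

        def emit_inv2(c, w0, wlen, mm):
            q, i = w0, w0 + c
            _emit_inverted(i, q, wlen, mm)

        def _emit_inverted(i, q, wlen, mm):
            j = m_scan - q - wlen  # unit2 start in x coordinates
            if j < 0:
                return
            if circular and (min(i, j) >= n or wlen > n):
                return
            u1, u2 = (i, j) if i <= j else (j, i)
            _add(u1, u2, wlen, mm, "inverted")

        a_inv = _encode(r, 4)
        _scan_pair(a_dir, b_inv, 0, m_scan, max_mismatch, min_length, emit_inv1)
        _scan_pair(a_inv, b_dir, 1, m_scan, max_mismatch, min_length, emit_inv2)

    pairs: list[RepeatPair] = []
    for (u1, u2, length, mm, orientation, wraps) in found.values():
        if circular and not _circular_maximal(
            genome, u1, u2, length, mm, orientation, max_mismatch
        ):
            # scan-boundary truncation artifact of the doubled sequence; the
            # genuinely maximal window is reported separately
            continue
        ev = repeat_evalue(length, mm, n)
        if evalue_max is not None and ev > evalue_max:
            continue
        seq1 = _unit_seq(genome, u1, length)
        seq2 = _unit_seq(genome, u2, length)
        # re-verify the mismatch count on re-extraction
        oriented2 = revcomp(seq2) if orientation == "inverted" else seq2
        mm_check = hamming(seq1, oriented2)
        if mm_check != mm or mm_check > max_mismatch:
            continue
        unit1 = _make_interval(u1, length, "+", n)
        strand2 = "-" if orientation == "inverted" else "+"
        unit2 = _make_interval(u2, length, strand2, n)
        pairs.append(
            RepeatPair(
                repeat_id="",
                unit1=unit1,
                unit2=unit2,
                orientation=orientation,
                length=length,
                mismatches=mm,
                evalue=ev,
                unit1_seq=seq1,
                unit2_seq=seq2,
                wraps_origin=wraps,
            )
        )
    pairs.sort(key=lambda p: (p.unit_starts0(), -p.length))
    for i, p in enumerate(pairs, 1):
        p.repeat_id = f"rep{i:04d}"
    return pairs


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _circular_maximal(
    genome: CircularGenome,
    u1: int,
    u2: int,
    length: int,
    mm: int,
    orientation: str,
    k: int,
) -> bool:
    """Can the pair be extended by one base on either side within the budget?

    Extension is blocked when it would push mismatches beyond ``k`` or make
    the two units collide on the circle (exit the genome arc).
    """
    s = genome.sequence
    n = len(s)
    d = (u2 - u1) % n
    if length + 1 > min(d, n - d):
        return True  # any extension makes the units overlap: maximal
    for side in ("left", "right"):
        if side == "left":
            b1 = s[(u1 - 1) % n]
            if orientation == "direct":
                b2 = s[(u2 - 1) % n]
            else:
                b2 = _COMP[s[(u2 + length) % n]]
        else:
            b1 = s[(u1 + length) % n]
            if orientation == "direct":
                b2 = s[(u2 + length) % n]
            else:
                b2 = _COMP[s[(u2 - 1) % n]]
        added = 1 if (b1 != b2 or b1 == "N") else 0
        if mm + added <= k:
            return False  # extendable: not maximal
    return True


def _unit_seq(genome: CircularGenome, start0: int, length: int) -> str:
    return genome.slice0(start0, start0 + length)


def _make_interval(start0: int, length: int, strand: str, n: int) -> Interval:
    """Reported interval for a unit.

    Units wrapping the origin keep an unwrapped end (> n) so the interval
    stays ascending; the pair's ``wraps_origin`` flag marks the case.
    """
    start1 = start0 + 1
    end1 = start0 + length
    if strand == "+":
        return Interval(start1, end1, "+")
    return Interval(end1, start1, "-")


def select_representatives(pairs: Sequence[RepeatPair]) -> list[RepeatPair]:
    """One representative per cluster of mutually overlapping repeat pairs.

    Around a biological repeat the scan reports several maximal windows that
    differ only in how the mismatch budget is spent at the edges.  Pairs of
    the same orientation whose unit1 and unit2 intervals both overlap are
    clustered; the longest pair wins (ties: fewer mismatches, then leftmost),
    mirroring the one-row-per-repeat convention of recombination tables.
    """
    remaining = sorted(
        pairs, key=lambda p: (-p.length, p.mismatches, p.unit_starts0())
    )
    chosen: list[RepeatPair] = []
    for cand in remaining:
        c1, c2 = cand.unit_starts0()
        clash = False
        for rep in chosen:
            if rep.orientation != cand.orientation:
                continue
            r1, r2 = rep.unit_starts0()
            if (
                c1 < r1 + rep.length
                and r1 < c1 + cand.length
                and c2 < r2 + rep.length
                and r2 < c2 + cand.length
            ):
                clash = True
                break
        if not clash:
            chosen.append(cand)
    chosen.sort(key=lambda p: p.unit_starts0())
    return chosen


# ---------------------------------------------------------------------------
# gene capture
# ---------------------------------------------------------------------------


def _arc_contains(unit_start0: int, unit_len: int, span: tuple[int, int], n: int, circular: bool) -> bool:
    """Is the 1-based inclusive genomic span contained in the unit's arc?"""
    gs0, ge0 = span[0] - 1, span[1]  # half-open
    if not circular:
        return unit_start0 <= gs0 and ge0 <= unit_start0 + unit_len
    rel = (gs0 - unit_start0) % n
    return rel + (ge0 - gs0) <= unit_len


def detect_gene_capture(
    repeats: Sequence[RepeatPair],
    genes: Sequence[GeneAnnotation],
    genome_length: int | None = None,
    circular: bool = True,
) -> list[GeneCapture]:
    """Genes whose full CDS span lies within a unit of a repeat pair.

    Containment is strict (partial overlap does not count).  Because the
    other unit is a copy of the containing one, a captured gene is present
    in both units; ``copy_number`` is that number of carrying units (2).
    """
    captures = []
    for rp in repeats:
        n = genome_length or max(rp.unit1.end, max(rp.unit2.start, rp.unit2.end))
        s1, s2 = rp.unit_starts0()
        for gene in genes:
            inside = sum(
                _arc_contains(s, rp.length, gene.span, n, circular) for s in (s1, s2)
            )
            if inside:
                captures.append(GeneCapture(gene.gene_id, rp.repeat_id, 2))
    return captures
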