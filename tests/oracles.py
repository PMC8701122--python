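"""Independent brute-force oracles used by the test suite.

These deliberately take different computational routes from the library:
repeat enumeration walks every alignment diagonal with cumulative mismatch
counts and binary search; conformation junctions are read off explicitly
constructed recombinant molecules.
"""

from __future__ import annotations

import numpy as np

from mitorec.io import CircularGenome, revcomp


def _codes(seq: str, n_code: int) -> np.ndarray:
    table = np.full(256, 99, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    table[ord("N")] = n_code
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def brute_force_repeats(
    seq: str, min_length: int = 30, max_mismatch: int = 3
) -> set[tuple[int, int, int, int, str]]:
    """All maximal ≤k-mismatch repeat pairs of a *linear* sequence.

    Returns tuples (unit1_start0, unit2_start0, length, mismatches,
    orientation) with unit1 leftmost and overlapping-unit (tandem) pairs
    excluded.  A window is maximal iff its start is blocked on the left
    (sequence start or a mismatch that would exceed the budget) and its end
    is the farthest position keeping at most k mismatches.
    """
    n = len(seq)
    k = max_mismatch
    out: set[tuple[int, int, int, int, str]] = set()

    def scan(a: np.ndarray, b: np.ndarray, diagonals, mapper):
        la, lb = a.size, b.size
        for c in diagonals:
            i0 = max(0, -c)
            j0 = i0 + c
            L = min(la - i0, lb - j0)
            if L < min_length:
                continue
            mm = (a[i0 : i0 + L] != b[j0 : j0 + L]).astype(np.int64)
            cs = np.concatenate(([0], np.cumsum(mm)))
            starts = np.flatnonzero(np.concatenate(([1], mm[:-1])))
            ends = np.searchsorted(cs, cs[starts] + k, side="right") - 1
            lens = ends - starts
            mms = cs[ends] - cs[starts]
            keep = (lens >= min_length) & ((mms == k) | ((starts == 0) & (ends == L)))
            for s0, e0, m in zip(starts[keep], ends[keep], mms[keep]):
                mapper(i0 + int(s0), j0 + int(s0), int(e0 - s0), int(m))

    a4 = _codes(seq, 4)
    b5 = _codes(seq, 5)  # N codes differ so N never matches, even N vs N

    def map_direct(i, j, L, m):
        u1, u2 = sorted((i, j))
        if u2 - u1 >= L:
            out.add((u1, u2, L, m, "direct"))

    scan(a4, b5, range(1, n), map_direct)

    r5 = _codes(revcomp(seq), 5)

    def map_inverted(i, q, L, m):
        j = n - q - L
        u1, u2 = sorted((i, j))
        if u2 != u1 and u2 - u1 >= L:
            out.add((u1, u2, L, m, "inverted"))

    scan(a4, r5, range(-(n - 1), n), map_inverted)
    return out


def repeat_set(pairs) -> set[tuple[int, int, int, int, str]]:
    """Project RepeatPair objects onto the oracle's tuple representation."""
    out = set()
    for p in pairs:
        s1, s2 = p.unit_starts0()
        u1, u2 = sorted((s1, s2))
        out.add((u1, u2, p.length, p.mismatches, p.orientation))
    return out


# ---------------------------------------------------------------------------
# conformation oracle
# ---------------------------------------------------------------------------


def explicit_alternative_junctions(
    genome: CircularGenome,
    u1_start0: int,
    u2_start0: int,
    length: int,
    orientation: str,
    flank: int,
) -> list[str]:
    """Junctions read off explicitly built recombinant molecules.

    Direct repeats: build the two subcircles produced by crossover at the
    repeat midpoint and cut each junction (flank + hybrid unit + flank) out
    of them.  Inverted repeats: build the single recombinant circle with the
    arc between the two crossover points reverse-complemented, then cut the
    junctions around both hybrid units.
    """
    s = genome.sequence
    n = len(s)
    a1, a2 = u1_start0, u2_start0
    b1, b2 = a1 + length, a2 + length
    mid = length // 2

    def circ(start, stop):  # [start, stop) with wrap, on the master circle
        arc = (stop - start) % n
        return genome.slice0(start, start + arc) if arc else ""

    if orientation == "direct":
        hybrid1 = circ(a1, a1 + mid) + circ(a2 + mid, b2)
        hybrid2 = circ(a2, a2 + mid) + circ(a1 + mid, b1)
        circle1 = hybrid1 + circ(b2, a1)  # hybrid copy + arc unit2-end -> unit1-start
        circle2 = hybrid2 + circ(b1, a2)  # hybrid copy + arc unit1-end -> unit2-start
        out = []
        for circle in (circle1, circle2):
            cl = len(circle)
            mol = CircularGenome("alt", circle, is_circular=True)
            take = min(length + 2 * flank, cl)
            start = (-flank) % cl
            out.append(mol.slice0(start, start + take))
        return out

    # inverted: crossover points at aligned offset mid in both units
    c1 = a1 + mid
    c2 = b2 - mid
    if c2 < c1:
        raise ValueError("units out of order for inverted oracle")
    alt = s[:c1] + revcomp(s[c1:c2]) + s[c2:]
    alt_mol = CircularGenome("alt", alt, is_circular=True)
    out = []
    for a, b in ((a1, b1), (a2, b2)):
        take = min(length + 2 * flank, n)
        out.append(alt_mol.slice0(a - flank, a - flank + take))
    return out
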