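"""Shared fixtures and sequence helpers for the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mitorec.io import CircularGenome, revcomp

_B = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_B[rng.integers(0, 4, n)]).decode()


def mutate_bases(seq: str, positions, rng) -> str:
    s = list(seq)
    for p in positions:
        s[p] = [b for b in "ACGT" if b != s[p]][int(rng.integers(0, 3))]
    return "".join(s)


def plant_repeat_genome(
    rng: np.random.Generator,
    n: int,
    placements: list[tuple[int, int, int, str, int]],
) -> str:
    """Random sequence with repeats planted at (pos1, pos2, length,
    orientation, n_mismatches)."""
    s = list(random_seq(rng, n))
    for pos1, pos2, length, orientation, mm in placements:
        unit = random_seq(rng, length)
        copy = mutate_bases(unit, rng.choice(length, mm, replace=False), rng) if mm else unit
        if orientation == "inverted":
            copy = revcomp(copy)
        s[pos1 : pos1 + length] = list(unit)
        s[pos2 : pos2 + length] = list(copy)
    return "".join(s)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_genome(rng):
    return CircularGenome("toy", random_seq(rng, 600), is_circular=True)
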