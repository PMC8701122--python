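"""Conformation building, read classification and frequency tables."""

import warnings

import numpy as np
import pytest

from mitorec.io import CircularGenome, Interval, revcomp
from mitorec.recombination import (
    ALTERNATIVE,
    AMBIGUOUS,
    MASTER,
    UNINFORMATIVE,
    build_conformations,
    classify_read,
    classify_reads,
    enumerate_isomers,
    isomer_total_length,
    recombination_table,
    round_half_up,
    screen_short_reads,
)
from mitorec.repeats import RepeatPair
from mitorec.simulate import (
    PlantedRepeat,
    SimConfig,
    mutate_read,
    simulate_genome,
    simulate_short_reads,
    simulate_spanning_reads,
)

from conftest import random_seq
from oracles import explicit_alternative_junctions


def make_pair(genome, a1, a2, length, orientation, repeat_id="r1"):
    u1 = genome.slice0(a1, a1 + length)
    u2 = genome.slice0(a2, a2 + length)
    unit2 = (
        Interval(a2 + length, a2 + 1, "-")
        if orientation == "inverted"
        else Interval(a2 + 1, a2 + length, "+")
    )
    return RepeatPair(
        repeat_id, Interval(a1 + 1, a1 + length, "+"), unit2,
        orientation, length, 0, 0.0, u1, u2,
    )


def planted_circle(rng, n, a1, a2, length, orientation):
    s = list(random_seq(rng, n))
    x = random_seq(rng, length)
    s[a1 : a1 + length] = list(x)
    copy = revcomp(x) if orientation == "inverted" else x
    for i, b in enumerate(copy):
        s[(a2 + i) % n] = b
    return CircularGenome("g", "".join(s), is_circular=True)


class TestBuildConformations:
    @pytest.mark.parametrize("orientation", ["direct", "inverted"])
    def test_alt_junctions_equal_explicit_molecule_oracle(self, rng, orientation):
        g = planted_circle(rng, 10_000, 2000, 6000, 200, orientation)
        rp = make_pair(g, 2000, 6000, 200, orientation)
        conf = build_conformations(g, rp, flank=500)
        oracle = explicit_alternative_junctions(g, 2000, 6000, 200, orientation, 500)
        assert sorted(conf.alternative_junctions) == sorted(oracle)
        assert conf.informative
        assert conf.kind == ("subdivision" if orientation == "direct" else "inversion")

    def test_direct_alt_junctions_swap_flanks(self, rng):
        """Direct repeat: alternative junctions pair unit1's left flank with
        unit2's right flank and vice versa."""
        g = planted_circle(rng, 10_000, 2000, 6000, 200, "direct")
        rp = make_pair(g, 2000, 6000, 200, "direct")
        f = 500
        conf = build_conformations(g, rp, flank=f)
        x = g.slice0(2000, 2200)
        j1 = g.slice0(1500, 2000) + x + g.slice0(6200, 6700)
        j2 = g.slice0(5500, 6000) + x + g.slice0(2200, 2700)
        assert sorted(conf.alternative_junctions) == sorted([j1, j2])

    @pytest.mark.parametrize("orientation", ["direct", "inverted"])
    def test_origin_spanning_repeat_matches_rotated_genome(self, rng, orientation):
        """Junctions are rotation-invariant, so an origin-spanning unit must
        give the same junction set as the same repeat on a rotated genome."""
        n, L = 8000, 150
        g = planted_circle(rng, n, 200, 5000, L, orientation)
        rot = 280  # moves unit1 (at 200) across the origin
        g_shift = CircularGenome("g", g.sequence[rot:] + g.sequence[:rot], True)
        a1s, a2s = (200 - rot) % n, 5000 - rot
        rp = make_pair(g, 200, 5000, L, orientation)
        rp_s = make_pair(g_shift, a1s, a2s, L, orientation)
        assert a1s + L > n  # really wraps
        c1 = build_conformations(g, rp, flank=300)
        c2 = build_conformations(g_shift, rp_s, flank=300)
        assert sorted(c1.alternative_junctions) == sorted(c2.alternative_junctions)
        assert sorted(c1.master_junctions) == sorted(c2.master_junctions)

    def test_identical_flanks_are_uninformative(self, rng):
        n = 8000
        s = list(random_seq(rng, n))
        x = random_seq(rng, 120)
        flank = random_seq(rng, 400)
        block = flank + x + flank  # same 400 bp flanks on both units
        s[1000 : 1000 + len(block)] = list(block)
        s[4000 : 4000 + len(block)] = list(block)
        g = CircularGenome("g", "".join(s), is_circular=True)
        rp = make_pair(g, 1400, 4400, 120, "direct")
        conf = build_conformations(g, rp, flank=400)
        assert not conf.informative
        assert classify_read(g.slice0(900, 2200), conf) == UNINFORMATIVE


class TestClassifyRead:
    @pytest.fixture
    def setup(self, rng):
        g = planted_circle(rng, 12_000, 2000, 7000, 300, "inverted")
        rp = make_pair(g, 2000, 7000, 300, "inverted")
        conf = build_conformations(g, rp, flank=1000)
        return g, rp, conf

    def test_error_free_master_read_votes_master(self, setup):
        g, rp, conf = setup
        read = g.slice0(2000 - 1200, 2000 + 300 + 1200)
        assert classify_read(read, conf) == MASTER
        assert classify_read(revcomp(read), conf) == MASTER

    def test_noisy_alternative_read_votes_alternative(self, setup, rng):
        g, rp, conf = setup
        mol = conf.alternative_molecules[0]
        jidx = mol.find(conf.alternative_junctions[0][100:-100])
        window = mol[jidx - 300 : jidx + len(conf.alternative_junctions[0]) + 300]
        noisy = mutate_read(window, rng, sub_rate=0.05, indel_rate=0.0)
        assert classify_read(noisy, conf) == ALTERNATIVE

    def test_partial_flank_coverage_is_uninformative(self, setup):
        """A read covering the repeat but only half of one flank violates the
        complete-junction-coverage rule."""
        g, rp, conf = setup
        read = g.slice0(2000 - 500, 2000 + 300 + 500)
        assert classify_read(read, conf) == UNINFORMATIVE

    def test_direction_independence_swapping_roles_swaps_counts(self, rng):
        g = planted_circle(rng, 12_000, 2000, 7000, 250, "direct")
        rp = make_pair(g, 2000, 7000, 250, "direct")
        conf = build_conformations(g, rp, flank=600)
        swapped = type(conf)(
            repeat_id=conf.repeat_id,
            flank=conf.flank,
            master_junctions=conf.alternative_junctions,
            alternative_junctions=conf.master_junctions,
            informative=conf.informative,
            alternative_molecules=conf.alternative_molecules,
            kind=conf.kind,
            unit_seq=conf.unit_seq,
        )
        cfg = SimConfig(seed=0, genome_length=12_000, long_read_mean_len=4000)
        reads, _ = simulate_spanning_reads(
            g, rp, conf, 60, 0.3, cfg, np.random.default_rng(5)
        )
        c1 = classify_reads(reads, conf)
        c2 = classify_reads(reads, swapped)
        assert c1[MASTER] == c2[ALTERNATIVE]
        assert c1[ALTERNATIVE] == c2[MASTER]

    def test_accelerated_equals_full_alignment(self, setup, rng):
        g, rp, conf = setup
        cfg = SimConfig(seed=0, genome_length=12_000, long_read_mean_len=5000)
        reads, _ = simulate_spanning_reads(
            g, rp, conf, 40, 0.2, cfg, np.random.default_rng(9)
        )
        for read in reads:
            assert classify_read(read, conf) == classify_read(
                read, conf, _accelerate=False
            )


class TestRecombinationTable:
    def test_percentages_round_half_up_to_two_decimals(self):
        rows = recombination_table({"a": (182, 11), "b": (135, 4), "c": (10, 0)})
        by_counts = {(r.master_count, r.alt_count): r for r in rows}
        assert by_counts[(182, 11)].master_pct == 94.30
        assert by_counts[(182, 11)].alt_pct == 5.70
        assert by_counts[(135, 4)].alt_pct == 2.88
        assert by_counts[(10, 0)].alt_pct == 0.00
        for r in rows:
            assert 99.99 <= r.master_pct + r.alt_pct <= 100.01

    def test_rows_sorted_by_length_and_renamed(self, rng):
        g = planted_circle(rng, 9000, 1000, 5000, 200, "direct")
        rp_long = make_pair(g, 1000, 5000, 200, "direct", "x")
        rp_short = make_pair(g, 1500, 6000, 100, "direct", "y")
        rows = recombination_table(
            {"x": (50, 5), "y": (40, 2)}, [rp_long, rp_short]
        )
        assert [r.repeat_id for r in rows] == ["R1", "R2"]
        assert rows[0].length == 200

    def test_zero_informative_row_suppressed_with_warning(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            rows = recombination_table({"a": (0, 0), "b": (3, 1)})
        assert len(rows) == 1
        assert any("suppressed" in str(x.message) for x in w)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            recombination_table({"a": (-1, 2)})


class TestScreenShortReads:
    def _sim(self, rng_seed, alt_fraction, depth=400, length=150):
        cfg = SimConfig(
            seed=rng_seed,
            genome_length=12_000,
            short_read_depth=depth,
            planted_repeats=(
                PlantedRepeat(length, "direct", 0, alt_fraction=alt_fraction),
            ),
        )
        g, _, truth = simulate_genome(cfg)
        pairs = simulate_short_reads(g, truth, cfg)
        return g, truth, pairs

    def test_mixture_is_flagged(self):
        g, truth, pairs = self._sim(1, alt_fraction=0.10)
        assert screen_short_reads(g, truth.repeats, pairs) == ["rep0001"]

    def test_master_only_not_flagged(self):
        g, truth, pairs = self._sim(1, alt_fraction=0.0)
        assert screen_short_reads(g, truth.repeats, pairs) == []

    def test_identical_flanks_not_flagged(self, rng):
        n = 12_000
        s = list(random_seq(rng, n))
        x = random_seq(rng, 150)
        flank = random_seq(rng, 300)
        for pos in (2000, 7000):
            s[pos - 300 : pos] = list(flank)
            s[pos : pos + 150] = list(x)
            s[pos + 150 : pos + 450] = list(flank)
        g = CircularGenome("g", "".join(s), is_circular=True)
        rp = make_pair(g, 2000, 7000, 150, "direct")
        cfg = SimConfig(seed=3, genome_length=n, short_read_depth=300)
        from mitorec.simulate import TruthTable

        truth = TruthTable(repeats=[rp], alt_fractions={"r1": 0.2})
        pairs = simulate_short_reads(g, truth, cfg)
        assert screen_short_reads(g, [rp], pairs) == []


class TestIsomers:
    def test_direct_repeat_subdivides_conserving_length(self, rng):
        g = planted_circle(rng, 9000, 1000, 5000, 120, "direct")
        rp = make_pair(g, 1000, 5000, 120, "direct")
        (iso,) = enumerate_isomers(g, [rp])
        assert iso.kind == "subdivision"
        assert len(iso.configurations) == 2
        assert isomer_total_length(iso, len(g)) == len(g)

    def test_inverted_repeat_inverts_one_circle(self, rng):
        g = planted_circle(rng, 9000, 1000, 5000, 120, "inverted")
        rp = make_pair(g, 1000, 5000, 120, "inverted")
        (iso,) = enumerate_isomers(g, [rp])
        assert iso.kind == "inversion"
        assert len(iso.configurations) == 1
        strands = {o for _, _, o in iso.configurations[0]}
        assert strands == {"+", "-"}
        assert isomer_total_length(iso, len(g)) == len(g)

    def test_three_repeats_three_isomer_sets(self, rng):
        g = CircularGenome("g", random_seq(rng, 20_000), is_circular=True)
        rps = [
            make_pair(g, 1000, 8000, 511, "inverted", "R1"),
            make_pair(g, 2000, 12_000, 393, "inverted", "R3"),
            make_pair(g, 3000, 16_000, 294, "direct", "R6"),
        ]
        isos = enumerate_isomers(g, rps)
        assert [i.kind for i in isos] == ["inversion", "inversion", "subdivision"]
        assert all(isomer_total_length(i, len(g)) == len(g) for i in isos)


class TestRounding:
    @pytest.mark.parametrize(
        "value,nd,expected",
        [(94.3005, 2, 94.30), (5.6995, 2, 5.70), (84.375, 1, 84.4), (15.625, 1, 15.6), (0.005, 2, 0.01)],
    )
    def test_half_up(self, value, nd, expected):
        assert round_half_up(value, nd) == expected
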