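"""Pileup construction, editing-site calling, start codons, summaries."""

import numpy as np
import pytest

from mitorec.editing import (
    EDIT_TYPES,
    EditingSite,
    PileupSite,
    ReadAlignment,
    call_editing_sites,
    classify_edit,
    detect_start_codon_editing,
    filter_genomic_variants,
    pileup_from_alignments,
    share_pct,
    summarize_editing,
)
from mitorec.io import CircularGenome, GeneAnnotation, revcomp

from conftest import random_seq


def perfect_reads(gene_id, transcript, n):
    return [
        ReadAlignment(
            gene_id, transcript, 0, [(q, q) for q in range(len(transcript))]
        )
        for _ in range(n)
    ]


def site(gene="g", pos=5, ref="C", depth=10, alt="T", edited=5, genome_pos=0):
    counts = {b: 0 for b in "ACGT"}
    counts[ref] = depth - edited
    counts[alt] = edited
    return PileupSite(gene, pos, genome_pos, ref, depth, counts)


class TestPileup:
    def test_error_free_reads_give_uniform_reference_pileup(self):
        t = "ATGGCTCATTAA"
        gene = GeneAnnotation("g", "+", [(1, 12)])
        pile = pileup_from_alignments(perfect_reads("g", t, 20), [gene], {"g": t})
        assert len(pile) == 12
        assert all(p.depth == 20 for p in pile)
        assert all(p.base_counts[p.ref_base] == 20 for p in pile)

    def test_minus_strand_genomic_mismatch_reports_transcript_strand(self, rng):
        """A genome-orientation G->A variant inside a minus-strand gene must
        surface as C->U on the transcript strand (manual strand-flip oracle)."""
        seq = list(random_seq(rng, 30))
        gene = GeneAnnotation("m", "-", [(4, 27)])
        genome = CircularGenome("g", "".join(seq), is_circular=True)
        t = gene.transcript(genome)
        # pick a transcript position whose genome base is G (transcript C)
        pos = next(i for i, b in enumerate(t, 1) if b == "C")
        read = t[: pos - 1] + "T" + t[pos:]  # the edited transcript
        pile = pileup_from_alignments(
            perfect_reads("m", t, 6) + perfect_reads("m", read, 4), [gene], {"m": t}
        )
        p = next(x for x in pile if x.cds_pos == pos)
        assert p.ref_base == "C"
        assert p.base_counts["T"] == 4
        # genome coordinate maps back to a G on the genome forward strand
        assert genome.sequence[p.genome_pos - 1] == "G"

    def test_read_with_deletion_reduces_site_depth(self):
        t = "ATGGCTCATTAA"
        gene = GeneAnnotation("g", "+", [(1, 12)])
        full = perfect_reads("g", t, 5)
        # read deleted at reference position 6 (0-based): pairs skip it
        pairs = [(q, r) for q, r in zip(range(11), [0, 1, 2, 3, 4, 5, 7, 8, 9, 10, 11])]
        deleted = ReadAlignment("g", t[:6] + t[7:], 0, pairs)
        pile = pileup_from_alignments(full + [deleted], [gene], {"g": t})
        depth = {p.cds_pos: p.depth for p in pile}
        assert depth[7] == 5  # 1-based position of the deleted base
        assert depth[6] == 6

    def test_unknown_gene_skipped_with_warning(self):
        t = "ATGTAA"
        gene = GeneAnnotation("g", "+", [(1, 6)])
        with pytest.warns(UserWarning, match="unannotated"):
            pile = pileup_from_alignments(
                perfect_reads("nope", t, 3), [gene], {"g": t}
            )
        assert pile == []

    def test_low_quality_bases_excluded(self):
        t = "ATGTAA"
        gene = GeneAnnotation("g", "+", [(1, 6)])
        good = ReadAlignment("g", t, 0, [(q, q) for q in range(6)], quals=[30] * 6)
        bad = ReadAlignment("g", t, 0, [(q, q) for q in range(6)], quals=[5] * 6)
        pile = pileup_from_alignments([good, bad], [gene], {"g": t})
        assert all(p.depth == 1 for p in pile)


class TestCalling:
    def test_depth_filter_boundary_exact(self):
        t = "C" * 12
        nine = site(depth=9, edited=9)
        ten = site(depth=10, edited=10)
        assert call_editing_sites([nine], {"g": t}) == []
        (got,) = call_editing_sites([ten], {"g": t})
        assert got.efficiency == 1.0

    def test_fraction_filter_boundary_inclusive(self):
        t = "C" * 102
        nine_pct = site(depth=100, edited=9)
        ten_pct = site(depth=100, edited=10)
        assert call_editing_sites([nine_pct], {"g": t}) == []
        (got,) = call_editing_sites([ten_pct], {"g": t})
        assert got.efficiency == pytest.approx(0.10)
        assert got.edit_type == "C-to-U"

    def test_multiple_alt_bases_emit_multiple_records(self):
        counts = {"C": 60, "T": 25, "G": 15, "A": 0}
        p = PileupSite("g", 5, 0, "C", 100, counts)
        got = call_editing_sites([p], {"g": "C" * 12})
        assert {(s.edit_type, s.edited_count) for s in got} == {
            ("C-to-U", 25),
            ("C-to-G", 15),
        }

    def test_codon_position_and_aa_change(self):
        t = "ATGCCTTAA"  # M P *
        p = site(pos=5, depth=20, edited=20)  # second base of codon 2: CCT->CTT
        (got,) = call_editing_sites([p], {"g": t})
        assert got.codon_position == 2
        assert got.aa_change == "P->L"


class TestClassifyEdit:
    def test_examples_and_type_closure(self):
        assert classify_edit("C", "T") == "C-to-U"
        assert classify_edit("T", "G") == "U-to-G"
        assert len(EDIT_TYPES) == 12
        with pytest.raises(ValueError):
            classify_edit("C", "C")
        with pytest.raises(ValueError):
            classify_edit("C", "J")

    def test_strand_symmetry_of_called_types(self, rng):
        """Relabeling a plus-strand gene as minus-strand (with revcomp
        reference and reads) leaves the edit-type set unchanged."""
        seq = random_seq(rng, 36)
        genome_plus = CircularGenome("g", seq, is_circular=True)
        gene_plus = GeneAnnotation("x", "+", [(1, 36)])
        genome_minus = CircularGenome("g", revcomp(seq), is_circular=True)
        gene_minus = GeneAnnotation("x", "-", [(1, 36)])
        t_plus = gene_plus.transcript(genome_plus)
        t_minus = gene_minus.transcript(genome_minus)
        assert t_plus == t_minus  # same transcript by construction
        pos = next(i for i, b in enumerate(t_plus, 1) if b in "C")
        edited = t_plus[: pos - 1] + "T" + t_plus[pos:]
        reads = perfect_reads("x", t_plus, 15) + perfect_reads("x", edited, 5)
        types_plus = {
            s.edit_type
            for s in call_editing_sites(
                pileup_from_alignments(reads, [gene_plus], {"x": t_plus}),
                {"x": t_plus},
            )
        }
        types_minus = {
            s.edit_type
            for s in call_editing_sites(
                pileup_from_alignments(reads, [gene_minus], {"x": t_minus}),
                {"x": t_minus},
            )
        }
        assert types_plus == types_minus == {"C-to-U"}


class TestVariantFilter:
    def _candidate(self):
        t = "C" * 12
        (cand,) = call_editing_sites([site(depth=20, edited=10)], {"g": t})
        return cand

    def test_dna_supported_alt_is_removed_as_snp(self):
        cand = self._candidate()
        dna = [site(depth=40, edited=20)]  # 50% alt in DNA
        assert filter_genomic_variants(dna, [cand]) == []

    def test_clean_dna_site_is_retained(self):
        cand = self._candidate()
        dna = [site(depth=40, edited=0)]
        (kept,) = filter_genomic_variants(dna, [cand])
        assert kept.dna_verified

    def test_missing_dna_coverage_retained_but_flagged(self):
        cand = self._candidate()
        (kept,) = filter_genomic_variants([], [cand])
        assert not kept.dna_verified


class TestStartCodon:
    def _gene(self):
        return GeneAnnotation("nad1", "-", [(1, 9)])

    def test_acg_start_with_edit_creates_aug(self):
        t = "ACGGCTTAA"
        sites = [
            EditingSite("nad1", 2, 0, "C-to-U", 4, 6, 4 / 6, 2, "T->M", "C", "U")
        ]
        ev = detect_start_codon_editing(self._gene(), t, sites)
        assert ev.status == "edited-start"
        assert ev.edited_codon == "AUG"
        assert ev.efficiency == pytest.approx(4 / 6)
        assert ev.depth_below_threshold  # depth 6 < 10, flagged not dropped

    def test_acg_start_without_edit_reported_unedited(self):
        ev = detect_start_codon_editing(
            GeneAnnotation("rps4", "+", [(1, 9)]), "ACGGCTTAA", []
        )
        assert ev.status == "unedited-non-canonical-start"

    def test_aug_start_returns_none(self):
        assert (
            detect_start_codon_editing(
                GeneAnnotation("cox1", "+", [(1, 9)]), "ATGGCTTAA", []
            )
            is None
        )


class TestSummaries:
    def test_reported_share_arithmetic(self):
        assert share_pct(432, 480) == 90.0
        assert share_pct(405, 480) == 84.4
        assert share_pct(75, 480) == 15.6

    def test_bins_and_type_closure(self):
        t = "C" * 30
        sites = []
        for i, eff in enumerate([0.2, 0.4, 0.6, 0.995, 1.0], start=1):
            depth = 200
            sites.extend(
                call_editing_sites(
                    [site(pos=3 * i, depth=depth, edited=int(depth * eff))],
                    {"g": t},
                )
            )
        summ = summarize_editing(sites)
        assert summ.total == 5
        assert summ.efficiency_bins == {"below50": 2, "at_least50": 3, "near100": 2}
        assert sum(summ.per_type.values()) == summ.total
        assert set(summ.per_type) == set(EDIT_TYPES)

    def test_empty_input_all_zero(self):
        summ = summarize_editing([])
        assert summ.total == 0
        assert all(v == 0 for v in summ.per_type.values())
        assert all(v == 0.0 for v in summ.efficiency_bin_pct.values())
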