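"""End-to-end orchestration and paper-style report rendering.

Runs the stage chain

    simulate (or load) -> find repeats -> short-read screen -> conformations
    -> long-read classification -> recombination table -> isomers

and, in parallel,

    RNA alignments -> pileup -> DNA-variant filter -> editing calls
    -> start-codon scan -> summaries

then renders TSV reports: a recombination-frequency table (two-decimal
percentages in parentheses, one repeat per row, sorted by length), editing
site and summary tables (one-decimal shares) and a genome-comparison table.
Rendering is a pure function of the result bundle, so re-rendering an
unchanged bundle is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import editing as ed
from . import recombination as rc
from . import repeats as rf
from . import simulate as sim
from .io import CircularGenome, GeneAnnotation, write_fasta
from .recombination import round_half_up

log = logging.getLogger("mitorec")


# ---------------------------------------------------------------------------
# genome comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSummary:
    """Headline numbers of one mitogenome, as used in cross-species tables."""

    species: str
    genome_size: int
    gc_pct: float
    n_core_pcgs: int | None = None
    n_variable_pcgs: int | None = None

    def __post_init__(self):
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if not 0.0 <= self.gc_pct <= 100.0:
            raise ValueError("gc_pct must be a percentage")


def compare_genomes(
    summaries: Sequence[GenomeSummary], reference: str | None = None
) -> pd.DataFrame:
    """Pairwise size/GC differences of each genome against a reference.

    The reference defaults to the first summary; duplicate species names are
    an error.  Size differences are reference minus other, so a positive
    value means the reference genome is larger.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two genomes to compare")
    names = [s.species for s in summaries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names")
    ref_name = reference or names[0]
    by_name = {s.species: s for s in summaries}
    if ref_name not in by_name:
        raise ValueError(f"reference {ref_name!r} not among summaries")
    ref = by_name[ref_name]
    rows = []
    for s in summaries:
        if s.species == ref_name:
            continue
        rows.append(
            {
                "species": s.species,
                "genome_size_bp": s.genome_size,
                "size_diff_vs_reference_bp": ref.genome_size - s.genome_size,
                "gc_pct": s.gc_pct,
                "gc_delta_vs_reference": round_half_up(ref.gc_pct - s.gc_pct, 2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's stated settings."""

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    # repeat finding
    min_repeat_length: int = 30
    max_mismatch: int = 3
    evalue_max: float = 1e-5
    # recombination
    flank: int = 1000
    min_identity: float = 0.75
    min_margin: int = 5
    min_flank_evidence: int = 2
    min_recomb_repeat_length: int = 100
    # editing
    min_depth: int = 10
    min_fraction: float = 0.10
    min_baseq: int = 20
    min_mapq: int = 20
    max_dna_alt_fraction: float = 0.05
    run_editing: bool = True
    run_recombination: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("planted_repeats", "planted_genes", "planted_edits"):
            if key in sim_raw:
                klass = {
                    "planted_repeats": sim.PlantedRepeat,
                    "planted_genes": sim.PlantedGene,
                    "planted_edits": sim.PlantedEdit,
                }[key]
                sim_raw[key] = tuple(klass(**item) for item in sim_raw[key])
        cfg = cls(sim=sim.SimConfig(**sim_raw))
        valid = {f.name for f in fields(cls)}
        for k, v in raw.items():
            if k not in valid:
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        return cfg


@dataclass
class ResultBundle:
    """Everything the reports are rendered from."""

    genome: CircularGenome
    genes: list[GeneAnnotation]
    truth: sim.TruthTable
    repeats: list[rf.RepeatPair] = field(default_factory=list)
    screened_ids: list[str] = field(default_factory=list)
    conformations: dict[str, rc.ConformationPair] = field(default_factory=dict)
    vote_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    recomb_rows: list[rc.RecombinationRecord] = field(default_factory=list)
    isomers: list[rc.IsomerSet] = field(default_factory=list)
    gene_captures: list[rf.GeneCapture] = field(default_factory=list)
    editing_sites: list[ed.EditingSite] = field(default_factory=list)
    editing_summary: ed.EditingSummary | None = None
    start_codon_events: list[ed.StartCodonEvent] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Simulate inputs per the config and run both analysis chains."""
    log.info("simulating genome: %d bp, seed %d", config.sim.genome_length, config.sim.seed)
    genome, genes, truth = sim.simulate_genome(config.sim)
    bundle = ResultBundle(genome=genome, genes=genes, truth=truth)

    log.info("scanning for repeats >= %d bp", config.min_repeat_length)
    all_pairs = rf.find_maximal_repeats(
        genome,
        min_length=config.min_repeat_length,
        max_mismatch=config.max_mismatch,
        evalue_max=config.evalue_max,
    )
    bundle.repeats = rf.select_representatives(all_pairs)
    log.info("%d maximal pairs -> %d representatives", len(all_pairs), len(bundle.repeats))
    bundle.gene_captures = rf.detect_gene_capture(
        bundle.repeats, genes, genome_length=len(genome)
    )

    if config.run_recombination:
        rng = np.random.default_rng(config.sim.seed + 10)
        candidates = [
            rp for rp in bundle.repeats if rp.length >= config.min_recomb_repeat_length
        ]
        pairs_sr = sim.simulate_short_reads(genome, truth, config.sim)
        bundle.screened_ids = rc.screen_short_reads(
            genome, candidates, pairs_sr, min_flank_evidence=config.min_flank_evidence
        )
        log.info("short-read screen: %d of %d candidates", len(bundle.screened_ids), len(candidates))
        long_reads = sim.simulate_long_reads(genome, truth, config.sim)
        selected = [rp for rp in candidates if rp.repeat_id in bundle.screened_ids] or candidates
        for rp in selected:
            conf = rc.build_conformations(genome, rp, flank=config.flank)
            bundle.conformations[rp.repeat_id] = conf
            if not conf.informative:
                bundle.notes.append(f"{rp.repeat_id}: uninformative conformations")
                continue
            counts = rc.classify_reads(
                [s for _, s in long_reads], conf,
                min_identity=config.min_identity, min_margin=config.min_margin,
            )
            log.debug("%s votes: %s", rp.repeat_id, counts)
            bundle.vote_counts[rp.repeat_id] = (counts[rc.MASTER], counts[rc.ALTERNATIVE])
        bundle.recomb_rows = rc.recombination_table(bundle.vote_counts, bundle.repeats)
        bundle.isomers = rc.enumerate_isomers(genome, selected)
    else:
        bundle.notes.append("recombination stage skipped by config")

    if config.run_editing and truth.genes:
        transcripts = {g.gene_id: g.transcript(genome) for g in genes}
        alns = sim.simulate_rnaseq_reads(genes, transcripts, truth, config.sim)
        pileup = ed.pileup_from_alignments(
            alns, genes, transcripts,
            min_baseq=config.min_baseq, min_mapq=config.min_mapq,
        )
        dna = sim.simulate_dna_pileup(genes, transcripts)
        sites = ed.call_editing_sites(
            pileup, transcripts,
            min_depth=config.min_depth, min_fraction=config.min_fraction,
        )
        sites = ed.filter_genomic_variants(dna, sites, config.max_dna_alt_fraction)
        bundle.editing_sites = sites
        bundle.editing_summary = ed.summarize_editing(sites)
        relaxed = ed.call_editing_sites(pileup, transcripts, min_depth=1,
                                        min_fraction=config.min_fraction)
        for gene in genes:
            ev = ed.detect_start_codon_editing(
                gene, transcripts[gene.gene_id], relaxed, min_depth=config.min_depth
            )
            if ev is not None:
                bundle.start_codon_events.append(ev)
    elif config.run_editing:
        bundle.notes.append("editing stage skipped: no genes/RNA reads configured")
    else:
        bundle.notes.append("editing stage skipped by config")
    return bundle


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _fmt_interval(iv) -> str:
    return f"{iv.start}-{iv.end}"


def render_reports(bundle: ResultBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the report files; returns name -> path.  Deterministic bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, text: str):
        p = outdir / name
        p.write_text(text)
        written[name] = p

    # repeat report
    lines = ["repeat_id\tlength\torientation\tunit1\tunit2\tmismatches\tevalue"]
    for rp in bundle.repeats:
        lines.append(
            f"{rp.repeat_id}\t{rp.length}\t{rp.orientation}\t"
            f"{_fmt_interval(rp.unit1)}\t{_fmt_interval(rp.unit2)}\t"
            f"{rp.mismatches}\t{rp.evalue:.3g}"
        )
    emit("repeats.tsv", "\n".join(lines) + "\n")

    # recombination table, one repeat per row
    lines = [
        "repeat\tlength_bp\tdirection\tposition_unit1\tposition_unit2\t"
        "reads_master\treads_alternative\tmaster_pct\talternative_pct"
    ]
    for row in bundle.recomb_rows:
        direction = "+/-" if row.orientation == "inverted" else "+/+"
        lines.append(
            f"{row.repeat_id}\t{row.length}\t{direction}\t"
            f"{_fmt_interval(row.unit1)}\t{_fmt_interval(row.unit2)}\t"
            f"{row.master_count}\t{row.alt_count}\t"
            f"({row.master_pct:.2f}%)\t({row.alt_pct:.2f}%)"
        )
    emit("recombination.tsv", "\n".join(lines) + "\n")

    # junction references
    recs = []
    for rid, conf in sorted(bundle.conformations.items()):
        for i, j in enumerate(conf.master_junctions, 1):
            recs.append((f"{rid}.master.{i}", j))
        for i, j in enumerate(conf.alternative_junctions, 1):
            recs.append((f"{rid}.alt.{i}", j))
    if recs:
        path = outdir / "junctions.fasta"
        write_fasta(recs, path)
        written["junctions.fasta"] = path

    # isomers
    n = len(bundle.genome)
    lines = []
    for iso in bundle.isomers:
        lines.append(f"{iso.repeat_id}\t{iso.kind}")
        for i, mol in enumerate(iso.configurations, 1):
            segs = ", ".join(
                f"[{(s % n) + 1}..{e if e else n}]{o}" for s, e, o in mol
            )
            total = sum(rc.segment_length(seg, n) for seg in mol)
            lines.append(f"  molecule{i} ({total} bp): {segs}")
    emit("isomers.txt", ("\n".join(lines) + "\n") if lines else "")

    # editing sites
    lines = [
        "gene\tcds_pos\tgenome_pos\ttype\tdepth\tedited\tefficiency_pct\t"
        "codon_pos\taa_change\tdna_verified"
    ]
    for s in sorted(bundle.editing_sites, key=lambda s: (s.gene_id, s.cds_pos)):
        lines.append(
            f"{s.gene_id}\t{s.cds_pos}\t{s.genome_pos}\t{s.edit_type}\t"
            f"{s.depth}\t{s.edited_count}\t{round_half_up(100 * s.efficiency, 2):.2f}\t"
            f"{s.codon_position}\t{s.aa_change}\t{'yes' if s.dna_verified else 'unverified'}"
        )
    emit("editing_sites.tsv", "\n".join(lines) + "\n")

    # editing summary
    summ = bundle.editing_summary
    lines = ["metric\tvalue\tshare_pct"]
    if summ is not None:
        lines.append(f"total_sites\t{summ.total}\t")
        for t in ed.EDIT_TYPES:
            cnt = summ.per_type.get(t, 0)
            lines.append(f"type:{t}\t{cnt}\t{summ.per_type_pct[t]:.1f}")
        for b, label in (
            ("below50", "efficiency<50%"),
            ("at_least50", "efficiency>=50%"),
            ("near100", "efficiency~100%"),
        ):
            lines.append(
                f"bin:{label}\t{summ.efficiency_bins[b]}\t{summ.efficiency_bin_pct[b]:.1f}"
            )
        for gid in sorted(summ.per_gene):
            lines.append(f"gene:{gid}\t{summ.per_gene[gid]}\t")
    emit("editing_summary.tsv", "\n".join(lines) + "\n")

    # start codons
    lines = ["gene\tgenomic_codon\tstatus\tefficiency_pct\tdepth\tdepth_flag"]
    for ev in bundle.start_codon_events:
        eff = f"{round_half_up(100 * ev.efficiency, 2):.2f}" if ev.efficiency is not None else ""
        lines.append(
            f"{ev.gene_id}\t{ev.genomic_codon}\t{ev.status}\t{eff}\t"
            f"{ev.depth if ev.depth is not None else ''}\t"
            f"{'below_depth_filter' if ev.depth_below_threshold else ''}"
        )
    emit("start_codons.tsv", "\n".join(lines) + "\n")
    return written
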