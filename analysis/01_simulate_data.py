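#!/usr/bin/env python
"""Generate the synthetic study data set.

Builds a 30 kb circular "mitogenome" at the GC content of a plum
mitochondrion, with three recombination-active repeat pairs (two inverted,
one direct, 150-511 bp, alternative fractions 1-6%), four protein-coding
genes (one minus-strand gene with a genomic ACG start) and planted C-to-U
edits, then writes the genome, annotations, reads and truth tables under
results/simdata/.

Run from the repository root:  python analysis/01_simulate_data.py [seed]
"""

import sys
from pathlib import Path

from mitorec.io import write_fasta, write_fastq, write_gff_genes
from mitorec.pipeline import PipelineConfig
from mitorec.simulate import (
    PlantedEdit,
    PlantedGene,
    PlantedRepeat,
    SimConfig,
    simulate_genome,
    simulate_long_reads,
    simulate_short_reads,
)

OUT = Path("results/simdata")


def study_config(seed: int = 0) -> PipelineConfig:
    """The data-generating conditions used throughout the analysis scripts."""
    return PipelineConfig(
        sim=SimConfig(
            seed=seed,
            genome_length=30_000,
            gc_target=0.4543,
            long_read_depth=120.0,
            planted_repeats=(
                PlantedRepeat(511, "inverted", 0, alt_fraction=0.057),
                PlantedRepeat(294, "inverted", 1, alt_fraction=0.03),
                PlantedRepeat(175, "direct", 0, alt_fraction=0.01),
            ),
            planted_genes=(
                PlantedGene("nad1", n_codons=60, strand="-", start_codon="ACG"),
                PlantedGene("cox1", n_codons=80, strand="+", n_exons=2),
                PlantedGene("rps4", n_codons=50, strand="+", start_codon="ACG"),
                PlantedGene("atp9", n_codons=40, strand="+"),
            ),
            planted_edits=(
                PlantedEdit("nad1", 2, "C", "T", efficiency=4 / 6),
                PlantedEdit("nad1", 44, "C", "T", efficiency=0.95),
                PlantedEdit("cox1", 50, "C", "T", efficiency=0.5),
                PlantedEdit("cox1", 121, "C", "T", efficiency=0.995),
                PlantedEdit("atp9", 35, "G", "A", efficiency=0.3),
            ),
        ),
        flank=1000,
    )


def main(seed: int = 0) -> None:
    cfg = study_config(seed)
    OUT.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate_genome(cfg.sim)
    write_fasta([genome], OUT / "genome.fasta")
    write_gff_genes(genes, OUT / "genes.gff3", genome.id)
    long_reads = simulate_long_reads(genome, truth, cfg.sim)
    write_fastq(long_reads, OUT / "long_reads.fastq")
    pairs = simulate_short_reads(genome, truth, cfg.sim)
    write_fastq(
        [(f"sr{i:06d}/1", a) for i, (a, _) in enumerate(pairs)], OUT / "short_R1.fastq"
    )
    write_fastq(
        [(f"sr{i:06d}/2", b) for i, (_, b) in enumerate(pairs)], OUT / "short_R2.fastq"
    )
    with open(OUT / "truth_repeats.tsv", "w") as fh:
        fh.write(
            "repeat_id\tunit1_start\tunit2_start\tlength\torientation\t"
            "mismatches\talt_fraction\n"
        )
        for rp in truth.repeats:
            s1, s2 = rp.unit_starts0()
            fh.write(
                f"{rp.repeat_id}\t{s1 + 1}\t{s2 + 1}\t{rp.length}\t"
                f"{rp.orientation}\t{rp.mismatches}\t"
                f"{truth.alt_fractions[rp.repeat_id]}\n"
            )
    with open(OUT / "truth_edits.tsv", "w") as fh:
        fh.write("gene\tcds_pos\tref\talt\tefficiency\n")
        for e in truth.edits:
            fh.write(f"{e.gene_id}\t{e.cds_pos}\t{e.ref_base}\t{e.alt_base}\t{e.efficiency}\n")
    print(
        f"simulated {len(genome)} bp circular genome "
        f"({len(truth.repeats)} repeat pairs, {len(genes)} genes), "
        f"{len(long_reads)} long reads (N50 {truth.long_read_n50} bp), "
        f"{len(pairs)} short-read pairs -> {OUT}"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
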