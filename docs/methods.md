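# Methods

`mitorec` re-implements, as a tested pipeline over synthetic data, two
analyses that characterize the structural and transcriptional dynamics of a
plant mitochondrial genome: quantification of repeat-mediated genome
recombination from junction-spanning long reads, and detection of RNA-editing
sites in protein-coding transcripts from transcriptome pileups.  This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic data do and do not show about real data.

## Coordinates and sequences

All computation uses 0-based half-open ascending coordinates; all reported
output is 1-based inclusive, with minus-oriented repeat units printed with
descending coordinates (e.g. `419510-419000`), the convention of organelle
recombination tables.  The conversion is lossless and covered by property
tests.  Sequences are restricted to `{A, C, G, T, N}`; `U` is mapped to `T`
on input, `N` never counts as a match in any comparison, and the simulator
never emits `N`.  Circular genomes support wrap-around extraction everywhere
(verified against a doubled-sequence slicing oracle); the position of the
assembly origin is treated as arbitrary metadata, and the repeat scan is
rotation-invariant by test.

## Maximal repeat pairs with mismatches

A repeat pair is two genome intervals of equal length whose sequences match
under a Hamming-distance budget, in the same orientation (direct/forward) or
with the second unit reverse-complemented (inverted/palindromic).  Defaults
follow the classic survey settings for organelle genomes: minimum length
30 bp, at most 3 mismatches, expected chance occurrences (e-value) at most
1e-5.  A pair is *maximal* when extending either end by one base would
exceed the mismatch budget or make the units collide on the circle.

The scan walks alignment diagonals of the (doubled, for circular input)
sequence.  Along a diagonal, maximal ≤k-mismatch windows are exactly the
stretches bounded by their (k+1)-th mismatch on each side, so the scan
screens blocks of 64 diagonals at a time for exact seed runs of the
pigeonhole length `ceil((L_min − k)/(k + 1))` (7 for 30/3) using vectorized
comparisons, then enumerates the budget splits only around those rare
seeds.  Origin-spanning repeats fall out of the doubled-sequence scan and
are de-duplicated modulo the genome length; windows truncated by the scan
boundary are removed by an explicit circular maximality check.  Every
reported pair re-verifies its own mismatch count on re-extraction.  The
whole-genome scan is O(n²) and intended for the ≤100 kb genomes this
package simulates (≈2 s at 10 kb, ≈45 s at 50 kb on one core); the unit
tests hold it to exact set equality with an independent brute-force
enumeration on 2 kb genomes.

The e-value uses the binomial null for a length-L, m-mismatch match between
two random positions of a genome of length n,

    E = C(L, m) · 3^m · n² · 4^(−L),

computed in log space so long repeats do not underflow before the
comparison.  Note that at realistic genome sizes this threshold admits
30 bp repeats only with few mismatches — the intended behavior of e-value
limiting.

Because a biological repeat surrounded by random sequence supports several
maximal windows (the budget can be spent at either edge), downstream stages
use `select_representatives`, which keeps the longest window per cluster of
mutually overlapping same-orientation pairs.  How the original survey
de-duplicated its repeat list is not stated anywhere we could follow, so
total repeat counts are not comparable across tools; the per-repeat
analyses are unaffected.

A gene is *captured* by a repeat when its full CDS span lies strictly
inside a repeat unit; since the other unit carries a copy of the same
sequence, the gene is effectively present in two copies.

## Recombination from junction-spanning long reads

Homologous recombination between the two units of a repeat rearranges the
circle: a **direct** repeat subdivides it into two subcircles, each with one
hybrid repeat copy; an **inverted** repeat inverts the arc between the
units.  For each repeat we build four junction references — the unit plus
both flanks (default 1000 bp) cut from the master circle around each unit,
and the same windows cut from explicitly constructed recombinant
molecules.  The crossover breakpoint inside mismatched copies is placed at
the repeat midpoint; the breakpoint is unobservable within identical
sequence and any interior choice yields the same junction flanks.  The
builder is checked against an independent oracle that assembles the
recombinant molecules by hand (subdivision and arc inversion), including
origin-spanning repeats via rotation invariance.  A pair whose alternative
junction equals a master junction (identical flanks) is flagged
uninformative and excluded.

A long read votes for a conformation only when it *completely covers* one
of that conformation's junctions: the whole junction reference must align
semiglobally (edlib, either read strand) within the read at identity at
least `min_identity`, and the best such junction must beat the other
conformation's best by at least `min_margin` edit operations.  Reads
covering no junction in full are uninformative; reads inside the margin are
ambiguous and counted in neither column.  The source data's screening
thresholds are described only as "stringent", so `min_identity = 0.75` and
`min_margin = 5` are this package's defaults, chosen for ONT-like error
rates (≈5% substitutions + 3% indels leave a 2.5 kb junction at ≈8%
distance, far inside both thresholds) and exposed in the configuration.
As an optimization the classifier first locates the repeat unit in the read
and aligns junctions only around it, falling back to whole-read alignment
when nothing is covered; tests assert exact agreement with whole-read
alignment.  Because master and alternative junctions share the repeat and
one flank, a read matching one conformation perfectly still "covers" the
other at ≈75–80% identity — the margin criterion, not coverage alone,
carries the decision.  The same complete-coverage requirement is what
excludes reads arising from intracellular sequence transfer (a transferred
copy matches neither junction over its full length).

The recombination frequency of a repeat is `alt / (master + alt)` over
informative spanning reads.  Percentages are rounded half-up to two
decimals; rows are sorted by repeat length descending and labelled R1..Rn.

Short-read screening is a cheap pre-filter: read pairs (insert ≈350 bp)
are assigned a left and right flank by k-mers unique to the flank windows
adjacent to the units; fragments combining unit1's left flank with unit2's
right flank (or vice versa) indicate an extra structure, and a repeat is
flagged at ≥2 such fragments (`min_flank_evidence`, a documented default —
the original count threshold is unstated).  Geometry limits power: a
fragment must hold an anchor k-mer on both sides of the repeat, so only
repeats shorter than insert − 2k are detectable, and the expected evidence
scales with depth × (insert − repeat − 2k).  Repeats whose units are
closer than one insert are skipped (a master fragment could bridge them).
Because of these limits the screen is advisory; when it flags nothing the
pipeline still tests all candidate repeats with long reads, which are the
decisive evidence.

Isomer enumeration emits each repeat's alternative configuration as
explicit oriented segment lists (two circles for direct, one circle with an
inverted arc for inverted); segment lengths always sum to the genome
length.

## RNA editing in protein-coding transcripts

References are the spliced transcripts (introns removed, minus-strand genes
reverse-complemented), so all calls are on the transcript strand: a
genome-orientation G→A variant in a minus-strand gene surfaces as C-to-U.
Pileups count read bases per CDS position, excluding bases below quality 20
and reads below mapping quality 20 where the alignments provide them
(mirroring the original caller's minimum-quality settings; no BAQ, no
indels).  A site becomes an editing call when depth ≥ 10 and the
alternative base is supported by ≥ 10% of reads — both inclusive ("at
least"), asserted exactly at the boundary in tests.  Efficiency is
edited/depth.  A site with two alternative bases above threshold yields two
records (the source is silent on this case).  Candidates whose alternative
base is present above 5% in DNA (WGS) reads are removed as genomic
variants; sites without DNA coverage are kept but flagged unverified.  The
twelve ordered substitution types over {A, C, G, U} are tallied;
efficiency bins are <50%, ≥50% and "near 100%", operationalized as ≥0.99
since no cutoff is stated in the source; shares are rounded half-up to one
decimal.

Start codons are scanned separately: a gene whose genomic start is not AUG
is reported either as an editing event (when a called edit converts the
codon to AUG, e.g. ACG with C-to-U at codon position 2) or as an unedited
non-canonical start.  This scan deliberately includes sites below the depth
filter — coverage thins at transcript ends, which is precisely where start
codons live — and flags them (`depth_below_threshold`) instead of dropping
them.  The motivating real-data case is a start codon confirmed in 4 of 6
transcript reads (66.67%), itself below the depth-10 filter.

## Synthetic data

The generator plants known truth into random sequence and is the study
condition, not a tuning dial.  Defaults emulate the source data set's
summary statistics: GC 45.43%, long reads with lognormal lengths of mean
13,430 bp (shape σ=0.6; realized N50 is logged, not enforced), long-read
depth 178×, 150 bp paired short reads at 48× with ~350±35 bp inserts, and
strand-specific RNA reads.  Error models are uniform: 5% substitutions +
3% balanced indels for long reads, 0.1% substitutions for short and RNA
reads.  The default test genome is 50 kb (full-scale half-megabase genomes
are not needed to exercise any code path and would dominate the suite's
runtime through the O(n²) repeat scan; the analysis drivers use 30 kb).

Repeats are planted as unit copies with an exact number of mismatches
(reverse-complemented for inverted pairs); long and short reads are drawn
from a mixture of the master circle and the per-repeat recombinant
molecules at the planted alternative fraction, with direct-repeat
subcircles sampled proportionally to length.  `simulate_spanning_reads`
samples the same model conditioned on the read covering a junction — the
subpopulation the frequency is estimated from — which is what the recovery
studies use.  RNA reads carry each planted edit independently per read with
probability equal to the planted efficiency, so realized per-site counts
are binomial; at depth 20 and efficiency 0.2 this implies an irreducible
≈7% chance that a site falls under the 10%-support filter, which bounds
what "zero false negatives" can mean at that corner of the recovery study.
A fixed seed reproduces byte-identical outputs.

What the simulations do not model: homopolymer-biased ONT errors, quality
score structure, transcript abundance variation (per-gene depth is
uniform), chimeric reads, nuclear/plastid homologs (the
intracellular-transfer exclusion is exercised only through the
complete-coverage rule), and biological length–frequency correlation of
recombination (with equal planted fractions the estimator is
length-invariant; the correlation seen in real data is biology, not
algorithm).  Passing recovery tests therefore validates the estimators
under the stated error model, not instrument realism.

## Recovery studies (what the suite asserts)

* Repeat finder vs brute force: exact set equality of (coordinates,
  orientation, mismatches) on 50 random 2 kb planted genomes.
* Recombination: on a 50 kb genome with a 511 bp inverted repeat, planted
  alternative fractions {1%, 5.7%, 50%}, 100 seeded replicates of 200
  spanning reads: the estimate falls inside the exact (Clopper–Pearson)
  95% interval of the truth in ≥95 replicates.
* Editing: planted efficiencies {0.2, 0.5, 0.99} at depths {20, 200} are
  recovered with estimates inside exact binomial intervals, with boundary
  filters asserted exactly; interval coverage ≥95% across replicates.

The project-wide seed convention is 0 for tests (fixed before any
measurement); the acceptance script derives all randomness from its
`--seed` argument.

## Known limitations

* The O(n²) repeat scan is desk-scale; a half-megabase genome takes tens
  of minutes and would want a suffix-automaton seed index instead.
* Compound isomers from simultaneous recombination at several repeats, and
  copy-number inference across tissues, are out of scope.
* The short-read screen's insert-geometry limits (above) make it
  insensitive for repeats near or above the library insert size; it never
  gates the long-read analysis.
* Editing calls are restricted to coding regions by construction; no
  stop-codon-creation scan is provided (no such event exists in the
  motivating data).
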