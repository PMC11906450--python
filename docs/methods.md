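# Methods

## Scope and data model

The package characterizes *annotated* circular mitochondrial genomes:
annotation is an input, never inferred (no gene finding, no tRNA
scanning, no alignment). Coordinates are 1-based and fully inclusive,
the convention of published mitogenome summary tables; conversion to
0-based half-open happens only inside readers/writers. The origin of the
circle lies between position `genome_length` and position 1, and a
feature with `end < start` is a wrap-around feature spanning the origin;
its length is `(genome_length − start + 1) + end`.

Strands are `+` (heavy) and `−` (light); `H`/`L` and the typographic
minus/en-dash are accepted on read. Gene symbols are folded onto one
canonical scheme on read (`COX1 → cox1`, `cob → cytB`, `ND4L → nad4L`,
…) so user files and the packaged tables agree. Ambiguity codes other
than `N` are rejected — every statistic here assumes unambiguous bases —
while `N` is carried but excluded from composition denominators so draft
sequences remain usable.

## Packaged reference tables

The published coordinate and composition tables for *Thrips tabaci*
(34 features, 15,277 bp) and *T. parvispinus* (33 features, 15,285 bp)
ship as gene-table TSVs — data files, not hard-coded structures, so they
double as format-parsing tests. They are coordinate-only on purpose: no
sequence is fabricated for the real species, and sequence-dependent
stages are exercised on generated genomes instead.

Two published quirks are carried explicitly:

* The *T. tabaci* atp8 coordinate span is 203 bp while the composition
  table and the 13-gene total use 126 bp. The coordinates are kept and
  the 126 travels as a `length_override`; summing PCG lengths with the
  override reproduces the published total of 10,584 bp (11,055 bp for
  *T. parvispinus*, where no override is needed).
* The *T. parvispinus* table prints 101 after cytB, but the coordinates
  give 158 bp to the genome end; no gap convention reproduces 101, so
  the printed value is retained only as an annotation comment and that
  row is excluded from per-row gap cross-checks.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C). Both are scale-invariant
(counts and percentages give identical values), antisymmetric under
argument exchange, and bounded in [−1, 1]. Per-feature composition is
computed on each feature's **sense strand** by default: the published
per-gene skews for minus-strand NADH genes match sense-strand
expectations, and a flag (`sense_strand=False`) provides the
plus-strand-slice alternative. Internal values keep full precision;
the reporting layer rounds percentages to 1–2 decimals and skews to 3,
with ties going away from zero (matching how the published tables round
values such as −0.2565 → −0.257).

## Architecture

For features sorted by ascending start (ties longer-first, logged), the
signed gap between consecutive features is `next_start − end − 1`:
positive = intergenic spacer, negative = overlap, zero = abutting. This
is the unique convention consistent with the published per-row values.
The terminal record runs linearly from the last feature to the genome
end (clamped at 0 when the feature abuts the origin); when the last
feature itself wraps the origin, the terminal record instead closes the
circle to the first feature. The region *before* the first feature is
reported (`leading_gap`) but excluded from spacer totals — the
accounting required to reproduce the published 1,560 bp / 23 sites.

The control-region candidate is the longest positive gap (all records
returned on ties, in genome order), consistent with the A+T-rich
control region of insect mitogenomes being the dominant non-coding
stretch. A bookkeeping identity is enforced in tests against a
position-marking oracle: on annotations without wrap-around or fully
nested features, leading gap + internal spacers + trailing run +
covered positions = genome length.

The published running text gives alternative totals (e.g. 1,109 bp over
22 spacers, longest 292 bp) that contradict the coordinate-derived
values; this package reproduces the coordinate-derived accounting
(1,560 / 23 / 451 for *T. tabaci*). For *T. parvispinus* the printed
1,039 bp / 24 sites is reachable only by substituting the printed 101
for the coordinate-derived 158 terminal gap; the package reports the
coordinate-derived 1,096 / 24.

## Codon analysis

A CDS is decomposed into maximal triplets from position 1; the 0–2 base
remainder is the tail. The start codon is the first triplet, canonical
iff in the code's initiator set; the stop is the tail when non-empty
(incomplete — `T`/`TA` terminators completed to UAA by
post-transcriptional polyadenylation) or otherwise the final triplet.
Incomplete tails are excluded from codon tallies and RSCU: they encode
no amino acid. Stop codons are excluded from RSCU families by default
(selectable), since RSCU is conventionally defined over sense codons.
Codon counts are pooled across all protein-coding genes of a genome.

The default genetic code is the invertebrate mitochondrial code (NCBI
table 5, where TGA = Trp and TTG is a valid initiator); the standard
code (table 1) is selectable as a reproduction mode for analyses that
used it. Note that some published coordinate spans are not
codon-consistent with their annotated incomplete stop (a 1,008 bp gene
with stop `t`); the classifier reports what the sequence shows, and the
generator-based tests therefore plant stops on codon-consistent lengths.

## Control-region scanners

All four scanners are exact string-level searches — no mismatch model,
no thermodynamic folding — verified against independent brute-force
oracles on regions up to ~1 kb:

* **poly-T**: maximal runs of `T` with length ≥ `min_run` (default 5).
* **IUPAC motifs**: all, possibly overlapping, matches of a degenerate
  pattern (`N` = any base); optional minus-strand scan.
* **Tandem repeats**: maximal exact arrays with unit length 2–50 and
  ≥ 2 copies by default; units are primitive (smallest period), shifted
  phases contained in a same-period array are suppressed, homopolymers
  only when `min_unit = 1`.
* **Stem-loops**: pairs of exact reverse-complement arms (6–20 bp) with
  a loop of 3–30 bp, after suppressing hits whose arms both lie inside a
  longer hit's arms.

Defaults are conventional control-region settings; no positional or
count claims are made beyond what the scanners find.

## Phylogeny preparation

Genes are assumed pre-aligned (the concatenator enforces equal per-gene
length across taxa and errors otherwise; alignment is out of scope).
The default concatenation order is nad5, nad4, nad4L, nad6, cox1, nad3,
cox2, cox3, atp6, atp8, nad1, nad2, cytB. Distances use pairwise
deletion of non-ACGT sites; models are p (mismatch fraction), JC69
(−¾ ln(1 − 4p/3), error on saturation p ≥ ¾) and K2P. Neighbor joining
is the classical Saitou–Nei algorithm with Studier–Keppler updates,
lexicographic tie-breaking for full determinism, and negative branch
estimates clamped to zero with a warning (standard practice). On
additive matrices NJ provably recovers the generating tree; the tests
exercise exact recovery for 4–10 taxa at 1e-9. This is a deliberately
desk-scale utility: maximum-likelihood inference, model selection and
bootstrapping are out of scope.

## Synthetic-genome generator

`GenomeSpec` fixes a layout (features with strands, start/stop codons),
per-gene composition targets, and literal "plants" (motifs, a T-stretch,
a tandem array, a hairpin) at explicit positions; `generate_genome`
samples each region per-position from its composition vector, writes
non-coding features first and PCGs second (so overlap overwrites never
clobber a planted codon), then writes plants verbatim. Identical seeds
give byte-identical output. Planted elements carry one guard base on
each side chosen so that the surrounding random sequence cannot extend a
planted run, array or stem — making exact recovery well-defined.

The default test spec is a ~6 kb, 8-gene circle exercising every
feature class: an origin-spanning PCG, a minus-strand PCG with an
incomplete stop, a 5 bp overlap, and a 300 bp spacer carrying one
planted instance of each control-region element. Problem sizes
throughout the tests (≤ 15 kb genomes, ≤ 1 kb scan regions, ≤ 10-taxon
trees, 3–12 kb composition checks) were chosen as the smallest at which
each property is sharply testable — discrete structure is recovered
exactly, and composition targets within ±2 percentage points at ≥ 3 kb
(binomial sampling at that length has σ ≈ 0.9 points).

What the generator does *not* emulate: real codon-usage profiles,
sequence homology between genes, tRNA secondary structure, or the
repeat-rich microstructure of real control regions. Passing tests
therefore demonstrate correctness of the accounting and scanning
machinery, not biological realism of the simulated sequence.

## Known limitations

* Per-gene composition strand choice is an assumption (sense strand);
  it is testable against the deposited sequences but not provable from
  the printed tables alone.
* Overlapping genes are not reconciled at the reading-frame level; the
  architecture is purely coordinate-based.
* The NJ utility is for desk-scale sanity checks, not publication-grade
  phylogenetics.
* Codon-position-stratified composition is not computed.
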