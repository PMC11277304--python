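# Methods

## Coordinates, strands, and the canonical vocabulary

Features use 1-based inclusive coordinates on the majority (J) strand, the
GenBank convention; the parser/serializer pair is the only place the 0-based
half-open internal form is converted.  A feature crossing the origin of the
circular molecule is stored with `wraps_origin=True` and `start > end`; its
span and extraction use circular arithmetic.  Gene labels are normalized into
a closed vocabulary of 37 genes + control region; the leucine/serine tRNA
paralogs are resolved by anticodon or codon family (trnL1 = Leu/CUN,
trnL2 = Leu/UUR, trnS1 = Ser/AGN, trnS2 = Ser/UCN).  Unrecognized labels are
kept verbatim and flagged non-canonical rather than dropped.

Junction accounting treats the annotation as a circular tiling: for each
consecutive feature pair, gap = start(next) − end(prev) − 1, negative gaps
being overlaps.  Fully nested features are excluded (with a warning) so the
tiling identity Σ spans + Σ signed gaps = genome length holds.  The A+T-rich
control region participates as a feature, so its flanks are junctions, not a
giant spacer.

## Skews and NG86 Ka

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C) over unambiguous bases;
an undefined skew (zero denominator) is reported as 0 with a flag.  Reports
round skews to two decimals.

Ka uses Nei–Gojobori (1986) counting under the invertebrate mitochondrial
code (NCBI table 5).  Per codon, each position contributes the fraction of
its possible single-base changes that are synonymous; changes to stop codons
are excluded and the position renormalized, so synonymous + nonsynonymous
sites always total 3.  Differences between codons are averaged over all
minimal mutational pathways; pathways passing through a stop codon are
dropped, and a pair whose pathways all hit stops is skipped with a flag, as
are codons containing gaps, ambiguity codes, or stops.  pN = Nd/N with site
counts averaged over the two sequences, and Ka = −(3/4)·ln(1 − (4/3)·pN);
pN ≥ 3/4 raises a saturation error rather than returning a number.  For
whole-mitogenome comparisons each shared protein-coding gene is aligned as
codons by translating and globally aligning the proteins (match +1, mismatch
−1, gap −2) and back-threading gaps as `---` triplets; per-gene and
concatenated 13-gene results are both reported.  The protein aligner may
occasionally prefer a spurious insertion/deletion pair over a dense run of
mismatches; the affected codon columns are gap-skipped by NG86, which costs a
fraction of a percent of the signal at most.

## Tandem decomposition

The decomposer is a two-stage, Tandem-Repeats-Finder-like search.  Candidate
(period, phase) pairs come from the distances between consecutive occurrences
of identical k-mers (k = min(10, min_period)); the 60 best-supported
candidates are refined.  Refinement grows a maximal run of gapless
period-length copies around the candidate phase, re-deriving a majority-rule
consensus as the run grows and admitting a copy while its mismatch fraction
is ≤ 20%.  A trailing tail matching the consensus prefix at ≥ 80% identity is
reported as the partial unit.  Decompositions score matches·2 − mismatches·7
(the TRF weights), must reach a score of 20, and overlapping reports are
deduplicated best-score-first with ties broken by smaller period, then
leftmost start.  Copies are modeled gapless — the repeat units analyzed here
are length-identical — which is a documented limitation for repeats with
internal indels.

## Remnant scanning

Each library gene (typically the record's own intact tRNAs) is aligned on
both strands against the spacer by Smith–Waterman (match +1, mismatch −1,
gap −2; the row recursion is vectorized with a max-plus prefix scan and is
exact).  Because pseudogene remnants are modeled as gapless fragments, the
raw local-alignment span is refined to the best ungapped diagonal segment
under +1/−4 match/mismatch scoring — break-even at 80% identity — which keeps
hit boundaries crisp instead of absorbing lucky flanking matches.  Hits
require length ≥ 15, identity ≥ 0.8, and score (matches − mismatches) ≥ 18.
The score floor exists because short matches at the bare length/identity
floor arise by chance between random sequences; 18 keeps a 20 bp remnant
carrying one substitution (score 18) while i.i.d. random 300 bp spacers
produce a hit against a full 44-entry library in ≈1% of seeds.  Non-overlapping
secondary hits are found by masking claimed bases and re-aligning.  Remnant
strand is reported as the strand of the intact source gene that matched.
TRU annotation assigns each hit to its covering repeat copy (hits spanning a
copy boundary are flagged, not assigned), partitions copies into remnant and
linker segments, and reports the pairwise linker identity matrix.

## TDRL inference

One TDRL event duplicates a contiguous block in tandem (2..max copies) and
deletes all but one copy of each gene; losses are free parts of the event and
copy count is a secondary parsimony criterion.  Strands pass through
unchanged — strand disagreement between the windows rejects TDRL outright.
Enumeration is exhaustive over (block, copy count, per-gene retained copy)
within a linearized window whose flanks are fixed; with max copies at least
the window size a single event reaches any same-strand permutation (any
permutation splits into that many increasing subsequences), so multi-event
search is unnecessary for transpositions and the identity window returns the
empty scenario.  Remnant evidence ranks scenarios: the lost copies a scenario
places between the two retained genes flanking the observed spacer must
reproduce the observed remnant genes in order and count; predicted remnants
of unobserved genes are tolerated as fully decayed.  Consequently k observed
remnants of a gene retained outside the remnant run force k + 2 copies —
six remnants imply an eight-copy expansion.

## Character mapping

The rearrangement is a binary leaf character (0 ancestral, 1 rearranged,
? unknown) on a rooted tree; unknown states take the full state set.  The
up-pass uses Hartigan's generalization of Fitch parsimony (exact on binary
and polytomous rooted trees): each node keeps the states with the maximal
child vote, adding (children − max votes) changes.  The down-pass keeps the
parent state when allowed, otherwise the lexicographically smallest allowed
state, yielding one optimal assignment.  The character is a synapomorphy of a
clade iff exactly one change is needed and it is a 0→1 gain on the edge
subtending exactly that clade.  Unrooted inputs must be rooted (an outgroup
helper is provided) because synapomorphy is a rooted notion.

## Synthetic data

The generator lays the 37 genes + control region in the ancestral insect
arrangement on a circular molecule.  Defaults mirror the study system:
16,546 bp target, base probabilities (A, T, G, C) = (0.471, 0.334, 0.074,
0.121), 12 overlaps of 1–8 bp and five spacers of 5–25 bp at seeded random
junctions (only junctions whose downstream gene is a tRNA may overlap, so
protein-coding genes stay intact), tRNAs 60–75 bp, protein genes at canonical
invertebrate lengths, rRNAs 1285/785 bp, and the control region absorbing the
remainder.  N-strand genes are drawn from the complemented base distribution
before reverse-complement placement, so the J-strand composition matches the
target.  Protein genes are random codons (ATG … TAA); an interior stop draw
is letter-shuffled into a non-stop permutation, preserving composition
exactly.  All randomness flows through one seeded numpy generator, and a
truth log records every coordinate, junction gap, and spacer string.

The planted rearrangement swaps the abutting trnW/trnC block and inserts a
spacer of n tandem units, each an identical random linker (82 bp) followed by
the leading fragment (29 bp) of the displaced trnW, plus a trailing partial
unit (44 bp, a unit prefix).  Two structural choices are deliberate: the
linker precedes the remnant within the unit so the 44 bp partial contains no
extra remnant copy (keeping "n units → n remnant hits" exact), and the
linker's first base is forced to differ from the gene's next base so local
alignment cannot extend the planted fragment by chance.  With the defaults
the spacer is 6·111 + 44 = 710 bp; the published account of this structure
prints a 702 bp spacer alongside repeat arithmetic totaling 710, an
inconsistency of 8 bp that the generator resolves in favor of the explicit
unit structure.  Optional Bernoulli point mutations (per-base rate) and an
exact count of interior remnant mutations (≥5 bp from the fragment edges, so
a degenerate copy remains one contiguous hit) emulate observed decay.
Divergence simulation mutates each internal codon of each protein gene with
a given probability by one uniformly chosen amino-acid-changing, stop-avoiding
base change, leaving synonymous sites untouched.

What the generator does not emulate: real tRNA secondary structure, codon
usage and site-rate heterogeneity, strand-asymmetric mutation processes, or
indel evolution.  Passing tests therefore demonstrate correctness of the
bookkeeping and inference machinery under a controlled model, not robustness
to every feature of empirical sequence data.

## Problem sizes and determinism

The test suite and the acceptance script run on single 16.5 kb synthetic
genomes, seed batteries of 20–100 replicates for stochastic recoveries,
exhaustive oracles on windows of ≤ 4 genes / trees of ≤ 8 leaves / alignments
of ≤ 200 bp, and a 13-gene (~3,700 codon) divergence simulation — sizes at
which the exhaustive oracles are exact and the whole battery completes in
well under a minute.  Identical seeds give byte-identical reports; JSON
output is key-sorted and timestamp-free.
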