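# Methods

`plastomics` analyses the comparative evolution of plastid (chloroplast)
genomes at very shallow divergence — congeneric species whose plastomes
differ by roughly one substitution per thousand sites. Everything in the
package is exact counting on alignments and annotated records; no
substitution-model correction is applied anywhere, because at p ≈ 10⁻³
multiple hits are negligible and the uncorrected p-distance is the
standard statistic.

## Quadripartite structure

A typical angiosperm plastome is a circle of ~160 kb: a large single-copy
region (LSC, ~90 kb) and a small single-copy region (SSC, ~20 kb)
separated by two inverted repeats (IRa/IRb, ~25 kb each) that are exact
reverse complements. `detect_inverted_repeats` finds the longest pair of
disjoint, exactly reverse-complementary repeats by seed-and-extend on the
doubled sequence (so the search is origin-independent): k-mers of the
reverse complement are indexed (k = clamp(min_ir_length/2, 12, 31)), seeds
are extended to maximal matches once per diagonal, and candidates shorter
than `min_ir_length` (default 1,000 bp — far below real IRs, above most
dispersed repeats) are discarded. Exact matching is intentional: the two
IR copies of one assembled genome are identical; a mismatch-tolerant mode
is out of scope. Ties on repeat length are broken by maximizing the
shorter single-copy region, then by coordinates, so detection is
deterministic. The longer single-copy region is labelled LSC; IRb is the
IR copy downstream of the LSC; junctions are named JLB (LSC/IRb), JSB
(IRb/SSC), JSA (SSC/IRa), JLA (IRa/LSC). The reported IR length is the
maximal exact repeat length; published junction coordinates that use
different boundary-base conventions may differ by a base.

The SSC exists in two equimolar inversion isomers and assemblies pick one
arbitrarily, so `canonicalize_orientation` aligns a genome's SSC against a
reference SSC in both orientations (edlib global edit distance) and flips
the segment when the reverse complement fits better. The flip reflects
coordinates and strands of features wholly inside the SSC; a gene that
crosses an SSC/IR junction (typically *ycf1*) keeps its original
annotation, which is then approximate — a known limitation.

## Divergence

* `p_distance`: mismatches over compared columns, pairwise deletion
  (columns with gap or N in either row are skipped), following the
  convention of the standard desktop phylogenetics tools.
* `region_variability`: per noncoding region with aligned length > 200
  columns (the filter applies to *aligned* length), percent variable =
  100 × (substitution sites + indel events) / aligned length. A
  substitution site is a column with ≥2 distinct bases among the taxa; an
  indel event is a maximal gap run counted once per distinct (start, end)
  interval — a run shared identically by several taxa is one event,
  overlapping runs with different boundaries are distinct events, and a
  run is attributed to the region containing its first column.
* `sliding_identity`: mVISTA-style windows (default 100 columns, step 25;
  the choice is cosmetic and configurable), identity = matching columns
  over columns where either taxon has a base.
* `count_informative_sites`: parsimony-informative columns (≥2 bases each
  carried by ≥2 taxa; gaps and N are not states).

## Outgroup polarization

Substitutions segregating in the ingroup get a direction from a single
outgroup. A column yields an event only when every considered taxon has a
base, the ingroup shows exactly two states, and the outgroup matches one
of them; the outgroup state is ancestral. Counting is per derived allele:
a derived state shared by k ingroup taxa is one event (single origin on a
shallow tree), not k. Columns failing the rules are tallied by reason, so
the denominator is always reconstructable.

Indels are called from maximal gap runs grouped by (interval, gapped-taxon
set). A run gapped in a proper nonempty ingroup subset, with everyone else
fully base-bearing, is a deletion in the gapped taxa. A run gapped in the
outgroup plus part of the ingroup, with the remaining ingroup base-bearing,
is an insertion in the base-bearing taxa (the sequence is ancestrally
absent). Runs identical across the whole ingroup are not variants within
the ingroup and are excluded; any taxon partially gapped over the interval
via a differently-bounded run makes the pattern unpolarizable. Distinct
gap runs separated by one or more base columns are never merged.

Repeat context, the slipped-strand-mispairing footprint, is classified
from ungapped flanks read from a taxon carrying the indel bases:
*homopolymer* if the event is a single repeated base inside a
mononucleotide run of total length ≥ 4 (threshold configurable);
*tandem repeat* if the event sequence exactly equals the adjacent upstream
or downstream flank of the same length. For 1-bp events only the
homopolymer rule applies — a single-base "tandem" is just a length-2 run,
below any plausible slippage substrate — and for longer events the tandem
rule is tried first. These are the minimal definitions that make the
slippage association testable; no fuzzy matching is attempted.

## Size decomposition

Two annotated genomes are each tiled into genes (exon unions), introns
(gaps between consecutive exons of one feature) and intergenic spacers, on
a single-IR representation (LSC + IRb + SSC; the IRa copy and its
duplicate annotations are dropped so nothing is counted twice).
Overlapping gene extents are resolved by assigning the overlap to the
earlier-starting gene and truncating the later element, which preserves an
exact tiling so that per-element length deltas sum to the represented
length difference. Elements match across genomes by name; spacers match
by the unordered pair of flanking gene names, so a local inversion does
not break matching, and rearranged neighbourhoods yield unmatched elements
rather than forced matches. `large_indel_accounting` takes a polarized
pairwise indel list, keeps events ≥ 100 bp (configurable), and reports
their signed total as a fraction of the whole-genome size difference.

## Tajima relative-rate test

For two ingroup lineages and an outgroup, columns with any gap or N are
wholly excluded (complete deletion); the rest classify as identical,
lineage-specific (one taxon differs from the agreeing other two),
outgroup-specific, or fully divergent. With m1 and m2 the two
ingroup-specific counts, χ² = (m1 − m2)²/(m1 + m2) on 1 df; the p-value
is computed from the chi-square survival function, never table-looked-up,
and reported with "< 0.001" flooring in the tabular output. m1 = m2 = 0
is reported as statistic 0, p = 1, and flagged undefined.

## The simulator and what passing tests mean

`simulate` builds an annotated root plastome — configurable LSC/SSC/IR
lengths (defaults 91,000 / 20,400 / 25,600 bp, GC 0.365, the magnitudes of
real Malvaceae plastomes), genes placed at ~0.5 genes/kb with 15%
two-exon models, rRNA/protein genes planted inside the IR and mirrored
into the other copy, one gene ("ycf1") crossing the IRb/SSC junction by a
configurable 36 bp, and ~300 short tandem-repeat loci seeded into
single-copy spacers as slippage substrates. Boundary bases flanking the IR
are chosen so the planted repeat is maximal, making detection exactly
recoverable. The genome then evolves along a rooted newick tree (default:
a quartet at branch lengths 2–5 × 10⁻⁴ over an outgroup ~2 × 10⁻²
away, reproducing the low-divergence regime and an outgroup at the
distance the rate tests need).

Per branch of length b: substitution events are Poisson(b × eligible
sites), sites drawn uniformly outside IRa, and the new base drawn from a
directional 12-cell matrix whose default gives each ancestral base's
transition exactly 1/3 of its row (event-level Ts/Tv = 0.5 independent of
composition) with A→C/T→G in excess and C→G/G→C depleted. A substitution
in the IR is mirrored as its complement in the other copy, emulating
plastid IR copy correction, and counts as one event. Indel events are
Poisson(0.28 × b × sites) (the empirical events-per-substitution ratio),
insertions with probability 41/58, geometric lengths with half the mass
at 1 bp, and a 52/58 fraction seeded at repeat contexts: 1-bp events
inside homopolymer runs, longer events as adjacent tandem duplications or
deletions of one copy of an existing tandem. Indels are restricted to
single-copy intergenic sequence (genes ±10 bp, junctions ±15 bp): this
keeps the IR copies exactly reverse-complementary, gene annotations exact
in every leaf, and matches the overwhelmingly noncoding location of real
plastome indels. Indels are applied after the branch's substitutions.

Every base carries a persistent column identity, so the true multiple
alignment is assembled by bookkeeping (no aligner), event logs are exact,
and replaying the logs on the root reproduces each leaf byte-for-byte —
the invariant the test suite checks. What the simulator does **not**
emulate: codon structure and selection, rate heterogeneity along the
genome, IR expansion/contraction, rearrangements, alignment error.
Passing recovery tests therefore demonstrates the correctness of the
counting and polarization machinery on known truth, not robustness to
aligner artefacts or annotation error in real data.

## Problem sizes used in the shipped tests

Unit tests run one compact family (18/5/6 kb regions) shared across the
suite; the end-to-end recovery check pools four full-size (~162 kb)
replicates, giving ≥300 substitution and ≥300 indel events so the 99%
binomial intervals around the planted Ts/Tv (0.5), insertion fraction
(41/58) and repeat fraction (52/58) are meaningful. The rate-test
calibration uses 500 equal-rate triplets of 20 kb. Exhaustive oracles
(all 4⁵ polarization columns, all 5³ site patterns, all single-run gap
patterns) are complete, not sampled.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; all files and reports are
1-based inclusive. Ambiguity codes other than N are rejected at parse
time — the analyses are defined only over {A,C,G,T,N,-}. A p-distance
with zero comparable columns, a Ts/Tv with zero transversions, and a size
fraction with zero total delta are reported as undefined rather than
silently zero. The trans-spliced *rps12* is treated as independent
features; its segments never define an intron spanning them. tRNA
isoacceptors at different loci are counted by (name, locus), never
collapsed.
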