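# Methods

This note records the statistical definitions, conventions and design
choices the package implements, in the spirit of a model-documentation
page: what is computed, under which assumptions, and what the synthetic
generators do and do not emulate.

## Coordinates and geometry

All public coordinates are 1-based inclusive, the convention of published
mitogenome annotation tables; Biopython's 0-based half-open convention is
confined to the GenBank boundary. A feature with `end < start` wraps the
origin and is legal only on circular records; its length is
`(L − start + 1) + end`.

The signed gap between adjacent features is `start_next − end_prev − 1`
(positive spacer, negative overlap, zero abutting). The origin-spanning
stretch between the last and first annotated feature is *not* a gap
entry: it is reported separately as the unannotated wraparound, because
in mitogenomes that stretch is the putative control region, not an
intergenic spacer. On the packaged *H. atra* table this yields 18
spacers, 7 overlaps and a 151 bp wraparound. A coverage identity —
feature lengths plus signed gaps plus wraparound equals genome length —
holds by telescoping for any record without nested features; nested pairs
are excluded from the gap list with a warning, since a containment depth
is not a gap.

### Overlap typology

Overlaps are labelled by the first matching rule:

1. **opposite_strand** — the two features lie on different strands;
2. **stop_codon** — the overlapped bases fall *entirely within* the
   upstream CDS's (possibly incomplete) stop codon, i.e. overlap length
   ≤ stop-codon length;
3. **pcg_pcg** — both features are protein-coding;
4. **other**.

The containment reading of rule 2 is a deliberate choice: a deep overlap
necessarily covers the upstream stop codon, so "intersects the stop"
would make rule 2 swallow every CDS–CDS overlap. Containment separates a
gene that merely starts inside a 1–3 bp termination codon from a genuine
coding–coding overlap such as the 7 bp atp8/atp6 junction, which rule 3
claims. The priority order (strand before stop before CDS–CDS) resolves
junctions that satisfy several descriptions at once.

## Composition and skew

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C); both are scale invariant
(counts and percentages give the same value), antisymmetric, and bounded
in [−1, 1]. Zero denominators yield NaN, never 0 — a sequence with no G
or C has *undefined* GC-skew, not a neutral one. N bases are excluded
from counts and denominators (a feature over 10 % N triggers a warning).

Per-feature profiles use the **plus-strand slice** of the feature's span
regardless of the feature's own strand. This is the convention under
which the single minus-strand CDS of the *H. atra* genome (nad6) shows
sign-inverted skews relative to its plus-strand peers, which is how the
published per-gene table reads; `coding_strand=True` gives the
reverse-complemented alternative. Output precision follows the field's
print convention: percentages to 1 decimal, skews to 3.

A note on reproducing printed skews from printed percentages: published
percentages are quantized to 0.1, so a skew recomputed from them carries
a propagated uncertainty of up to `0.1·(1+|skew|)/(x+y)` (about 0.002–
0.004 for tRNA-sized features). The acceptance tests therefore assert
exact 3-decimal agreement only where the quantized inputs support it and
use that propagated bound elsewhere; the bound is derived from print
precision, not fitted.

## Codon usage

Translation tables 1, 2, 5 and 9 are hard-coded (table 9: AAA→Asn,
AGA/AGG→Ser, TGA→Trp, ATA stays Ile; stops exactly TAA/TAG; starts
ATG/GTG) and cross-checked in the tests against Biopython's independent
tables. CDS codons are read on the coding strand from the feature's
first position; a trailing 1–2 bp remainder is an incomplete stop
fragment (completed to TAA by polyadenylation in vivo), reported as
`T--`/`TA-` and never counted. Complete terminal stops are excluded from
usage counts (CodonW convention); the start codon is counted as Met.
Internal stops and non-canonical start codons are warnings with
positions, not errors — they indicate annotation problems the user should
see, not states the library should refuse.

RSCU families are full amino-acid synonymous families (Ser is 8-fold
under table 9, Leu 6-fold); sub-family display labels like "Ser1" carry
no computational weight. For every family with nonzero usage,
Σ RSCU = family size exactly — this conservation is asserted
property-style on random inputs. Amino-acid percentages pool all CDSs
jointly (a per-gene-averaged alternative would weight short genes up;
joint pooling matches how single-genome codon studies report
composition). N-containing codons are skipped with a tally.

A small auditor cross-checks each tRNA's label against its annotated
anticodon (reverse-complement, then translate). On the packaged table it
flags the feature at 13,133–13,200: labelled trnL, but its anticodon GAU
decodes isoleucine. The table is preserved as published and the conflict
surfaced as a warning rather than silently corrected.

## Diversity indices

For an alignment of n sequences and L sites after filtering:
H = number of exactly-identical-row classes; Hd = n/(n−1)·(1 − Σ pᵢ²)
(Nei's unbiased estimator, the DnaSP default); S = columns with ≥ 2
states; k = mean pairwise Hamming distance over all C(n,2) pairs
(computed on haplotype classes, weighted by class sizes); π = k/L; and
the within-group mean p-distance, which equals π under these definitions
— consistent with the published report where "distance within group"
matches π to print precision. Gapped or ambiguous columns are removed
before analysis (complete deletion); pairwise deletion is deliberately
not the default because it makes L pair-dependent and breaks π = k/L.

k and π are computed as exact rationals and converted to float once, so
generator-planted truth is recovered bit-for-bit rather than to a
tolerance. Reporting precision follows the field: Hd 3 dp, k 3 dp,
π 4 dp.

The published specimen-level values for this species (30 animals;
16S: Hd 0.697, π 0.0026, k 1.234; COI: Hd 0.384, π 0.0072, k 4.469)
cannot be recomputed here because the specimen sequences were not
deposited; they serve only as a report-format reference. The tests
instead verify exact parameter recovery on synthetic plans, including
one with the structure of the 16S result (n = 30, four haplotypes, three
singleton sites).

## Gene-order comparison

A gene order is a signed circular sequence canonicalized by rotating
cox1 to the front and mirroring the circle if cox1 is on the minus
strand — cox1 being the one gene whose position is conserved across the
holothurian orders compared. An adjacency `x→y` is identified with its
reverse complement `flip(y)→flip(x)`; the breakpoint distance is the
number of adjacencies of one canonical order absent from the other. On
equal gene content this is symmetric and satisfies the triangle
inequality (both verified exhaustively over all 384 signed circular
orders of 5 genes). Unequal content restricts to the shared genes with a
warning; tRNA naming differences across databases are absorbed by an
editable harmonization map.

Event classification is deliberately single-event: translocation (remove
one gene from both orders → identical), inversion (reverse-and-flip one
contiguous segment), block shift (relocate one contiguous block), tried
in that order; anything else is `unclassified` with its breakpoint
count, rather than a guessed multi-event history. Every emitted event is
replayable, and the tests assert that replaying it transforms one order
into the other. A consequence of the priority order is that an adjacent
two-gene swap is reported as a translocation (both descriptions are
valid single events).

## Synthetic generators

**Genomes.** A plan (gene order, per-feature lengths, signed gap vector,
per-feature base weights, control-region size) is realized by coordinate
arithmetic; overlapping features share bases rather than duplicating
them, as in real annotations. CDS features are built codon-wise: ATG
start, sense (non-stop) middle codons drawn with probability
proportional to the product of per-base weights, and a complete TAA/TAG
or incomplete T/TA stop chosen by length mod 3. When the downstream
member of an overlap is itself a CDS it owns the shared bases, and its
codons are rejection-sampled (seeded, bounded retries, with a bounded
whole-genome restart above that) until every upstream CDS still reads
through with no internal stop and an intact stop codon — the same
double-duty the real atp8/atp6 junction performs. The default plan
mirrors the published *H. atra* architecture (order, lengths, gap
vector, 151 bp control region) with genome-typical base weights
(A 0.341, C 0.259, G 0.149, T 0.251).

The emitted truth sidecar (gap vector, per-feature base counts, per-CDS
codon counts and peptides) is derived from the assembled sequence by
independent direct slicing, so pipeline results can be asserted exactly
after a full file round trip.

**Haplotypes.** A reference row is drawn from base weights and
replicated per class; each non-reference class carries a planted map of
site → substitute base (the reference base at a planted site is forced
to differ, so every planted mutation is real). Infinite sites is the
default — each site used at most once — making S equal the number of
planted sites; recurrent hits are available behind a flag. Truth (H, Hd,
S, k, π) is computed from the plan alone in exact arithmetic.

Each generator consumes its own named substream of one integer seed, so
adding a generator never perturbs another's output, and repeated runs
are byte-identical.

What the generators do **not** emulate: realistic substitution processes
(no transition/transversion bias, no rate heterogeneity, no coalescent
genealogy), tRNA/rRNA secondary structure, codon autocorrelation along
genes, or sequencing error. Passing tests therefore demonstrate
correctness of the *statistics and geometry*, not robustness to
real-data messiness such as misannotation or alignment error.

## Problem sizes and numerical choices

The default verification workloads are sized for interactive runs: 200
random haplotype plans (n ≤ 30, L ≤ 800) with an O(n²L) brute-force
oracle, one 15.8 kb synthetic genome per seed, and exhaustive 5-gene
enumeration (384 orders) for the metric axioms. Degenerate inputs are
defined rather than left to chance: empty/all-N sequences, sub-6-bp CDSs
and featureless GenBank files are errors; undefined skews and unused
RSCU families are NaN; single-feature records summarize to zeros;
fewer than two sequences cannot have diversity indices.

## Known limitations

- Overlap typing depends on annotated stop-codon metadata; without it,
  rule 2 cannot fire and deep CDS overlaps fall through to rules 3/4.
- The event classifier is single-event by design; composite histories
  are common across distant families and will read `unclassified`.
- No minimal rearrangement distance (sorting by reversals / DCJ) is
  computed; breakpoint distance is a dissimilarity, not an edit count.
- Diversity indices assume aligned, same-locus input; the package does
  not align sequences.
- GFF3 input and annotation inference from raw sequence are out of
  scope; annotations must come from a gene table or GenBank file.
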