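# Methods

This note records the models implemented, the conventions and parameter
defaults, the design choices made where several readings were defensible,
and what the synthetic-data generator does and does not emulate.

## Coordinates and formats

All intervals are 0-based half-open internally (the BED convention).
RepeatMasker `.out` rows (1-based inclusive) and the SNP table (1-based
positions) are converted at parse time. For `.out` rows the consensus
columns depend on strand: `repStart, repEnd, (repLeft)` on `+`,
`(repLeft), repEnd, repStart` on `C`; both normalise to
`cons_start ≤ cons_end` with `cons_length = cons_end + repLeft`. Repeat
classes outside {LINE, SINE, DNA, LTR} are labelled `other` and excluded
from exaptation analysis. MAF blocks are reference-anchored with the
reference row first.

## CNEE derivation and classification

Derivation removes a conserved element *whole* if it overlaps ≥ 1 base of
the union of the exonic tracks — no base-level trimming — because the goal
is a set of elements that appear in no mature transcript at all.
Classification counts covered bases with per-base de-duplication: a base
under two annotations counts once toward the union (so the repeat fraction
cannot exceed 1) but toward each taxon's own tally at every level. A strict
majority (> 0.5) is required for exaptation and for each taxon assignment;
exactly half does not qualify. Consequently class-level counts can exceed
the sum of their superfamily rows (an element split 45%/45% between two
superfamilies of one class counts only at class level).

Summary ratios (genomic elements per exaptation, genomic bases per exapted
base) are computed in integer arithmetic and truncated — not rounded — to
one decimal (`(10·a)//b / 10`); a zero exapted count renders `NA`. Exapted
bases count all bases of an exapted element, attributed to the majority
taxon of the relevant level; the alternative of counting only
repeat-annotated bases within the element would differ by at most the
minority fraction and is not used.

## DAF rank-shift test

Sites must be segregating (0 < derived count < sample size). The
Mann–Whitney U statistic uses the `#(a>b) + ½#(a=b)` convention. For pooled
sizes ≤ 12 the p-value is computed by exhaustive enumeration of all label
assignments of the pooled sample, which handles ties exactly; larger
samples use the tie-corrected normal approximation. Both one-sided
("a-less", for a downward shift of the first spectrum) and two-sided
alternatives are exposed; the default is two-sided since directionality is
a caller-level hypothesis. The result names the spectrum with the lower
mean pooled rank.

## Rate of evolution (single-constant tree scaling)

The neutral model is a rooted tree with branch lengths in expected
substitutions/site and a time-reversible generator Q built from
exchangeabilities and equilibrium frequencies, scaled to one expected
substitution per unit branch length; Jukes–Cantor is the default when no
model is supplied. The likelihood of an element's alignment is the product
over columns of the Felsenstein pruning likelihood with every branch length
multiplied by ρ, transition matrices `expm(ρ t Q)`. Gaps and unknown
characters are marginalised (fully ambiguous), not treated as a fifth
state; an all-gap column therefore contributes likelihood 1. ρ is fitted by
bounded Brent search on [0, 4] with tolerance 1e-6 — values above 4 are
biologically implausible for conserved elements and the bound guarantees
termination. Alignments with no unambiguous character are rejected.
Distinct neutral models (e.g. a separate chromosome-X tree) are supported
by passing a different `PhyloModel` per element set.

Estimator behaviour, measured on 500-column, 12-leaf simulations with the
default tree: unbiased (20-seed mean within 0.002 of truth at ρ = 0.3 and
1.0) with sampling SD ≈ 0.016 at ρ = 0.3 and ≈ 0.035 at ρ = 1.0. Per-seed
recovery tolerances in the tests reflect these SDs. Rate recovery is only
meaningful for elements present across the whole tree, so recovery fixtures
pin the insertion to the root-most branch.

## Dating

The species ladder is derived from the tree: each internal node on the
root-to-reference path defines a group (the lineages that diverged there)
labelled with the reference-lineage branch above it. An element's aligned
fraction in a group is the share of its reference bases aligned to a
non-gap character in **any** species of the group. Scanning groups from
most divergent to least, the first group reaching the presence threshold
fixes the branch; failing all groups, the element is reference-specific.
The threshold is ≥ 0.5 uniformly and exposed as a flag, because "half or
more" and "more than half" both appear in the field's descriptions of this
procedure; at the default fixture sizes the two readings differ only for
even-length elements aligned exactly half.

## Genomic landscape

Elements are binned by midpoint into fixed windows (default 1 Mb; the final
partial window is kept), and counts are used rather than base coverage
(flag planned if coverage is wanted): midpoint conventions are not dictated
by the underlying data. Track similarity is the Pearson r of first
differences of the normalised densities, concatenated across chromosomes
with no cross-chromosome difference — differencing removes the shared
large-scale trend that would otherwise dominate r. Gene-desert depletion
uses midpoint distance to the nearest TSS, "far" meaning > 1 Mb, and a
one-sided hypergeometric tail (depletion of exapted elements among far
elements); chromosomes without a TSS are excluded with a warning. Fold
enrichment compares the fraction of elements overlapping a feature with the
mean fraction over R seeded placements of length-matched intervals at
uniformly random positions (default R = 1000); a zero expectation reports an
infinite fold rather than failing.

## Consensus profiles, peaks, motifs

Genomic↔consensus mapping is affine interpolation between the hit's
genomic span and its consensus span, mirrored from `cons_end` on the minus
strand and clipped to the hit span. Real `.out` annotations do not retain
the alignment, so indels inside a hit are spread evenly by the
interpolation; synthetic fixtures are indel-free, making the mapping exact
and testable against a per-base oracle.

Profiles weight bases, not insertions: genomic coverage increments over
every hit's consensus span, exapted coverage over the projection of each
exapted element ∩ hit, de-duplicated per element (an element contributes a
position at most once). The fold track is the per-position share of exapted
bases divided by the per-position share of genomic bases — the
proportional-co-option null under which fold ≡ 1 — undefined (NaN) where
genomic coverage is zero. Peaks are maximal runs of defined fold > 2
supported by ≥ 40 distinct elements touching ≥ 1 run position (per-peak
support; a per-position minimum is a flag away). The permutation null
re-places the element length multiset uniformly without overlap and re-runs
classification → profiling → peak calling per trial; published genome-scale
peak counts are not reproducible at fixture scale, so the null is used for
planted-signal calibration only.

Paralog extraction inverts the affine map to cut, for each supporting
element, the genomic sequence projecting onto the peak, reverse-complemented
to consensus orientation; elements are de-duplicated by identity and hits
not spanning the peak are skipped with a warning. PWMs use additive
smoothing `(count + c)/(n + 4c)` with pseudocount 0.5. The PWM comparator
scans all offsets and both orientations, scores the mean per-column Pearson
r over the overlap (≥ 4 columns), and derives p from seeded column-shuffle
permutations; it is a deliberately simple internal comparator — Tomtom
remains the reference tool for real motif libraries, and MEME for motif
discovery.

## Synthetic-data generator

The generator emulates the study system: background sequence is i.i.d.
with configurable GC (0.41 default — no analysis here depends on background
composition); insertions copy contiguous consensus sub-spans (uniform span,
either strand) into the background without overlap, with explicit failure
when the requested density cannot be placed; a configurable fraction of
insertions (default 0.7) carries one constrained sub-interval evolving at
`constraint_scale` times the neutral rate (default 0.30, the mean rate
observed for exapted elements); insertion branches are uniform over the
reference-lineage ladder of a 12-leaf default tree. Alignments are evolved
by traversing the tree from the reference leaf outward — valid because the
substitution model is time-reversible — which pins the reference row to the
genome exactly; lineages older than the insertion's branch are all-gap
across it. Segregating sites fall uniformly on the genome; frequencies are
Beta(0.5, 3) inside constrained intervals and Beta(1, 1) outside, sampled
to derived counts by a Binomial(n = 120) conditioned on segregating — a
simple caricature of the downward DAF shift under purifying selection.

Reproducibility: each stage draws from a child RNG stream keyed
(seed, stage) in a documented order, so a fixed seed yields byte-identical
fixtures regardless of which stages are invoked.

Not emulated: retrotransposition mechanics (target-site duplications, 5′
truncation), CpG hypermutability, indel evolution inside insertions,
alignment error other than optional random gap masking, linked selection
and demography in the site-frequency model. Passing tests therefore
demonstrate the correctness of the inference machinery under the stated
generative assumptions, not robustness to these real-data complications.

## Problem sizes

Defaults were chosen so the whole suite runs in well under a minute of
pipeline time per stage: 2 × 100 kb chromosomes, ~0.4 insertions/kb
(~80 insertions), 5,000 segregating sites (20,000 for the DAF power
analysis), 500-column alignments over 20 seeds for rate recovery, 100
insertions for dating recovery, 200 permutation trials and 10–20 seeds for
peak calling. Published genome-scale counts (hundreds of thousands of
elements, hundreds of peaks) are reproduced only in these scaled-down
synthetic forms; the bundled published count table is the sole real-data
input, used to verify the summary-table arithmetic.
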