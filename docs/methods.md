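# Methods

This note documents the models behind each stage of the pipeline, the
parameter choices that matter, what the synthetic scenario does and does
not emulate, and the numerical conventions used throughout.

## Coordinates and conventions

All internal coordinates are 0-based, half-open. 1-based coordinates appear
only in VCF output (`POS` is the 0-based breakend coordinate plus one). A
derivative chromosome is represented as a sequence plus a provenance list of
`(source chromosome, interval, orientation)` segments, which every
downstream operation (marker scoring, read mapping, transcript splicing)
consults instead of re-deriving junction arithmetic.

## The translocation model

A reciprocal translocation between chromosomes A and B is parameterized by
breakpoints `posA`, `posB` and a microdeletion of `delLen` bases removed
from A at the der(3) junction. The join topology is *fold-back*: one
derivative carries the proximal (low-coordinate) segments of **both**
chromosomes,

    der(4) = B[0, posB) ++ revcomp(A[0, posA))
    der(3) = revcomp(B[posB, end)) ++ A[posA + delLen, end)

so right end joins right end and left end joins left end. This is the only
topology consistent with a hybrid-clone retention pattern in which a single
derivative is positive for the proximal markers of both chromosomes — the
naive head-to-tail model would pair one chromosome's proximal block with
the other's distal block. Sequence length is conserved up to the deletion:
`len(der3) + len(der4) + delLen == len(A) + len(B)`.

The default `feve_toy` scenario scales the motivating study's megabase
coordinates by 10⁻³ (23.8 Mb → 23,800 bp) so that the fixture echoes the
original numbers while every sequence fits comfortably in memory: A is
50 kb broken at 23,800, B is 150 kb broken at 107,800, and the 5 bp motif
`TACAC` is written into A at the breakpoint before being deleted from
der(3). The background sequence is i.i.d. uniform ACGT from a seeded
generator; identical seeds give byte-identical scenarios.

## Hybrid-panel model

Somatic-hybrid clones from a homozygous carrier donor can only receive
der(3) and/or der(4) for the two chromosomes of interest. Each simulated
clone retains each derivative independently with probability 0.4 (the study
does not report a retention rate; its panel retained one derivative in 8 of
12 clones and the other in 1). A marker scores 1 iff its position lies on a
retained fragment — chromosome-A markers below `posA` and chromosome-B
markers below `posB` sit on der(4); positions at or beyond the breakpoint
sit on der(3); positions inside the deleted motif amplify from neither —
and assay failures flip true positives to 0 with a configurable
probability (default 0).

Classification of clone content from a retention matrix labels a pattern
EMPTY (all target markers 0), ALL_POSITIVE (all 1), SINGLE_DERIVATIVE
(positives form one contiguous block anchored at the same chromosome end on
every chromosome: a proximal prefix for the derivative carrying both
proximal segments, a distal suffix for its partner), or INCONSISTENT —
reported, never repaired, because assay noise must surface in QC. Marker
order per chromosome uses physical positions when every marker has one,
else genetic (cM) positions, else row order; the basis used is recorded in
the result.

The initial breakpoint interval runs from the last positive to the first
negative marker. When a flanking marker lacks an assembly position, the
nearest physically mapped marker on the genetic map *in the direction away
from the interval interior* substitutes, and the substitution is recorded
— this conservative rule can only widen the interval, never lose the
breakpoint. On the packaged retention table it reproduces the printed
9.313 Mb and 13.998 Mb intervals exactly, including both substitutions.

## STS walk

Each round of the walk plans up to `k` probes at the ideal equal-spacing
points `start + i·width/(k+1)` (integer floor), snapped to the nearest
available marker strictly inside the interval, ties toward the lower
coordinate. Marker availability comes in ordered phases — microsatellites,
a finite SNP-chip set, then freely designable sequence STSs — and the walk
uses the first phase with any marker inside the current interval, falling
through as each phase runs dry. The SNP-chip set is simulated with a
~200 bp spacing but a 1.5 kb marker drought around each breakpoint, so a
walk restricted to chip markers stalls at the gap, reproducing the need for
a sequence-STS phase.

Refinement requires the augmented result vector (left flank 1, probes,
right flank 0) to be monotone; the new interval spans the 1→0 transition.
Non-monotone results raise an explicit inconsistency error after one
re-assay (the retest budget mirrors the use of a both-derivatives clone as
PCR positive control); they are never repaired silently. Note that an assay
*failure* (1 flipped to 0) produces a monotone but wrong pattern that no
internal check can catch — exactly as in the laboratory, where it is
guarded against by the positive control and by retesting flanking markers.
With failure probability 0 the interval provably never loses the
breakpoint, and with dense availability the round count meets
`ceil(log_{k+1}(W0/Wf))` on exactly divisible widths.

A probe at exactly `posA` scores 0 (the retained segment is half-open), so
the final interval `(last positive, first negative]` brackets the
breakpoint from the left strictly and from the right inclusively; tests
check containment accordingly.

## In-silico PCR and junction calling

The PCR engine is pure site logic: exact matching of the forward primer
and of the reverse primer's reverse complement, both primer-order
assignments considered (making the amplicon set symmetric), every ordered
site pair within `max_len` (default 10 kb) reported. No melting
temperature, mismatch tolerance or secondary-structure modeling — the
analysis needs binding-site combinatorics, not thermodynamics.

The genotyping assay uses three primers: a shared forward primer on B, the
normal-copy reverse primer 346 bp downstream on B, and a primer placed
upstream of the A breakpoint *stored as the A top-strand sequence*: on
der(4), where that segment is inverted, it acts as a reverse primer and
yields a 277 bp junction product (199 bp of B + 78 bp of A). The decode
{346} → N/N, {277} → T/T, {277, 346} → N/T is a bijection verified
exhaustively.

Junction calling anchors a 30 bp seed from each end of a sequenced junction
fragment in the corresponding reference and extends the exact match. Bases
matching both references are microhomology: the breakend is ambiguous
across `mh` positions and is reported left-aligned on chromosome A with a
CIPOS-style interval of width `mh`. A call needs ≥ 20 anchored bases per
side after removing the overlap, else NO_CALL.

Reconciling the der(3) and der(4) junction calls exploits an invariance:
across the admissible representations `(pos_a + t, pos_b − t)` of each
call, the net deletion `(a3 − a4) + (b3 − b4)` is constant. The deleted
motif is read at the representation placing both junctions on a common
chromosome-B breakpoint (left-aligned on A); when the motif's edges are
homologous with its flanks the reported window may be a shifted equivalent
of the generator's, but it always reconstructs identical derivative
sequences — the round-trip tests assert exactly that. Both toy junctions
happen to carry 1 bp of incidental homology from the random background,
which exercises this machinery on the default scenario.

Transcript truncation: an exon is retained on a derivative iff it lies
wholly inside a colinear provenance segment of the gene's chromosome; an
exon cut by a junction raises an explicit straddle error. The default gene
has 19 exons of 100 bp with the breakpoint in intron 15 — the exon count
is configurable because only "breakpoint in intron 15" and "four exons
lost" are fixed facts about the modeled gene, not the full exon
complement. RT-PCR prediction runs the PCR engine on spliced cDNA: the
pair spanning the breakpoint (exons 15/17) yields nothing from the
truncated allele while the control pair (exons 13/14) amplifies from both.

## Mate-pair library and pool simulation

The library model is a 6 kb-insert, 100 bp-read mate-pair library in
innie/FR convention (the convention that results from reverse-complement
preprocessing of raw outie mate-pairs before alignment). Insert lengths are
normal (μ = 6000, σ = 600) truncated to [1000, 12000]; mapping quality is
60 with a 5% fraction at 5 to exercise the quality gate.

A pool is a set of individuals with genotypes N/N, N/T or T/T, each
contributing four relevant haplotypes (N/N → {A, A, B, B}; N/T →
{A, B, der3, der4}; T/T → {der3, der3, der4, der4}). Fragment counts per
haplotype are Poisson with mean `coverage × length / μ`, so each haplotype
copy carries the nominal physical coverage; reads are emitted in reference
coordinates through the derivative provenance maps, and a read crossing a
junction is dropped (it would not align end-to-end). A fragment spanning a
derivative junction therefore yields an inter-chromosomal pair whose strand
signature follows from the fold-back topology: (+,+) proximal pairs for
the der(4) junction, (−,−) distal pairs for der(3). The expected number of
junction-spanning pairs has the closed form
`Σ_derivatives coverage·len/μ · E[(ins − 2L + 1)/(len − ins + 1)]`,
which the simulation matches within sampling error; the default coverage
of 17.5× per haplotype makes the two-junction total ≈ 36, echoing the
34 supporting pairs the motivating study observed from its pool with one
heterozygous carrier among five animals.

Background noise is modeled as (i) uniform chimeric inter-chromosomal
pairs and (ii) recurrent artifact loci — tight pseudo-clusters of
support 15 placed at the same three positions in case and control pools,
standing in for reference-assembly artifacts. The noise count is 60 pairs
per pool: the original data's >12,000 chimeric pairs lie in a regime where
the expected number of noise neighbours within one clustering radius is
≈ 4×10⁻⁵; at the toy's 10⁻³ linear scale the same absolute count would put
~16 neighbours within every pair's radius, percolating into giant clusters
that swallow the signal. 60 pairs per pool (≈ 0.5 expected neighbours per
pair) preserves the sparse-noise regime the method actually operates in;
the noise *level relative to signal* is exercised by the artifact loci and
the differential filter rather than by raw chimera count.

## Translocation screen

Pairs at mapping quality ≤ 10 are discarded (the threshold is exclusive,
"above 10"). Same-chromosome pairs are concordant when innie with span
within μ ± 3σ. Inter-chromosomal pairs are binned by (chromosome pair,
strand signature) and single-linkage chained: two pairs link iff their
positions differ by at most μ + 3σ on *both* chromosomes; connected
components become clusters. Single linkage mirrors the geometry of a
junction cluster (members spread over up to one insert length on each
side) and is order-independent; a brute-force union-find oracle guards the
implementation.

Each cluster side gets a breakend confidence interval from read-end /
insert-bound geometry: a '+' member implies the junction lies in
`[pos + L, pos + maxInsert]` (mirrored for '−'), where `maxInsert` is the
library's truncation bound — the hard upper limit an insert can reach,
which is what bounds the junction distance (μ + 3σ would be violated by
legitimate long-insert pairs about once per cluster in twenty). Because
single linkage occasionally chains a background pair into a real cluster,
the interval is the *quorum consensus*: the hull of the region supported
by ≥ 80% of members, realized per bound as the `ceil(0.2 n)`-trimmed order
statistic, with a maximal-coverage-region fallback if no coherent majority
exists. A minority of chained outliers therefore cannot displace the
interval; for a pure cluster the estimate reduces to the exact
intersection `[max(read end), min(read start) + maxInsert]`.

Clusters supported by ≤ 10 pairs are flagged LOW_SUPPORT (exclusive
threshold, "more than 10"). Complementary-signature clusters on the same
chromosome pair whose breakend intervals lie within μ + 3σ of each other
on both chromosomes merge into one reciprocal (balanced) call — interval
distance rather than midpoint distance, because the intervals of the two
junctions abut at the breakpoint while their midpoints sit on opposite
sides of it. Unpaired passing clusters are kept, flagged non-reciprocal
(dropped in balanced-only mode). The differential filter flags a case call
IN_CONTROL when a *supported* control candidate shares the chromosome pair
with both breakend midpoints within μ; matching against unsupported
single-pair control clusters would veto real calls by coincidence.

VCF output renders each junction as two BND records with `MATEID`,
`CIPOS = (0, interval width)`, `SUPPORT` and an `EVENT` tag grouping
reciprocal pairs; the bundled parser round-trips everything the records
carry, and the output is also readable by standard VCF libraries. The SAM
importer intentionally reads only QNAME/FLAG/RNAME/POS/MAPQ/RNEXT/PNEXT
and flags 0x1/0x10/0x20/0x40/0x80.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the original study — marker
retention logic, junction sequence content, product sizes, pool
composition, junction-spanning pair statistics, recurrent artifacts — on
i.i.d. random background sequence. It does not emulate repetitive or
low-complexity sequence (so primer sites and junction anchors are unique
almost surely), alignment errors (reads are emitted in truth coordinates;
there is no aligner), reference mis-assembly beyond the stylized artifact
loci, or chromosome-scale marker maps. Passing tests therefore validate
the analysis logic and its statistical behaviour under the stated
sampling model, not robustness to repeat-mediated mismapping.

Stochastic margins: with per-junction expected support ≈ 17 and the
exclusive > 10 threshold, a junction cluster drops below threshold in a few
percent of seeds; in roughly 1 in 30 simulations both do, and the screen
reports no PASS call. This is a property of the sampling model at the
chosen coverage, matching the study's own margin (34 total supporting
pairs against a > 10 threshold), and is deliberately not tuned away.

## Problem sizes

The default test suite and acceptance script use the 200 kb toy genome,
12–200-clone panels, pools of ~6,000 fragments, and 20-seed replicates for
stochastic properties; everything completes in well under a minute on one
core.
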