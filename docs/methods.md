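# Methods

`minichrom` reproduces, at desk scale, the three read-coverage analyses used
to characterize maize mini chromosomes derived from the supernumerary B
chromosome and from 9-Bic-1 (a chromosome 9 carrying an inactive B
centromere on its short arm): copy-number-variation (CNV) breakpoint
mapping on chromosome 9, B-chromosome deficiency mapping, and CENH3
ChIP-seq occupancy comparison including de novo centromere calling.  This
note documents the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## The coordinate model

Real maize data operate on a 2.1 Gb genome; the package instead builds a
*scaled model* in which one "paper megabase" (paper-Mb) of chromosome
corresponds to `scale_factor` model base pairs (default **10 kb/paper-Mb**).
All breakpoints of interest lie in the first 10 Mb of 9S and the first
8 Mb of the assembled B reference, so the model carries:

| contig | paper extent | model size | content |
|---|---|---|---|
| `chr9` | 0–15 Mb | 150 kb | 9S region; CentC/CRM centromere array at 12.0–12.33 Mb; knob180 array at 14 Mb |
| `chrOther` | 85 Mb | 850 kb | ballast for the rest of the A genome, with its own centromere and knob |
| `chrB` | 0–8 Mb | 80 kb | proximal centromere region (ZmBs array plus single shared monomers) at 0–0.25 Mb; scattered knob180/CentC/CRM monomers along the arm |
| `B_scaf1..3` | 575 kb total | 5.75 kb | unplaced B centromeric scaffolds: ZmBs plus B-specific sequence |

The ballast contig is not cosmetic: ratios are normalized by library size,
and on a chr9-only model a 3 Mb hemizygous deletion would shift the
library by ~10% and bias the disomic ratio accordingly.  With 100 paper-Mb
of A-genome model the residual bias is ~1.5%, matching the situation in
the real data where the deletion is negligible against the whole genome.

Background sequence is i.i.d. uniform A/C/G/T, which guarantees that
B-specific sequence shares no read-length k-mer with the A contigs (the
builder verifies this exactly at build time with rolling-hash screening
plus direct comparison).  Repeat monomers are the deliberate exception:
each *shared* monomer variant (CentC 156 bp, CRM 300 bp stand-in,
knob180 180 bp) is placed verbatim at **≥ 2 A-genome locations and exactly
one B location**.  Reads from such a monomer therefore multi-map on the A
genome, survive stage 1 of subtractive mapping (which removes only
*uniquely* A-mapped reads), and land uniquely on the B side — mechanically
reproducing the knob/CentC cross-homology background observed in B-less
control lines.  ZmBs (150 bp stand-in) is B-specific and tandem-arrayed,
so its reads multi-map within the B targets and drop out, as in real data.

## Karyotypes

A karyotype is a list of chromosomes, each an ordered fusion of reference
segments with a copy count, plus the intervals where CENH3 (the
centromere-specific histone H3 variant marking active centromeres) is
loaded in that line:

* **B73** — chr9 ×2, chrOther ×2.
* **B73+B**, **TB-9Sb** — B73 plus a full B (chrB + scaffolds), active B
  centromere.  TB-9Sb is modelled with the same content: for these
  analyses it serves only as a positive control with an active B
  centromere.
* **9-Bic-1 heterozygote** — one intact chr9, one derived chromosome =
  chr9[3.06 Mb → end] fused to chrB[0 → 2.1 Mb] (+ scaffolds); B
  centromere inactive (no CENH3 interval).
* **mini B1104** — chr9 ×2 plus a mini = chr9[3.06 → 3.52 Mb] +
  chrB[0 → 2.1 Mb]; de novo CENH3 domain at chr9 3.10–3.35 Mb and a
  *partial* B-centromere re-association modelled as enrichment weight 0.25.
* **mini B496** — chr9 ×2 plus a mini = chrB[0 → 7.5 Mb] +
  chr9[9.51 → 9.67 Mb]; de novo CENH3 domain on that 9S piece; B
  centromere inactive.

Junctions are modelled as clean fusions; reads spanning a junction match
nothing in the references and count as unmapped, which slightly depresses
coverage within one read length of each junction.

## Read simulation

WGS read starts are uniform over the concatenated chromosome copies, so a
locus at copy number *c* receives `depth × c/2` coverage (depth is quoted
for a disomic locus; default 30×, single-end 100 nt, error-free unless an
error rate is set).  ChIP libraries are a two-component mixture: with
probability `chip_fraction` (default 0.3, roughly a tenfold peak over
background on the default layout — the real ChIP efficiency is not
published, so this is a convention) a 300 bp fragment is drawn wholly
inside one of the line's CENH3 intervals (interval chosen ∝ length ×
weight), otherwise genome-wide; both mates of the pair are emitted (100 nt,
fixed insert, no variance — pileup geometry, not insert modelling, is
under test).  Input libraries are WGS-like.  Qualities are constant Q35
with an optional low-quality tail so trimming has work to do.  Truth
provenance (contig, position, strand) rides along on every read for
testing and is never consumed by analysis code.

## Mapping

Trimming follows the leading/trailing/sliding-window/min-length/average-
quality rule set (defaults 30/29/4:30/29/28); mates are treated as
singletons and orphans retained.  The mapper is exact: a read is reported
iff it matches exactly **one** location with **zero mismatches** over both
strands of the whole target set — the contract that "align, then filter to
0-mismatch unique records" converges to.  Implementation: 29-bp 2-bit
seeds (29 = the minimum read length after trimming) in a sorted index,
every candidate verified by direct base comparison, so the output is
provably identical to an exhaustive substring scan (and is tested against
one).  Reads containing N are unmapped by definition.  Any object with the
same `classify` interface can replace the internal matcher (the seam for
plugging in an external aligner).

Subtractive mapping routes a library A-then-B: stage 1 removes reads
placing *uniquely* on the A targets; stage 2 keeps survivors placing
uniquely on the B targets.  The tally (input = A-filtered + B-unique +
B-multi + unmapped) is conserved exactly on every run.

## CNV analysis

Counting uses contiguous 0.05 paper-Mb gene windows on chr9 (300 windows;
read assigned by start coordinate, half-open).  The per-window ratio is
library-normalized, `(s_w / S) / (r_w / R)`; windows with reference count
below `min_ref_count` (default 10) are masked — in practice the
repeat-array windows whose unique-read coverage collapses.  Window width
is a resolution compromise: at 30× a 500 bp model window holds ~150
control reads (per-window ratio noise ≈ 11%), while the smallest segment
of interest (the 160 paper-kb 9S piece of mini B496) still spans ~3
windows.

Breakpoints are the **exact** single change point: the split minimizing
total within-segment SSE of the ratio over every boundary (computed by
cumulative sums, verified against brute force).  A call requires
confidence ≥ 3, where confidence = |Δmean| / pooled within-segment s.d.;
flat tracks return no breakpoint.

Segment detection uses a two-level rule around the track median
(default margin 0.25): windows join a run at half the margin, and a run is
reported only if it has ≥ `min_windows` (default 3) windows, its mean
deviates by the full margin, *and* its pooled counts are significant at
z ≥ 4 (Poisson s.e. of the log pooled ratio — roughly a Bonferroni level
for a few-hundred-window track).  The two-level form is needed because a
3-window segment with a true +0.5 shift sits only ~3σ per window above
noise: a single hard threshold misses it ~30% of the time, while the
pooled-count test keeps chance runs on null tracks out (0 false segments
in 10 null B73-vs-B73 comparisons at these defaults).

## Deficiency mapping

B-specific alignments are counted in 1 paper-kb windows along `chrB`.
A window is *covered* when its count exceeds the background level,
estimated as the 95th-percentile window count of a paired B-less control
(the paper shows this background visually but sets no numeric rule).  The
truncation point is the exact SSE change point of the covered indicator,
subject to: (i) each side of the split keeps ≥ 25 windows, so read-length
edge effects at the reference ends cannot mimic a truncation; (ii) the
left side must be covered (indicator mean ≥ 0.5) and the right side not —
a deficient-proximal/covered-distal split is the ZmBs/satellite
multi-mapping dead zone at the centromere, not a truncation, which always
removes the distal side.  Tracks covered on both sides return
`no_deficiency`; background-only tracks return `no_b_material`.

## CENH3 occupancy

Coverage is mean per-base read coverage per 1 paper-kb bin, scaled to
reads-per-million, separately for ChIP and input; at this model scale a
100 bp read spans ten bins, so body coverage (what browser pileups show)
is used rather than start counts, which would leave read-length holes at
domain edges.  Enrichment is `(chip + ε)/(input + ε)` (ε = 0.5 RPM) with
bins below the 5th percentile of input masked, then divided by its median
over unmasked bins so background sits at 1 regardless of ChIP efficiency.
A raw chip-vs-chip mode (`chip_vs_chip`) is available for line-vs-line
comparison of pileups.

*B-centromere occupancy* (after subtractive routing of the ChIP reads to
the B targets): the score is the aggregate ChIP:input mass ratio over the
scaffold bins; a line is `absent` at ≤ 1.5× the negative-control score,
`active` at ≥ 0.5× the positive-control score, `reduced` between.  The
thresholds are this package's formalization of a visual comparison and
were chosen to separate the simulated positive and negative controls by a
wide margin; the sweep test shows the label is monotone in the planted
enrichment.

*De novo domains*: unmasked bins with enrichment ≥ 3 are merged across
gaps of ≤ 2 sub-threshold bins (masked bins carry no evidence and do not
break a domain, up to 15 bins of total gap — the input mask removes its
percentile of bins even inside true domains); merged intervals must be
≥ 10 paper-kb wide, have mean enrichment ≥ 3, and pass a pooled
read-start significance test at z ≥ 5 (start counts are independent
evidence units; body-coverage bins a read length apart are not, so one
excess ChIP fragment over an input dip can clear the enrichment threshold
but never this test).  A domain is *unique* to the focal line iff every
control line's mean enrichment over the interval stays below 1.5; a
control with no unmasked bins there cannot attest and blocks uniqueness.

## Screen statistics

Fate tallies of the kernel screen are validated against their identities
(fates sum to the kernels with breakage signs; B-derived minis cannot
exceed recovered minis) and reported as exact fractions plus two-decimal
half-up percentages, the rounding that reproduces the published 0.42%
(6/1412).  Rates against the ~10,000 total kernels are not derived because
that denominator is approximate.

## What the simulation does and does not show

The generator emulates segmental aneuploidy, repeat-induced multi-mapping
with A/B cross-homology, and localized CENH3 enrichment — the features
these analyses actually consume.  It does not model sequence divergence
between sample and reference, GC or PCR bias, indels, insert-size
variance, partial repeat homology (shared monomers are exact copies), or
chromatin-shaped input non-uniformity.  Passing tests therefore show that
the *inference machinery* recovers planted truth under faithful coverage
geometry; they do not certify robustness to alignment artifacts that only
divergent real reads produce.  Model-scale geometry also makes one read
length equal 10 paper-kb, so called boundaries carry an intrinsic
~0.01 paper-Mb softness near junctions that real 100 nt reads would not
cause.

## Problem sizes

Default analyses run on the 10 kb/paper-Mb model at 30× WGS (≈ 300k reads
per line) and 10× ChIP+input; a full six-line replicate takes ~15 s on one
CPU, and the replicated acceptance analysis (20 seeds) a few minutes.
These sizes were chosen so the whole study, including its replicated
statistics, runs interactively at a desk.
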