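# Methods

This note documents the models, parameter choices, and numerical
conventions behind `enhancerdyn`, and what the synthetic scenario does and
does not establish about real data.

## Coordinate and interval conventions

All intervals are 0-based half-open (BED). A site's position for distance
computation and profile anchoring is the integer midpoint
`floor((start+end)/2)`. Nearest-TSS distances are signed
(`site center − TSS`, positive to the right in genome orientation,
independent of gene strand); windowed analyses use the absolute value.
Equidistant genes are resolved toward the lexicographically smaller gene
id so that results are deterministic. Overlapping bedGraph records are
summed, treating records as additive fragment piles. Merging with
`min_gap=0` is the plain union of covered bases; book-ended intervals
coalesce.

## Binding dynamics

Per-time-point peak calls for one factor are merged across all time points
into a non-redundant region universe; `presence[r, t]` is true iff a peak
at time *t* overlaps region *r* by at least `min_overlap` (default 1 bp).

**Stability.** "Stably bound up to the terminal time" is ambiguous between
(a) present at the terminal time and (b) continuously present from first
detection onward. The default (`gapfree`) uses the stricter rule (b):
a region is stable iff it is present at the terminal time *and* at every
sampled post-induction time from its first detection; `terminal` mode
implements (a). The baseline (t = 0) sample is excluded from the stability
assessment — uninduced cells can show leaky low-level binding — but is the
reference for the PU.1 pre-binding fraction.

**Binding order.** Calls use detection order only, not signal magnitude:
factor A first iff A's first detection strictly precedes B's (or B is never
detected while A is); simultaneous iff equal; unclassified iff neither is
detected. The early series (10/30/60 min) is scored on the joint merged
universe of both factors' peaks so that the two presence matrices share
regions and time axis.

## Enhancer classification

Mark states are fold enrichments: mean coverage in site center ± 1 kb
divided by a genomic background, where the background is the median of mean
coverages over 5,000 random 1-kb windows (seeded; floored at 1e-6 for empty
tracks). A mark is "present" at fold ≥ 2. These window/threshold defaults
are package decisions — the quantification behind "decorated"/"depleted" in
the source study is not published — and are exposed in configuration.

The mark rule at baseline: *pre-existing* iff H3K4Me1 ∧ H3K27Ac ∧
¬H3K27Me3; *de novo* iff none of {H3K4Me1, H3K27Ac, P300}; everything else
is *ambiguous*. P300 is recorded but not required for the pre-existing call
(observed co-decoration is typical but not universal); a `require_p300`
flag tightens the rule. "Depleted for H3K27Me3" is operationalized as
not-marked (fold < threshold), not below-background.

Promoter state is called in TSS ± 1 kb: H3K4Me3 only → active; both →
bivalent; H3K27Me3 only or neither → inactive. Final classes require
concordance — pre-existing with an active promoter, de novo with an
inactive promoter; all other combinations are excluded rather than
force-assigned, mirroring the use of two clean sets. Promoter-state mixes
are reported on the mark classes (pre-refinement), matching the order in
which the two definitions are introduced. Distal selection keeps sites
with |TSS distance| > 2 kb (the source study's exclusion distance is
unstated; 2 kb is the package default).

## Signal profiles

Binned matrices hold per-bin mean per-base coverage in fixed windows around
anchors, multiplied by `1e7 / library total` so tracks of different depths
are comparable; any fixed linear scale preserves the class contrasts.
Chromosome-edge windows are kept in matrices (NaN-padded) but flagged and
dropped from average profiles. The center summary of an even-length profile
uses the left-of-center bin (recorded in metadata). MNase profiles count
protected-fragment midpoints per bp around anchors (midpoints give the
sharpest phasing; a coverage mode is available by flag) and are normalized
by median subtraction, so a flat profile sits at 0.

## Statistics

`compare_groups` implements the Wilcoxon rank-sum test (two-tailed) with an
exactly enumerated null for combined n ≤ 20 — all C(n, n_a) assignments of
the pooled mid-ranks, which handles ties exactly and returns p = 1 for
identical samples — and a tie-corrected normal approximation otherwise
(no continuity correction). The exact two-sided p is twice the smaller
one-sided tail, capped at 1, the standard convention. The one-tailed
Student's t (alternative: mean(a) > mean(b)) delegates to
`scipy.stats.ttest_ind`.

Regulation calls use floored folds, `(terminal + floor)/(baseline +
floor)` with floor 1.0 expression unit: this keeps all-zero genes
"unchanged" and tames ratios between background-level values. Gene–site
association measures |TSS − nearest stable-site center|; the windows
default to 0–1 Mb in 10-kb steps.

## Lineage atlas

Activity and occupancy are binary peak-overlap calls (≥ 1 bp against the
enhancer region ± 500 bp flank), because external per-cell-type datasets
arrive as peak calls; the flank absorbs summit-vs-center offsets. The
lineage tree is user-supplied configuration (`child: parent` lines); the
hematopoietic tree used throughout (LT-HSC root; MPP; CMP → GMP → Gn/MΦ and
CMP → MEP → Ery; CLP → B/T) ships as a preset.

## Synthetic scenario

The generator emulates the statistical structure of the study system at
desk scale; its defaults are the study conditions.

**Layout.** Each enhancer lives in a fixed 24-kb genomic "unit" together
with its designated gene: TSS at +2 kb, enhancer midpoint at a jittered
10.2–11.8 kb offset. The geometry guarantees that the designated gene is
the enhancer's nearest TSS, that every enhancer is distal (> 10 kb from any
TSS), and that every enhancer-linked gene lies within 100 kb of its site.
Genes without enhancers occupy per-chromosome "desert" segments separated
from the units by a 500-kb buffer, which makes the 100-kb association
fraction identifiable. A deterministic layout was chosen over rejection
sampling because it makes the nearest-gene designation provable; configs
whose counts exceed the layout capacity fail with a "genome too small"
error.

**Planted quantities** (defaults; all realized as exact counts, not
Bernoulli draws, so recovery tolerances are dominated by pipeline noise):
800 pre-existing + 600 de novo stable enhancers; transient C/EBPα regions
at 4× the stable count (echoing the ≈5:1 ratio of detected to stable
regions), present over a random sub-interval of the non-terminal
post-induction times; 40% of stable sites PU.1-bound at t = 0 (drawn from
the pre-existing class, i.e. 70% of pre-existing sites, consistent with
"about two-thirds" PU.1 co-occupancy); promoter-state mixes 73/7/20
(active/inactive/bivalent) for pre-existing and 36/44/20 for de novo; 74%
of de novo sites C/EBPα-first over the 10/30/60-min series, with the
remainder split evenly between simultaneous and PU.1-first; expression
folds 4× (pre-existing, baseline 200 units) and 9× (de novo, baseline 30
units) with log-normal noise (σ = 0.15) and a geometric ramp over the time
course; 70% of upregulated genes placed within 100 kb of a stable site (the
enhancer genes), the rest in the deserts with folds in 2.5–6×; per-cell-
type activity/occupancy fractions as configured (58% LT-HSC pre-existing
activity, 80% GMP occupancy, < 10% LSK occupancy, etc.). Selections that
define per-cell-type subsets are stratified over promoter states within
each class so the planted fraction holds on any promoter-defined subset.

**Signal model.** Mark tracks are Gaussian peaks (sd = width/4 = 250 bp,
mode 50× background) over a Poisson background of 0.02 per bp, realized as
Poisson counts per 1-kb run for compact run-length bedGraphs. These
background/height values are generator defaults stated in the config, not
claims about any particular dataset. De novo enhancers carry H3K27Me3 at
t = 0 decaying to zero by 24 hpi and gain active marks after C/EBPα
arrival; pre-existing enhancers carry active marks throughout with a mild
post-induction increase. MNase fragments (147 bp) have midpoints drawn
from Gaussians at ±150 bp (positioned nucleosomes flanking a depleted
valley) at pre-existing sites — sharper in the induced-macrophage condition
— and uniformly over ±1 kb (nucleosome-dense) at de novo sites in the
pre-B condition.

**What passing tests show.** Recovery of the planted fractions
demonstrates that the pipeline's operations are correct and internally
consistent at realistic effect sizes, not that the thresholds would
reproduce the published numbers on raw sequencing data: the synthetic
tracks have idealized peak shapes, no mappability/GC structure, no
replicate variability, and peak calls are inputs rather than re-called
from coverage.

## Problem sizes and determinism

The default scenario (4 × 10 Mb genome, 1,400 stable + 5,600 transient
sites, 3,000 genes) was sized so a full end-to-end run completes in well
under a minute on a single CPU while keeping per-class sample sizes large
enough that exact-count planting dominates sampling noise. Every random
choice flows from a single integer seed through `numpy.random.default_rng`;
regenerating with the same seed is byte-identical, and the pipeline report
omits filesystem paths so identical runs compare equal.

## Known limitations

- No BAM/bigWig input; plain-text BED/bedGraph only (adequate at synthetic
  scale, by design).
- No peak calling from coverage and no differential-binding statistics;
  peak calls are inputs.
- Nearest-gene linkage only; no chromatin-loop-aware enhancer-gene
  assignment.
- The rank-sum normal approximation omits the continuity correction;
  exact enumeration covers the small-sample regime where it matters most.
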