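# enhancerdyn

Integrative analysis of transcription-factor ChIP-seq time courses and
expression data for enhancer-centric studies of induced cell-fate
conversion, modeled on C/EBPα-driven transdifferentiation of pre-B cells
into macrophages.

During such a conversion, the induced factor binds thousands of distal
regulatory regions that fall into two classes with very different chromatin
logic:

- **pre-existing enhancers** — already decorated with active marks
  (H3K4Me1, H3K27Ac, P300, typically PU.1-bound) in the starting cell and
  hyper-activated upon C/EBPα binding;
- **de novo enhancers** — lacking all active marks (often H3K27Me3-
  decorated, nucleosome-dense) and activated only after pioneer binding by
  C/EBPα, which precedes PU.1 recruitment at most of these sites.

`enhancerdyn` implements the full analysis chain as a reusable library +
CLI:

1. **Interval core** — BED/bedGraph readers and writers, interval merge /
   intersect / nearest-TSS on 0-based half-open coordinates.
2. **Binding dynamics** — per-time-point peak calls are merged into
   non-redundant regions; a region is *stable* if, once first detected, it
   stays present at every sampled post-induction time through the terminal
   time point, and *transient* otherwise; binding order of two factors is
   called from first detections over an early minute-scale series
   (factor-A-first / simultaneous / factor-B-first).
3. **Enhancer classes** — distal stable sites (|TSS distance| > 2 kb) are
   classified from baseline marks: *pre-existing* iff
   H3K4Me1 ∧ H3K27Ac ∧ ¬H3K27Me3; *de novo* iff no active mark; classes are
   refined by the nearest promoter's state (H3K4Me3-only = active, both
   marks = bivalent, H3K27Me3/none = inactive): final pre-existing pairs
   with active promoters, final de novo with inactive ones.
4. **Signal profiles** — binned coverage matrices around site centers
   (e.g. window 6 kb, bin 100 bp, scaled per 10 M units), peak-bin and
   center-bin kinetic summaries, and median-subtracted MNase
   fragment-midpoint profiles that expose nucleosome-depleted valleys.
5. **Gene linkage** — >2-fold regulation calls (with an expression floor),
   the sliding-window fraction of regulated genes within a distance of a
   site, per-class median expression kinetics, per-cell-type mean
   normalization, and Wilcoxon rank-sum (exact for combined n ≤ 20) /
   one-tailed t statistics.
6. **Lineage atlas** — activity (H3K27Ac/H3K4Me1 overlap) and C/EBPα
   occupancy of both classes across a user-supplied hematopoietic lineage
   tree, with root-to-leaf trajectory reports.
7. **Synthetic cohort** — a deterministic generator that plants enhancer
   classes, binding order, promoter states, expression folds, lineage
   activity and nucleosome structure as exact counts, together with a truth
   table, so the whole pipeline is testable without any external data.

## Worked example

Run the bundled default scenario (4 × 10 Mb genome, 800 pre-existing + 600
de novo enhancers, 3,000 genes, seed 1) end to end:

```bash
enhancerdyn pipeline --demo --seed 1 --out demo_run
```

This prints (abridged):

```json
{
 "n_stable": 1400,
 "prebound_pu1_pct": 40.0,
 "classes": {
  "mark": {"pre_existing": 800, "de_novo": 600, "ambiguous": 0},
  "final": {"pre_existing": 584, "de_novo": 264, "excluded": 552},
  "promoter_mix_pre_existing_pct": {"active": 73.0, "inactive": 7.0, "bivalent": 20.0},
  "promoter_mix_de_novo_pct": {"active": 36.0, "inactive": 44.0, "bivalent": 20.0}
 },
 "linkage": {
  "n_up": 1988,
  "upregulated_within_100kb_pct": 70.32,
  "terminal_fold_median": {"pre_existing": 3.90, "de_novo": 8.76}
 }
}
```

Reading: of 7,000 non-redundant C/EBPα regions, 1,400 are stably bound and
40% of those were already PU.1-bound at t = 0.  All 800/600 planted mark
classes are recovered; 73% of pre-existing enhancers pair with active
promoters versus 36% of de novo enhancers (44% inactive).  70% of >2-fold
upregulated genes lie within 100 kb of a stable site, and genes nearest
final-class pre-existing / de novo enhancers are upregulated ~4-fold and
~9-fold by the terminal time point.  `demo_run/` additionally contains the
stability table, per-enhancer classification TSV, lineage activity and
occupancy tables, MNase profiles, and `report.json` with all quantities.

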