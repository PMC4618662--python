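"""Pre-existing vs de novo enhancer classification.

Distal TF-bound regions are classified from baseline (t=0) chromatin marks:
pre-existing enhancers carry H3K4Me1 and H3K27Ac (typically with P300) and
lack H3K27Me3; de novo enhancers lack all active enhancer marks and are
often H3K27Me3-decorated.  Classes are then refined by the state of the
nearest promoter: pre-existing enhancers pair with active promoters
(H3K4Me3 only), de novo enhancers with inactive promoters (H3K27Me3 or no
marks); bivalent promoters carry both marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    CoverageTrack,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    ValidationError,
    intersect,
    nearest_tss,
)

BACKGROUND_FLOOR = 1e-6

ACTIVE_MARKS = ("H3K4Me1", "H3K27Ac", "P300")
REPRESSIVE_MARK = "H3K27Me3"


@dataclass(frozen=True)
class MarkState:
    mark: str
    fold_enrichment: float
    marked: bool

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise ValidationError("fold_enrichment must be >= 0")


@dataclass
class EnhancerRecord:
    """One distal TF-bound region with its mark/promoter classification."""

    region: GenomicInterval
    mark_states: dict[str, MarkState] = field(default_factory=dict)
    mark_class: str = "ambiguous"  # pre_existing | de_novo | ambiguous
    promoter_state: str = "inactive"  # active | bivalent | inactive
    final_class: str = "excluded"  # pre_existing | de_novo | excluded
    nearest_gene: str | None = None
    tss_distance: int | None = None


def select_distal(
    sites: PeakSet, genes: GeneAnnotation, min_tss_distance: int = 2000
) -> PeakSet:
    """Keep sites whose midpoint lies more than ``min_tss_distance`` bp from
    the nearest TSS (putative enhancers; promoter-proximal sites removed).
    """
    kept = []
    for iv, (_, dist) in zip(sites.intervals, nearest_tss(sites, genes)):
        if dist is not None and abs(dist) > min_tss_distance:
            kept.append(iv)
    return PeakSet(kept, sites.source_label)


def estimate_background(
    track: CoverageTrack, n_windows: int = 5000, window: int = 1000, seed: int = 0
) -> float:
    """Genomic background: median of mean coverages over random windows.

    Deterministic given ``seed``; returns a small floor (1e-6) when the
    median is 0 so that fold enrichments stay defined.
    """
    rng = np.random.default_rng(seed)
    chroms = track.genome.chrom_names
    lengths = np.array(track.genome.chrom_lengths, dtype=np.float64)
    probs = lengths / lengths.sum()
    picks = rng.choice(len(chroms), size=n_windows, p=probs)
    means = np.empty(n_windows)
    for i, ci in enumerate(picks):
        n = int(lengths[ci])
        w = min(window, n)
        start = int(rng.integers(0, n - w + 1))
        means[i] = track.window_mean(chroms[ci], start, start + w)
    med = float(np.median(means))
    return med if med > 0 else BACKGROUND_FLOOR


def call_mark_state(
    center: int,
    chrom: str,
    track: CoverageTrack,
    mark: str,
    background: float,
    half_window: int = 1000,
    threshold: float = 2.0,
) -> MarkState:
    """Fold enrichment of the mark in a window around ``center`` vs background.

    fold = mean coverage over [center - half_window, center + half_window)
    divided by ``background``; marked iff fold >= threshold.  Windows running
    off the chromosome are truncated.
    """
    if background <= 0:
        raise ValidationError("background must be > 0")
    mean = track.window_mean(chrom, center - half_window, center + half_window)
    fold = mean / background
    return MarkState(mark, fold, fold >= threshold)


def classify_by_marks(
    states: Mapping[str, MarkState], require_p300: bool = False
) -> str:
    """Mark-based enhancer class from baseline mark states.

    pre_existing: H3K4Me1 AND H3K27Ac marked (AND P300 if ``require_p300``)
    AND H3K27Me3 not marked.  de_novo: none of the active marks
    (H3K4Me1, H3K27Ac, P300) marked.  Anything else: ambiguous.
    """
    k4me1 = states["H3K4Me1"].marked
    k27ac = states["H3K27Ac"].marked
    p300 = states["P300"].marked
    k27me3 = states[REPRESSIVE_MARK].marked
    pre = k4me1 and k27ac and not k27me3 and (p300 or not require_p300)
    if pre:
        return "pre_existing"
    if not (k4me1 or k27ac or p300):
        return "de_novo"
    return "ambiguous"


def classify_promoter(
    tss: int,
    chrom: str,
    k4me3: CoverageTrack,
    k27me3: CoverageTrack,
    background_k4me3: float,
    background_k27me3: float,
    promoter_half_window: int = 1000,
    threshold: float = 2.0,
) -> str:
    """Promoter state from H3K4Me3/H3K27Me3 in TSS +/- promoter_half_window.

    H3K4Me3 only -> active; both marks -> bivalent; H3K27Me3 only or no
    marks -> inactive.
    """
    m4 = call_mark_state(
        tss, chrom, k4me3, "H3K4Me3", background_k4me3, promoter_half_window, threshold
    ).marked
    m27 = call_mark_state(
        tss, chrom, k27me3, "H3K27Me3", background_k27me3, promoter_half_window, threshold
    ).marked
    if m4 and m27:
        return "bivalent"
    if m4:
        return "active"
    return "inactive"


def finalize_classes(records: Sequence[EnhancerRecord]) -> list[EnhancerRecord]:
    """Refine mark classes by nearest-promoter state.

    final pre_existing = mark pre_existing AND active promoter;
    final de_novo = mark de_novo AND inactive promoter;
    every other combination is excluded.
    """
    for rec in records:
        if rec.mark_class == "pre_existing" and rec.promoter_state == "active":
            rec.final_class = "pre_existing"
        elif rec.mark_class == "de_novo" and rec.promoter_state == "inactive":
            rec.final_class = "de_novo"
        else:
            rec.final_class = "excluded"
    return list(records)


def overlap_with_factor(
    records: Sequence[EnhancerRecord],
    factor_peaks: PeakSet,
    flank: int = 0,
    classes: tuple[str, ...] = ("pre_existing", "de_novo"),
    by: str = "final_class",
) -> dict[str, float]:
    """Per-class fraction of enhancer regions overlapping a factor peak set.

    Regions are extended by ``flank`` bp on both sides; overlap >= 1 bp.
    Classes with no members get NaN.
    """
    out: dict[str, float] = {}
    for cls in classes:
        members = [r for r in records if getattr(r, by) == cls]
        if not members:
            out[cls] = float("nan")
            continue
        regions = PeakSet(
            [
                GenomicInterval(
                    r.region.chrom, max(0, r.region.start - flank), r.region.end + flank
                )
                for r in members
            ]
        )
        hit = {i for i, _ in intersect(regions, factor_peaks, 1)}
        out[cls] = len(hit) / len(members)
    return out


def build_enhancer_records(
    sites: PeakSet,
    genes: GeneAnnotation,
    mark_tracks: Mapping[str, CoverageTrack],
    promoter_tracks: Mapping[str, CoverageTrack],
    min_tss_distance: int = 2000,
    half_window: int = 1000,
    promoter_half_window: int = 1000,
    threshold: float = 2.0,
    require_p300: bool = False,
    background_seed: int = 0,
) -> list[EnhancerRecord]:
    """End-to-end classification of a distal site set.

    ``mark_tracks`` must provide baseline H3K4Me1, H3K27Ac, P300 and
    H3K27Me3; ``promoter_tracks`` H3K4Me3 and H3K27Me3.  Backgrounds are
    estimated per track by random-window medians.
    """
    distal = select_distal(sites, genes, min_tss_distance)
    assignments = nearest_tss(distal, genes)
    tss_lookup = {gid: GeneAnnotation.tss_of(iv) for gid, iv in genes.genes}

    backgrounds = {
        m: estimate_background(t, seed=background_seed) for m, t in mark_tracks.items()
    }
    prom_bg = {
        m: estimate_background(t, seed=background_seed)
        for m, t in promoter_tracks.items()
    }

    records: list[EnhancerRecord] = []
    for iv, (gene, dist) in zip(distal.intervals, assignments):
        states = {
            m: call_mark_state(
                iv.midpoint, iv.chrom, track, m, backgrounds[m], half_window, threshold
            )
            for m, track in mark_tracks.items()
        }
        rec = EnhancerRecord(
            region=iv,
            mark_states=states,
            mark_class=classify_by_marks(states, require_p300),
            nearest_gene=gene,
            tss_distance=dist,
        )
        if gene is not None:
            rec.promoter_state = classify_promoter(
                tss_lookup[gene],
                iv.chrom,
                promoter_tracks["H3K4Me3"],
                promoter_tracks["H3K27Me3"],
                prom_bg["H3K4Me3"],
                prom_bg["H3K27Me3"],
                promoter_half_window,
                threshold,
            )
        records.append(rec)
    return finalize_classes(records)
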