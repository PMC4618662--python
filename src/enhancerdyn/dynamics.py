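"""Time-course peak integration, stability calls, and TF binding order.

Per-time-point peak calls for one factor are integrated over a merged,
non-redundant region universe; each region gets a boolean presence row over
the time axis.  Stability ("bound up to the terminal time point") and
pairwise binding order between two factors are derived from those rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

from .genome import PeakSet, ValidationError, intersect, merge_intervals


@dataclass
class TimeCoursePresence:
    """Region x time boolean presence matrix for one factor."""

    regions: PeakSet
    time_points: list
    presence: np.ndarray  # bool, shape (n_regions, n_times)
    factor: str = ""

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.regions), len(self.time_points)):
            raise ValidationError(
                "presence matrix shape does not match regions x time_points"
            )


@dataclass(frozen=True)
class BindingOrderCall:
    region_id: int
    order: str  # a_first | simultaneous | b_first | unclassified
    first_detection_a: Hashable | None
    first_detection_b: Hashable | None


def build_presence(
    peaksets: Mapping[Hashable, PeakSet],
    min_overlap: int = 1,
    regions: PeakSet | None = None,
    factor: str = "",
) -> TimeCoursePresence:
    """Merge peaks across time points and mark per-region presence.

    ``regions`` may be supplied to score presence on an external universe
    (e.g. the joint universe of two factors, as binding-order calls require);
    by default the universe is the merged union of the given peak sets.
    """
    if not peaksets:
        raise ValidationError("at least one time point required")
    times = list(peaksets.keys())
    if regions is None:
        pooled = PeakSet(
            [iv for t in times for iv in peaksets[t].intervals], source_label=factor
        )
        regions = merge_intervals(pooled)
    presence = np.zeros((len(regions), len(times)), dtype=bool)
    for j, t in enumerate(times):
        for i, _ in intersect(regions, peaksets[t], min_overlap):
            presence[i, j] = True
    return TimeCoursePresence(regions, times, presence, factor=factor)


def first_detection(p: TimeCoursePresence, region_id: int) -> Hashable | None:
    """Earliest time point at which the region is present, or None."""
    row = p.presence[region_id]
    idx = np.flatnonzero(row)
    return p.time_points[int(idx[0])] if idx.size else None


def classify_stability(
    p: TimeCoursePresence,
    terminal_time: Hashable,
    baseline_times: Sequence[Hashable] = (),
    mode: str = "gapfree",
) -> list[str]:
    """Per-region "stable"/"transient" call over post-induction time points.

    ``baseline_times`` (typically the uninduced t=0 sample, where baseline
    leaky binding occurs) are excluded from the stability assessment.

    mode="gapfree" (default): stable iff present at the terminal time AND at
    every sampled post-induction time from its first detection through the
    terminal time.  mode="terminal": stable iff present at the terminal time.
    """
    if terminal_time not in p.time_points:
        raise ValidationError(f"terminal_time {terminal_time!r} not in time axis")
    if mode not in ("gapfree", "terminal"):
        raise ValidationError(f"unknown stability mode {mode!r}")
    keep = [j for j, t in enumerate(p.time_points) if t not in set(baseline_times)]
    times = [p.time_points[j] for j in keep]
    sub = p.presence[:, keep]
    t_idx = times.index(terminal_time)
    labels: list[str] = []
    for row in sub:
        if not row[t_idx]:
            labels.append("transient")
            continue
        if mode == "terminal":
            labels.append("stable")
            continue
        detected = np.flatnonzero(row[: t_idx + 1])
        if detected.size == 0:
            labels.append("transient")  # only seen after terminal (exotic axis)
            continue
        first = int(detected[0])
        labels.append("stable" if row[first : t_idx + 1].all() else "transient")
    return labels


def classify_binding_order(
    pa: TimeCoursePresence, pb: TimeCoursePresence, region_id: int
) -> BindingOrderCall:
    """Order of first detection of factors a and b at one region.

    a_first iff a is detected strictly before b (or b never while a is);
    symmetric for b_first; simultaneous iff equal first detections;
    unclassified iff neither factor is ever detected.
    """
    if pa.time_points != pb.time_points:
        raise ValidationError("presence matrices must share the time axis")
    if len(pa.regions) != len(pb.regions):
        raise ValidationError("presence matrices must share the region universe")
    fa = first_detection(pa, region_id)
    fb = first_detection(pb, region_id)
    order_index = {t: i for i, t in enumerate(pa.time_points)}
    if fa is None and fb is None:
        order = "unclassified"
    elif fb is None:
        order = "a_first"
    elif fa is None:
        order = "b_first"
    elif order_index[fa] < order_index[fb]:
        order = "a_first"
    elif order_index[fa] > order_index[fb]:
        order = "b_first"
    else:
        order = "simultaneous"
    return BindingOrderCall(region_id, order, fa, fb)


def binding_order_table(
    pa: TimeCoursePresence, pb: TimeCoursePresence
) -> list[BindingOrderCall]:
    return [classify_binding_order(pa, pb, i) for i in range(len(pa.regions))]


def prebound_fraction(
    sites: PeakSet, baseline_peaks: PeakSet, min_overlap: int = 1
) -> float:
    """Fraction of ``sites`` overlapping the baseline peak set."""
    if len(sites) == 0:
        raise ValidationError("prebound fraction undefined for empty site set")
    hit = {i for i, _ in intersect(sites, baseline_peaks, min_overlap)}
    return len(hit) / len(sites)
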