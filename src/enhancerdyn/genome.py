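"""Genome model, interval algebra, and plain-text readers/writers.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; 1-based conversions, if ever needed, happen only at report
boundaries.  A site's "position" for distance and profile anchoring is the
integer midpoint ``floor((start + end) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed line in a BED/bedGraph file (message names the line number)."""


class ValidationError(ValueError):
    """Interval or track content violating an invariant."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be > 0")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with optional BED name/score/strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """A list of intervals from one source (factor, time point, or cell type)."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.intervals, key=GenomicInterval.sort_key), self.source_label
        )

    def by_chrom(self) -> dict[str, list[tuple[int, GenomicInterval]]]:
        """Intervals grouped by chromosome, keeping original indices."""
        out: dict[str, list[tuple[int, GenomicInterval]]] = {}
        for i, iv in enumerate(self.intervals):
            out.setdefault(iv.chrom, []).append((i, iv))
        return out


class CoverageTrack:
    """Per-base non-negative signal over a genome (dense float32 per chrom).

    ``library_scale`` is the total signal of the track, used when scaling
    matrices to per-10-million units.
    """

    def __init__(self, genome: GenomeModel, values: dict[str, np.ndarray] | None = None):
        self.genome = genome
        self.values: dict[str, np.ndarray] = {}
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            if values is not None and name in values:
                arr = np.asarray(values[name], dtype=np.float32)
                if arr.shape != (length,):
                    raise ValidationError(
                        f"values for {name} have shape {arr.shape}, expected ({length},)"
                    )
                if np.any(arr < 0):
                    raise ValidationError("coverage values must be >= 0")
                self.values[name] = arr
            else:
                self.values[name] = np.zeros(length, dtype=np.float32)
        self._prefix: dict[str, np.ndarray] | None = None

    @property
    def library_scale(self) -> float:
        return float(sum(float(v.sum()) for v in self.values.values()))

    def prefix_sums(self) -> dict[str, np.ndarray]:
        """Cached prefix sums (float64, length n+1) for O(1) window means."""
        if self._prefix is None:
            self._prefix = {
                c: np.concatenate(([0.0], np.cumsum(v, dtype=np.float64)))
                for c, v in self.values.items()
            }
        return self._prefix

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base coverage over [start, end), clipped to the chromosome."""
        n = self.genome.length_of(chrom)
        s, e = max(0, start), min(n, end)
        if e <= s:
            return 0.0
        p = self.prefix_sums()[chrom]
        return float((p[e] - p[s]) / (e - s))


@dataclass
class GeneAnnotation:
    """Stranded genes with derived TSS positions.

    TSS is ``start`` for + strand and ``end - 1`` for - strand.
    """

    genes: list[tuple[str, GenomicInterval]]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("gene ids are not unique")
        self._tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    @staticmethod
    def tss_of(iv: GenomicInterval) -> int:
        return iv.start if iv.strand != "-" else iv.end - 1

    def tss_table(self) -> dict[str, tuple[np.ndarray, list[str]]]:
        """Per-chromosome sorted TSS positions with parallel gene-id lists."""
        if self._tss_by_chrom is None:
            tmp: dict[str, list[tuple[int, str]]] = {}
            for gid, iv in self.genes:
                tmp.setdefault(iv.chrom, []).append((self.tss_of(iv), gid))
            self._tss_by_chrom = {}
            for chrom, pairs in tmp.items():
                pairs.sort()
                self._tss_by_chrom[chrom] = (
                    np.array([p for p, _ in pairs], dtype=np.int64),
                    [g for _, g in pairs],
                )
        return self._tss_by_chrom


# ---------------------------------------------------------------------------
# Readers / writers


def _is_comment(line: str) -> bool:
    return line.startswith("#") or line.startswith("track") or line.startswith("browser")


def read_bed(path: str | Path, source_label: str | None = None) -> PeakSet:
    """Read a BED3-BED6 file into a PeakSet.

    Missing name/score/strand columns default to ".", 0, ".".
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_comment(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, score, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(intervals, source_label or path.stem)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as sorted BED6."""
    with open(path, "w") as fh:
        for iv in sorted(peaks.intervals, key=GenomicInterval.sort_key):
            # fixed 6-decimal score, trimmed: round-trips within 1e-6
            score = f"{iv.score:.6f}".rstrip("0").rstrip(".") or "0"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def read_bedgraph(path: str | Path, genome: GenomeModel) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense CoverageTrack.

    Overlapping records are summed (records are treated as additive fragment
    piles); uncovered bases are 0.
    """
    track = CoverageTrack(genome)
    lengths = genome.lengths
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_comment(line):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom = fields[0]
            if chrom not in lengths:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: malformed record") from None
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative coverage value")
            if not 0 <= start < end <= lengths[chrom]:
                raise ValidationError(f"{path}:{lineno}: interval outside genome bounds")
            track.values[chrom][start:end] += value
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a CoverageTrack as run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            v = track.values[chrom]
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                val = float(v[s])
                if val != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{val:.6g}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(peaks: PeakSet, min_gap: int = 0) -> PeakSet:
    """Merge intervals closer than ``min_gap`` bp into non-redundant regions.

    With ``min_gap=0`` this is the plain union: overlapping or book-ended
    intervals coalesce, and the covered base set is preserved.
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(peaks.intervals, key=GenomicInterval.sort_key):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start <= merged[-1].end + min_gap
        ):
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = replace(prev, end=iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return PeakSet(merged, peaks.source_label)


def intersect(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> list[tuple[int, int]]:
    """All (index in a, index in b) pairs overlapping by >= min_overlap bp.

    Sorted sweep per chromosome; output ordered by (a index, b index).
    """
    if min_overlap < 1:
        raise ValidationError("min_overlap must be >= 1")
    pairs: list[tuple[int, int]] = []
    b_by_chrom = b.by_chrom()
    for chrom, a_items in a.by_chrom().items():
        b_items = b_by_chrom.get(chrom)
        if not b_items:
            continue
        b_sorted = sorted(b_items, key=lambda t: t[1].start)
        b_starts = np.array([iv.start for _, iv in b_sorted], dtype=np.int64)
        b_ends = np.array([iv.end for _, iv in b_sorted], dtype=np.int64)
        b_idx = np.array([j for j, _ in b_sorted], dtype=np.int64)
        max_end = np.maximum.accumulate(b_ends)
        for i, iv in a_items:
            # candidates: b.start < iv.end and running max end > iv.start
            hi = int(np.searchsorted(b_starts, iv.end - min_overlap, side="right"))
            for k in range(hi):
                if max_end[k] <= iv.start:
                    continue
                ov = min(iv.end, b_ends[k]) - max(iv.start, b_starts[k])
                if ov >= min_overlap:
                    pairs.append((i, int(b_idx[k])))
    pairs.sort()
    return pairs


def overlaps_any(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> np.ndarray:
    """Boolean per interval of ``a``: overlaps some interval of ``b``."""
    hit = np.zeros(len(a), dtype=bool)
    for i, _ in intersect(a, b, min_overlap):
        hit[i] = True
    return hit


def nearest_tss(
    sites: PeakSet, genes: GeneAnnotation
) -> list[tuple[str | None, int | None]]:
    """Per site: (nearest gene_id, signed distance = site midpoint - TSS).

    Distance is signed relative to genome orientation (positive when the
    site center lies right of the TSS), independent of gene strand.
    Equidistant genes are broken toward the lexicographically smaller
    gene_id.  Sites on chromosomes without genes get ``(None, None)``.
    """
    table = genes.tss_table()
    out: list[tuple[str | None, int | None]] = []
    for iv in sites.intervals:
        entry = table.get(iv.chrom)
        if entry is None:
            out.append((None, None))
            continue
        positions, ids = entry
        center = iv.midpoint
        j = int(np.searchsorted(positions, center))
        best: tuple[int, str, int] | None = None  # (|d|, gene_id, signed d)
        for k in (j - 1, j):
            if 0 <= k < len(positions):
                d = center - int(positions[k])
                cand = (abs(d), ids[k], d)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        # equidistant genes at the same TSS position need the full scan of ties
        assert best is not None
        lo = int(np.searchsorted(positions, center - best[0], side="left"))
        hi = int(np.searchsorted(positions, center + best[0], side="right"))
        for k in range(lo, hi):
            d = center - int(positions[k])
            cand = (abs(d), ids[k], d)
            if cand[:2] < best[:2]:
                best = cand
        out.append((best[1], best[2]))
    return out


def read_genes(path: str | Path) -> GeneAnnotation:
    """Read a gene table: BED6 whose name column is the gene_id."""
    peaks = read_bed(path)
    return GeneAnnotation([(iv.name, iv) for iv in peaks.intervals])


def write_genes(genes: GeneAnnotation, path: str | Path) -> None:
    write_bed(PeakSet([iv for _, iv in genes.genes]), path)
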