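"""Interval algebra and plain-text format round-trips, checked against
brute-force per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhancerdyn.genome import (
    BedParseError,
    GenomeModel,
    GenomicInterval,
    PeakSet,
    ValidationError,
    intersect,
    merge_intervals,
    nearest_tss,
    read_bed,
    read_bedgraph,
    write_bed,
    write_bedgraph,
    GeneAnnotation,
    CoverageTrack,
)
from conftest import random_peakset


class TestBedIO:
    def test_minimal_bed3(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        ps = read_bed(p)
        assert len(ps) == 1
        iv = ps[0]
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 100, 200, ".")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_comment_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("# comment\ntrack name=x\nchr1\t0\t10\n")
        assert len(read_bed(p)) == 1

    def test_bed6_strand_round_trip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t50\tpeak1\t3.5\t-\n")
        ps = read_bed(p)
        assert ps[0].strand == "-" and ps[0].name == "peak1" and ps[0].score == 3.5
        out = tmp_path / "b.bed"
        write_bed(ps, out)
        again = read_bed(out)
        assert again.intervals == ps.intervals

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\nchr1\tnope\t20\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_start_ge_end_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t20\t20\n")
        with pytest.raises(ValidationError):
            read_bed(p)

    def test_write_sorts_and_is_deterministic(self, tmp_path, tiny_genome):
        rng = np.random.default_rng(0)
        ps = random_peakset(rng, 1000, tiny_genome)
        p1, p2 = tmp_path / "x1.bed", tmp_path / "x2.bed"
        write_bed(ps, p1)
        write_bed(ps, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_bed(p1)
        keys = [(iv.chrom, iv.start, iv.end) for iv in back]
        assert keys == sorted(keys)
        assert sorted(i.sort_key() for i in back) == sorted(i.sort_key() for i in ps)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        specs=st.lists(
            st.tuples(
                st.integers(0, 900), st.integers(1, 100),
                st.sampled_from("+-."), st.floats(0, 10),
            ),
            min_size=1, max_size=20,
        )
    )
    def test_round_trip_lossless(self, specs, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        ps = PeakSet(
            [
                GenomicInterval("chr1", s, s + l, f"p{i}", sc, strand)
                for i, (s, l, strand, sc) in enumerate(specs)
            ]
        )
        path = tmp / "rt.bed"
        write_bed(ps, path)
        back = read_bed(path)
        orig = sorted(ps.intervals, key=GenomicInterval.sort_key)
        got = sorted(back.intervals, key=GenomicInterval.sort_key)
        for a, b in zip(orig, got):
            assert (a.chrom, a.start, a.end, a.name, a.strand) == (
                b.chrom, b.start, b.end, b.name, b.strand)
            assert abs(a.score - b.score) < 1e-6


class TestBedGraph:
    def test_hand_summed_mean(self, tmp_path):
        genome = GenomeModel(("chr1",), (100,))
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t10\t2.0\n")
        track = read_bedgraph(p, genome)
        assert track.window_mean("chr1", 0, 100) == pytest.approx(0.2)

    def test_empty_file_all_zero(self, tmp_path, tiny_genome):
        p = tmp_path / "a.bg"
        p.write_text("")
        track = read_bedgraph(p, tiny_genome)
        assert all(v.sum() == 0 for v in track.values.values())

    def test_overlapping_records_sum(self, tmp_path):
        genome = GenomeModel(("chr1",), (100,))
        p = tmp_path / "a.bg"
        p.write_text("chr1\t10\t30\t1\nchr1\t10\t30\t2\n")
        track = read_bedgraph(p, genome)
        assert track.values["chr1"][15] == pytest.approx(3.0)

    def test_negative_value_rejected(self, tmp_path, tiny_genome):
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t10\t-1\n")
        with pytest.raises(ValidationError):
            read_bedgraph(p, tiny_genome)

    def test_unknown_chromosome_rejected(self, tmp_path, tiny_genome):
        p = tmp_path / "a.bg"
        p.write_text("chrX\t0\t10\t1\n")
        with pytest.raises(ValidationError):
            read_bedgraph(p, tiny_genome)

    def test_write_read_round_trip(self, tmp_path):
        genome = GenomeModel(("chr1",), (50,))
        values = np.zeros(50, dtype=np.float32)
        values[5:15] = 2.25
        values[15:20] = 0.5
        track = CoverageTrack(genome, {"chr1": values})
        p = tmp_path / "a.bg"
        write_bedgraph(track, p)
        back = read_bedgraph(p, genome)
        np.testing.assert_allclose(back.values["chr1"], values, atol=1e-6)


class TestMerge:
    def test_overlap_union(self):
        ps = PeakSet([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 250)])
        merged = merge_intervals(ps)
        assert [(i.start, i.end) for i in merged] == [(100, 250)]

    def test_disjoint_unchanged(self):
        ps = PeakSet([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)])
        assert [(i.start, i.end) for i in merge_intervals(ps)] == [(100, 200), (300, 400)]

    def test_min_gap_bridges_nearby(self):
        ps = PeakSet([GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 15, 20)])
        assert len(merge_intervals(ps, min_gap=5)) == 1
        assert len(merge_intervals(ps, min_gap=4)) == 2

    def test_against_per_base_oracle(self, tiny_genome):
        rng = np.random.default_rng(1)
        ps = random_peakset(rng, 500, tiny_genome)
        merged = merge_intervals(ps)
        # oracle: mark covered bases, read off maximal runs
        for chrom, length in zip(tiny_genome.chrom_names, tiny_genome.chrom_lengths):
            covered = np.zeros(length, dtype=bool)
            for iv in ps:
                if iv.chrom == chrom:
                    covered[iv.start:iv.end] = True
            runs = []
            in_run = False
            for pos in range(length):
                if covered[pos] and not in_run:
                    start, in_run = pos, True
                if not covered[pos] and in_run:
                    runs.append((start, pos))
                    in_run = False
            if in_run:
                runs.append((start, length))
            got = [(i.start, i.end) for i in merged if i.chrom == chrom]
            assert got == runs

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)), max_size=30))
    def test_idempotent(self, specs):
        ps = PeakSet([GenomicInterval("chr1", s, s + l) for s, l in specs])
        once = merge_intervals(ps)
        twice = merge_intervals(once)
        assert [i.sort_key() for i in once] == [i.sort_key() for i in twice]


class TestIntersect:
    def test_one_bp_overlap(self):
        a = PeakSet([GenomicInterval("chr1", 0, 100)])
        b = PeakSet([GenomicInterval("chr1", 99, 200)])
        assert intersect(a, b, 1) == [(0, 0)]

    def test_half_open_adjacency(self):
        a = PeakSet([GenomicInterval("chr1", 0, 100)])
        b = PeakSet([GenomicInterval("chr1", 100, 200)])
        assert intersect(a, b, 1) == []

    def test_min_overlap_threshold(self):
        a = PeakSet([GenomicInterval("chr1", 0, 100)])
        b = PeakSet([GenomicInterval("chr1", 95, 200)])
        assert intersect(a, b, 5) == [(0, 0)]
        assert intersect(a, b, 6) == []

    def test_against_quadratic_oracle_and_symmetry(self, tiny_genome):
        rng = np.random.default_rng(2)
        a = random_peakset(rng, 200, tiny_genome)
        b = random_peakset(rng, 300, tiny_genome)
        for mo in (1, 25):
            got = set(intersect(a, b, mo))
            expected = set()
            for i, ia in enumerate(a):
                for j, ib in enumerate(b):
                    if ia.chrom != ib.chrom:
                        continue
                    ov = min(ia.end, ib.end) - max(ia.start, ib.start)
                    if ov >= mo:
                        expected.add((i, j))
            assert got == expected
            assert len(got) == len(intersect(b, a, mo))


class TestNearestTss:
    def _genes(self):
        return GeneAnnotation(
            [
                ("geneA", GenomicInterval("chr1", 1000, 3000, "geneA", 0, "+")),
                ("geneB", GenomicInterval("chr1", 7000, 9000, "geneB", 0, "-")),
            ]
        )

    def test_site_center_at_tss(self):
        sites = PeakSet([GenomicInterval("chr1", 900, 1100)])
        [(gid, d)] = nearest_tss(sites, self._genes())
        assert gid == "geneA" and d == 0

    def test_signed_distance(self):
        sites = PeakSet([GenomicInterval("chr1", 5900, 6100)])  # center 6000
        [(gid, d)] = nearest_tss(sites, self._genes())
        # geneB TSS is end-1 = 8999 (minus strand): distance 6000-8999=-2999
        # geneA TSS = 1000: 5000 away; geneB closer
        assert gid == "geneB" and d == -2999

    def test_tie_broken_lexicographically(self):
        genes = GeneAnnotation(
            [
                ("gB", GenomicInterval("chr1", 2000, 2100, "gB", 0, "+")),
                ("gA", GenomicInterval("chr1", 1000, 1100, "gA", 0, "+")),
            ]
        )
        sites = PeakSet([GenomicInterval("chr1", 1400, 1600)])  # center 1500, ties
        [(gid, d)] = nearest_tss(sites, genes)
        assert gid == "gA" and d == 500

    def test_gene_free_chromosome_unassigned(self):
        sites = PeakSet([GenomicInterval("chr2", 0, 100)])
        [(gid, d)] = nearest_tss(sites, self._genes())
        assert gid is None and d is None

    def test_against_brute_force(self, tiny_genome):
        rng = np.random.default_rng(3)
        sites = random_peakset(rng, 200, tiny_genome)
        genes = []
        for k in range(50):
            ci = int(rng.integers(2))
            chrom = tiny_genome.chrom_names[ci]
            pos = int(rng.integers(100, tiny_genome.chrom_lengths[ci] - 100))
            strand = "+" if rng.random() < 0.5 else "-"
            s, e = (pos, pos + 50) if strand == "+" else (pos - 49, pos + 1)
            genes.append((f"g{k:02d}", GenomicInterval(chrom, s, e, f"g{k:02d}", 0, strand)))
        ann = GeneAnnotation(genes)
        got = nearest_tss(sites, ann)
        for iv, (gid, d) in zip(sites, got):
            center = iv.midpoint
            best = None
            for g, giv in genes:
                if giv.chrom != iv.chrom:
                    continue
                dd = center - GeneAnnotation.tss_of(giv)
                key = (abs(dd), g)
                if best is None or key < best[0]:
                    best = (key, g, dd)
            assert best is not None
            assert (gid, d) == (best[1], best[2])
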