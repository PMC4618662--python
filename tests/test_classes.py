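"""Mark-based and promoter-refined enhancer classification."""

from itertools import product

import numpy as np
import pytest

from enhancerdyn.classes import (
    EnhancerRecord,
    MarkState,
    build_enhancer_records,
    call_mark_state,
    classify_by_marks,
    classify_promoter,
    estimate_background,
    finalize_classes,
    overlap_with_factor,
    select_distal,
)
from enhancerdyn.genome import (
    CoverageTrack,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    PeakSet,
)

MARKS = ("H3K4Me1", "H3K27Ac", "P300", "H3K27Me3")


def states_from_bits(bits):
    return {
        m: MarkState(m, 10.0 if b else 0.5, bool(b)) for m, b in zip(MARKS, bits)
    }


class TestMarkRule:
    def test_exhaustive_16_combinations(self):
        """The class rule over every boolean mark combination, against an
        independent restatement: pre-existing needs both K4Me1 and K27Ac
        without K27Me3; de novo needs no active mark at all."""
        for bits in product([0, 1], repeat=4):
            k4me1, k27ac, p300, k27me3 = bits
            got = classify_by_marks(states_from_bits(bits))
            if k4me1 and k27ac and not k27me3:
                expected = "pre_existing"
            elif not (k4me1 or k27ac or p300):
                expected = "de_novo"
            else:
                expected = "ambiguous"
            assert got == expected, bits

    def test_partition_exhaustive_and_exclusive(self):
        seen = set()
        for bits in product([0, 1], repeat=4):
            seen.add(classify_by_marks(states_from_bits(bits)))
        assert seen == {"pre_existing", "de_novo", "ambiguous"}

    def test_k27ac_only_is_ambiguous(self):
        assert classify_by_marks(states_from_bits((0, 1, 0, 0))) == "ambiguous"

    def test_repressed_pattern_is_de_novo(self):
        assert classify_by_marks(states_from_bits((0, 0, 0, 1))) == "de_novo"

    def test_require_p300_flag(self):
        bits = (1, 1, 0, 0)
        assert classify_by_marks(states_from_bits(bits)) == "pre_existing"
        assert classify_by_marks(states_from_bits(bits), require_p300=True) == "ambiguous"

    def test_threshold_monotonicity(self):
        """Raising the mark threshold can only shrink the pre-existing set
        and grow the de novo set."""
        rng = np.random.default_rng(11)
        folds = rng.uniform(0, 5, size=(300, 4))
        counts = {}
        for thr in (1.5, 2.0, 3.0):
            labels = []
            for row in folds:
                states = {
                    m: MarkState(m, f, f >= thr) for m, f in zip(MARKS, row)
                }
                labels.append(classify_by_marks(states))
            counts[thr] = (
                labels.count("pre_existing"), labels.count("de_novo"))
        assert counts[1.5][0] >= counts[2.0][0] >= counts[3.0][0]
        assert counts[1.5][1] <= counts[2.0][1] <= counts[3.0][1]


class TestMarkStateCalls:
    def test_flat_track_fold_one(self):
        genome = GenomeModel(("chr1",), (10_000,))
        track = CoverageTrack(genome, {"chr1": np.full(10_000, 0.3, dtype=np.float32)})
        st = call_mark_state(5_000, "chr1", track, "H3K27Ac", background=0.3)
        assert st.fold_enrichment == pytest.approx(1.0, rel=1e-5)
        assert not st.marked

    def test_zero_track_unmarked(self):
        genome = GenomeModel(("chr1",), (10_000,))
        track = CoverageTrack(genome)
        st = call_mark_state(5_000, "chr1", track, "H3K27Ac", background=0.02)
        assert st.fold_enrichment == 0.0 and not st.marked

    def test_planted_gaussian_matches_closed_form(self):
        """Window mean over a Gaussian peak equals the erf integral within 5%."""
        from scipy.special import erf

        genome = GenomeModel(("chr1",), (100_000,))
        bg, height, sd, half_w = 0.02, 50.0, 250.0, 1000
        x = np.arange(100_000)
        center = 50_000
        vals = bg + height * bg * np.exp(-((x - center) ** 2) / (2 * sd**2))
        track = CoverageTrack(genome, {"chr1": vals.astype(np.float32)})
        st = call_mark_state(center, "chr1", track, "H3K27Ac", background=bg,
                             half_window=half_w)
        integral = height * bg * sd * np.sqrt(2 * np.pi) * erf(half_w / (sd * np.sqrt(2)))
        expected_fold = (bg + integral / (2 * half_w)) / bg
        assert st.marked
        assert st.fold_enrichment == pytest.approx(expected_fold, rel=0.05)

    def test_edge_window_truncated(self):
        genome = GenomeModel(("chr1",), (1_500,))
        track = CoverageTrack(genome, {"chr1": np.full(1_500, 0.1, dtype=np.float32)})
        st = call_mark_state(100, "chr1", track, "H3K27Ac", background=0.1)
        assert st.fold_enrichment == pytest.approx(1.0, rel=1e-5)


class TestBackground:
    def test_constant_track(self):
        genome = GenomeModel(("chr1",), (50_000,))
        track = CoverageTrack(genome, {"chr1": np.full(50_000, 0.7, dtype=np.float32)})
        assert estimate_background(track, 200, 500, seed=0) == pytest.approx(0.7, rel=1e-5)

    def test_zero_track_floor(self):
        genome = GenomeModel(("chr1",), (50_000,))
        assert estimate_background(CoverageTrack(genome), 100, 500, seed=0) == 1e-6

    def test_poisson_background_recovered(self):
        genome = GenomeModel(("chr1",), (1_000_000,))
        rng = np.random.default_rng(12)
        vals = rng.poisson(0.02, 1_000_000).astype(np.float32)
        track = CoverageTrack(genome, {"chr1": vals})
        est = estimate_background(track, 5000, 1000, seed=0)
        assert est == pytest.approx(0.02, rel=0.20)

    def test_deterministic_given_seed(self):
        genome = GenomeModel(("chr1",), (100_000,))
        rng = np.random.default_rng(13)
        vals = rng.poisson(0.5, 100_000).astype(np.float32)
        track = CoverageTrack(genome, {"chr1": vals})
        assert estimate_background(track, 500, 200, seed=4) == estimate_background(
            track, 500, 200, seed=4)


class TestPromoterRule:
    def _tracks(self, k4, k27):
        genome = GenomeModel(("chr1",), (10_000,))
        mk = lambda on: CoverageTrack(
            genome, {"chr1": np.full(10_000, 1.0 if on else 0.01, dtype=np.float32)})
        return genome, mk(k4), mk(k27)

    @pytest.mark.parametrize(
        "k4,k27,expected",
        [
            (True, False, "active"),
            (True, True, "bivalent"),
            (False, True, "inactive"),
            (False, False, "inactive"),
        ],
    )
    def test_rule(self, k4, k27, expected):
        _, t4, t27 = self._tracks(k4, k27)
        got = classify_promoter(5_000, "chr1", t4, t27, 0.05, 0.05)
        assert got == expected


class TestFinalize:
    def test_rule_enumeration_9_combinations(self):
        for mark_cls in ("pre_existing", "de_novo", "ambiguous"):
            for prom in ("active", "inactive", "bivalent"):
                rec = EnhancerRecord(
                    region=GenomicInterval("chr1", 100, 200),
                    mark_class=mark_cls,
                    promoter_state=prom,
                )
                [out] = finalize_classes([rec])
                if mark_cls == "pre_existing" and prom == "active":
                    assert out.final_class == "pre_existing"
                elif mark_cls == "de_novo" and prom == "inactive":
                    assert out.final_class == "de_novo"
                else:
                    assert out.final_class == "excluded"


class TestSelectDistal:
    def test_brute_force_equivalence(self, tiny_genome):
        rng = np.random.default_rng(14)
        genes = GeneAnnotation(
            [
                (f"g{k}", GenomicInterval("chr1", p, p + 100, f"g{k}", 0, "+"))
                for k, p in enumerate(sorted(rng.integers(0, 9_000, 5)))
            ]
        )
        sites = PeakSet(
            [GenomicInterval("chr1", int(s), int(s) + 50) for s in rng.integers(0, 9_900, 100)]
        )
        kept = select_distal(sites, genes, 500)
        tss = [g.start for _, g in genes.genes]
        expected = [
            iv for iv in sites
            if min(abs(iv.midpoint - t) for t in tss) > 500
        ]
        assert [i.sort_key() for i in kept] == [i.sort_key() for i in expected]

    def test_site_at_tss_removed_far_site_kept(self):
        genes = GeneAnnotation([("g", GenomicInterval("chr1", 50_000, 52_000, "g", 0, "+"))])
        sites = PeakSet([
            GenomicInterval("chr1", 49_900, 50_100),   # at TSS
            GenomicInterval("chr1", 99_000, 100_000),  # ~49.5 kb away
        ])
        kept = select_distal(sites, genes, 2000)
        assert len(kept) == 1 and kept[0].start == 99_000


class TestOverlapWithFactor:
    def _records(self):
        recs = []
        for i, cls in enumerate(["pre_existing"] * 3 + ["de_novo"] * 2):
            recs.append(
                EnhancerRecord(
                    region=GenomicInterval("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 500),
                    final_class=cls,
                )
            )
        return recs

    def test_full_and_empty(self):
        recs = self._records()
        everything = PeakSet([GenomicInterval("chr1", 1, 100_000)])
        out = overlap_with_factor(recs, everything)
        assert out == {"pre_existing": 1.0, "de_novo": 1.0}
        out = overlap_with_factor(recs, PeakSet([]))
        assert out == {"pre_existing": 0.0, "de_novo": 0.0}

    def test_flank_extends_reach(self):
        recs = self._records()
        near = PeakSet([GenomicInterval("chr1", 10_600, 10_700)])  # 100 bp past rec 0
        assert overlap_with_factor(recs, near, flank=0)["pre_existing"] == 0.0
        assert overlap_with_factor(recs, near, flank=200)["pre_existing"] == pytest.approx(1 / 3)
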