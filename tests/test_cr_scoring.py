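import numpy as np
import pytest
from scipy.stats import spearmanr

from tadsi.boundaries import BoundaryCall
from tadsi.cr_scoring import (
    FilterConfig,
    cr_enhancer_score_whole,
    cr_enhancer_score_windows,
    cr_insulation_score,
    filter_crs,
    mean_si,
    percentile_transform,
    score_crs,
    si_scores,
    top_boundary,
)
from tadsi.genome_intervals import CREvent, EnhancerTrack, GenomicInterval
from conftest import coverage_oracle


def bc(pos, strength, chrom="chr1"):
    return BoundaryCall(chrom=chrom, position=pos, strength=strength, bin=pos // 10_000)


def cr(cr_id, start, end, cr_type="deletion", chrom="chr1"):
    return CREvent(cr_id, GenomicInterval(chrom, start, end), cr_type)


class TestFilter:
    BOUNDARIES = [bc(1_000_000, 0.5), bc(2_000_000, 0.8), bc(3_000_000, 0.3)]

    def test_boundary_containment_stage(self):
        crs = [
            cr("span1", 900_000, 1_200_000),
            cr("span2", 1_900_000, 2_200_000),
            cr("span3", 900_000, 3_100_000),
            cr("inside1", 1_100_000, 1_400_000),
            cr("inside2", 2_100_000, 2_500_000),
        ]
        kept, report = filter_crs(crs, self.BOUNDARIES)
        assert {c.cr_id for c in kept} == {"span1", "span2", "span3"}
        assert report.n_after_boundary == 3
        assert report.dropped["inside1"] == "no boundary"

    def test_type_and_length_drops(self):
        crs = [
            cr("ok", 900_000, 1_200_000),
            cr("transloc", 900_000, 1_200_000, "translocation"),
            cr("short", 990_000, 1_040_000),
            cr("long", 0, 50_000_000),
        ]
        kept, report = filter_crs(crs, self.BOUNDARIES)
        assert [c.cr_id for c in kept] == ["ok"]
        assert report.dropped["transloc"] == "type"
        assert report.dropped["short"] == "length"
        assert report.dropped["long"] == "length"
        assert report.n_input == 4

    def test_chromosome_whitelist(self):
        crs = [cr("a", 900_000, 1_200_000), cr("b", 900_000, 1_200_000, chrom="chrUn")]
        kept, report = filter_crs(
            crs, self.BOUNDARIES, FilterConfig(chromosomes=frozenset({"chr1"}))
        )
        assert [c.cr_id for c in kept] == ["a"]
        assert report.dropped["b"] == "loci"

    def test_counts_nonincreasing_and_consistent(self):
        crs = [
            cr("a", 900_000, 1_200_000),
            cr("b", 900_000, 1_200_000, "ring"),
            cr("c", 1_100_000, 1_200_000),
        ]
        kept, r = filter_crs(crs, self.BOUNDARIES)
        stages = [r.n_input, r.n_after_type, r.n_after_loci, r.n_after_length,
                  r.n_after_boundary]
        assert stages == sorted(stages, reverse=True)
        assert r.n_input == len(kept) + len(r.dropped)

    def test_empty_boundary_list_rejected(self):
        with pytest.raises(ValueError, match="empty boundary list"):
            filter_crs([cr("a", 900_000, 1_200_000)], [])


class TestInsulationScore:
    def test_max_rule(self):
        boundaries = [bc(1_100_000, 0.4), bc(1_200_000, 0.9), bc(5_000_000, 2.0)]
        c = cr("x", 1_000_000, 1_500_000)
        assert cr_insulation_score(c, boundaries) == 0.9
        assert top_boundary(c, boundaries).position == 1_200_000

    def test_single_boundary_identity(self):
        assert cr_insulation_score(cr("x", 0 + 1, 2_000_000), [bc(1_000_000, 0.42)]) == 0.42

    def test_no_boundary_error_or_zero(self):
        c = cr("x", 1_000_000, 1_500_000)
        with pytest.raises(ValueError, match="no TAD boundary"):
            cr_insulation_score(c, [bc(9_000_000, 1.0)])
        assert cr_insulation_score(c, [bc(9_000_000, 1.0)], missing="zero") == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            boundaries = [
                bc(int(p), float(s))
                for p, s in zip(
                    rng.integers(0, 10_000_000, size=12), rng.uniform(0, 2, size=12)
                )
            ]
            s, e = sorted(rng.integers(0, 10_000_000, size=2))
            if s == e:
                continue
            c = cr("x", int(s), int(e))
            inside = [b.strength for b in boundaries if s <= b.position < e]
            if inside:
                assert cr_insulation_score(c, boundaries) == max(inside)
            else:
                with pytest.raises(ValueError):
                    cr_insulation_score(c, boundaries)


class TestEnhancerScores:
    def test_windowed_sum_of_three_tallies(self):
        # enhancer coverage 1000 / 2000 / 500 bp in the three windows
        c = cr("x", 2_000_000, 5_000_000)
        tb = bc(3_500_000, 1.0)
        track = EnhancerTrack(
            [
                GenomicInterval("chr1", 1_900_000, 1_901_000),  # near start
                GenomicInterval("chr1", 5_100_000, 5_102_000),  # near end
                GenomicInterval("chr1", 3_400_000, 3_400_500),  # near boundary
            ]
        )
        assert cr_enhancer_score_windows(c, tb, track) == 3500

    def test_no_enhancers_zero(self):
        c = cr("x", 2_000_000, 5_000_000)
        assert cr_enhancer_score_windows(c, bc(3_000_000, 1.0), EnhancerTrack([])) == 0

    def test_windows_match_per_base_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ivs = [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 5000)))
                for s in rng.integers(0, 6_000_000, size=30)
            ]
            track = EnhancerTrack(ivs)
            c = cr("x", 1_000_000, 4_000_000)
            tb = bc(int(rng.integers(1_000_000, 4_000_000)), 1.0)
            merged = track.merged().intervals
            expect = 0
            from tadsi.genome_intervals import window_around

            for anchor in (1_000_000, 4_000_000, tb.position):
                expect += coverage_oracle(window_around(anchor, 400_000, "chr1"), merged)
            assert cr_enhancer_score_windows(c, tb, track) == expect

    def test_whole_region_variant(self):
        c = cr("x", 1_000_000, 2_000_000)
        full = EnhancerTrack([GenomicInterval("chr1", 1_000_000, 2_000_000)])
        half = EnhancerTrack([GenomicInterval("chr1", 1_000_000, 1_500_000)])
        assert cr_enhancer_score_whole(c, full) == 1.0
        assert cr_enhancer_score_whole(c, half) == 0.5
        assert cr_enhancer_score_whole(c, EnhancerTrack([])) == 0.0


class TestPercentileAndSI:
    def test_distinct_values(self):
        assert percentile_transform([1, 2, 3, 4]).tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_ties_take_max_rank(self):
        assert percentile_transform([1, 1, 2]).tolist() == pytest.approx(
            [2 / 3, 2 / 3, 1.0]
        )

    def test_monotone_and_range(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=200)
        p = percentile_transform(v)
        order = np.argsort(v)
        assert (np.diff(p[order]) >= 0).all()
        assert p.min() > 0 and p.max() == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_transform([])

    def test_si_is_percentile_product(self):
        scores = si_scores([3.0, 1.0, 2.0], [10.0, 30.0, 20.0])
        assert [s.si for s in scores] == pytest.approx(
            [1.0 * (1 / 3), (1 / 3) * 1.0, (2 / 3) * (2 / 3)]
        )
        assert [s.si_sum for s in scores] == pytest.approx([4 / 3, 4 / 3, 4 / 3])
        assert min(s.si for s in scores) > 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            si_scores([1.0], [1.0, 2.0])

    def test_si_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        ins = rng.uniform(0, 2, size=50)
        enh = rng.integers(0, 10_000, size=50).astype(float)
        base = [s.si for s in si_scores(ins, enh)]
        warped = [s.si for s in si_scores(np.exp(3 * ins), enh ** 3 + 7)]
        assert base == pytest.approx(warped)


class TestMeanSI:
    def make(self, cell, ids, sis):
        return [
            type("S", (), {"cr_id": i, "si": s})() for i, s in zip(ids, sis)
        ]

    def test_identical_values(self):
        scores = {
            c: self.make(c, ["a"], [0.7]) for c in ("l1", "l2", "l3")
        }
        assert mean_si(scores)["a"] == pytest.approx(0.7)

    def test_hand_sum(self):
        scores = {
            "l1": self.make("l1", ["a", "b"], [1.0, 0.5]),
            "l2": self.make("l2", ["a", "b"], [0.2, 0.1]),
        }
        out = mean_si(scores)
        assert out["a"] == pytest.approx(0.6)
        assert out["b"] == pytest.approx(0.3)

    def test_single_cell_line_identity_and_missing(self):
        scores = {
            "l1": self.make("l1", ["a", "b"], [0.4, 0.6]),
            "l2": self.make("l2", ["a"], [0.8]),
        }
        out = mean_si(scores)
        assert out["a"] == pytest.approx(0.6)
        assert out["b"] == pytest.approx(0.6)  # present in one line only


class TestEnhancerVariantAgreement:
    def test_windowed_and_whole_positively_rank_correlated(self):
        rng = np.random.default_rng(4)
        # random enhancer landscape; CRs sample it at random loci
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(500, 20_000)))
            for s in rng.integers(0, 50_000_000, size=400)
        ]
        track = EnhancerTrack(ivs)
        win, whole = [], []
        for _ in range(60):
            s = int(rng.integers(1_000_000, 45_000_000))
            c = cr("x", s, s + int(rng.integers(500_000, 3_000_000)))
            tb = bc(int(rng.integers(c.interval.start, c.interval.end)), 1.0)
            win.append(cr_enhancer_score_windows(c, tb, track))
            whole.append(cr_enhancer_score_whole(c, track))
        rho = spearmanr(win, whole).statistic
        assert rho > 0.3
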