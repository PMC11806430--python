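"""Overlay geometry, interval construction, Dice, and discordance taxonomy."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import gaconcord as g
from gaconcord.concordance import (
    ConcordanceRecord,
    DiscordanceClass,
    nearest_locus_index,
)
from gaconcord.concordance import tested_extent_um as perimetered_extent
from gaconcord.intervals import IntervalSet
from gaconcord.microperimetry import ABSOLUTE


def record(tp, fp, fn, n_abs=2):
    denom = 2 * tp + fp + fn
    return ConcordanceRecord(
        tp_px=tp, fp_px=fp, fn_px=fn,
        dsc=(2 * tp / denom) if denom else None,
        n_absolute_loci=n_abs,
    )


class TestLociOnAxis:
    def test_counts_on_default_grid(self, concordant_phantom, default_grid):
        smap = g.simulate_exam(concordant_phantom, default_grid)
        assert len(g.loci_on_axis(smap, "horizontal")) == 16  # fovea + 15 temporal
        assert len(g.loci_on_axis(smap, "vertical")) == 25  # fovea + 12 + 12

    def test_positions_sorted_and_signed(self, concordant_phantom, default_grid):
        smap = g.simulate_exam(concordant_phantom, default_grid)
        vert = g.loci_on_axis(smap, "vertical")
        pos = [p for p, _ in vert]
        assert pos == sorted(pos)
        assert pos[0] == pytest.approx(-g.deg_to_um(12))
        assert pos[-1] == pytest.approx(g.deg_to_um(12))


class TestScotomaIntervals:
    def test_middle_absolute_locus(self):
        # loci at 0, 1, 2 deg with the middle one absolute: nearest-neighbour
        # cell spans the midpoints, i.e. [0.5 deg, 1.5 deg)
        loci = [
            (float(g.deg_to_um(0)), 14.0),
            (float(g.deg_to_um(1)), ABSOLUTE),
            (float(g.deg_to_um(2)), 14.0),
        ]
        s = g.scotoma_intervals(loci)
        assert len(s) == 1
        assert s.intervals[0][0] == pytest.approx(145.3, abs=0.1)
        assert s.intervals[0][1] == pytest.approx(436.0, abs=0.1)

    def test_all_absolute_full_cover(self):
        loci = [(0.0, ABSOLUTE), (100.0, ABSOLUTE), (200.0, ABSOLUTE)]
        s = g.scotoma_intervals(loci)
        assert s.intervals == ((-50.0, 250.0),)

    def test_no_absolute_is_empty(self):
        assert g.scotoma_intervals([(0.0, 10.0), (100.0, 14.0)]).is_empty

    def test_single_locus_needs_halfwidth(self):
        with pytest.raises(ValueError):
            g.scotoma_intervals([(0.0, ABSOLUTE)])
        s = g.scotoma_intervals([(0.0, ABSOLUTE)], terminal_halfwidth_um=145.3)
        assert s.intervals == ((-145.3, 145.3),)

    def test_nearest_neighbour_ties_go_to_lower_locus(self):
        assert nearest_locus_index([0.0, 100.0], 50.0) == 0

    def test_tested_extent(self):
        loci = [(0.0, 14.0), (100.0, 14.0), (200.0, 14.0)]
        assert perimetered_extent(loci) == (-50.0, 250.0)


class TestFafIntervals:
    def test_chord_through_circle_centre(self):
        # circle radius 2 deg centred on the axis at 5 deg: chord of 4 deg
        circle = Point(5.0, 0.0).buffer(2.0, quad_segs=256)
        s = g.faf_intervals([circle], "horizontal")
        assert len(s) == 1
        assert s.total_length == pytest.approx(g.deg_to_um(4.0), rel=1e-3)

    def test_polygon_off_the_line_is_empty(self):
        circle = Point(5.0, 5.0).buffer(2.0)
        assert g.faf_intervals([circle], "horizontal").is_empty

    def test_two_disjoint_lesions_give_two_ordered_intervals(self):
        a = Point(-5.0, 0.0).buffer(1.0)
        b = Point(5.0, 0.0).buffer(1.0)
        s = g.faf_intervals([b, a], "horizontal")
        assert len(s) == 2
        assert s.intervals[0][1] < s.intervals[1][0]

    def test_tangent_touch_dropped(self):
        # circle tangent to the axis at a single point: no chord, no interval
        circle = Point(0.0, 2.0).buffer(2.0, quad_segs=64)
        s = g.faf_intervals([circle], "horizontal")
        assert s.is_empty

    def test_vertical_axis(self):
        circle = Point(0.0, -6.0).buffer(1.5, quad_segs=256)
        s = g.faf_intervals([circle], "vertical")
        assert s.total_length == pytest.approx(g.deg_to_um(3.0), rel=1e-3)


class TestDice:
    def test_identical_sets_give_one(self):
        a = IntervalSet(((100.0, 400.0),))
        tp, fp, fn, dsc = g.dice(a, a, 1.0, (0.0, 500.0))
        assert dsc == 1.0 and fp == fn == 0 and tp == 300

    def test_disjoint_sets_give_zero(self):
        a = IntervalSet(((0.0, 100.0),))
        b = IntervalSet(((200.0, 300.0),))
        _, _, _, dsc = g.dice(a, b, 1.0, (0.0, 300.0))
        assert dsc == 0.0

    def test_half_overlap_against_pixel_oracle(self):
        a = IntervalSet(((0.0, 100.0),))
        b = IntervalSet(((50.0, 150.0),))
        tp, fp, fn, dsc = g.dice(a, b, 1.0, (0.0, 150.0))
        # brute-force pixel count on the same grid
        centers = np.arange(150) + 0.5
        in_a = (centers >= 0) & (centers < 100)
        in_b = (centers >= 50) & (centers < 150)
        assert (tp, fp, fn) == (
            int((in_a & in_b).sum()),
            int((in_a & ~in_b).sum()),
            int((~in_a & in_b).sum()),
        )
        assert (tp, fp, fn, dsc) == (50, 50, 50, 0.5)

    def test_both_empty_is_undefined(self):
        e = IntervalSet()
        tp, fp, fn, dsc = g.dice(e, e, 1.0, (0.0, 100.0))
        assert dsc is None and tp == fp == fn == 0

    def test_symmetry_swaps_fp_fn(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = IntervalSet.from_pairs([(rng.uniform(0, 400), rng.uniform(500, 900))])
            b = IntervalSet.from_pairs([(rng.uniform(0, 400), rng.uniform(500, 900))])
            tp1, fp1, fn1, d1 = g.dice(a, b, 2.0, (0.0, 1000.0))
            tp2, fp2, fn2, d2 = g.dice(b, a, 2.0, (0.0, 1000.0))
            assert (tp1, fp1, fn1) == (tp2, fn2, fp2)
            assert d1 == d2

    def test_dsc_bounds_and_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pairs = [
                (x, x + rng.uniform(5, 100))
                for x in rng.uniform(0, 800, size=rng.integers(1, 4))
            ]
            a = IntervalSet.from_pairs(pairs)
            b = IntervalSet.from_pairs([(p[0] + 1, p[1] + 1) for p in pairs])
            _, _, _, dsc = g.dice(a, b, 1.0, (-10.0, 1000.0))
            assert 0.0 <= dsc <= 1.0
            ra = a.rasterize((-10.0, 1000.0), 1.0)
            rb = b.rasterize((-10.0, 1000.0), 1.0)
            assert (dsc == 1.0) == np.array_equal(ra, rb)

    def test_outside_domain_raises(self):
        a = IntervalSet(((-50.0, 100.0),))
        with pytest.raises(ValueError):
            g.dice(a, a, 1.0, (0.0, 200.0))

    def test_raster_agrees_with_exact_interval_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_a, n_b = rng.integers(1, 4, size=2)
            a = IntervalSet.from_pairs(
                [(x, x + rng.uniform(5, 200)) for x in rng.uniform(0, 2000, n_a)]
            )
            b = IntervalSet.from_pairs(
                [(x, x + rng.uniform(5, 200)) for x in rng.uniform(0, 2000, n_b)]
            )
            tp, _, _, _ = g.dice(a, b, 1.0, (0.0, 2500.0))
            exact = a.overlap_length(b)
            budget = 2.0 * (len(a) + len(b))  # 2 px per boundary pair
            assert abs(tp - exact) <= budget


class TestDiscordanceTaxonomy:
    def test_high_dsc_is_concordant(self):
        assert g.classify_discordance(record(90, 5, 5)) == DiscordanceClass.CONCORDANT

    def test_fp_dominant_is_scotoma_without_atrophy(self):
        r = record(20, 60, 5)
        assert r.dsc < 0.5
        assert g.classify_discordance(r) == DiscordanceClass.SCOTOMA_WITHOUT_ATROPHY

    def test_fn_dominant_is_atrophy_without_scotoma(self):
        r = record(0, 0, 100)
        assert g.classify_discordance(r) == DiscordanceClass.ATROPHY_WITHOUT_SCOTOMA

    def test_balanced_errors_are_mixed(self):
        r = record(10, 40, 40)
        assert g.classify_discordance(r) == DiscordanceClass.MIXED

    def test_undefined_dsc_is_mixed(self):
        r = record(0, 0, 0)
        assert g.classify_discordance(r) == DiscordanceClass.MIXED

    def test_record_validates_dsc_consistency(self):
        with pytest.raises(ValueError):
            ConcordanceRecord(tp_px=10, fp_px=0, fn_px=0, dsc=0.5)


class TestSingleScotomaFilter:
    def test_excludes_exactly_one(self):
        records = [record(5, 5, 5, n_abs=n) for n in (0, 1, 2, 3, 1)]
        kept = g.filter_single_scotoma_lines(records)
        assert [r.n_absolute_loci for r in kept] == [0, 2, 3]
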