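"""Imaging score tables, grade bands and plateau region geometry."""

import numpy as np
import pytest

from tibiacut import (
    DisplacementMeasurement,
    Grade,
    Region,
    SurfaceDamage,
    ValidationError,
    count_damaged_regions,
    divide_plateau,
    score_displacement,
    score_surface,
    total_score,
)

ARTICULAR = [
    Region.ANTEROLATERAL,
    Region.ANTEROMEDIAL,
    Region.POSTEROLATERAL,
    Region.POSTEROMEDIAL,
]


# literal transcriptions of the scoring tables, used as lookup oracles
def oracle_collapse(v):
    return 6 if v == 0 else 4 if v <= 5 else 2 if v <= 10 else 0


def oracle_broadening(v):
    return 6 if v == 0 else 4 if v < 5 else 2 if v <= 10 else 0


def oracle_angulation(v):
    return 6 if v == 0 else 4 if v < 10 else 2 if v <= 20 else 0


def oracle_displacement_grade(total):
    return (
        Grade.EXCELLENT if total == 18
        else Grade.GOOD if total >= 12
        else Grade.COMMON if total >= 6
        else Grade.BAD
    )


def oracle_total_grade(total):
    return (
        Grade.EXCELLENT if total >= 28
        else Grade.GOOD if total >= 20
        else Grade.COMMON if total >= 10
        else Grade.BAD
    )


class TestDisplacementScore:
    def test_perfect_reduction_scores_maximum(self):
        s = score_displacement(DisplacementMeasurement(0, 0, 0))
        assert (s.collapse_pts, s.broadening_pts, s.angulation_pts) == (6, 6, 6)
        assert s.displacement_total == 18
        assert s.displacement_grade is Grade.EXCELLENT

    def test_collapse_of_8mm_is_common_band(self):
        assert score_displacement(DisplacementMeasurement(8, 0, 0)).collapse_pts == 2

    def test_mixed_measurement(self):
        s = score_displacement(DisplacementMeasurement(8, 12, 5))
        assert (s.collapse_pts, s.broadening_pts, s.angulation_pts) == (2, 0, 4)
        assert s.displacement_total == 6
        assert s.displacement_grade is Grade.COMMON

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValidationError):
            DisplacementMeasurement(-1, 0, 0)
        with pytest.raises(ValidationError):
            DisplacementMeasurement(0, 0, float("nan"))

    def test_full_integer_enumeration_against_table_oracle(self):
        """Every integer mm 0..25 and degree 0..30 maps to the transcribed
        table points, and the grade matches the stated bands."""
        for collapse in range(26):
            for broadening in range(26):
                for angulation in range(31):
                    s = score_displacement(
                        DisplacementMeasurement(collapse, broadening, angulation)
                    )
                    assert s.collapse_pts == oracle_collapse(collapse)
                    assert s.broadening_pts == oracle_broadening(broadening)
                    assert s.angulation_pts == oracle_angulation(angulation)
                    total = (
                        oracle_collapse(collapse)
                        + oracle_broadening(broadening)
                        + oracle_angulation(angulation)
                    )
                    assert s.displacement_total == total
                    assert s.displacement_grade is oracle_displacement_grade(total)

    def test_band_closures_at_fractional_boundaries(self):
        # collapse keeps 5.0 in the 4-pt band; broadening and angulation
        # push their printed boundary into the lower-scoring band
        assert score_displacement(DisplacementMeasurement(5.0, 0, 0)).collapse_pts == 4
        assert score_displacement(DisplacementMeasurement(5.5, 0, 0)).collapse_pts == 2
        assert score_displacement(DisplacementMeasurement(0, 5.0, 0)).broadening_pts == 2
        assert score_displacement(DisplacementMeasurement(0, 4.9, 0)).broadening_pts == 4
        assert score_displacement(DisplacementMeasurement(0, 0, 10.0)).angulation_pts == 2
        assert score_displacement(DisplacementMeasurement(0, 0, 9.9)).angulation_pts == 4


class TestSurfaceScore:
    def test_intercondylar_only_zero_fragments(self):
        d = SurfaceDamage(frozenset({Region.INTERCONDYLAR}), 0)
        assert score_surface(d) == (6, 6)

    def test_no_damage_at_all_takes_best_band(self):
        assert score_surface(SurfaceDamage(frozenset(), 0)) == (6, 6)

    def test_two_areas_two_fragments(self):
        d = SurfaceDamage(frozenset(ARTICULAR[:2]), 2)
        assert score_surface(d) == (4, 2)

    def test_all_four_areas_heavy_comminution(self):
        d = SurfaceDamage(frozenset(ARTICULAR), 5)
        assert score_surface(d) == (0, 0)

    @pytest.mark.parametrize(
        "n_areas,expected", [(0, 6), (1, 4), (2, 4), (3, 2), (4, 0)]
    )
    def test_damage_band_per_area_count(self, n_areas, expected):
        d = SurfaceDamage(frozenset(ARTICULAR[:n_areas]), max(n_areas, 1))
        assert score_surface(d)[0] == expected

    @pytest.mark.parametrize(
        "frags,expected", [(0, 6), (1, 4), (2, 2), (3, 0), (7, 0)]
    )
    def test_comminution_band_per_fragment_count(self, frags, expected):
        regions = frozenset() if frags == 0 else frozenset({Region.ANTEROLATERAL})
        assert score_surface(SurfaceDamage(regions, frags))[1] == expected

    def test_intercondylar_involvement_never_lowers_damage_points(self):
        with_em = SurfaceDamage(frozenset(ARTICULAR[:2]) | {Region.INTERCONDYLAR}, 2)
        without = SurfaceDamage(frozenset(ARTICULAR[:2]), 2)
        assert score_surface(with_em)[0] == score_surface(without)[0]

    def test_zero_fragments_with_articular_damage_rejected(self):
        with pytest.raises(ValidationError):
            SurfaceDamage(frozenset({Region.ANTEROLATERAL}), 0)


class TestTotalScore:
    def test_perfect_case_totals_thirty_excellent(self):
        s = total_score(
            DisplacementMeasurement(0, 0, 0),
            SurfaceDamage(frozenset({Region.INTERCONDYLAR}), 0),
        )
        assert s.total == 30
        assert s.total_grade is Grade.EXCELLENT

    def test_grade_boundary_around_twenty(self):
        # collapse 4 + broadening 2 + angulation 6 = 12, + damage 4 +
        # comminution 4 = 20 -> good
        s20 = total_score(
            DisplacementMeasurement(3, 7, 0),
            SurfaceDamage(frozenset({Region.ANTEROLATERAL}), 1),
        )
        assert (s20.total, s20.total_grade) == (20, Grade.GOOD)
        # all sub-scores are even so 19 itself is unreachable; the nearest
        # attainable total below the boundary must grade common
        s18 = total_score(
            DisplacementMeasurement(3, 7, 0),
            SurfaceDamage(frozenset({Region.ANTEROLATERAL}), 2),
        )
        assert (s18.total, s18.total_grade) == (18, Grade.COMMON)

    def test_worked_bad_case(self):
        s = total_score(
            DisplacementMeasurement(8, 12, 5),
            SurfaceDamage(frozenset(ARTICULAR[:3]), 3),
        )
        assert s.displacement_total == 6
        assert (s.damage_pts, s.comminution_pts) == (2, 0)
        assert s.total == 8
        assert s.total_grade is Grade.BAD

    def test_score_extrema_over_the_input_domain(self):
        best = total_score(
            DisplacementMeasurement(0, 0, 0),
            SurfaceDamage(frozenset(), 0),
        )
        worst = total_score(
            DisplacementMeasurement(11, 11, 21),
            SurfaceDamage(frozenset(ARTICULAR), 3),
        )
        assert (best.displacement_total, best.total) == (18, 30)
        assert (worst.displacement_total, worst.total) == (0, 0)

    def test_grade_monotone_in_total(self):
        rank = {Grade.BAD: 0, Grade.COMMON: 1, Grade.GOOD: 2, Grade.EXCELLENT: 3}
        from tibiacut.scoring import _total_grade

        grades = [rank[_total_grade(t)] for t in range(31)]
        assert grades == sorted(grades)
        for t in range(31):
            assert _total_grade(t) is oracle_total_grade(t)


class TestDividePlateau:
    def test_symmetric_rectangle_equal_quadrants(self):
        mask = np.ones((60, 100), dtype=bool)
        regions = divide_plateau(mask, eminence_halfwidth_frac=0.1)
        counts = regions.pixel_counts()
        quad = [counts[r] for r in ARTICULAR]
        assert len(set(quad)) == 1
        assert counts[Region.INTERCONDYLAR] == 20 * 60

    def test_partition_of_foreground(self, rng):
        mask = rng.random((40, 50)) > 0.3
        mask[20, 25] = True
        regions = divide_plateau(mask)
        assert np.array_equal(regions.foreground, mask)
        assert sum(regions.pixel_counts().values()) == int(mask.sum())

    def test_band_geometry_closed_form(self):
        mask = np.ones((60, 100), dtype=bool)
        regions = divide_plateau(mask, eminence_halfwidth_frac=0.1)
        band = regions.region_mask(Region.INTERCONDYLAR)
        cols = np.nonzero(band.any(axis=0))[0]
        # centroid column 49.5, half-width 10 -> columns 40..59
        assert cols.min() == 40 and cols.max() == 59

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            divide_plateau(np.zeros((5, 5), dtype=bool))
        with pytest.raises(ValidationError):
            divide_plateau(np.ones((5, 5), dtype=bool), eminence_halfwidth_frac=0.7)

    def test_quadrant_orientation(self):
        mask = np.ones((20, 40), dtype=bool)
        regions = divide_plateau(mask, eminence_halfwidth_frac=0.1)
        al = regions.region_mask(Region.ANTEROLATERAL)
        pm = regions.region_mask(Region.POSTEROMEDIAL)
        assert al[0, 0] and not al[19, 39]
        assert pm[19, 39] and not pm[0, 0]


class TestCountDamagedRegions:
    @pytest.fixture
    def regions(self):
        return divide_plateau(np.ones((60, 100), dtype=bool), 0.1)

    def test_central_line_hits_only_the_eminence(self, regions):
        dmg = np.zeros((60, 100), dtype=bool)
        dmg[10:50, 49] = True
        assert count_damaged_regions(regions, dmg) == frozenset({Region.INTERCONDYLAR})

    def test_diagonal_line_hits_opposite_quadrants(self, regions):
        dmg = np.zeros((60, 100), dtype=bool)
        rr = np.arange(60)
        cc = np.clip((rr * 100) // 60, 0, 99)
        dmg[rr, cc] = True
        hit = count_damaged_regions(regions, dmg, min_overlap_px=1)
        assert Region.ANTEROLATERAL in hit and Region.POSTEROMEDIAL in hit

    def test_empty_damage_mask(self, regions):
        assert count_damaged_regions(regions, np.zeros((60, 100), dtype=bool)) == frozenset()

    def test_min_overlap_threshold(self, regions):
        dmg = np.zeros((60, 100), dtype=bool)
        dmg[5, 5] = True  # single anterolateral pixel
        assert count_damaged_regions(regions, dmg, min_overlap_px=1) == frozenset(
            {Region.ANTEROLATERAL}
        )
        assert count_damaged_regions(regions, dmg, min_overlap_px=2) == frozenset()

    def test_dimension_mismatch_rejected(self, regions):
        with pytest.raises(ValidationError):
            count_damaged_regions(regions, np.zeros((2, 2), dtype=bool))
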