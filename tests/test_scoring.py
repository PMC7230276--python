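"""Scoring engine: worked examples, band boundaries, validation, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hfscore as h
from hfscore import FibrosisCategory

from conftest import HC, N, R, TB, assessment_from_reticular, region


class TestRegionPoints:
    @pytest.mark.parametrize(
        ("extents", "expected"),
        [
            ({N: 95.0, R: 5.0}, 105.0),
            ({N: 100.0}, 100.0),
            ({HC: 100.0}, 400.0),
            ({N: 70.0, R: 30.0}, 130.0),
            ({N: 50.0, R: 25.0, TB: 15.0, HC: 10.0}, 185.0),
        ],
    )
    def test_weighted_sum(self, extents, expected):
        assert h.region_points(h.RegionRead("carina_R", extents)) == expected

    def test_partition_must_total_100(self):
        with pytest.raises(h.ValidationError, match="mid_L"):
            h.RegionRead("mid_L", {N: 90.0, R: 5.0})

    def test_offgrid_extent_rejected(self):
        with pytest.raises(h.ValidationError, match="multiple of 5"):
            h.RegionRead("ipv_R", {N: 97.0, R: 3.0})

    def test_negative_extent_rejected(self):
        with pytest.raises(h.ValidationError, match="negative"):
            h.RegionRead("ipv_R", {N: 105.0, R: -5.0})

    @given(
        steps=st.lists(st.integers(0, 20), min_size=3, max_size=3).filter(
            lambda s: sum(s) <= 20
        ),
        shift=st.sampled_from([(R, TB), (TB, HC), (R, HC), (N, R)]),
    )
    @settings(deadline=None)
    def test_shifting_extent_to_heavier_category_raises_score(self, steps, shift):
        """Moving 5% of extent from a lighter to a heavier category adds 5 * dweight."""
        r, tb, hc = (5.0 * s for s in steps)
        extents = {N: 100.0 - r - tb - hc, R: r, TB: tb, HC: hc}
        lo, hi = shift
        if extents[lo] < 5.0:
            return  # nothing to move from the lighter category
        base = h.region_points(h.RegionRead("carina_R", extents))
        moved = dict(extents)
        moved[lo] -= 5.0
        moved[hi] += 5.0
        delta = h.CATEGORY_WEIGHTS[hi] - h.CATEGORY_WEIGHTS[lo]
        assert h.region_points(h.RegionRead("carina_R", moved)) == base + 5.0 * delta
        assert 100.0 <= base <= 400.0


class TestReaderAndPatientHFS:
    def test_worked_example_reader_a(self, patient_a_reader_hg):
        assert h.reader_hfs(patient_a_reader_hg) == 105.0

    def test_worked_example_reader_b(self, patient_b_reader_hg):
        assert h.reader_hfs(patient_b_reader_hg) == 125.0

    def test_all_normal_reader_scores_100(self):
        a = assessment_from_reticular("X", "R1", {})
        assert h.reader_hfs(a) == 100.0

    def test_patient_average_from_reader_scores(self):
        assert h.patient_hfs([105.0, 103.0]) == 104.0
        assert h.patient_hfs([117.0]) == 117.0

    def test_patient_average_from_assessments(self, patient_b_reader_hg, patient_b_reader_hi):
        assert h.patient_hfs([patient_b_reader_hg, patient_b_reader_hi]) == 122.5

    def test_mixed_patients_rejected(self, patient_a_reader_hg, patient_b_reader_hg):
        with pytest.raises(h.ValidationError, match="mixed patient_ids"):
            h.patient_hfs([patient_a_reader_hg, patient_b_reader_hg])

    def test_zero_readers_rejected(self):
        with pytest.raises(h.ValidationError):
            h.patient_hfs([])

    def test_missing_region_rejected(self):
        fib = tuple(region(r, normal=100.0) for r in h.REGION_IDS[:5])
        with pytest.raises(h.ValidationError, match="missing"):
            h.ReaderAssessment("R1", "X", fib)

    def test_duplicate_region_rejected(self):
        fib = tuple(region(r, normal=100.0) for r in h.REGION_IDS) + (
            region(h.REGION_IDS[0], normal=100.0),
        )
        with pytest.raises(h.ValidationError, match="duplicate"):
            h.ReaderAssessment("R1", "X", fib)

    @given(perm=st.permutations(list(range(6))))
    @settings(deadline=None)
    def test_reader_hfs_invariant_to_region_order(self, perm):
        extents = {"carina_R": 5.0, "carina_L": 10.0, "mid_R": 0.0,
                   "mid_L": 15.0, "ipv_R": 20.0, "ipv_L": 5.0}
        base = assessment_from_reticular("X", "R1", extents)
        shuffled = h.ReaderAssessment(
            "R1", "X",
            tuple(base.fibrosis[i] for i in perm),
            tuple(base.emphysema[i] for i in perm),
        )
        assert h.reader_hfs(shuffled) == h.reader_hfs(base)


class TestGoddard:
    @pytest.mark.parametrize(
        ("laa", "expected"),
        [(0.0, 0), (5.0, 0), (5.5, 1), (25.0, 1), (26.0, 2), (50.0, 2),
         (60.0, 3), (75.0, 3), (80.0, 4), (100.0, 4)],
    )
    def test_band_score(self, laa, expected):
        assert h.gs_region_score(h.LAARead("carina_R", laa)) == expected

    def test_laa_out_of_range(self):
        with pytest.raises(h.ValidationError):
            h.LAARead("carina_R", 101.0)

    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    def test_band_score_monotone_in_laa(self, a, b):
        lo, hi = sorted([a, b])
        assert h.gs_region_score(h.LAARead("mid_R", lo)) <= h.gs_region_score(
            h.LAARead("mid_R", hi)
        )

    def test_reader_gs_worked_example(self, patient_b_reader_hg):
        assert h.reader_gs(patient_b_reader_hg) == 18

    def test_reader_gs_sums_bands(self, patient_b_reader_hi):
        assert h.reader_gs(patient_b_reader_hi) == 15

    def test_patient_gs_average(self, patient_b_reader_hg, patient_b_reader_hi):
        assert h.patient_gs([patient_b_reader_hg, patient_b_reader_hi]) == 16.5
        assert h.patient_gs([18.0, 15.0]) == 16.5

    def test_patient_gs_trivial_cases(self):
        assert h.patient_gs([0.0, 0.0]) == 0.0
        assert h.patient_gs([24.0]) == 24.0


class TestBandsAndStrata:
    @pytest.mark.parametrize(
        ("hfs", "severity", "stratum"),
        [
            (100.0, "none", "eq100"),
            (104.0, "mild", "gt100_le110"),
            (110.0, "mild", "gt100_le110"),
            (110.0 + 5 / 6, "mild", "gt110"),
            (122.5, "mild", "gt110"),
            (200.0, "mild", "gt110"),
            (200.5, "moderate", "gt110"),
            (300.5, "severe", "gt110"),
            (400.0, "severe", "gt110"),
        ],
    )
    def test_ild_bands_and_strata(self, hfs, severity, stratum):
        assert h.ild_severity(hfs) == severity
        assert h.hfs_stratum(hfs) == stratum

    @pytest.mark.parametrize(
        ("gs", "severity"),
        [(0.0, "none"), (0.5, "mild"), (7.0, "mild"), (7.5, "moderate"),
         (15.0, "moderate"), (16.5, "severe"), (24.0, "severe")],
    )
    def test_emphysema_bands(self, gs, severity):
        assert h.emphysema_severity(gs) == severity

    @pytest.mark.parametrize("bad", [99.0, 401.0])
    def test_out_of_range_hfs(self, bad):
        with pytest.raises(h.ValidationError):
            h.ild_severity(bad)
        with pytest.raises(h.ValidationError):
            h.hfs_stratum(bad)

    def test_score_patient_consistency(self, patient_b_reader_hg, patient_b_reader_hi):
        ps = h.score_patient([patient_b_reader_hg, patient_b_reader_hi])
        assert ps.hfs == 122.5
        assert ps.gs == 16.5
        assert ps.ild_severity == "mild"
        assert ps.emphysema_severity == "severe"
        assert ps.hfs_stratum == "gt110"


class TestSnapToGrid:
    def test_snap_rounds_to_nearest_step(self):
        snapped = h.scoring.snap_to_grid({N: 96.0, R: 4.0})
        assert snapped[R] == 5.0 and snapped[N] == 95.0

    def test_ties_round_away_from_normal(self):
        snapped = h.scoring.snap_to_grid({N: 97.5, R: 2.5})
        assert snapped[R] == 5.0 and snapped[N] == 95.0
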