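"""Deciban coefficients, informativeness, the inversion oracle, and
table assembly."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import waldgenkin as wg
from waldgenkin.indices import CRITERIA, Group, Status
from waldgenkin.prognostic import GradationCounts
from waldgenkin.reference import PRINTED_ROWS

from conftest import EXPECTED_COUNTS, make_profile, uniform_profile

interior_count = st.integers(min_value=1, max_value=14)


class TestPredictiveCoefficient:
    @pytest.mark.parametrize("d1, d2, gradation, expected_display", [
        (12, 1, "presence", 10.8),   # 10 log10(12) = 10.7918
        (12, 1, "absence", -6.7),    # 10 log10(3/14) = -6.690
        (10, 1, "presence", 10.0),   # exactly 10 log10(10)
        (10, 1, "absence", -4.5),
    ])
    def test_reference_pairs(self, d1, d2, gradation, expected_display):
        from waldgenkin._round import round_half_up
        pc = wg.predictive_coefficient(
            GradationCounts(d1, 15, d2, 15), gradation, smoothing=0.0)
        assert round_half_up(pc, 1) == expected_display

    def test_exact_ten_for_tenfold_ratio(self):
        pc = wg.predictive_coefficient(GradationCounts(10, 15, 1, 15),
                                       "presence", smoothing=0.0)
        assert pc == pytest.approx(10.0, abs=1e-12)

    def test_equal_proportions_give_zero(self):
        assert wg.predictive_coefficient(GradationCounts(7, 15, 7, 15),
                                         "presence") == pytest.approx(0.0)

    def test_degenerate_counts_without_smoothing_raise(self):
        with pytest.raises(wg.DegenerateCountsError):
            wg.predictive_coefficient(GradationCounts(0, 15, 3, 15),
                                      "presence", smoothing=0.0)

    def test_degenerate_counts_with_smoothing_are_finite(self):
        pc = wg.predictive_coefficient(GradationCounts(15, 15, 0, 15),
                                       "presence", smoothing=0.5)
        assert pc == pytest.approx(10.0 * __import__("math").log10(31.0))

    @given(d1=interior_count, d2=interior_count)
    @settings(derandomize=True, max_examples=100)
    def test_antisymmetry_under_group_swap(self, d1, d2):
        counts = GradationCounts(d1, 15, d2, 15)
        for gradation in ("presence", "absence"):
            assert wg.predictive_coefficient(counts.swapped(), gradation) == \
                pytest.approx(-wg.predictive_coefficient(counts, gradation))

    @given(d1=interior_count, d2=interior_count)
    @settings(derandomize=True, max_examples=100)
    def test_gradation_complement(self, d1, d2):
        """Scoring absence equals scoring presence of the complemented
        criterion with numerators complemented."""
        counts = GradationCounts(d1, 15, d2, 15)
        complemented = GradationCounts(15 - d1, 15, 15 - d2, 15)
        assert wg.predictive_coefficient(counts, "absence") == \
            pytest.approx(wg.predictive_coefficient(complemented, "presence"))


class TestInformativeness:
    @pytest.mark.parametrize("d1, d2, expected_display", [
        (12, 1, 395.70),
        (9, 1, 254.46),   # sensitive to using the unrounded coefficient
        (14, 9, 31.98),
    ])
    def test_reference_values(self, d1, d2, expected_display):
        from waldgenkin._round import round_half_up
        info = wg.informativeness(GradationCounts(d1, 15, d2, 15),
                                  smoothing=0.0)
        assert round_half_up(info, 2) == expected_display

    def test_unrounded_coefficient_matters(self):
        # With the printed 9.5 instead of 9.5424... the (9,1) row would
        # come out 253.33, not the published 254.46.
        info = wg.informativeness(GradationCounts(9, 15, 1, 15), smoothing=0.0)
        assert info == pytest.approx(254.46, abs=0.005)
        assert info != pytest.approx(253.33, abs=0.5)

    def test_zero_iff_equal_proportions(self):
        assert wg.informativeness(GradationCounts(5, 15, 5, 15)) == 0.0

    @given(d1=interior_count, d2=interior_count)
    @settings(derandomize=True, max_examples=100)
    def test_nonnegative(self, d1, d2):
        counts = GradationCounts(d1, 15, d2, 15)
        assert wg.informativeness(counts) >= 0.0
        assert wg.informativeness(counts, both_gradations=True) >= 0.0

    @given(d1=interior_count, d2=interior_count)
    @settings(derandomize=True, max_examples=50)
    def test_both_gradation_sum_dominates_presence_term(self, d1, d2):
        counts = GradationCounts(d1, 15, d2, 15)
        assert wg.informativeness(counts, both_gradations=True) >= \
            wg.informativeness(counts) - 1e-12


class TestInversionOracle:
    def test_reference_row_inverts_uniquely(self):
        result = wg.invert_pc_pair(10.8, -6.7, 15, 15)
        assert result.unique
        assert (result.counts.d1, result.counts.d2) == (12, 1)

    def test_flexibility_row_inverts(self):
        result = wg.invert_pc_pair(6.7, -10.8, 15, 15)
        assert (result.counts.d1, result.counts.d2) == (14, 3)

    def test_zero_pair_is_maximally_ambiguous(self):
        result = wg.invert_pc_pair(0.0, 0.0, 15, 15)
        assert not result.unique
        assert len(result.matches) == 14  # every interior d1 == d2
        assert all(c.d1 == c.d2 for c in result.matches)
        with pytest.raises(wg.InversionError):
            result.counts

    def test_impossible_pair_reports_nearest(self):
        with pytest.raises(wg.InversionError, match="nearest"):
            wg.invert_pc_pair(10.8, -0.1, 15, 15)

    def test_round_trip_over_all_interior_pairs(self):
        """forward -> round -> invert recovers every (d1, d2) pair."""
        from waldgenkin._round import round_half_up
        for d1, d2 in itertools.product(range(1, 15), repeat=2):
            counts = GradationCounts(d1, 15, d2, 15)
            pres = round_half_up(
                wg.predictive_coefficient(counts, "presence", 0.0), 1)
            absn = round_half_up(
                wg.predictive_coefficient(counts, "absence", 0.0), 1)
            matches = wg.invert_pc_pair(pres, absn, 15, 15).matches
            assert counts in matches


class TestCountExceedances:
    def test_engineered_counts_recovered(self):
        profiles = [uniform_profile(i < 12, f"a{i}", Group.ATHLETE)
                    for i in range(15)]
        profiles += [uniform_profile(i < 1, f"c{i}", Group.CONTROL)
                     for i in range(15)]
        counts = wg.count_exceedances(profiles)
        assert counts["vlc_ratio_gt1"] == GradationCounts(12, 15, 1, 15)

    def test_all_present_in_both_groups(self):
        profiles = [uniform_profile(True, f"a{i}", Group.ATHLETE)
                    for i in range(4)]
        profiles += [uniform_profile(True, f"c{i}", Group.CONTROL)
                     for i in range(6)]
        assert wg.count_exceedances(profiles)["crab_lt60"] == \
            GradationCounts(4, 4, 6, 6)

    def test_missing_status_shrinks_effective_group_size(self):
        profiles = [uniform_profile(True, f"a{i}", Group.ATHLETE)
                    for i in range(3)]
        profiles.append(make_profile(
            {c: (None if c == "crab_lt60" else True) for c in CRITERIA},
            "a3", Group.ATHLETE))
        profiles += [uniform_profile(False, f"c{i}", Group.CONTROL)
                     for i in range(5)]
        counts = wg.count_exceedances(profiles)
        assert counts["crab_lt60"] == GradationCounts(3, 3, 0, 5)
        assert counts["splits_lt0"] == GradationCounts(4, 4, 0, 5)

    def test_unlabelled_profile_rejected(self):
        with pytest.raises(wg.ValidationError, match="group"):
            wg.count_exceedances([uniform_profile(True, "x", None)])

    def test_empty_group_rejected(self):
        with pytest.raises(wg.ValidationError, match="non-empty"):
            wg.count_exceedances(
                [uniform_profile(True, "a", Group.ATHLETE)])


class TestBuildTable:
    def test_reference_counts_reproduce_all_printed_values(self):
        """Flagship check: the nine reconstructed count pairs rebuild
        every printed number of the published table, in printed order."""
        counts = {c: GradationCounts(d1, 15, d2, 15)
                  for c, (d1, d2) in EXPECTED_COUNTS.items()}
        table = wg.build_table(counts, smoothing=0.0)
        assert len(table) == 9
        for printed, row in zip(PRINTED_ROWS, table):
            assert row.criterion_id == printed.criterion_id
            assert row.pc_presence_display == printed.pc_presence
            assert row.pc_absence_display == printed.pc_absence
            assert row.informativeness_display == printed.informativeness

    def test_cutoff_excludes_below_threshold(self):
        counts = {c: GradationCounts(d1, 15, d2, 15)
                  for c, (d1, d2) in EXPECTED_COUNTS.items()}
        counts["crab_lt60"] = GradationCounts(13, 15, 9, 15)  # info 29.93
        assert wg.informativeness(counts["crab_lt60"]) < 30.0
        table = wg.build_table(counts, smoothing=0.0)
        assert len(table) == 8
        assert all(row.criterion_id != "crab_lt60" for row in table)

    def test_tied_rows_keep_canonical_adjacent_order(self):
        counts = {c: GradationCounts(d1, 15, d2, 15)
                  for c, (d1, d2) in EXPECTED_COUNTS.items()}
        table = wg.build_table(counts, smoothing=0.0)
        ids = [row.criterion_id for row in table]
        assert ids.index("forward_bend_gt10s") + 1 == ids.index("splits_lt0")

    def test_all_rows_below_cutoff_is_an_error(self):
        with pytest.raises(wg.EmptyTableError):
            wg.build_table({"crab_lt60": GradationCounts(8, 15, 7, 15)})

    def test_row_count_warning_outside_seven_to_ten(self):
        with pytest.warns(UserWarning, match="7-10"):
            wg.build_table({"crab_lt60": GradationCounts(14, 15, 1, 15)})

    def test_informativeness_sorted_descending(self, reference_table):
        infos = [row.informativeness for row in reference_table]
        assert infos == sorted(infos, reverse=True)

    def test_csv_round_trip_is_lossless(self, reference_table, tmp_path):
        path = tmp_path / "table.csv"
        reference_table.write_csv(path)
        loaded = wg.PrognosticTable.read_csv(path)
        for original, reread in zip(reference_table, loaded):
            assert reread.criterion_id == original.criterion_id
            assert reread.counts == original.counts
            assert reread.pc_presence == pytest.approx(
                original.pc_presence, abs=1e-12)
            assert reread.informativeness == pytest.approx(
                original.informativeness, abs=1e-12)
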