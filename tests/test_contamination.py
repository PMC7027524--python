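"""Peak calling against the uniform null, removal, screening, TV distances."""

import numpy as np
import pytest

from ampliclean import (
    AmpliconDesign,
    CoordRecord,
    SimConfig,
    build_profile,
    compare_decontaminated,
    decontaminate,
    detect_peaks,
    profile_from_coords,
    profile_tv_distance,
    records_from_truth,
    screen_ssu_lsu,
    simulate_amplicon,
    simulate_shotgun_rrna,
)
from ampliclean.contamination import PeakWindow
from ampliclean.simdata import merge_sets


def _rec(read_id, start, end, marker="SSU"):
    return CoordRecord(read_id, marker, start, end)


class TestBuildProfile:
    def test_counts_land_on_their_positions(self):
        prof = build_profile([_rec(f"r{i}", 341, 805) for i in range(3)],
                             "SSU", 1542)
        assert prof.start_counts[340] == 3 and prof.start_counts.sum() == 3
        assert prof.end_counts[804] == 3 and prof.end_counts.sum() == 3

    def test_empty_records_give_zero_profile(self):
        prof = build_profile([], "SSU", 1542)
        assert prof.total == 0
        assert not prof.start_counts.any() and not prof.end_counts.any()

    def test_out_of_range_coordinate_names_the_read(self):
        with pytest.raises(ValueError, match="badread"):
            build_profile([_rec("badread", 100, 2000)], "SSU", 1542)

    def test_wrong_marker_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            build_profile([_rec("r", 1, 10, marker="LSU")], "SSU", 1542)

    def test_conservation_on_simulated_input(self, ref16s):
        rs = simulate_shotgun_rrna(ref16s, SimConfig(n_shotgun=10_000, seed=31))
        prof = build_profile(records_from_truth(rs), "SSU", ref16s.length)
        assert prof.start_counts.sum() == prof.end_counts.sum() == 10_000


class TestDetectPeaks:
    def test_spike_produces_start_and_end_windows(self, spiked_records):
        records, _ = spiked_records
        prof = build_profile(records, "SSU", 1542)
        windows = detect_peaks(prof)
        start_wins = [w for w in windows if w.kind == "start"]
        end_wins = [w for w in windows if w.kind == "end"]
        assert len(start_wins) == 1 and 341 in start_wins[0]
        assert len(end_wins) == 1 and 805 in end_wins[0]

    def test_jittered_spike_window_overlaps_primer_region(self, ref16s):
        """A spike centered at 341 with small positional jitter yields a
        start window overlapping 338-344 (ragged amplicon ends)."""
        shotgun = simulate_shotgun_rrna(ref16s, SimConfig(n_shotgun=20_000, seed=33))
        amp = simulate_amplicon(ref16s, AmpliconDesign(jitter_sd=1.5),
                                SimConfig(n_amplicon=5000, seed=34))
        records = records_from_truth(merge_sets([shotgun, amp]))
        windows = detect_peaks(build_profile(records, "SSU", 1542))
        start_wins = [w for w in windows if w.kind == "start"]
        assert any(w.lo <= 344 and w.hi >= 338 for w in start_wins)

    def test_zero_read_profile_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(build_profile([], "SSU", 1542))

    def test_pure_null_rarely_flags(self, ref16s):
        """5 independent null runs at alpha=0.01 with the fold/count
        floors: no windows expected (full 20-seed sweep lives in the
        acceptance suite)."""
        flagged_runs = 0
        for seed in range(5):
            rs = simulate_shotgun_rrna(ref16s, SimConfig(n_shotgun=50_000, seed=seed))
            prof = build_profile(records_from_truth(rs), "SSU", 1542)
            if detect_peaks(prof):
                flagged_runs += 1
        assert flagged_runs <= 1


class TestDecontaminate:
    WINDOWS = [
        PeakWindow("start", 338, 344, 0, 0.0, 0.0),
        PeakWindow("end", 644, 704, 0, 0.0, 0.0),
    ]

    def test_membership_on_fixed_windows(self):
        records = [_rec("in_start", 340, 710), _rec("in_end", 350, 700),
                   _rec("outside", 350, 710)]
        retained, report = decontaminate(records, self.WINDOWS)
        assert sorted(report.removed_ids) == ["in_end", "in_start"]
        assert [r.read_id for r in retained] == ["outside"]
        assert report.n_removed + report.n_retained == report.n_input == 3

    def test_no_windows_is_identity(self):
        records = [_rec("a", 10, 100), _rec("b", 20, 200)]
        retained, report = decontaminate(records, [])
        assert retained == records and report.n_removed == 0

    def test_idempotent_on_cleaned_records(self, spiked_records):
        records, _ = spiked_records
        windows = detect_peaks(build_profile(records, "SSU", 1542))
        retained, _ = decontaminate(records, windows)
        again, report2 = decontaminate(retained, windows)
        assert report2.n_removed == 0 and again == retained

    def test_enlarging_windows_never_removes_fewer(self, spiked_records):
        records, _ = spiked_records
        small = [PeakWindow("start", 341, 341, 0, 0, 0)]
        big = [PeakWindow("start", 338, 344, 0, 0, 0)]
        _, rep_small = decontaminate(records, small)
        _, rep_big = decontaminate(records, big)
        assert rep_big.n_removed >= rep_small.n_removed

    def test_spike_fully_removed_with_bounded_collateral(self, spiked_records):
        records, truth = spiked_records
        windows = detect_peaks(build_profile(records, "SSU", 1542))
        _, report = decontaminate(records, windows)
        removed = set(report.removed_ids)
        amplicon_ids = {rid for rid, lab in truth.truth.items() if lab == "amplicon"}
        assert amplicon_ids <= removed  # recall 1.0
        width = sum(w.width for w in windows)
        expected_collateral = 20_000 * width / 1542
        assert len(removed - amplicon_ids) <= 3 * expected_collateral


class TestScreen:
    def test_inflated_ssu_count_is_flagged(self):
        res = screen_ssu_lsu(36_195_266, 856_622)
        assert res.flagged
        assert res.ratio == pytest.approx(42.25, abs=0.01)

    def test_balanced_counts_pass(self):
        res = screen_ssu_lsu(1000, 900)
        assert not res.flagged and res.ratio == pytest.approx(1.11, abs=0.01)

    def test_zero_lsu_with_ssu_flags_undefined_ratio(self):
        res = screen_ssu_lsu(5, 0)
        assert res.flagged and res.ratio is None

    def test_no_reads_warns_and_passes(self):
        with pytest.warns(UserWarning):
            res = screen_ssu_lsu(0, 0)
        assert not res.flagged and res.ratio is None


class TestProfileDistance:
    def test_identical_profiles_have_zero_distance(self, spiked_records):
        records, _ = spiked_records
        prof = build_profile(records, "SSU", 1542)
        assert profile_tv_distance(prof, prof) == 0.0

    def test_disjoint_single_position_profiles_are_maximal(self):
        a = profile_from_coords([10], [10], "SSU", 100)
        b = profile_from_coords([90], [90], "SSU", 100)
        assert profile_tv_distance(a, b) == 1.0

    def test_zero_total_profile_rejected(self):
        a = build_profile([], "SSU", 100)
        b = profile_from_coords([10], [10], "SSU", 100)
        with pytest.raises(ValueError):
            profile_tv_distance(a, b)

    def test_cleaning_moves_profile_toward_truth(self, spiked_records):
        records, truth = spiked_records
        shotgun_recs = [r for r in records if truth.truth[r.read_id] == "shotgun"]
        reference = build_profile(shotgun_recs, "SSU", 1542)
        before = build_profile(records, "SSU", 1542)
        windows = detect_peaks(before)
        retained, _ = decontaminate(records, windows)
        after = build_profile(retained, "SSU", 1542)
        d_after, d_before = compare_decontaminated(before, after, reference)
        assert d_after < d_before
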