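import datetime as dt
import itertools

import numpy as np
import pytest

from accelpool import (CleaningConfig, FileFlag, WearMask, attrition,
                       classify_file, detect_nonwear, detect_overnight_wear,
                       detect_plateaus, detect_temporal_shift,
                       resolve_duplicates)
from accelpool.cleaning import CorruptFile, detect_baseline_floor
from accelpool.simulate import inject_artifact
from conftest import mk_series

MIDNIGHT = dt.datetime(2004, 4, 5, 0, 0)


def day_active_series(days=3, wake=7, sleep=22):
    """Clean diurnal profile: non-zero counts during waking hours only."""
    rng = np.random.default_rng(8)
    c = np.zeros(days * 1440, dtype=np.int64)
    for d in range(days):
        span = slice(d * 1440 + wake * 60, d * 1440 + sleep * 60)
        c[span] = rng.integers(1, 900, span.stop - span.start)
    return mk_series(c, start=MIDNIGHT)


class TestResolveDuplicates:
    def test_corrupt_loses_to_intact(self):
        a = CorruptFile("kA", "A", "boom")
        b = mk_series([1, 2], source_name="B")
        kept, dropped = resolve_duplicates([a, b])
        assert kept is b
        assert [d.flag for d in dropped] == [FileFlag.DUPLICATE_DROPPED]

    def test_first_label_wins_when_both_intact(self):
        a = mk_series([1], source_name="A")
        b = mk_series([2], source_name="B")
        kept, dropped = resolve_duplicates([b, a])
        assert kept is a
        assert "kept A" in dropped[0].evidence[0].detail

    def test_singleton_group(self):
        a = mk_series([1], source_name="A")
        assert resolve_duplicates([a]) == (a, [])

    def test_all_corrupt_keeps_first_label(self):
        a = CorruptFile("kA", "A", "x")
        b = CorruptFile("kB", "B", "y")
        kept, dropped = resolve_duplicates([b, a])
        assert kept is a and len(dropped) == 1


class TestOvernightWear:
    def _series_with_night_wear(self, start_min, n_min):
        c = np.zeros(1440, dtype=np.int64)
        c[start_min: start_min + n_min] = 200
        s = mk_series(c, start=MIDNIGHT)
        mask = WearMask(c != 0)
        return s, mask

    def test_ten_minutes_in_hour_two_fires(self):
        s, m = self._series_with_night_wear(2 * 60 + 5, 10)  # 02:05-02:15
        ev = detect_overnight_wear(s, m)
        assert len(ev) == 1 and "hour 02" in ev[0].detail

    def test_nine_minutes_does_not_fire(self):
        s, m = self._series_with_night_wear(3 * 60, 9)
        assert detect_overnight_wear(s, m) == []

    def test_split_across_hours_does_not_fire_per_hour(self):
        c = np.zeros(1440, dtype=np.int64)
        c[2 * 60 + 55: 3 * 60] = 200   # 5 min in hour 2
        c[3 * 60: 3 * 60 + 5] = 200    # 5 min in hour 3
        s = mk_series(c, start=MIDNIGHT)
        m = WearMask(c != 0)
        assert detect_overnight_wear(s, m) == []
        summed = CleaningConfig(overnight_per_hour=False)
        assert detect_overnight_wear(s, m, summed) != []

    def test_requires_minute_epochs(self):
        with pytest.raises(ValueError):
            detect_overnight_wear(mk_series([0] * 10, epoch=30),
                                  WearMask(np.ones(10, bool)))


class TestPlateaus:
    def test_minimal_plateau(self):
        runs = detect_plateaus(mk_series([12, 12, 12]))
        assert [(r.start_index, r.length, r.value) for r in runs] == [(0, 3, 12)]

    def test_below_value_threshold(self):
        assert detect_plateaus(mk_series([9, 9, 9, 9])) == []

    def test_saturation_tagged(self):
        c = [100, 250, 90, 410, 77] + [32767] * 240 + [50, 61, 52, 40, 3]
        runs = detect_plateaus(mk_series(c))
        assert len(runs) == 1 and runs[0].is_saturation and runs[0].length == 240

    def test_zero_runs_ignored(self):
        assert detect_plateaus(mk_series([0] * 500)) == []

    def test_matches_exhaustive_scan(self):
        # every index triple flagged by brute force lies inside a reported run
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(3, 2000))
            c = rng.integers(0, 15, n)
            runs = detect_plateaus(mk_series(c))
            covered = np.zeros(n, bool)
            for r in runs:
                covered[r.start_index: r.start_index + r.length] = True
            brute = np.zeros(n, bool)
            for i in range(n - 2):
                if c[i] >= 10 and c[i] == c[i + 1] == c[i + 2]:
                    brute[i:i + 3] = True
            assert np.array_equal(covered, brute)


class TestTemporalShift:
    def test_rotated_profile_recovered(self):
        s = day_active_series()
        shifted, _ = inject_artifact(s, "temporal_shift",
                                     {"shift_hours": 6}, seed=0)
        mask = detect_nonwear(shifted)
        fired, lag, ev = detect_temporal_shift(shifted, mask)
        assert fired and lag == 6

    def test_unrotated_profile_not_flagged(self):
        s = day_active_series()
        fired, lag, _ = detect_temporal_shift(s, detect_nonwear(s))
        assert not fired and lag is None

    def test_night_activity_on_one_day_only(self):
        s = day_active_series(days=5)
        c = s.counts.copy()
        c[2 * 1440 + 120: 2 * 1440 + 180] = 500  # 02:00 on day 3 only
        s2 = s.replace(counts=c)
        fired, _, _ = detect_temporal_shift(s2, detect_nonwear(s2))
        assert not fired

    def test_insufficient_days(self):
        s = mk_series(np.ones(1440, dtype=int), start=MIDNIGHT)
        fired, lag, ev = detect_temporal_shift(s, detect_nonwear(s))
        assert not fired and lag is None
        assert "insufficient" in ev[0].detail

    @pytest.mark.parametrize("hours", [6, 9, 11])
    def test_lag_estimate_tracks_injection(self, hours):
        s = day_active_series()
        shifted, _ = inject_artifact(s, "temporal_shift",
                                     {"shift_hours": hours}, seed=0)
        _, lag, _ = detect_temporal_shift(shifted, detect_nonwear(shifted))
        assert lag == hours


class TestClassify:
    def test_all_zero_file_is_no_wear(self):
        s = mk_series(np.zeros(2880, dtype=int), start=MIDNIGHT)
        rep = classify_file(s, detect_nonwear(s))
        assert rep.flag is FileFlag.NO_WEAR

    def test_saturation_plateau_is_spurious(self):
        s = day_active_series()
        bad, _ = inject_artifact(s, "saturation_plateau", seed=1)
        rep = classify_file(bad, detect_nonwear(bad))
        assert rep.flag is FileFlag.SPURIOUS
        assert any(e.rule_id == "plateau" for e in rep.evidence)

    def test_baseline_floor_is_spurious(self):
        s = day_active_series()
        bad, _ = inject_artifact(s, "no_baseline_return", seed=1)
        rep = classify_file(bad, detect_nonwear(bad))
        assert rep.flag is FileFlag.SPURIOUS

    def test_clean_file_ok_with_empty_evidence(self):
        s = day_active_series()
        rep = classify_file(s, detect_nonwear(s))
        assert rep.flag is FileFlag.OK and rep.evidence == ()

    def test_shift_outranks_spurious(self):
        s = day_active_series()
        bad, _ = inject_artifact(s, "temporal_shift", seed=2)
        c = bad.counts.copy()
        c[1200:1203] = 15  # add a plateau inside the displaced activity
        bad = bad.replace(counts=c)
        rep = classify_file(bad, detect_nonwear(bad))
        assert rep.flag is FileFlag.TEMPORALLY_SHIFTED
        assert any(e.rule_id == "plateau" for e in rep.evidence)

    def test_pure_function(self):
        s = day_active_series()
        m = detect_nonwear(s)
        assert classify_file(s, m) == classify_file(s, m)


class TestBaselineFloor:
    def test_fires_only_when_every_night_nonzero(self):
        s = day_active_series(days=3)
        c = s.counts.copy()
        c[:5 * 60] += 30
        c[1440: 1440 + 5 * 60] += 30  # day 3 night left at zero
        assert detect_baseline_floor(s.replace(counts=c)) == []
        c[2 * 1440: 2 * 1440 + 5 * 60] += 30
        assert detect_baseline_floor(s.replace(counts=c)) != []


class TestAttrition:
    def test_accounting_identity(self, mixed_cohort):
        reports = []
        for s in mixed_cohort.files:
            reports.append(classify_file(s, detect_nonwear(s)))
        acct = attrition(reports)
        assert acct["total"] == (
            acct["viable"] + acct["duplicate_dropped"]
            + acct["missing_phenotype"] + acct["no_wear"] + acct["corrupt"]
            + acct["excluded_flagged"])
        assert acct["total"] == len(mixed_cohort.files)
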