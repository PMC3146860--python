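import datetime as dt

import numpy as np
import pandas as pd
import pytest

from accelpool import (CUTPOINT_REGISTRY, CutpointSet, TimeWindow, WearMask,
                       bout_minutes, classify_intensity, data_dictionary,
                       hourly_windows, summarize_series, window_summaries)
from accelpool.summarize import LIGHT, MODERATE, NONWEAR, SEDENTARY, VIGOROUS
from conftest import mk_series

CP = CutpointSet("test", 100, 2000, 4000)
MIDNIGHT = dt.datetime(2004, 4, 5, 0, 0)


class TestCutpointSet:
    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            CutpointSet("bad", 100, 100, 4000)

    @pytest.mark.parametrize("count,code", [
        (0, SEDENTARY), (99, SEDENTARY),
        (100, LIGHT), (1999, LIGHT),
        (2000, MODERATE),  # lower bound inclusive
        (3999, MODERATE), (4000, VIGOROUS), (32767, VIGOROUS)])
    def test_interval_membership(self, count, code):
        assert CP.classify(np.array([count]))[0] == code

    def test_registry_entries_valid(self):
        for cs in CUTPOINT_REGISTRY.values():
            assert cs.light < cs.moderate < cs.vigorous
            assert cs.citation


class TestClassifyIntensity:
    def test_nonwear_zero_is_not_sedentary(self):
        s = mk_series([0, 0, 150], start=MIDNIGHT)
        labels = classify_intensity(s, WearMask([False, True, True]), CP)
        assert list(labels) == [NONWEAR, SEDENTARY, LIGHT]

    def test_mask_must_align(self):
        with pytest.raises(ValueError):
            classify_intensity(mk_series([1, 2]), WearMask([True]), CP)


class TestBouts:
    @staticmethod
    def _labels(run_lengths, gap=3):
        out = []
        for length in run_lengths:
            out += [MODERATE] * length + [SEDENTARY] * gap
        return np.array(out, dtype=np.int8)

    def test_bins_by_run_length(self):
        got = bout_minutes(self._labels([5, 12, 3]))
        assert got == {"short": 8, "long": 12}

    def test_ten_minute_bout_in_upper_bin(self):
        assert bout_minutes(self._labels([10])) == {"short": 0, "long": 10}

    def test_nonwear_breaks_bouts(self):
        lab = np.array([MODERATE] * 6 + [NONWEAR] + [MODERATE] * 6,
                       dtype=np.int8)
        assert bout_minutes(lab) == {"short": 12, "long": 0}

    def test_vigorous_counts_toward_mvpa(self):
        lab = np.array([MODERATE, VIGOROUS, MODERATE] * 4, dtype=np.int8)
        assert bout_minutes(lab) == {"short": 0, "long": 12}

    def test_tolerance_bridges_single_gap(self):
        lab = self._labels([6], gap=1)
        lab = np.concatenate([lab, self._labels([6], gap=0)])
        assert bout_minutes(lab, tolerance=1) == {"short": 0, "long": 13}

    def test_bout_partition_against_run_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            lab = rng.choice(
                [NONWEAR, SEDENTARY, LIGHT, MODERATE, VIGOROUS],
                size=int(rng.integers(1, 500))).astype(np.int8)
            got = bout_minutes(lab)
            assert got["short"] + got["long"] == int((lab >= MODERATE).sum())


class TestWindows:
    def test_0859_belongs_to_hr9(self):
        hr9 = hourly_windows()[8]
        assert hr9.label == "hr9"
        assert hr9.contains(dt.time(8, 59)) and not hr9.contains(dt.time(9, 0))

    def test_hourly_partition_of_day(self):
        rng = np.random.default_rng(4)
        c = rng.integers(0, 3000, 1440)
        s = mk_series(c, start=MIDNIGHT)
        mask = WearMask(rng.random(1440) < 0.8)
        labels = classify_intensity(s, mask, CP)
        ws = window_summaries(s, mask, labels, hourly_windows())
        assert ws["wear_min"].sum() == mask.wear_minutes
        for cat in ("sedentary", "light", "moderate", "vigorous"):
            assert ws[f"{cat}_min"].sum() == int(
                (labels == {"sedentary": 0, "light": 1, "moderate": 2,
                            "vigorous": 3}[cat]).sum())

    def test_custom_window_minutes(self):
        w = TimeWindow("commute", dt.time(7, 30), dt.time(8, 30))
        c = np.zeros(1440, dtype=int)
        c[7 * 60 + 30: 8 * 60 + 30] = 500
        s = mk_series(c, start=MIDNIGHT)
        mask = WearMask(np.ones(1440, bool))
        labels = classify_intensity(s, mask, CP)
        ws = window_summaries(s, mask, labels, [w])
        assert int(ws["light_min"].iloc[0]) == 60

    def test_midnight_wrapping_window(self):
        w = TimeWindow("night", dt.time(23, 0), dt.time(1, 0))
        assert w.contains(dt.time(23, 30)) and w.contains(dt.time(0, 30))
        assert not w.contains(dt.time(2, 0))

    def test_overlap_logged(self):
        log = []
        s = mk_series(np.zeros(60, dtype=int), start=MIDNIGHT)
        mask = WearMask(np.ones(60, bool))
        labels = classify_intensity(s, mask, CP)
        window_summaries(s, mask, labels, [
            TimeWindow("a", dt.time(0, 0), dt.time(0, 40)),
            TimeWindow("b", dt.time(0, 30), dt.time(1, 0))], log=log)
        assert log


class TestSummarizeDay:
    def test_all_wear_sedentary_day(self):
        s = mk_series(np.zeros(1440, dtype=int), start=MIDNIGHT)
        summ = summarize_series(s, WearMask(np.ones(1440, bool)), [CP])
        row = summ.iloc[0]
        assert row["test_sedentary_min"] == 1440
        assert row["test_mvpa_min"] == 0
        assert row["test_mvpa_bout_lt10_min"] == 0
        assert row["valid_8h"] and row["valid_12h"]

    def test_zero_wear_day(self):
        s = mk_series(np.zeros(1440, dtype=int), start=MIDNIGHT)
        summ = summarize_series(s, WearMask(np.zeros(1440, bool)), [CP])
        row = summ.iloc[0]
        assert row["wear_minutes"] == 0 and row["test_sedentary_min"] == 0
        assert not row["valid_8h"]

    def test_partitions_and_mean_identity(self, clean_cohort):
        cats = ("sedentary", "light", "moderate", "vigorous")
        sets = list(CUTPOINT_REGISTRY.values())
        for s in clean_cohort.files[:3]:
            mask = WearMask(clean_cohort.truth.files[s.source_name].wear)
            summ = summarize_series(s, mask, sets)
            for _, row in summ.iterrows():
                for cs in sets:
                    total = sum(row[f"{cs.name}_{c}_min"] for c in cats)
                    assert total == row["wear_minutes"]
                    assert (row[f"{cs.name}_mvpa_bout_lt10_min"]
                            + row[f"{cs.name}_mvpa_bout_10plus_min"]
                            == row[f"{cs.name}_mvpa_min"])
                # exact integer identity: mean * wear = total counts
                assert (row["counts_per_wear_minute"] * row["wear_minutes"]
                        == pytest.approx(row["total_counts"]))

    def test_cutpoint_choice_never_changes_wear(self, clean_cohort):
        s = clean_cohort.files[0]
        mask = WearMask(clean_cohort.truth.files[s.source_name].wear)
        a = summarize_series(s, mask, [CUTPOINT_REGISTRY["evenson_2008"]])
        b = summarize_series(s, mask, [CUTPOINT_REGISTRY["puyau_2002"]])
        assert (a["wear_minutes"] == b["wear_minutes"]).all()

    def test_truth_minutes_recovered(self, clean_cohort):
        cs = CUTPOINT_REGISTRY["evenson_2008"]
        for s in clean_cohort.files[:4]:
            truth = clean_cohort.truth.files[s.source_name]
            summ = summarize_series(s, WearMask(truth.wear), [cs])
            for _, row in summ.iterrows():
                want = truth.intensity_minutes.loc[row["date"]]
                for cat in ("sedentary", "light", "moderate", "vigorous"):
                    assert row[f"{cs.name}_{cat}_min"] == want[cat]


def test_data_dictionary_covers_summary_columns(clean_cohort):
    sets = [CUTPOINT_REGISTRY["evenson_2008"]]
    s = clean_cohort.files[0]
    mask = WearMask(clean_cohort.truth.files[s.source_name].wear)
    summ = summarize_series(s, mask, sets)
    documented = set(data_dictionary(sets)["variable"])
    assert set(summ.columns) <= documented
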