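"""Outcome variables: intensity minutes, bouts and clock-window summaries.

Wear minutes are mapped to intensity categories (sedentary, light,
moderate, vigorous) by counts-per-minute cutpoints.  Because there is no
consensus cutpoint set for children, the registry ships several widely
used sets and summaries can be produced under all of them at once.
MVPA (moderate + vigorous) minutes are additionally accumulated by bout
duration (bouts shorter than 10 min vs 10+ min), and all intensity
variables are reported for clock windows: the 24 on-the-hour windows
hr1..hr24 plus any custom windows (school commute, lunch, recess, ...)
supplied through configuration.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import EpochSeries, require_minute_epochs
from .wear import WearMask

#: integer codes for per-minute labels
NONWEAR, SEDENTARY, LIGHT, MODERATE, VIGOROUS = -1, 0, 1, 2, 3
CATEGORIES = ("sedentary", "light", "moderate", "vigorous")
_CODE = {name: i for i, name in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class CutpointSet:
    """Counts-per-minute thresholds partitioning [0, inf) into intensities.

    ``light``, ``moderate`` and ``vigorous`` are the (inclusive) lower
    bounds of those categories; sedentary is [0, light).  Intervals are
    lower-bound inclusive, contiguous and exhaustive.
    """

    name: str
    light: int
    moderate: int
    vigorous: int
    age_range: tuple | None = None
    citation: str = ""

    def __post_init__(self):
        if not 0 < self.light < self.moderate < self.vigorous:
            raise ValueError(
                f"{self.name}: boundaries must be strictly increasing and "
                "positive")

    @property
    def boundaries(self) -> tuple:
        return (self.light, self.moderate, self.vigorous)

    def classify(self, counts: np.ndarray) -> np.ndarray:
        """Category code (0..3) for each count; lower bounds inclusive."""
        return np.searchsorted(
            np.asarray(self.boundaries), np.asarray(counts), side="right"
        ).astype(np.int8)


#: widely used child/adolescent cutpoint sets (counts/min at 60-s epochs)
CUTPOINT_REGISTRY: dict[str, CutpointSet] = {
    cs.name: cs
    for cs in (
        CutpointSet("evenson_2008", 100, 2296, 4012, (5, 15),
                    "Evenson et al. 2008, J Sports Sci 26:1557-65"),
        CutpointSet("mattocks_2007", 100, 3581, 6130, (10, 14),
                    "Mattocks et al. 2007, J Phys Act Health 4:S98-106"),
        CutpointSet("puyau_2002", 800, 3200, 8200, (6, 16),
                    "Puyau et al. 2002, Obes Res 10:150-7"),
    )
}


@dataclass(frozen=True)
class TimeWindow:
    """A half-open clock window [start, end); may wrap midnight."""

    label: str
    start: dt.time
    end: dt.time

    def __post_init__(self):
        if self.start == self.end:
            raise ValueError(f"{self.label}: start and end must differ")

    def contains(self, t: dt.time) -> bool:
        if self.start < self.end:
            return self.start <= t < self.end
        return t >= self.start or t < self.end  # wraps midnight


def hourly_windows() -> list[TimeWindow]:
    """The 24 on-the-hour windows hr1..hr24 ([00:00,01:00) .. [23:00,24:00))."""
    out = []
    for h in range(24):
        end = dt.time(0, 0) if h == 23 else dt.time(h + 1, 0)
        out.append(TimeWindow(f"hr{h + 1}", dt.time(h, 0), end))
    return out


def classify_intensity(
    series: EpochSeries,
    mask: WearMask,
    cutpoints: CutpointSet,
) -> np.ndarray:
    """Per-minute intensity codes; non-wear minutes are coded -1.

    Non-wear zeros are excluded — they are never counted as sedentary.
    """
    require_minute_epochs(series, "classify_intensity")
    if len(series) != len(mask):
        raise ValueError("mask not aligned to series")
    labels = cutpoints.classify(series.counts).astype(np.int8)
    labels[~mask.wear] = NONWEAR
    return labels


@dataclass(frozen=True)
class BoutBins:
    """Duration bins for bout-accumulated minutes: [1,10) and [10,inf)."""

    short_max: int = 10  # exclusive upper edge of the short bin


def bout_minutes(
    labels: np.ndarray,
    target: str = "moderate",
    bins: BoutBins = BoutBins(),
    tolerance: int = 0,
) -> dict[str, int]:
    """Minutes accumulated in bouts at/above ``target`` intensity.

    A bout is a maximal run of consecutive minutes at or above the target
    (MVPA when target is ``moderate``), with at most ``tolerance``
    below-target interruption minutes (default 0, the strictest reading);
    non-wear always breaks a bout.  Each bout's full length accrues to
    the bin containing its duration: ``short`` = [1, 10) min, ``long`` =
    [10, inf) min.
    """
    code = _CODE[target]
    at_or_above = np.asarray(labels) >= code
    runs = _runs_with_tolerance(at_or_above, np.asarray(labels) == NONWEAR,
                                tolerance)
    out = {"short": 0, "long": 0}
    for length in runs:
        out["long" if length >= bins.short_max else "short"] += length
    return out


def _runs_with_tolerance(hit: np.ndarray, hard_break: np.ndarray,
                         tolerance: int) -> list[int]:
    """Lengths of maximal hit-runs, allowing `tolerance` soft gaps inside."""
    if tolerance == 0:
        padded = np.concatenate([[False], hit, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        return list((edges[1::2] - edges[0::2]).astype(int))
    # scan: extend a bout across <= tolerance non-hit, non-break minutes
    runs, n = [], len(hit)
    i = 0
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j, gaps, last_hit = i, 0, i
        while j < n and not hard_break[j]:
            if hit[j]:
                last_hit = j
            else:
                gaps += 1
                if gaps > tolerance:
                    break
            j += 1
        runs.append(last_hit - i + 1)
        i = last_hit + 1
    return runs


def window_summaries(
    series: EpochSeries,
    mask: WearMask,
    labels: np.ndarray,
    windows: list[TimeWindow],
    log: list | None = None,
) -> pd.DataFrame:
    """Per-day, per-window wear and intensity minutes.

    A minute belongs to a window iff its start timestamp lies in
    [start, end).  Overlapping custom windows are allowed (minutes may
    count in several) and are noted in ``log``.
    """
    require_minute_epochs(series, "window_summaries")
    ts = series.timestamps()
    minute_of_day = ts.hour.values * 60 + ts.minute.values
    dates = ts.normalize().date

    if log is not None:
        cover = np.zeros(1440, dtype=int)
        for w in windows:
            sel = _window_selector(w)
            cover += sel
        if (cover > 1).any():
            log.append(
                f"{int((cover > 1).sum())} minute slots covered by more than "
                "one window")

    rows = []
    labels = np.asarray(labels)
    for w in windows:
        sel_lut = _window_selector(w)
        in_w = sel_lut[minute_of_day]
        for day in np.unique(dates):
            pick = in_w & (dates == day)
            lab = labels[pick]
            row = {
                "date": day, "window": w.label,
                "wear_min": int((lab != NONWEAR).sum()),
            }
            for name, code in _CODE.items():
                row[f"{name}_min"] = int((lab == code).sum())
            row["mvpa_min"] = row["moderate_min"] + row["vigorous_min"]
            rows.append(row)
    return pd.DataFrame(rows)


def _window_selector(w: TimeWindow) -> np.ndarray:
    """Boolean lookup over the 1440 minute-of-day slots."""
    lut = np.zeros(1440, dtype=bool)
    s = w.start.hour * 60 + w.start.minute
    e = w.end.hour * 60 + w.end.minute
    if e == 0:
        e = 1440
    if s < e:
        lut[s:e] = True
    else:
        lut[s:] = True
        lut[:e] = True
    return lut


def summarize_series(
    series: EpochSeries,
    mask: WearMask,
    cutpoint_sets: list[CutpointSet] | None = None,
    windows: list[TimeWindow] | None = None,
    criteria=(8, 10, 12),
) -> pd.DataFrame:
    """Assemble the per-day outcome table for one file.

    One row per monitored calendar day with: wear and monitored minutes,
    mean counts per wear minute, per cutpoint set the minutes in each
    intensity and the MVPA bout-bin minutes, and the valid flag at each
    wear criterion.  Hourly/custom window summaries are produced
    separately by :func:`window_summaries`.
    """
    require_minute_epochs(series, "summarize_series")
    if cutpoint_sets is None:
        cutpoint_sets = [CUTPOINT_REGISTRY["evenson_2008"]]
    ts = series.timestamps()
    dates = ts.normalize().date
    counts = series.counts

    all_labels = {cs.name: classify_intensity(series, mask, cs)
                  for cs in cutpoint_sets}

    rows = []
    for day in pd.unique(dates):
        pick = dates == day
        wear_sel = mask.wear[pick]
        wear_min = int(wear_sel.sum())
        total_counts = int(counts[pick][wear_sel].sum())
        row = {
            "file_key": series.file_key,
            "date": day,
            "monitored_minutes": int(pick.sum()),
            "wear_minutes": wear_min,
            "total_counts": total_counts,
            "counts_per_wear_minute":
                (total_counts / wear_min) if wear_min else 0.0,
        }
        for cs in cutpoint_sets:
            lab = all_labels[cs.name][pick]
            for name, code in _CODE.items():
                row[f"{cs.name}_{name}_min"] = int((lab == code).sum())
            row[f"{cs.name}_mvpa_min"] = (
                row[f"{cs.name}_moderate_min"] + row[f"{cs.name}_vigorous_min"])
            bouts = bout_minutes(lab, "moderate")
            row[f"{cs.name}_mvpa_bout_lt10_min"] = bouts["short"]
            row[f"{cs.name}_mvpa_bout_10plus_min"] = bouts["long"]
        for crit in criteria:
            row[f"valid_{crit}h"] = wear_min >= crit * 60
        rows.append(row)
    return pd.DataFrame(rows)


def data_dictionary(
    cutpoint_sets: list[CutpointSet],
    criteria=(8, 10, 12),
) -> pd.DataFrame:
    """Machine-readable definitions of every per-day summary column."""
    rows = [
        ("file_key", "study|participant|wave|serial|filename identity key"),
        ("date", "local-clock calendar day (midnight to midnight)"),
        ("monitored_minutes", "minutes of data recorded on the day"),
        ("wear_minutes", "minutes labeled wear by the 60-min/2-interruption"
                         " non-wear rule"),
        ("total_counts", "sum of counts over wear minutes"),
        ("counts_per_wear_minute", "total_counts / wear_minutes"),
    ]
    for cs in cutpoint_sets:
        bounds = (f"sed [0,{cs.light}), light [{cs.light},{cs.moderate}), "
                  f"mod [{cs.moderate},{cs.vigorous}), vig [{cs.vigorous},inf)"
                  "; lower bounds inclusive")
        for name in CATEGORIES:
            rows.append((f"{cs.name}_{name}_min",
                         f"wear minutes in {name} under {cs.name} "
                         f"({bounds}; {cs.citation})"))
        rows.append((f"{cs.name}_mvpa_min",
                     f"moderate + vigorous minutes under {cs.name}"))
        rows.append((f"{cs.name}_mvpa_bout_lt10_min",
                     "MVPA minutes accumulated in bouts of 1-9 min "
                     "(0 interruption tolerance)"))
        rows.append((f"{cs.name}_mvpa_bout_10plus_min",
                     "MVPA minutes accumulated in bouts of >= 10 min"))
    for crit in criteria:
        rows.append((f"valid_{crit}h",
                     f"wear_minutes >= {crit * 60} (>= {crit} h criterion)"))
    return pd.DataFrame(rows, columns=["variable", "definition"])
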