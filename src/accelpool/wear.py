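"""Wear/non-wear segmentation and valid-day accounting.

A monitor is considered not worn wherever a window of at least 60
consecutive minutes of zero counts occurs, allowing up to 2 minutes of
non-zero interruptions inside the window.  Non-wear zeros are separated
from legitimate sedentary zeros so that only worn time contributes to
outcome variables.  Days are local-clock calendar days; a day is *valid*
when its wear time meets a minimum-hours criterion (8, 10 or 12 h in the
standard analyses).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import EpochSeries, require_minute_epochs

#: minimum non-wear window length, minutes
NONWEAR_WINDOW = 60
#: maximum non-zero interruption minutes tolerated inside a window
MAX_INTERRUPTIONS = 2

AGE_BINS = ((3, 5), (6, 8), (9, 11), (12, 14), (15, 18))


@dataclass
class WearMask:
    """Per-epoch wear labels aligned to a 60-s-epoch series.

    ``wear`` is a boolean array: True = worn, False = non-wear.
    """

    wear: np.ndarray

    def __post_init__(self):
        self.wear = np.asarray(self.wear, dtype=bool)

    def __len__(self) -> int:
        return int(self.wear.size)

    @property
    def wear_minutes(self) -> int:
        return int(self.wear.sum())

    def runs(self) -> list[tuple[int, int, str]]:
        """Run-length encoding: (start, end, 'wear'|'nonwear'), end half-open."""
        if len(self) == 0:
            return []
        w = self.wear
        change = np.flatnonzero(w[1:] != w[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(w)]])
        return [
            (int(s), int(e), "wear" if w[s] else "nonwear")
            for s, e in zip(starts, ends)
        ]


@dataclass(frozen=True)
class DayWear:
    """Wear accounting for one monitored calendar day."""

    date: dt.date
    wear_minutes: int
    monitored_minutes: int

    def __post_init__(self):
        if not 0 <= self.wear_minutes <= self.monitored_minutes <= 1440:
            raise ValueError(
                f"need 0 <= wear ({self.wear_minutes}) <= monitored "
                f"({self.monitored_minutes}) <= 1440"
            )


def detect_nonwear(
    series: EpochSeries,
    window: int = NONWEAR_WINDOW,
    max_interruptions: int = MAX_INTERRUPTIONS,
    interruption_cap: int | None = None,
) -> WearMask:
    """Label each minute of a 60-s-epoch series as wear or non-wear.

    A minute is non-wear iff it lies in some window of length >= ``window``
    whose first and last minutes are zero and which contains at most
    ``max_interruptions`` non-zero minutes (all interior).  Interruption
    minutes inside a qualifying window are themselves non-wear; qualifying
    windows are unioned.  ``interruption_cap``, if given, restricts which
    counts may serve as interruptions (counts above the cap break a
    window); by default any non-zero count can be an interruption.

    Runs in O(n) via a two-pointer sweep; equivalent to the exhaustive
    :func:`nonwear_oracle`.
    """
    require_minute_epochs(series, "detect_nonwear")
    c = series.counts
    n = len(c)
    mask = np.ones(n, dtype=bool)  # True = wear
    if n == 0:
        return WearMask(mask)

    # minutes that may NOT appear inside a window at all
    if interruption_cap is None:
        blocker = np.zeros(n, dtype=bool)
    else:
        blocker = c > interruption_cap
    nonzero = (c != 0) & ~blocker

    # prefix sums of countable interruptions
    nz_prefix = np.concatenate([[0], np.cumsum(nonzero)])
    is_zero = c == 0
    # last zero index at or before i
    last_zero = np.where(is_zero, np.arange(n), -1)
    np.maximum.accumulate(last_zero, out=last_zero)

    marked_until = 0
    k = 0  # exclusive right frontier
    for i in range(n):
        if not is_zero[i]:
            continue
        if k < i + 1:
            k = i + 1
        # extend frontier while interruption budget and no blocker
        while k < n and not blocker[k] and nz_prefix[k + 1] - nz_prefix[i] <= max_interruptions:
            k += 1
        j_end = last_zero[k - 1]  # last zero in [i, k)
        if j_end - i + 1 >= window:
            lo = max(i, marked_until)
            if lo <= j_end:
                mask[lo: j_end + 1] = False
                marked_until = j_end + 1
    return WearMask(mask)


def nonwear_oracle(
    counts,
    window: int = NONWEAR_WINDOW,
    max_interruptions: int = MAX_INTERRUPTIONS,
) -> WearMask:
    """Exhaustive O(n^2) reference for the non-wear rule (tests only).

    Enumerates every window ``[i, j)`` with ``j - i >= window``, zero first
    and last minutes, and at most ``max_interruptions`` non-zero interior
    minutes, and marks the union non-wear.  Quadratic in memory and time;
    intended for sequences up to a few thousand minutes.
    """
    c = np.asarray(counts, dtype=np.int64)
    n = len(c)
    mask = np.ones(n, dtype=bool)
    if n < window:
        return WearMask(mask)
    z = c == 0
    nz_prefix = np.concatenate([[0], np.cumsum(c != 0)])

    i_idx = np.arange(n)[:, None]          # window start
    j_idx = np.arange(1, n + 1)[None, :]   # window end, exclusive
    qualifies = (
        (j_idx - i_idx >= window)
        & z[:, None]                       # first minute zero
        & z[j_idx - 1]                     # last minute zero
        & ((nz_prefix[j_idx] - nz_prefix[i_idx]) <= max_interruptions)
    )
    any_row = qualifies.any(axis=1)
    if any_row.any():
        # column m of `qualifies` is window end j = m + 1; the furthest
        # qualifying end for row i is the last True column + 1
        jmax = np.where(
            any_row, n - np.argmax(qualifies[:, ::-1], axis=1), -1
        )
        diff = np.zeros(n + 1, dtype=np.int64)
        for i in np.flatnonzero(any_row):
            diff[i] += 1
            diff[jmax[i]] -= 1
        covered = np.cumsum(diff[:-1]) > 0
        mask[covered] = False
    return WearMask(mask)


def day_wear(series: EpochSeries, mask: WearMask) -> list[DayWear]:
    """Per-calendar-day wear minutes (local clock, midnight to midnight).

    Partial first/last days are reported with their true monitored
    minutes.
    """
    require_minute_epochs(series, "day_wear")
    if len(series) != len(mask):
        raise ValueError("mask is not aligned to series")
    if len(series) == 0:
        return []
    dates = series.timestamps().normalize()
    df = pd.DataFrame({"date": dates.date, "wear": mask.wear})
    out = []
    for date, grp in df.groupby("date", sort=True):
        out.append(DayWear(
            date=date,
            wear_minutes=int(grp["wear"].sum()),
            monitored_minutes=int(len(grp)),
        ))
    return out


@dataclass(frozen=True)
class ValidDayResult:
    """Valid-day evaluation of one file at one wear criterion."""

    criterion_hours: float
    valid: tuple
    n_valid: int
    has_1: bool
    has_4: bool


def valid_days(days: list[DayWear], criterion_hours: float) -> ValidDayResult:
    """Evaluate the valid-day criterion: wear >= criterion_hours * 60 min."""
    flags = tuple(d.wear_minutes >= criterion_hours * 60 for d in days)
    n = sum(flags)
    return ValidDayResult(criterion_hours, flags, n, n >= 1, n >= 4)


def _age_bin(age: float) -> str | None:
    for lo, hi in AGE_BINS:
        if lo <= age <= hi:
            return f"{lo} to {hi}"
    return None


def tabulate_valid_day_distribution(
    cohort: pd.DataFrame,
    criteria=(8, 10, 12),
    max_days: int = 7,
) -> pd.DataFrame:
    """Distribution of valid-day counts by sex, age group and criterion.

    ``cohort`` has one baseline row per participant with columns ``sex``,
    ``age`` and one column per criterion named ``n_valid_{c}h`` (e.g.
    ``n_valid_8h``).  Valid-day counts are capped at ``max_days`` for
    tabulation.  The result has one row per (sex, age group, criterion)
    plus an overall row per (sex, criterion), with percentage columns
    ``0``..``7``, ``ge1`` and ``ge4``; rows sum to 100% over 0..7, and the
    structural identities ``ge1 = 100 - P(0)`` and ``ge4 = P(4)+..+P(7)``
    hold by construction.  Empty sex/age cells are absent from the output.
    """
    df = cohort.copy()
    df["age_bin"] = df["age"].map(_age_bin)
    df = df[df["age_bin"].notna()]

    rows = []
    bin_labels = [f"{lo} to {hi}" for lo, hi in AGE_BINS]
    for sex, sex_grp in df.groupby("sex", sort=True):
        for crit in criteria:
            col = f"n_valid_{crit}h"
            capped_all = sex_grp[col].clip(upper=max_days)
            for label in bin_labels:
                grp = capped_all[sex_grp["age_bin"] == label]
                if len(grp) == 0:
                    continue
                rows.append(_distribution_row(sex, label, crit, grp, max_days))
            rows.append(_distribution_row(sex, "overall", crit, capped_all, max_days))
    out = pd.DataFrame(rows)
    return out.set_index(["sex", "age_bin", "criterion"])


def _distribution_row(sex, label, crit, capped: pd.Series, max_days: int) -> dict:
    n = len(capped)
    pct = {
        str(k): 100.0 * (capped == k).sum() / n for k in range(max_days + 1)
    }
    row = {"sex": sex, "age_bin": label, "criterion": crit, "n": n, **pct}
    row["ge1"] = 100.0 * (capped >= 1).sum() / n
    row["ge4"] = 100.0 * (capped >= 4).sum() / n
    return row


def write_wear_mask(series: EpochSeries, mask: WearMask, path) -> None:
    """Export a wear mask as run-length-encoded tab-separated text."""
    pd.DataFrame(
        [(series.file_key, s, e, lab) for s, e, lab in mask.runs()],
        columns=["file_key", "start_epoch", "end_epoch", "label"],
    ).to_csv(path, sep="\t", index=False)
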