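"""File-quality flagging: duplicates, artifacts and attrition accounting.

Every deposited file receives exactly one flag.  Files that cannot be
parsed are CORRUPT; files with zero wear time are NO_WEAR; recordings
whose timestamps are offset by whole hours (activity at night, long zero
runs in the day, on every monitored day) are TEMPORALLY_SHIFTED; device
malfunctions — count plateaus (3+ identical consecutive counts at a value
>= 10, most often at the 32767 saturation ceiling) and night counts that
never return to baseline zero — are SPURIOUS.  Duplicate files for the
same participant are resolved before flagging: a non-corrupt file beats a
corrupt one, otherwise the first-labeled file wins.

The original adjudication of overnight wear was by visual graphing with
four possible causes (legitimate overnight wear, temporal shift, no
return to baseline, malfunctioned unit); here the shift, baseline-floor
and plateau detectors stand in for the visual step so the classification
is deterministic.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .series import (SATURATION_CEILING, CorruptFileError, EpochSeries,
                     complete_day_slices, require_minute_epochs)
from .wear import WearMask


class FileFlag(str, Enum):
    OK = "OK"
    SPURIOUS = "SPURIOUS"
    TEMPORALLY_SHIFTED = "TEMPORALLY_SHIFTED"
    CORRUPT = "CORRUPT"
    NO_WEAR = "NO_WEAR"
    DUPLICATE_DROPPED = "DUPLICATE_DROPPED"
    MISSING_PHENOTYPE = "MISSING_PHENOTYPE"


#: flags that exclude a file from the viable analysis set outright
HARD_EXCLUSION_FLAGS = frozenset(
    {FileFlag.CORRUPT, FileFlag.NO_WEAR, FileFlag.DUPLICATE_DROPPED,
     FileFlag.MISSING_PHENOTYPE}
)
#: flags retained in the database but marked excluded-by-default
SOFT_EXCLUSION_FLAGS = frozenset(
    {FileFlag.SPURIOUS, FileFlag.TEMPORALLY_SHIFTED}
)


@dataclass(frozen=True)
class Evidence:
    """One rule firing: which rule, where, and a human-readable detail."""

    rule_id: str
    start_epoch: int
    end_epoch: int  # half-open; (0, 0) when no span applies
    detail: str


@dataclass(frozen=True)
class FlagReport:
    """Per-file quality classification with supporting evidence.

    ``flag`` is the single precedence-resolved flag; ``evidence`` lists
    every rule that fired, including those of lower precedence.  A file is
    OK iff no rule fired.
    """

    file_key: str
    flag: FileFlag
    evidence: tuple = ()


@dataclass(frozen=True)
class PlateauRun:
    """A maximal run of >= 3 identical consecutive counts at value >= 10."""

    start_index: int
    length: int
    value: int

    def __post_init__(self):
        if self.length < 3 or self.value < 10:
            raise ValueError("plateau runs require length >= 3 and value >= 10")

    @property
    def is_saturation(self) -> bool:
        return self.value == SATURATION_CEILING


@dataclass(frozen=True)
class CorruptFile:
    """Marker for a file that failed to parse (stands in for the series)."""

    file_key: str
    source_name: str
    error: str


@dataclass(frozen=True)
class CleaningConfig:
    """Tunable thresholds for the automated flag rules.

    overnight_min_minutes / overnight_hours / overnight_per_hour
        The overnight-wear trigger: >= 10 wear minutes within any single
        clock hour among 02-03, 03-04, 04-05 (per-hour reading); set
        ``overnight_per_hour=False`` to sum across the three hours
        instead.
    night_block / day_block
        Clock-hour spans used by the temporal-shift symptom test.
    shift_night_active_min
        Minimum non-zero minutes in the night block, per day, for the
        shift symptom.
    shift_day_zero_run_min
        Minimum length (min) of the longest zero run in the day block,
        per day, for the shift symptom.
    shift_template_active
        Clock-hour span of the trapezoidal day-active template used for
        lag estimation (1-h linear ramps on each side).
    floor_min_value
        Minimum night-block count for the no-return-to-baseline rule; the
        rule fires when the night-block minimum is >= this on every
        complete day.
    """

    overnight_min_minutes: int = 10
    overnight_hours: tuple = (2, 3, 4)
    overnight_per_hour: bool = True
    night_block: tuple = (0, 5)
    day_block: tuple = (9, 18)
    shift_night_active_min: int = 10
    shift_day_zero_run_min: int = 180
    shift_template_active: tuple = (8, 20)
    floor_min_value: int = 1


DEFAULT_CLEANING = CleaningConfig()


# ---------------------------------------------------------------------------
# duplicate resolution

def resolve_duplicates(files: list) -> tuple[object, list[FlagReport]]:
    """Resolve a group of files deposited for the same participant.

    ``files`` may mix parsed :class:`EpochSeries` and :class:`CorruptFile`
    markers.  Exactly one entry is kept: if exactly one is non-corrupt it
    is used; if several are non-corrupt the first-labeled (lexicographic
    filename stem) is used; if all are corrupt the first-labeled is kept
    (and will be flagged CORRUPT downstream).  Dropped entries receive
    DUPLICATE_DROPPED reports naming the winner.
    """
    if not files:
        raise ValueError("empty duplicate group")
    ordered = sorted(files, key=lambda f: f.source_name)
    non_corrupt = [f for f in ordered if not isinstance(f, CorruptFile)]
    kept = non_corrupt[0] if non_corrupt else ordered[0]
    dropped = [
        FlagReport(
            f.file_key, FileFlag.DUPLICATE_DROPPED,
            (Evidence("duplicate", 0, 0,
                      f"duplicate of same participant; kept {kept.source_name}"),),
        )
        for f in ordered if f is not kept
    ]
    return kept, dropped


# ---------------------------------------------------------------------------
# individual rules

def detect_overnight_wear(
    series: EpochSeries,
    wear: WearMask,
    config: CleaningConfig = DEFAULT_CLEANING,
) -> list[Evidence]:
    """Overnight-wear trigger: >= 10 wear minutes at hrs 2, 3 and/or 4 am.

    Under the default per-hour reading the rule fires when, on any
    monitored calendar day, the wear minutes within any single clock hour
    among [02:00,03:00), [03:00,04:00), [04:00,05:00) total at least
    ``overnight_min_minutes``.  Returns one evidence item per (day, hour)
    firing; empty list if none.
    """
    require_minute_epochs(series, "detect_overnight_wear")
    if len(series) != len(wear):
        raise ValueError("wear mask not aligned")
    evidence = []
    ts = series.timestamps()
    hours = ts.hour.values
    dates = ts.normalize().date
    for day in np.unique(dates):
        on_day = dates == day
        per_hour = {}
        for h in config.overnight_hours:
            sel = on_day & (hours == h)
            per_hour[h] = int(wear.wear[sel].sum())
        if config.overnight_per_hour:
            fired = [h for h, m in per_hour.items()
                     if m >= config.overnight_min_minutes]
        else:
            fired = (list(per_hour) if sum(per_hour.values())
                     >= config.overnight_min_minutes else [])
        for h in fired:
            sel = np.flatnonzero(on_day & (hours == h))
            evidence.append(Evidence(
                "overnight_wear", int(sel[0]), int(sel[-1]) + 1,
                f"{per_hour[h] if config.overnight_per_hour else sum(per_hour.values())}"
                f" wear min, {day} hour {h:02d}",
            ))
    return evidence


def detect_plateaus(series: EpochSeries) -> list[PlateauRun]:
    """All maximal runs of >= 3 identical consecutive counts at value >= 10.

    Saturation runs (value 32767) are a malfunction signature and can be
    recognized via :attr:`PlateauRun.is_saturation`.
    """
    c = series.counts
    n = len(c)
    if n < 3:
        return []
    change = np.flatnonzero(c[1:] != c[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return [
        PlateauRun(int(s), int(e - s), int(c[s]))
        for s, e in zip(starts, ends)
        if e - s >= 3 and c[s] >= 10
    ]


def _longest_zero_run(values: np.ndarray) -> int:
    z = values == 0
    if not z.any():
        return 0
    padded = np.concatenate([[False], z, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return int((edges[1::2] - edges[0::2]).max())


def day_active_template(active: tuple = (8, 20)) -> np.ndarray:
    """Trapezoidal diurnal activity template over 1440 minutes.

    1.0 during the active clock span, 0 at night, with 1-hour linear
    ramps on each side.
    """
    t = np.zeros(1440)
    lo, hi = active[0] * 60, active[1] * 60
    t[lo:hi] = 1.0
    ramp = np.linspace(0.0, 1.0, 62)[1:-1]
    t[lo - 60: lo] = ramp
    t[hi: hi + 60] = ramp[::-1]
    return t


def detect_temporal_shift(
    series: EpochSeries,
    wear: WearMask,
    config: CleaningConfig = DEFAULT_CLEANING,
) -> tuple[bool, int | None, list[Evidence]]:
    """Detect whole-hour timestamp offsets.

    The symptom must hold on EVERY complete monitored day: the night
    block (default 00:00-05:00) contains substantial activity (>=
    ``shift_night_active_min`` non-zero minutes) and the day block
    (default 09:00-18:00) is dominated by a long zero run (>=
    ``shift_day_zero_run_min`` min).  The shift estimate is the circular
    whole-hour lag maximizing the correlation of the mean diurnal count
    profile against a trapezoidal day-active template; positive values
    mean the recorded activity appears that many hours late.

    Requires at least 2 complete days; otherwise ``(False, None, ...)``
    with insufficient-data evidence.
    """
    require_minute_epochs(series, "detect_temporal_shift")
    days = complete_day_slices(series)
    if len(days) < 2:
        return False, None, [Evidence(
            "temporal_shift", 0, 0,
            f"insufficient data: {len(days)} complete day(s), need >= 2")]

    n_lo, n_hi = config.night_block[0] * 60, config.night_block[1] * 60
    d_lo, d_hi = config.day_block[0] * 60, config.day_block[1] * 60
    for day, sl in days:
        block = series.counts[sl]
        night_active = int((block[n_lo:n_hi] != 0).sum())
        day_zero_run = _longest_zero_run(block[d_lo:d_hi])
        if (night_active < config.shift_night_active_min
                or day_zero_run < config.shift_day_zero_run_min):
            return False, None, []

    profile = np.mean(
        [series.counts[sl].astype(float) for _, sl in days], axis=0)
    template = day_active_template(config.shift_template_active)
    scores = np.array([
        float(np.dot(np.roll(profile, -60 * h), template)) for h in range(24)
    ])
    # when the active span is wider than the template the score has a
    # near-tie plateau of adjacent lags; take the plateau's midpoint
    near = scores >= scores.max() * (1 - 0.03)
    best = int(np.argmax(scores))
    lo = best
    while near[(lo - 1) % 24]:
        lo -= 1
        if lo == best - 23:
            break
    hi = best
    while near[(hi + 1) % 24]:
        hi += 1
        if hi == best + 23:
            break
    best = (lo + (hi - lo) // 2) % 24
    shift = best - 24 if best > 12 else best
    ev = [Evidence(
        "temporal_shift", 0, len(series),
        f"night activity + daytime zeros on all {len(days)} days; "
        f"estimated shift {shift:+d} h")]
    return True, shift, ev


def detect_baseline_floor(
    series: EpochSeries,
    config: CleaningConfig = DEFAULT_CLEANING,
) -> list[Evidence]:
    """Night counts that never return to baseline (zero).

    Fires when on every complete monitored day the minimum count within
    the night block is >= ``floor_min_value`` (i.e. the trace never
    touches zero at night) — the signature of a device offset rather than
    legitimate overnight wear, which shows interspersed zeros.  The
    numeric criterion is this package's own; the original adjudication
    was visual.
    """
    days = complete_day_slices(series)
    if not days:
        return []
    n_lo, n_hi = config.night_block[0] * 60, config.night_block[1] * 60
    mins = [int(series.counts[sl][n_lo:n_hi].min()) for _, sl in days]
    if all(m >= config.floor_min_value for m in mins):
        return [Evidence(
            "no_baseline_return", 0, len(series),
            f"night-block minimum count {min(mins)}..{max(mins)} > 0 on all "
            f"{len(days)} complete days")]
    return []


# ---------------------------------------------------------------------------
# classification

def classify_file(
    series: EpochSeries,
    wear: WearMask,
    config: CleaningConfig = DEFAULT_CLEANING,
) -> FlagReport:
    """Assign the single precedence-resolved flag for a parsed file.

    Precedence: NO_WEAR > TEMPORALLY_SHIFTED > SPURIOUS > OK (CORRUPT is
    assigned upstream at parse time and outranks everything).  SPURIOUS
    fires on plateau evidence or when overnight wear is attributed to a
    non-returning baseline; overnight wear with neither attribution is
    treated as legitimate and left OK (with its evidence recorded).  Pure
    function of its inputs.
    """
    evidence: list[Evidence] = []

    if wear.wear_minutes == 0:
        evidence.append(Evidence("no_wear", 0, len(series), "zero wear minutes"))
        return FlagReport(series.file_key, FileFlag.NO_WEAR, tuple(evidence))

    plateaus = detect_plateaus(series)
    for p in plateaus:
        tag = " (saturation)" if p.is_saturation else ""
        evidence.append(Evidence(
            "plateau", p.start_index, p.start_index + p.length,
            f"{p.length} consecutive counts at {p.value}{tag}"))

    overnight = detect_overnight_wear(series, wear, config)
    evidence.extend(overnight)

    shifted, shift_h, shift_ev = detect_temporal_shift(series, wear, config)
    evidence.extend(e for e in shift_ev if shifted)

    floor_ev = detect_baseline_floor(series, config) if overnight else []
    evidence.extend(floor_ev)

    if shifted:
        flag = FileFlag.TEMPORALLY_SHIFTED
    elif plateaus or floor_ev:
        flag = FileFlag.SPURIOUS
    else:
        flag = FileFlag.OK
    if flag is FileFlag.OK:
        # OK iff nothing fired; overnight evidence with no shift/floor/
        # plateau attribution means cause (i), legitimate overnight wear,
        # which is not an exclusionable firing
        evidence = [e for e in evidence if e.rule_id != "overnight_wear"]
    return FlagReport(series.file_key, flag, tuple(evidence))


def attrition(reports: list[FlagReport]) -> dict:
    """Attrition accounting over a batch of per-file reports.

    ``total = viable + duplicate_dropped + missing_phenotype + no_wear +
    corrupt + excluded_flagged`` where viable counts OK files and
    excluded_flagged counts spurious + temporally shifted files (retained
    in the database but marked excluded by default).
    """
    c = Counter(r.flag for r in reports)
    out = {
        "total": len(reports),
        "duplicate_dropped": c[FileFlag.DUPLICATE_DROPPED],
        "missing_phenotype": c[FileFlag.MISSING_PHENOTYPE],
        "no_wear": c[FileFlag.NO_WEAR],
        "corrupt": c[FileFlag.CORRUPT],
        "spurious": c[FileFlag.SPURIOUS],
        "temporally_shifted": c[FileFlag.TEMPORALLY_SHIFTED],
        "viable": c[FileFlag.OK],
    }
    out["excluded_flagged"] = out["spurious"] + out["temporally_shifted"]
    out["processed"] = out["viable"] + out["excluded_flagged"]
    return out


def write_flag_reports(reports: list[FlagReport], path) -> None:
    """Write flag reports as tab-separated text (one row per evidence item)."""
    rows = []
    for r in reports:
        if r.evidence:
            for e in r.evidence:
                rows.append((r.file_key, r.flag.value, e.rule_id,
                             e.start_epoch, e.end_epoch, e.detail))
        else:
            rows.append((r.file_key, r.flag.value, "", "", "", ""))
    pd.DataFrame(
        rows,
        columns=["file_key", "flag", "rule_id", "start_epoch", "end_epoch",
                 "detail"],
    ).to_csv(path, sep="\t", index=False)


def reports_frame(reports: list[FlagReport]) -> pd.DataFrame:
    """One row per file: file_key, flag, n_evidence."""
    return pd.DataFrame(
        [(r.file_key, r.flag.value, len(r.evidence)) for r in reports],
        columns=["file_key", "flag", "n_evidence"],
    )
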