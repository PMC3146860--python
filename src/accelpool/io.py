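"""Reading and writing legacy Actigraph plain-text count files.

Legacy ``.dat`` files are a short plain-text header followed by the count
body.  Real-world headers vary between download-software versions, so the
writer emits a fixed canonical 10-line layout and the reader supports two
dialects: ``strict`` (the canonical layout) and a permissive mode that
recovers the four needed fields (serial, start time, start date, epoch
period) by labeled-line search anywhere in the header block.

Also provided: reconstitution of headerless time-stamped count tables
(NHANES-style exports, where the raw files and their headers are withheld)
into ordinary count series, and application of per-file start-date/time
exception lists for monitors initialized before deployment.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import CorruptFileError, EpochSeries

_HEADER_END = "-" * 50


@dataclass(frozen=True)
class DialectConfig:
    """Conventions for parsing/writing count files.

    date_order
        ``"MDY"`` or ``"DMY"`` — how dates in headers are interpreted.
    delimiter
        ``None`` for any whitespace, or an explicit character such as
        ``","`` for comma-separated bodies.
    strict_header
        If True the header must be the canonical 10-line layout; otherwise
        the needed fields are located by label.
    """

    date_order: str = "MDY"
    delimiter: str | None = None
    strict_header: bool = False

    def __post_init__(self):
        if self.date_order not in ("MDY", "DMY"):
            raise ValueError("date_order must be 'MDY' or 'DMY'")


DEFAULT_DIALECT = DialectConfig()


@dataclass(frozen=True)
class StartException:
    """A per-file correction of the recorded start date and/or time.

    Used when a monitor was initialized before being deployed: the header
    start stamp is wrong and is overridden from a read-in exception list.
    At least one of date/time must be present.
    """

    file_key: str
    corrected_start_date: dt.date | None = None
    corrected_start_time: dt.time | None = None

    def __post_init__(self):
        if self.corrected_start_date is None and self.corrected_start_time is None:
            raise ValueError("StartException must carry a date and/or a time")


# ---------------------------------------------------------------------------
# date / time formatting helpers

def _format_date(d: dt.date, order: str) -> str:
    return f"{d.month}/{d.day}/{d.year}" if order == "MDY" else f"{d.day}/{d.month}/{d.year}"


def _parse_date(text: str, order: str) -> dt.date:
    parts = re.split(r"[/\-.]", text.strip())
    if len(parts) != 3:
        raise ValueError(f"cannot parse date {text!r}")
    a, b, y = (int(p) for p in parts)
    month, day = (a, b) if order == "MDY" else (b, a)
    return dt.date(y, month, day)


def _parse_time(text: str) -> dt.time:
    h, m, s = (int(p) for p in text.strip().split(":"))
    return dt.time(h, m, s)


def _epoch_to_hms(epoch_seconds: int) -> str:
    return f"00:00:{epoch_seconds:02d}" if epoch_seconds < 60 else "00:01:00"


def _hms_to_epoch(text: str) -> int:
    h, m, s = (int(p) for p in text.strip().split(":"))
    return h * 3600 + m * 60 + s


# ---------------------------------------------------------------------------
# reader / writer

def write_count_file(
    series: EpochSeries,
    path: str | Path,
    dialect: DialectConfig = DEFAULT_DIALECT,
    counts_per_line: int = 10,
) -> Path:
    """Write ``series`` as a canonical-header plain-text count file.

    Round-trip guarantee: :func:`read_count_file` on the result reproduces
    the counts, epoch length, start datetime, serial and device model.
    """
    path = Path(path)
    d = series.start_datetime
    sep = "," if dialect.delimiter == "," else " "
    lines = [
        f"--- Data File Created By ActiGraph {series.device_model} ActiSoft ---",
        f"Serial Number: {series.serial_number}",
        f"Start Time {d.time().strftime('%H:%M:%S')}",
        f"Start Date {_format_date(d.date(), dialect.date_order)}",
        f"Epoch Period (hh:mm:ss) {_epoch_to_hms(series.epoch_length)}",
        "Download Time 00:00:00",
        f"Download Date {_format_date(series.end_datetime.date(), dialect.date_order)}",
        "Current Memory Address: 0",
        "Current Battery Voltage: 4.10     Mode = 0",
        _HEADER_END,
    ]
    body_lines = []
    c = series.counts
    for i in range(0, len(c), counts_per_line):
        body_lines.append(sep.join(str(int(v)) for v in c[i:i + counts_per_line]))
    path.write_text("\n".join(lines + body_lines) + "\n")
    return path


_LABELS = {
    "serial": re.compile(r"serial\s*number\s*:?\s*(\S+)", re.I),
    "start_time": re.compile(r"start\s*time\s*:?\s*(\d{1,2}:\d{2}:\d{2})", re.I),
    "start_date": re.compile(r"start\s*date\s*:?\s*([\d/\-.]+)", re.I),
    "epoch": re.compile(r"epoch\s*period\s*\(hh:mm:ss\)\s*:?\s*(\d{2}:\d{2}:\d{2})", re.I),
}
_MODEL_RE = re.compile(r"ActiGraph\s+(7164|71256|GT1M)", re.I)


def read_count_file(
    path: str | Path,
    dialect: DialectConfig = DEFAULT_DIALECT,
) -> EpochSeries:
    """Parse a legacy plain-text count file into an :class:`EpochSeries`.

    The parse is loss-free: every integer token in the body becomes one
    count, in order; trailing blank lines are ignored.  Unparseable
    headers, negative/non-integer tokens and empty bodies raise
    :class:`CorruptFileError` carrying the byte offset of the failure.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.split("\n")

    # locate end of header
    header_n = None
    for i, line in enumerate(lines[:30]):
        if set(line.strip()) == {"-"} and len(line.strip()) >= 10 and i > 0:
            header_n = i + 1
            break
    if header_n is None:
        raise CorruptFileError(f"{path.name}: no header terminator found", byte_offset=0)
    if dialect.strict_header and header_n != 10:
        raise CorruptFileError(
            f"{path.name}: strict dialect expects a 10-line header, got {header_n}",
            byte_offset=0,
        )
    header = "\n".join(lines[:header_n])

    fields = {}
    for name, rx in _LABELS.items():
        m = rx.search(header)
        if m:
            fields[name] = m.group(1)
    missing = {"serial", "start_time", "start_date", "epoch"} - fields.keys()
    if missing:
        raise CorruptFileError(
            f"{path.name}: header missing field(s) {sorted(missing)}", byte_offset=0
        )
    model_m = _MODEL_RE.search(header)
    model = model_m.group(1) if model_m else "unknown"

    try:
        start = dt.datetime.combine(
            _parse_date(fields["start_date"], dialect.date_order),
            _parse_time(fields["start_time"]),
        )
        epoch = _hms_to_epoch(fields["epoch"])
    except (ValueError, OverflowError) as exc:
        raise CorruptFileError(f"{path.name}: bad header value: {exc}", byte_offset=0)

    body_offset = sum(len(l) + 1 for l in lines[:header_n])
    body = text[body_offset:]
    if dialect.delimiter and dialect.delimiter != " ":
        body = body.replace(dialect.delimiter, " ")
    tokens = body.split()
    if not tokens:
        raise CorruptFileError(f"{path.name}: empty count body", byte_offset=body_offset)

    counts = np.empty(len(tokens), dtype=np.int64)
    pos = body_offset
    for i, tok in enumerate(tokens):
        try:
            v = int(tok)
        except ValueError:
            raise CorruptFileError(
                f"{path.name}: non-integer token {tok!r}", byte_offset=pos
            )
        if v < 0:
            raise CorruptFileError(
                f"{path.name}: negative count {v}", byte_offset=pos
            )
        counts[i] = v
        pos += len(tok) + 1

    return EpochSeries(
        serial_number=fields["serial"],
        device_model=model,
        epoch_length=epoch,
        start_datetime=start,
        counts=counts,
        source_name=path.stem,
    )


# ---------------------------------------------------------------------------
# NHANES-style reconstitution

def reconstitute_headerless(
    table: pd.DataFrame | Iterable[tuple],
    cycle_year: int,
    day_of_week: int,
    serial_number: str = "RECONSTITUTED",
) -> EpochSeries:
    """Rebuild an :class:`EpochSeries` from a headerless time-stamped table.

    Survey exports (e.g. NHANES physical-activity monitor files) withhold
    the raw file headers; only (day, clock time, count) rows at 60-s epochs
    remain.  The series is reconstituted with start time 00:00:00 and epoch
    60 s, and the start *date* is set to the unique date in January 1-7 of
    ``cycle_year`` whose weekday matches ``day_of_week``, preserving the
    day of the week without disclosing the true date.

    Parameters
    ----------
    table
        DataFrame with columns (day, time, count) — or any iterable of such
        rows.  ``time`` may be ``datetime.time`` or ``"HH:MM:SS"`` strings.
    cycle_year
        Year stamped on the reconstituted file (e.g. 2004 for a 2003-04
        survey cycle, 2006 for 2005-06).
    day_of_week
        ISO weekday of the true first monitored day (1=Monday .. 7=Sunday).
    """
    if not 1 <= day_of_week <= 7:
        raise ValueError(f"day_of_week must be in 1..7, got {day_of_week}")

    if isinstance(table, pd.DataFrame):
        rows = table.itertuples(index=False)
    else:
        rows = iter(table)

    counts = []
    for i, row in enumerate(rows):
        _day, t, c = row[0], row[1], row[2]
        if isinstance(t, str):
            t = _parse_time(t)
        elif isinstance(t, dt.datetime):
            t = t.time()
        expected_minute = i % 1440
        if t.hour * 60 + t.minute != expected_minute or t.second != 0:
            raise CorruptFileError(
                f"gap in minute grid at row {i}: expected minute {expected_minute}, "
                f"got {t}",
            )
        c = int(c)
        if c < 0:
            raise CorruptFileError(f"negative count {c} at row {i}")
        counts.append(c)
    if not counts:
        raise CorruptFileError("empty table")

    start_date = next(
        d for d in (dt.date(cycle_year, 1, n) for n in range(1, 8))
        if d.isoweekday() == day_of_week
    )
    return EpochSeries(
        serial_number=serial_number,
        device_model="unknown",
        epoch_length=60,
        start_datetime=dt.datetime.combine(start_date, dt.time(0, 0, 0)),
        counts=np.asarray(counts, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# start-date / start-time exceptions

def apply_start_exceptions(
    series: EpochSeries,
    exceptions: Sequence[StartException],
    log: list | None = None,
) -> EpochSeries:
    """Override the start stamp of ``series`` if an exception matches it.

    Exceptions are keyed on the filename stem (``source_name``) or the full
    file key; counts are never touched.  Non-matching series are returned
    unchanged.  Duplicate keys in the exception list are an error.
    """
    keys = [e.file_key for e in exceptions]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate exception keys: {dupes}")

    match = next(
        (e for e in exceptions
         if e.file_key in (series.source_name, series.file_key)),
        None,
    )
    if match is None:
        return series
    new_date = match.corrected_start_date or series.start_datetime.date()
    new_time = match.corrected_start_time or series.start_datetime.time()
    new_start = dt.datetime.combine(new_date, new_time)
    if log is not None:
        log.append(
            f"{series.source_name}: start {series.start_datetime.isoformat()} "
            f"-> {new_start.isoformat()}"
        )
    return series.replace(start_datetime=new_start)


def read_exception_table(path: str | Path) -> list[StartException]:
    """Read a delimited exception list (columns: file_key, start_date, start_time).

    Dates are ISO (YYYY-MM-DD); empty cells mean "leave unchanged".
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        date = dt.date.fromisoformat(row.start_date) if row.start_date else None
        time = _parse_time(row.start_time) if row.start_time else None
        out.append(StartException(row.file_key, date, time))
    return out
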