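"""Core domain types for epoch-level accelerometer count series.

The unit of all processing is the :class:`EpochSeries`: a device-stamped,
fixed-epoch sequence of integer activity counts as produced by legacy
uniaxial Actigraph monitors (models 7164, 71256, GT1M).  Counts are
dimensionless device output, summed over a fixed epoch (1-60 s), with a
hardware saturation ceiling of 32767 on these devices.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Hardware ceiling of the legacy uniaxial sensors; counts plateau here
#: when a unit malfunctions.
SATURATION_CEILING = 32767

DEVICE_MODELS = ("7164", "71256", "GT1M", "unknown")


class CorruptFileError(ValueError):
    """A count file (or headerless table) could not be parsed.

    Parameters
    ----------
    message : str
    byte_offset : int, optional
        Position in the input at which parsing failed, when known.
    """

    def __init__(self, message: str, byte_offset: int | None = None):
        super().__init__(message)
        self.byte_offset = byte_offset


@dataclass(frozen=True)
class DstEvent:
    """A daylight-saving / summer-time clock change within a recording.

    ``event_datetime`` is the local clock instant at which clocks change:
    for ``spring_forward`` the first missing minute, for ``fall_back`` the
    first minute of the doubled (repeated) hour.
    """

    event_datetime: dt.datetime
    direction: str  # "spring_forward" | "fall_back"

    def __post_init__(self):
        if self.direction not in ("spring_forward", "fall_back"):
            raise ValueError(f"unknown DST direction {self.direction!r}")


@dataclass
class EpochSeries:
    """A fixed-epoch integer count time series from one monitor deployment.

    The timestamp of epoch ``i`` is ``start_datetime + i * epoch_length``
    seconds; timestamps are derived, never stored.

    Attributes
    ----------
    serial_number : str
        Device serial as recorded in the file header.
    device_model : str
        One of ``7164``, ``71256``, ``GT1M`` or ``unknown``.
    epoch_length : int
        Epoch duration in seconds; a divisor of 60 (or 60 itself).
    start_datetime : datetime.datetime
        Local clock time of the first epoch.
    counts : numpy.ndarray
        Non-negative integer counts, temporal order.
    study_id, participant_id, wave : str
        Pooling keys; empty strings when not yet assigned.
    source_name : str
        Filename stem (the file "label" used for duplicate resolution
        and start-date exceptions).
    dst_events : list of DstEvent
        Clock changes known to fall within the recording span.
    """

    serial_number: str
    epoch_length: int
    start_datetime: dt.datetime
    counts: np.ndarray
    device_model: str = "unknown"
    study_id: str = ""
    participant_id: str = ""
    wave: str = ""
    source_name: str = ""
    dst_events: list[DstEvent] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if not (1 <= self.epoch_length <= 60) or 60 % self.epoch_length != 0:
            raise ValueError(
                f"epoch_length must be a divisor of 60 in 1..60, got {self.epoch_length}"
            )
        if self.device_model not in DEVICE_MODELS:
            raise ValueError(f"unknown device model {self.device_model!r}")
        if self.counts.size and self.counts.max() > SATURATION_CEILING:
            # classification of over-ceiling values belongs to cleaning
            warnings.warn(
                f"counts exceed the {SATURATION_CEILING} saturation ceiling "
                f"(max {int(self.counts.max())}); flag candidate",
                stacklevel=2,
            )

    # -- derived views -------------------------------------------------

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def end_datetime(self) -> dt.datetime:
        """Local clock time one epoch past the last stored epoch."""
        return self.start_datetime + dt.timedelta(
            seconds=self.epoch_length * len(self)
        )

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_datetime, periods=len(self),
            freq=pd.Timedelta(seconds=self.epoch_length),
        )

    @property
    def file_key(self) -> str:
        """Identity key: study, participant, wave, serial, filename stem."""
        return "|".join(
            (self.study_id, self.participant_id, self.wave,
             self.serial_number, self.source_name)
        )

    def replace(self, **changes) -> "EpochSeries":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def minute_index(self, when: dt.datetime) -> int:
        """Epoch index of the local clock instant ``when`` (60-s epochs)."""
        if self.epoch_length != 60:
            raise ValueError("minute_index requires 60-s epochs")
        delta = when - self.start_datetime
        return int(delta.total_seconds() // 60)


def require_minute_epochs(series: EpochSeries, op: str) -> None:
    if series.epoch_length != 60:
        raise ValueError(
            f"{op} requires 60-s epochs; got {series.epoch_length}-s "
            "(reintegrate first)"
        )


def complete_day_slices(series: EpochSeries) -> list[tuple[dt.date, slice]]:
    """Slices of full midnight-to-midnight days (1440 min) in a 60-s series."""
    require_minute_epochs(series, "complete_day_slices")
    n = len(series)
    start = series.start_datetime
    out: list[tuple[dt.date, slice]] = []
    # first midnight at or after start
    if start.time() == dt.time(0, 0):
        first = 0
    else:
        next_mid = dt.datetime.combine(
            start.date() + dt.timedelta(days=1), dt.time(0, 0))
        first = int((next_mid - start).total_seconds() // 60)
    i = first
    while i + 1440 <= n:
        day = (start + dt.timedelta(minutes=i)).date()
        out.append((day, slice(i, i + 1440)))
        i += 1440
    return out
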