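"""Epoch harmonization and daylight-saving normalization.

Studies contributed counts at epochs from 5 to 60 s; for pooled outcome
variables every file is reintegrated up to 60-s epochs by summing blocks
of sub-minute counts.  Recordings spanning a clock change are normalized
so every complete local-clock day has exactly 1440 minutes: the hour lost
in spring is imputed by replicating the 30 minutes before and after the
event, and of the doubled autumn hour only the middle hour of the 120-min
span is retained.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np

from .series import DstEvent, EpochSeries, require_minute_epochs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProvenanceRecord:
    """One modification made to a series, for the provenance sidecar."""

    file_key: str
    start_epoch: int
    end_epoch: int  # half-open
    action: str  # imputed_spring | collapsed_fall | dropped_tail


def reintegrate(
    series: EpochSeries,
    target_epoch: int = 60,
    provenance: list[ProvenanceRecord] | None = None,
) -> EpochSeries:
    """Sum sub-minute epochs into ``target_epoch``-second epochs.

    Counts are summed over consecutive blocks of ``target/source`` epochs;
    a trailing partial block is dropped and logged.  The start time is
    unchanged, and the total count is conserved up to the dropped tail.
    Idempotent for series already at the target epoch.
    """
    src = series.epoch_length
    if src == target_epoch:
        return series
    if target_epoch % src != 0:
        raise ValueError(
            f"target epoch {target_epoch}s is not a multiple of source {src}s"
        )
    block = target_epoch // src
    n_full = len(series) // block
    tail = len(series) - n_full * block
    if tail:
        dropped = series.counts[n_full * block:]
        logger.info(
            "%s: dropped trailing partial block of %d epoch(s), sum %d",
            series.source_name or "<series>", tail, int(dropped.sum()),
        )
        if provenance is not None:
            provenance.append(ProvenanceRecord(
                series.file_key, n_full * block, len(series), "dropped_tail"))
    summed = series.counts[: n_full * block].reshape(n_full, block).sum(axis=1)
    return series.replace(counts=summed, epoch_length=target_epoch)


def adjust_dst(
    series: EpochSeries,
    event: DstEvent,
    provenance: list[ProvenanceRecord] | None = None,
    fall_rule: str = "middle",
) -> EpochSeries:
    """Normalize a 60-s-epoch recording that spans a clock change.

    spring_forward
        The missing local-clock hour is imputed at the event instant by
        replicating the 30 minutes immediately preceding it followed by
        the 30 minutes immediately following it.  If fewer than 30 minutes
        exist on either side, the shortfall is filled with zeros and a
        warning logged.
    fall_back
        Of the 120 device-recorded minutes covering the repeated
        local-clock hour twice, a single hour is retained: the middle 60
        minutes (minutes 30-89 of the doubled span) under the default
        rule, or the first repetition with ``fall_rule="first"``.

    After adjustment every complete local-clock day has exactly 1440
    minutes.  A series not spanning the event is returned unchanged.
    Imputed/collapsed ranges are appended to ``provenance``.
    """
    require_minute_epochs(series, "adjust_dst")
    if fall_rule not in ("middle", "first"):
        raise ValueError("fall_rule must be 'middle' or 'first'")
    idx = series.minute_index(event.event_datetime)
    c = series.counts

    if event.direction == "spring_forward":
        if idx <= 0 or idx >= len(c):
            return series
        pre = c[max(idx - 30, 0): idx]
        post = c[idx: idx + 30]
        if len(pre) < 30 or len(post) < 30:
            logger.warning(
                "%s: DST event within 30 min of a recording boundary; "
                "partial imputation padded with zeros",
                series.source_name or "<series>",
            )
        pre = np.concatenate([np.zeros(30 - len(pre), dtype=np.int64), pre])
        post = np.concatenate([post, np.zeros(30 - len(post), dtype=np.int64)])
        inserted = np.concatenate([pre, post])
        new_counts = np.concatenate([c[:idx], inserted, c[idx:]])
        if provenance is not None:
            provenance.append(ProvenanceRecord(
                series.file_key, idx, idx + 60, "imputed_spring"))
        return series.replace(counts=new_counts)

    # fall_back: device timeline holds 120 min for one local-clock hour
    if idx < 0 or idx + 120 > len(c):
        return series
    doubled = c[idx: idx + 120]
    kept = doubled[30:90] if fall_rule == "middle" else doubled[:60]
    new_counts = np.concatenate([c[:idx], kept, c[idx + 120:]])
    if provenance is not None:
        provenance.append(ProvenanceRecord(
            series.file_key, idx, idx + 120, "collapsed_fall"))
    return series.replace(counts=new_counts)


def normalize(
    series: EpochSeries,
    provenance: list[ProvenanceRecord] | None = None,
) -> EpochSeries:
    """Reintegrate to 60-s epochs and apply every attached DST event."""
    out = reintegrate(series, 60, provenance)
    for event in sorted(out.dst_events, key=lambda e: e.event_datetime):
        out = adjust_dst(out, event, provenance)
    return out


def write_provenance(records: list[ProvenanceRecord], path) -> None:
    """Write the provenance sidecar as tab-separated text."""
    import pandas as pd

    pd.DataFrame(
        [(r.file_key, r.start_epoch, r.end_epoch, r.action) for r in records],
        columns=["file_key", "start_epoch", "end_epoch", "action"],
    ).to_csv(path, sep="\t", index=False)
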