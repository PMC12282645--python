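"""Total sleep opportunity (TSO) windows and the short-window exclusion rule.

The TSO is the nightly window from getting into bed intending to sleep to
finally getting out of bed intending to stay awake.  For the human-labelled
Reference it comes from rater consensus; for each device it is derived from
the device's own reported sleep periods, so the device is evaluated the way
it would be deployed (without access to video).  Windows shorter than a
minimum duration (default 3.5 h, strict) are excluded per source: a night may
remain analyzable for the Reference while being dropped for one device.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .intervals import EventTrack, Interval, merge_gaps

__all__ = [
    "TsoRecord",
    "derive_device_tso",
    "exclude_short_tso",
    "exclusion_summary",
    "paired_overlap_window",
    "DEFAULT_TSO_MERGE_GAP_MIN",
    "DEFAULT_TSO_MIN_HOURS",
]

DEFAULT_TSO_MERGE_GAP_MIN = 30.0
DEFAULT_TSO_MIN_HOURS = 3.5


@dataclass
class TsoRecord:
    """One source's TSO window for one participant-night."""

    participant_id: str
    night_id: str
    source: str
    tso: Optional[Interval]
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    @property
    def duration_h(self) -> Optional[float]:
        return None if self.tso is None else self.tso.duration_h


def derive_device_tso(
    sleep_periods: EventTrack, merge_gap_min: float = DEFAULT_TSO_MERGE_GAP_MIN
) -> Optional[Interval]:
    """Derive a device's nightly TSO from its reported sleep periods.

    Sleep periods on the same night separated by a gap strictly shorter than
    ``merge_gap_min`` minutes are merged.  If several merged periods remain,
    the longest is taken as the night's main rest period.  Returns ``None``
    for an empty input (night unusable for this source).
    """
    if merge_gap_min < 0:
        raise ValueError(f"merge_gap_min must be non-negative, got {merge_gap_min}")
    if sleep_periods.is_empty:
        return None
    merged = merge_gaps(sleep_periods, max_gap_s=60.0 * merge_gap_min)
    arr = merged.intervals
    durations = arr[:, 1] - arr[:, 0]
    best = int(durations.argmax())
    return Interval(float(arr[best, 0]), float(arr[best, 1]))


def exclude_short_tso(
    records: Sequence[TsoRecord], min_hours: float = DEFAULT_TSO_MIN_HOURS
) -> tuple[list[TsoRecord], pd.DataFrame]:
    """Flag TSO windows strictly shorter than ``min_hours``.

    Returns the kept records and an exclusion log (one row per excluded
    record, with participant, night, source, duration and reason).  Records
    with no TSO at all are excluded with reason ``"no_tso"``.
    """
    kept: list[TsoRecord] = []
    dropped: list[TsoRecord] = []
    for rec in records:
        if rec.tso is None:
            rec.excluded = True
            rec.exclusion_reason = "no_tso"
            dropped.append(rec)
        elif rec.duration_h < min_hours:
            rec.excluded = True
            rec.exclusion_reason = f"tso_shorter_than_{min_hours}h"
            dropped.append(rec)
        else:
            rec.excluded = False
            rec.exclusion_reason = None
            kept.append(rec)
    log = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "night_id": r.night_id,
                "source": r.source,
                "duration_h": r.duration_h,
                "reason": r.exclusion_reason,
            }
            for r in dropped
        ],
        columns=["participant_id", "night_id", "source", "duration_h", "reason"],
    )
    return kept, log


def exclusion_summary(records: Sequence[TsoRecord]) -> pd.DataFrame:
    """Per-source counts of analyzable and excluded nights."""
    rows = []
    by_source: dict[str, list[TsoRecord]] = {}
    for rec in records:
        by_source.setdefault(rec.source, []).append(rec)
    for source, recs in sorted(by_source.items()):
        n_total = len(recs)
        n_excluded = sum(r.excluded for r in recs)
        rows.append(
            {
                "source": source,
                "n_nights": n_total,
                "n_excluded": n_excluded,
                "pct_excluded": 100.0 * n_excluded / n_total if n_total else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["source", "n_nights", "n_excluded", "pct_excluded"])


def paired_overlap_window(ref: TsoRecord, dht: TsoRecord) -> Optional[Interval]:
    """Intersection of the Reference and device TSO windows for one night.

    The within-night epoch comparison is evaluated only inside this window;
    an empty intersection marks the pair unusable.  Both records must have
    survived the short-TSO exclusion.
    """
    if ref.excluded or dht.excluded:
        raise ValueError("paired_overlap_window requires records kept after exclusion")
    if ref.tso is None or dht.tso is None:
        return None
    from .intervals import intersect

    return intersect(ref.tso, dht.tso)
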