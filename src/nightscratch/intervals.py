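"""Half-open interval algebra for nightly event tracks.

All times are real-valued seconds measured from a per-night origin (noon of
the evening the night begins), so every nightly timestamp is positive and
monotone across midnight.  Intervals are half-open ``[start, end)``: adjacency
is unambiguous and durations add exactly.  Every downstream stage of the
pipeline — rater consensus, sleep-window derivation, epoch labelling, outcome
normalisation — is built on the handful of operations defined here.

Boundary conventions (fixed throughout the package):

* gap merging uses a *strict* inequality: consecutive bouts separated by a
  gap strictly shorter than ``max_gap_s`` are fused;
* the minimum-duration filter is *inclusive*: bouts of exactly the minimum
  duration are retained;
* the intersection-over-union of two empty tracks is 1.0 — two raters who
  both mark no scratching in a segment are in perfect agreement.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Interval",
    "EventTrack",
    "VALID_KINDS",
    "normalize_track",
    "merge_gaps",
    "filter_min_duration",
    "intersect",
    "intersect_tracks",
    "union_duration",
    "total_duration",
    "iou",
]

VALID_KINDS = ("scratch", "sleep_period", "tso")


@dataclass(frozen=True)
class Interval:
    """A half-open time interval ``[start_s, end_s)`` in night seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start_s) and math.isfinite(self.end_s)):
            raise ValueError(f"interval endpoints must be finite, got {self}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"interval end must exceed start, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duration_h(self) -> float:
        return (self.end_s - self.start_s) / 3600.0

    def as_tuple(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)


IntervalLike = Union[Interval, Sequence[float]]


def _coerce_intervals(raw: Union["EventTrack", Iterable[IntervalLike], np.ndarray]) -> np.ndarray:
    """Coerce raw input into a validated ``(n, 2)`` float array.

    Rejects any individual interval with non-finite endpoints or
    ``end <= start``, naming the offending record.
    """
    if isinstance(raw, EventTrack):
        return raw.intervals
    if isinstance(raw, np.ndarray):
        arr = np.asarray(raw, dtype=float)
        if arr.size == 0:
            return np.empty((0, 2), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"expected an (n, 2) array of intervals, got shape {arr.shape}")
    else:
        rows = []
        for item in raw:
            if isinstance(item, Interval):
                rows.append(item.as_tuple())
            else:
                pair = tuple(item)
                if len(pair) != 2:
                    raise ValueError(f"interval record must have 2 fields, got {item!r}")
                rows.append((float(pair[0]), float(pair[1])))
        if not rows:
            return np.empty((0, 2), dtype=float)
        arr = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0, 0]
        raise ValueError(f"non-finite interval endpoints in record {bad}: {arr[bad]}")
    inverted = arr[:, 1] <= arr[:, 0]
    if np.any(inverted):
        bad = int(np.argmax(inverted))
        raise ValueError(
            f"invalid interval in record {bad}: end {arr[bad, 1]} <= start {arr[bad, 0]}"
        )
    return arr


@dataclass(frozen=True)
class EventTrack:
    """An ordered, non-overlapping set of intervals for one night and source.

    ``intervals`` is an ``(n, 2)`` float array, sorted by start, with no two
    intervals overlapping or touching (construct via :func:`normalize_track`).
    """

    intervals: np.ndarray
    participant_id: Optional[str] = None
    night_id: Optional[str] = None
    source: Optional[str] = None
    kind: str = "scratch"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}; expected one of {VALID_KINDS}")
        arr = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        arr.setflags(write=False)
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        for start, end in self.intervals:
            yield Interval(float(start), float(end))

    @property
    def is_empty(self) -> bool:
        return self.intervals.shape[0] == 0

    def replace(self, **changes) -> "EventTrack":
        return dataclasses.replace(self, **changes)

    def meta(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "night_id": self.night_id,
            "source": self.source,
            "kind": self.kind,
        }


def _coalesce(arr: np.ndarray) -> np.ndarray:
    """Sort and fuse overlapping or touching intervals; total cover preserved."""
    if arr.shape[0] == 0:
        return arr.reshape(0, 2)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    out = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= out[-1][1]:  # overlapping or touching
            if end > out[-1][1]:
                out[-1][1] = end
        else:
            out.append([start, end])
    return np.asarray(out, dtype=float)


def normalize_track(
    raw_intervals: Union[EventTrack, Iterable[IntervalLike], np.ndarray],
    *,
    participant_id: Optional[str] = None,
    night_id: Optional[str] = None,
    source: Optional[str] = None,
    kind: str = "scratch",
) -> EventTrack:
    """Build a normalized :class:`EventTrack` from raw intervals.

    Sorts by start and coalesces overlapping or touching intervals into
    single intervals; the total covered duration is preserved.
    """
    if isinstance(raw_intervals, EventTrack):
        meta = raw_intervals.meta()
        meta.update(
            {
                k: v
                for k, v in dict(
                    participant_id=participant_id,
                    night_id=night_id,
                    source=source,
                ).items()
                if v is not None
            }
        )
        if kind != "scratch":
            meta["kind"] = kind
        arr = raw_intervals.intervals
        return EventTrack(_coalesce(np.array(arr, dtype=float)), **meta)
    arr = _coerce_intervals(raw_intervals)
    return EventTrack(
        _coalesce(arr),
        participant_id=participant_id,
        night_id=night_id,
        source=source,
        kind=kind,
    )


def merge_gaps(track: EventTrack, max_gap_s: float = 3.0) -> EventTrack:
    """Fuse consecutive intervals separated by a gap strictly below ``max_gap_s``.

    Merging is transitive: a chain of short gaps collapses into one bout.
    Bout count never increases and total duration never decreases.
    """
    if max_gap_s < 0:
        raise ValueError(f"max_gap_s must be non-negative, got {max_gap_s}")
    arr = track.intervals
    if arr.shape[0] <= 1:
        return track
    out = [list(arr[0])]
    for start, end in arr[1:]:
        if start - out[-1][1] < max_gap_s:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return track.replace(intervals=np.asarray(out, dtype=float))


def filter_min_duration(track: EventTrack, min_dur_s: float = 2.0) -> EventTrack:
    """Retain intervals of duration at least ``min_dur_s`` (inclusive)."""
    if min_dur_s < 0:
        raise ValueError(f"min_dur_s must be non-negative, got {min_dur_s}")
    arr = track.intervals
    keep = (arr[:, 1] - arr[:, 0]) >= min_dur_s
    return track.replace(intervals=arr[keep])


def intersect(a: Interval, b: Interval) -> Optional[Interval]:
    """Intersection of two half-open intervals, or ``None`` when empty.

    Touching intervals (``a.end == b.start``) intersect in the empty set.
    """
    start = max(a.start_s, b.start_s)
    end = min(a.end_s, b.end_s)
    if end > start:
        return Interval(start, end)
    return None


def intersect_tracks(a: EventTrack, b: EventTrack, **meta) -> EventTrack:
    """Interval-set intersection of two normalized tracks."""
    out = []
    i = j = 0
    A, B = a.intervals, b.intervals
    while i < len(A) and j < len(B):
        start = max(A[i, 0], B[j, 0])
        end = min(A[i, 1], B[j, 1])
        if end > start:
            out.append([start, end])
        if A[i, 1] <= B[j, 1]:
            i += 1
        else:
            j += 1
    arr = np.asarray(out, dtype=float).reshape(-1, 2)
    fields = {"kind": a.kind, "participant_id": a.participant_id, "night_id": a.night_id}
    fields.update(meta)
    return EventTrack(arr, **fields)


def total_duration(track: Union[EventTrack, np.ndarray]) -> float:
    """Total covered duration in seconds of a normalized track."""
    arr = track.intervals if isinstance(track, EventTrack) else np.asarray(track, dtype=float).reshape(-1, 2)
    if arr.shape[0] == 0:
        return 0.0
    return float(np.sum(arr[:, 1] - arr[:, 0]))


def union_duration(a: EventTrack, b: EventTrack) -> float:
    """Duration of the union of two normalized tracks (inclusion-exclusion)."""
    return total_duration(a) + total_duration(b) - total_duration(intersect_tracks(a, b))


def _check_same_night(a: EventTrack, b: EventTrack) -> None:
    if (
        a.night_id is not None
        and b.night_id is not None
        and a.night_id != b.night_id
    ):
        raise ValueError(
            f"tracks belong to different nights: {a.night_id!r} vs {b.night_id!r}"
        )
    if (
        a.participant_id is not None
        and b.participant_id is not None
        and a.participant_id != b.participant_id
    ):
        raise ValueError(
            "tracks belong to different participants: "
            f"{a.participant_id!r} vs {b.participant_id!r}"
        )


def iou(a: EventTrack, b: EventTrack) -> float:
    """Duration-based intersection over union of two tracks, in ``[0, 1]``.

    Defined as 1.0 when both tracks are empty: a segment in which neither
    annotator marks any event is perfect agreement, not missing data.
    """
    _check_same_night(a, b)
    if a.is_empty and b.is_empty:
        return 1.0
    inter = total_duration(intersect_tracks(a, b))
    union = total_duration(a) + total_duration(b) - inter
    return inter / union
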