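"""Night-level scratch outcomes, participant summaries and itch stratification.

The two primary outcomes are the normalized scratch duration (seconds of
scratching per hour of TSO) and the normalized scratch frequency (scratch
bouts per hour of TSO), computed per night and source after gap merging and
the minimum-duration filter.  Both are right-skewed, so participant-level
summaries use geometric means with a configurable additive offset
``exp(mean(log(x + delta))) - delta`` (default delta = 1 in original units)
that keeps zero-scratch nights in the analysis.  Group characterization
reports medians and quartiles on the linear scale.

Morning patient-reported itch (0-10 numeric rating scale, asked about the
previous night) is validity-filtered — timestamps between 04:00 and 12:00
inclusive, and any participant-day with duplicate morning responses dropped
entirely — and then used to stratify night summaries into itch bands.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import EventTrack, total_duration
from .tso import TsoRecord

__all__ = [
    "NightSummary",
    "ProResponse",
    "DEFAULT_ITCH_BANDS",
    "night_summary",
    "geometric_mean",
    "participant_summary",
    "group_summary",
    "filter_pro_responses",
    "stratify_by_itch",
]

OUTCOMES = ("norm_duration", "norm_frequency")

#: NRS severity bands: (label, low, high), inclusive on both edges.
DEFAULT_ITCH_BANDS: tuple[tuple[str, int, int], ...] = (
    ("no itch", 0, 0),
    ("mild", 1, 3),
    ("moderate", 4, 6),
    ("severe", 7, 10),
)


@dataclass(frozen=True)
class NightSummary:
    """Normalized scratch outcomes for one night and source."""

    participant_id: str
    night_id: str
    source: str
    tso_hours: float
    scratch_seconds: float
    bout_count: int
    norm_duration: float  # seconds of scratch per hour of TSO
    norm_frequency: float  # bouts per hour of TSO


@dataclass(frozen=True)
class ProResponse:
    """One patient-reported itch response."""

    participant_id: str
    date: dt.date
    administration: str  # "morning" | "evening"
    timestamp: dt.time
    itch_nrs: int

    def __post_init__(self) -> None:
        if not 0 <= self.itch_nrs <= 10:
            raise ValueError(f"itch_nrs must be in [0, 10], got {self.itch_nrs}")
        if self.administration not in ("morning", "evening"):
            raise ValueError(f"unknown administration {self.administration!r}")


def night_summary(scratch_track: EventTrack, tso_rec: TsoRecord) -> NightSummary:
    """Per-night normalized outcomes from an already merged+filtered track."""
    if tso_rec.excluded or tso_rec.tso is None:
        raise ValueError(
            f"night {tso_rec.night_id!r} source {tso_rec.source!r} was excluded; "
            "excluded nights are never summarized"
        )
    tso_h = tso_rec.tso.duration_h
    scratch_s = total_duration(scratch_track)
    bouts = len(scratch_track)
    return NightSummary(
        participant_id=tso_rec.participant_id,
        night_id=tso_rec.night_id,
        source=tso_rec.source,
        tso_hours=tso_h,
        scratch_seconds=scratch_s,
        bout_count=bouts,
        norm_duration=scratch_s / tso_h,
        norm_frequency=bouts / tso_h,
    )


def geometric_mean(values: Sequence[float], offset: float = 1.0) -> float:
    """Offset geometric mean ``exp(mean(log(x + offset))) - offset``.

    With ``offset=0`` this is the plain geometric mean (all values must then
    be positive); a positive offset keeps zero-valued nights in the summary.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of an empty set is undefined")
    if np.any(x + offset <= 0):
        raise ValueError("geometric mean requires x + offset > 0 for every value")
    return float(np.exp(np.mean(np.log(x + offset))) - offset)


def _summaries_frame(nights) -> pd.DataFrame:
    if isinstance(nights, pd.DataFrame):
        return nights
    return pd.DataFrame([vars(n) if not isinstance(n, dict) else n for n in nights])


def participant_summary(nights, offset: float = 1.0) -> pd.DataFrame:
    """Participant-level geometric means of the normalized outcomes.

    ``nights`` is a sequence of :class:`NightSummary` (or an equivalent
    DataFrame); summaries are computed per participant and source over all of
    that participant's analyzable nights.
    """
    df = _summaries_frame(nights)
    if df.empty:
        raise ValueError("participant_summary requires at least one night")
    rows = []
    for (pid, source), grp in df.groupby(["participant_id", "source"], sort=True):
        rows.append(
            {
                "participant_id": pid,
                "source": source,
                "n_nights": len(grp),
                "norm_duration": geometric_mean(grp["norm_duration"], offset),
                "norm_frequency": geometric_mean(grp["norm_frequency"], offset),
            }
        )
    return pd.DataFrame(rows)


def group_summary(
    participant_summaries: pd.DataFrame,
    group_col: str,
    value_cols: Sequence[str] = OUTCOMES,
) -> pd.DataFrame:
    """Per-group median, quartiles and n on the linear scale."""
    rows = []
    for group, grp in participant_summaries.groupby(group_col, sort=True):
        row = {group_col: group, "n": len(grp)}
        for col in value_cols:
            x = grp[col].to_numpy(dtype=float)
            row[f"{col}_median"] = float(np.median(x))
            row[f"{col}_q1"] = float(np.percentile(x, 25))
            row[f"{col}_q3"] = float(np.percentile(x, 75))
        rows.append(row)
    return pd.DataFrame(rows)


def filter_pro_responses(
    responses: Sequence[ProResponse],
    window_start: dt.time = dt.time(4, 0),
    window_end: dt.time = dt.time(12, 0),
) -> list[ProResponse]:
    """Validity-filter morning itch responses.

    Keeps morning administrations with a timestamp inside the validity
    window (inclusive at both ends).  If a participant-day carries more than
    one morning response, *all* of that day's responses are dropped.
    """
    morning = [r for r in responses if r.administration == "morning"]
    counts: dict[tuple[str, dt.date], int] = {}
    for r in morning:
        key = (r.participant_id, r.date)
        counts[key] = counts.get(key, 0) + 1
    return [
        r
        for r in morning
        if counts[(r.participant_id, r.date)] == 1
        and window_start <= r.timestamp <= window_end
    ]


def _band_lookup(bands: Sequence[tuple[str, int, int]]):
    seen = set()
    for label, low, high in bands:
        if low > high:
            raise ValueError(f"band {label!r} has low {low} > high {high}")
        for v in range(low, high + 1):
            if v in seen:
                raise ValueError(f"itch bands overlap at NRS value {v}")
            seen.add(v)

    def lookup(value: int) -> Optional[str]:
        for label, low, high in bands:
            if low <= value <= high:
                return label
        return None

    return lookup


def stratify_by_itch(
    night_summaries,
    valid_pros: Sequence[ProResponse],
    bands: Sequence[tuple[str, int, int]] = DEFAULT_ITCH_BANDS,
) -> pd.DataFrame:
    """Assign each night to an itch band via the following morning's response.

    A morning response dated D reports on the night that began on D - 1 day,
    so it joins to ``night_id`` equal to that evening's ISO date.  Nights
    without a valid morning response are left out of the stratified view.
    """
    lookup = _band_lookup(bands)
    df = _summaries_frame(night_summaries).copy()
    pro_map = {
        (r.participant_id, (r.date - dt.timedelta(days=1)).isoformat()): r.itch_nrs
        for r in valid_pros
    }
    df["itch_nrs"] = [
        pro_map.get((pid, nid)) for pid, nid in zip(df["participant_id"], df["night_id"])
    ]
    df = df[df["itch_nrs"].notna()].copy()
    df["itch_nrs"] = df["itch_nrs"].astype(int)
    df["itch_band"] = [lookup(v) for v in df["itch_nrs"]]
    df = df[df["itch_band"].notna()]
    return df.reset_index(drop=True)
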