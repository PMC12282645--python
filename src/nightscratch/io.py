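"""File I/O for the event, TSO and PRO tables.

The events CSV is long format, one row per interval:
``participant_id, night_id, source, kind{scratch|sleep_period|tso},
start_s, end_s`` (extra columns pass through untouched).  Times are seconds
from the night origin — noon of the evening the night begins — so times
within a night are positive and increase across midnight; conversion from
calendar timestamps happens here, never in the math core.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import VALID_KINDS, EventTrack, normalize_track
from .outcomes import ProResponse

__all__ = [
    "EVENT_COLUMNS",
    "RowError",
    "night_origin_seconds",
    "read_events",
    "events_to_tracks",
    "tracks_to_events",
    "write_events",
    "read_pro",
    "write_pro",
]

EVENT_COLUMNS = ["participant_id", "night_id", "source", "kind", "start_s", "end_s"]


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based data line number in the file (header is line 1)
    message: str


def night_origin_seconds(timestamp: dt.datetime, night_date: dt.date) -> float:
    """Seconds from the night origin (noon of ``night_date``) to ``timestamp``."""
    origin = dt.datetime.combine(night_date, dt.time(12, 0))
    return (timestamp - origin).total_seconds()


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[RowError]]:
    errors: list[RowError] = []
    start = pd.to_numeric(df["start_s"], errors="coerce")
    end = pd.to_numeric(df["end_s"], errors="coerce")
    bad_numeric = start.isna() | end.isna() | ~np.isfinite(start.fillna(0)) | ~np.isfinite(end.fillna(0))
    bad_order = ~bad_numeric & (end <= start)
    bad_kind = ~df["kind"].isin(VALID_KINDS)
    for idx in df.index[bad_numeric]:
        errors.append(RowError(int(idx) + 2, "non-numeric or non-finite interval endpoints"))
    for idx in df.index[bad_order]:
        errors.append(
            RowError(int(idx) + 2, f"end_s {end[idx]} <= start_s {start[idx]}")
        )
    for idx in df.index[bad_kind & ~bad_numeric & ~bad_order]:
        errors.append(RowError(int(idx) + 2, f"unknown kind {df['kind'][idx]!r}"))
    good = df[~(bad_numeric | bad_order | bad_kind)].copy()
    good["start_s"] = start[good.index]
    good["end_s"] = end[good.index]
    return good, errors


def read_events(path) -> tuple[pd.DataFrame, list[RowError]]:
    """Read and validate an events CSV.

    Returns the valid rows and a list of row-level errors (with 1-based file
    line numbers); a missing required column raises immediately.
    """
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "night_id": str, "source": str, "kind": str},
        float_precision="round_trip",
    )
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} is missing required columns: {missing}")
    return _validate_rows(df)


def events_to_tracks(df: pd.DataFrame) -> dict[tuple, EventTrack]:
    """Group validated event rows into normalized tracks.

    Keys are ``(participant_id, night_id, source, kind)``.
    """
    tracks: dict[tuple, EventTrack] = {}
    for key, grp in df.groupby(["participant_id", "night_id", "source", "kind"], sort=True):
        pid, nid, source, kind = key
        tracks[key] = normalize_track(
            grp[["start_s", "end_s"]].to_numpy(dtype=float),
            participant_id=pid,
            night_id=nid,
            source=source,
            kind=kind,
        )
    return tracks


def tracks_to_events(tracks) -> pd.DataFrame:
    rows = []
    for track in tracks:
        for s, e in track.intervals:
            rows.append(
                {
                    "participant_id": track.participant_id,
                    "night_id": track.night_id,
                    "source": track.source,
                    "kind": track.kind,
                    "start_s": float(s),
                    "end_s": float(e),
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_pro(path) -> list[ProResponse]:
    """Read a PRO CSV (participant_id, date, administration, timestamp, itch_nrs)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "administration": str, "timestamp": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            ProResponse(
                participant_id=row["participant_id"],
                date=dt.date.fromisoformat(str(row["date"])),
                administration=str(row["administration"]),
                timestamp=dt.time.fromisoformat(str(row["timestamp"])),
                itch_nrs=int(row["itch_nrs"]),
            )
        )
    return out


def write_pro(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
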