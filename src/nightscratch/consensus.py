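"""Reference construction from multiple human raters.

Scratch-bout consensus proceeds in up to three rounds.  Two raters label the
same material independently; if the duration-based intersection-over-union of
their annotations strictly exceeds a threshold (default 0.765), the round
reaches consensus and the interval-set *intersection* of the two raters'
labels is the Reference.  Otherwise two further raters repeat the exercise in
round 2 under the same rule, and if that also fails a fifth rater's labels
are taken verbatim in round 3.

The intended-sleep window (TSO) is labelled by two raters; when both
endpoints agree within a tolerance (default 60 s) the Reference TSO endpoints
are the means of the two raters' endpoints, otherwise a third rater
adjudicates and their window is taken as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import (
    EventTrack,
    Interval,
    intersect_tracks,
    iou,
    normalize_track,
)

__all__ = [
    "ConsensusResult",
    "TsoConsensusResult",
    "bout_consensus",
    "bout_consensus_segmented",
    "tso_consensus",
    "DEFAULT_IOU_THRESHOLD",
    "DEFAULT_TSO_TOLERANCE_S",
]

DEFAULT_IOU_THRESHOLD = 0.765
DEFAULT_TSO_TOLERANCE_S = 60.0


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of multi-round scratch-bout consensus for one night/segment."""

    final_track: EventTrack
    round_reached: int  # 1, 2 or 3
    iou_round1: float
    iou_round2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.round_reached not in (1, 2, 3):
            raise ValueError(f"round_reached must be 1, 2 or 3, got {self.round_reached}")


@dataclass(frozen=True)
class TsoConsensusResult:
    final_tso: Interval
    adjudicated: bool


def _reference_meta(track: EventTrack) -> dict:
    return {
        "source": "Reference",
        "participant_id": track.participant_id,
        "night_id": track.night_id,
    }


def bout_consensus(
    r1: EventTrack,
    r2: EventTrack,
    r3: Optional[EventTrack] = None,
    r4: Optional[EventTrack] = None,
    r5: Optional[EventTrack] = None,
    threshold: float = DEFAULT_IOU_THRESHOLD,
) -> ConsensusResult:
    """Multi-round scratch-bout consensus.

    Round 1 uses raters 1 and 2; round 2 (only reached when round 1 fails)
    uses raters 3 and 4; round 3 takes rater 5's labels verbatim.  A round
    reaches consensus when the IoU of its two raters *strictly exceeds*
    ``threshold``, and its output is the interval-set intersection of the two
    raters' labels.

    Raters needed only for escalated rounds may be omitted as long as those
    rounds are never reached.
    """
    iou1 = iou(r1, r2)
    if iou1 > threshold:
        final = intersect_tracks(r1, r2, **_reference_meta(r1))
        return ConsensusResult(final, 1, iou1)
    if r3 is None or r4 is None:
        raise ValueError(
            "consensus escalated to round 2 but raters R3/R4 are missing"
        )
    iou2 = iou(r3, r4)
    if iou2 > threshold:
        final = intersect_tracks(r3, r4, **_reference_meta(r3))
        return ConsensusResult(final, 2, iou1, iou2)
    if r5 is None:
        raise ValueError(
            "consensus escalated to round 3 but rater R5 is missing"
        )
    final = r5.replace(source="Reference")
    return ConsensusResult(final, 3, iou1, iou2)


def bout_consensus_segmented(
    raters: Mapping[str, EventTrack],
    segments: Sequence[Interval],
    threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[EventTrack, list[ConsensusResult]]:
    """Run bout consensus independently per motion segment and concatenate.

    ``raters`` maps rater names ``"R1"``..``"R5"`` to whole-night tracks;
    each track is clipped to every segment before the round logic runs.
    Segment boundaries are an input (produced upstream by motion filtering),
    not computed here.  Returns the concatenated Reference track and the
    per-segment consensus provenance, in segment order.
    """
    if "R1" not in raters or "R2" not in raters:
        raise ValueError("segmented consensus requires at least raters R1 and R2")
    results: list[ConsensusResult] = []
    pieces: list[np.ndarray] = []
    template = raters["R1"]
    for seg in segments:
        seg_track = normalize_track(
            [seg], participant_id=template.participant_id, night_id=template.night_id
        )

        def clip(name: str) -> Optional[EventTrack]:
            track = raters.get(name)
            if track is None:
                return None
            return intersect_tracks(track, seg_track, source=track.source)

        res = bout_consensus(
            clip("R1"), clip("R2"), clip("R3"), clip("R4"), clip("R5"), threshold
        )
        results.append(res)
        pieces.append(res.final_track.intervals)
    merged = np.concatenate(pieces) if pieces else np.empty((0, 2))
    final = normalize_track(
        merged,
        participant_id=template.participant_id,
        night_id=template.night_id,
        source="Reference",
    )
    return final, results


def tso_consensus(
    r1_tso: Interval,
    r2_tso: Interval,
    adjudicator_tso: Optional[Interval] = None,
    tolerance_s: float = DEFAULT_TSO_TOLERANCE_S,
) -> TsoConsensusResult:
    """Two-rater TSO consensus with third-rater adjudication.

    Disagreement is a difference strictly greater than ``tolerance_s`` in
    either the TSO start or the TSO end.  Agreeing windows are combined by
    averaging the two raters' endpoints (a symmetric, unbiased choice; how
    agreeing labels are combined is otherwise unspecified).
    """
    start_diff = abs(r1_tso.start_s - r2_tso.start_s)
    end_diff = abs(r1_tso.end_s - r2_tso.end_s)
    if start_diff <= tolerance_s and end_diff <= tolerance_s:
        final = Interval(
            (r1_tso.start_s + r2_tso.start_s) / 2.0,
            (r1_tso.end_s + r2_tso.end_s) / 2.0,
        )
        return TsoConsensusResult(final, adjudicated=False)
    if adjudicator_tso is None:
        raise ValueError(
            "TSO raters disagree by more than "
            f"{tolerance_s} s (start diff {start_diff:.1f} s, end diff "
            f"{end_diff:.1f} s) and no adjudicator TSO was provided"
        )
    return TsoConsensusResult(adjudicator_tso, adjudicated=True)
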