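"""Epoch-level scratch classification scoring.

The within-night comparison of a device to the Reference divides the
intersection of their TSO windows into consecutive non-overlapping epochs
(10 s primary, 1 s for the sensitivity analysis).  An epoch is positive if
any part of any scratch event overlaps it.  Per-night 2x2 tallies are pooled
*before* metric computation (micro-averaging), with no balancing of scratch
and non-scratch epochs, and the usual detection metrics are derived from the
pooled counts.  Zero-denominator metrics are reported as ``None`` (absent),
never coerced to 0 or 1.

The epoch grid is anchored at the start of the comparison window and a
trailing partial epoch is discarded, so all epochs have equal length and
pooled counts are comparable across nights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .intervals import EventTrack, Interval

__all__ = [
    "EpochGrid",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "make_epochs",
    "label_epochs",
    "score_night",
    "pool",
    "pool_and_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpochGrid:
    """Consecutive equal-length epochs tiling a comparison window."""

    window: Interval
    epoch_s: float
    n_epochs: int

    @property
    def starts(self) -> np.ndarray:
        return self.window.start_s + self.epoch_s * np.arange(self.n_epochs)

    @property
    def end_s(self) -> float:
        """End of the last full epoch (partial tail discarded)."""
        return self.window.start_s + self.epoch_s * self.n_epochs


def make_epochs(window: Interval, epoch_s: float) -> EpochGrid:
    """Tile ``window`` with ``floor(duration / epoch_s)`` epochs from its start."""
    if epoch_s <= 0:
        raise ValueError(f"epoch_s must be positive, got {epoch_s}")
    n = int(math.floor(window.duration_s / epoch_s))
    return EpochGrid(window=window, epoch_s=epoch_s, n_epochs=n)


def label_epochs(grid: EpochGrid, track: EventTrack) -> np.ndarray:
    """Binary epoch labels: positive iff any event overlaps the epoch.

    Overlap uses half-open semantics: an event starting exactly at an epoch
    boundary does not touch the preceding epoch.
    """
    labels = np.zeros(grid.n_epochs, dtype=bool)
    if grid.n_epochs == 0 or track.is_empty:
        return labels
    w0 = grid.window.start_s
    eps = grid.epoch_s
    for start, end in track.intervals:
        if end <= w0 or start >= grid.end_s:
            continue
        first = max(0, int(math.floor((start - w0) / eps)))
        last = min(grid.n_epochs - 1, int(math.ceil((end - w0) / eps)) - 1)
        if last >= first:
            labels[first : last + 1] = True
    return labels


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pooled epoch counts; pools additively across nights and participants."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"confusion count {name} must be non-negative")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def score_night(ref_labels: np.ndarray, dht_labels: np.ndarray) -> ConfusionMatrix:
    """Element-wise 2x2 tally of device labels against Reference labels."""
    ref = np.asarray(ref_labels, dtype=bool)
    dht = np.asarray(dht_labels, dtype=bool)
    if ref.shape != dht.shape:
        raise ValueError(
            f"label vectors must share one epoch grid, got lengths {ref.size} and {dht.size}"
        )
    return ConfusionMatrix(
        tp=int(np.sum(ref & dht)),
        fp=int(np.sum(~ref & dht)),
        tn=int(np.sum(~ref & ~dht)),
        fn=int(np.sum(ref & ~dht)),
    )


def pool(matrices: Iterable[ConfusionMatrix]) -> ConfusionMatrix:
    """Sum confusion counts across nights (micro-averaging happens here)."""
    out = ConfusionMatrix()
    for m in matrices:
        out = out + m
    return out


@dataclass(frozen=True)
class ClassificationMetrics:
    """Detection metrics derived from pooled epoch counts.

    ``None`` marks a metric whose denominator is zero in the pooled counts.
    """

    sensitivity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    balanced_accuracy: Optional[float]
    prevalence: Optional[float]
    counts: ConfusionMatrix
    n_participants: Optional[int] = None
    n_participant_nights: Optional[int] = None


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def pool_and_score(
    matrices: Sequence[ConfusionMatrix],
    n_participants: Optional[int] = None,
    n_participant_nights: Optional[int] = None,
) -> ClassificationMetrics:
    """Pool counts across nights, then compute metrics from the pooled totals.

    Counts are summed *before* any ratio is formed, so the result is the
    micro-average over all epochs, not a mean of per-night metrics.
    """
    cm = pool(matrices)
    if cm.total == 0:
        raise ValueError("cannot score an empty epoch pool")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    if sens is not None and sens == 0.0:
        f1: Optional[float] = 0.0
    elif prec is not None and prec == 0.0:
        f1 = 0.0
    elif sens is None or prec is None:
        f1 = None
    else:
        f1 = 2.0 * sens * prec / (sens + prec)
    bacc = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    for name, value in (("sensitivity", sens), ("precision", prec), ("balanced_accuracy", bacc)):
        if value is None:
            logger.warning("metric %s undefined (zero denominator) for counts %s", name, cm)
    return ClassificationMetrics(
        sensitivity=sens,
        precision=prec,
        f1=f1,
        balanced_accuracy=bacc,
        prevalence=_ratio(cm.tp + cm.fn, cm.total),
        counts=cm,
        n_participants=n_participants,
        n_participant_nights=n_participant_nights,
    )
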