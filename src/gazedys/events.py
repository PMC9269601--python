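"""Run-length segmentation of the per-sample event status signal.

The tracker labels every sample as fixation, saccade or blink/missing; all
downstream features operate on maximal runs of one label ("segments") and on
the fixation polylines those runs trace in the x-y plane.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .trials import BLINK, FIXATION, GazeTrial, SACCADE


@dataclasses.dataclass(frozen=True)
class EventSegment:
    """A maximal run of one event kind, as a half-open sample range."""

    kind: str
    start: int  # inclusive
    end: int  # exclusive
    duration: float  # seconds, (end - start) / sampling_rate

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def segment_events(trial: GazeTrial) -> list[EventSegment]:
    """Encode the trial's label stream as maximal segments.

    The segments tile the trial exactly: the first starts at 0, the last
    ends at ``trial.n_samples``, consecutive segments differ in kind and
    there are no gaps or overlaps.
    """
    labels = trial.event
    n = len(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate(([0], change, [n]))
    fs = trial.sampling_rate
    return [
        EventSegment(kind=str(labels[s]), start=int(s), end=int(e),
                     duration=(int(e) - int(s)) / fs)
        for s, e in zip(bounds[:-1], bounds[1:])
    ]


def fixation_polylines(
    trial: GazeTrial, segments: Sequence[EventSegment] | None = None
) -> list[np.ndarray]:
    """Per-fixation gaze polylines, one ``(m, 2)`` array per FIXATION segment.

    Points appear in sample order; the number of polylines equals the trial's
    fixation count (the ``n`` over which the complexity features average).
    Single-sample fixations yield a one-point polyline with no line segments.
    """
    if segments is None:
        segments = segment_events(trial)
    pts = np.column_stack([trial.x, trial.y])
    return [pts[seg.start:seg.end] for seg in segments if seg.kind == FIXATION]


def blink_boundary_points(
    trial: GazeTrial, segments: Sequence[EventSegment] | None = None
) -> list[tuple[tuple[float, float] | None, tuple[float, float] | None]]:
    """Last gaze point before and first after each blink segment.

    Returns one ``(before, after)`` pair per BLINK segment, in segment order.
    ``before`` is absent (None) when the blink starts the trial and ``after``
    is absent when it ends it.  Because segments are maximal, the adjacent
    samples are guaranteed non-blink and therefore carry finite coordinates.
    """
    if segments is None:
        segments = segment_events(trial)
    out = []
    n = trial.n_samples
    for seg in segments:
        if seg.kind != BLINK:
            continue
        before = (float(trial.x[seg.start - 1]), float(trial.y[seg.start - 1])) if seg.start > 0 else None
        after = (float(trial.x[seg.end]), float(trial.y[seg.end])) if seg.end < n else None
        out.append((before, after))
    return out


def segments_to_labels(segments: Sequence[EventSegment]) -> np.ndarray:
    """Inverse of :func:`segment_events`: expand segments back to labels."""
    return np.concatenate(
        [np.full(seg.n_samples, seg.kind, dtype=object) for seg in segments]
    ) if segments else np.empty(0, dtype=object)
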