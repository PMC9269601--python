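"""The 14-feature scalar description of a reading trial.

Nine conventional eye-tracking metrics (counts, durations, frequencies and
total reading time), two proposed temporal features (active reading time and
saccade-interval variability) and the three proposed spatial
fixation-complexity features computed in :mod:`gazedys.complexity`.

Conventions adopted for corner cases so every retained trial yields a
complete vector: averages over an empty event kind are 0, frequencies are
counts divided by *total* reading time, and standard deviations use the
population form (divisor = number of values), returning 0 when fewer than
two inter-saccade intervals exist.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import complexity
from .events import EventSegment, segment_events
from .trials import BLINK, FIXATION, SACCADE, GazeTrial

#: Conventional feature names, in the order of the input-option table.
CONVENTIONAL_FEATURES = [
    "fixation_count",
    "fixation_total_duration",
    "fixation_frequency",
    "fixation_average_duration",
    "saccade_count",
    "saccade_total_duration",
    "saccade_frequency",
    "saccade_average_duration",
    "total_reading_time",
]

#: Proposed feature names (two temporal, three spatial).
PROPOSED_FEATURES = [
    "active_reading_time",
    "fixation_intersection_coefficient",
    "saccade_variability",
    "fixation_intersection_variability",
    "fixation_fractal_dimension",
]

ALL_FEATURES = CONVENTIONAL_FEATURES + PROPOSED_FEATURES

METADATA_COLUMNS = ["subject_id", "group", "color_config"]


@dataclasses.dataclass
class FeatureVector:
    """The 14 named scalar features of one trial (durations in seconds)."""

    fixation_count: float
    fixation_total_duration: float
    fixation_frequency: float
    fixation_average_duration: float
    saccade_count: float
    saccade_total_duration: float
    saccade_frequency: float
    saccade_average_duration: float
    total_reading_time: float
    active_reading_time: float
    fixation_intersection_coefficient: float
    saccade_variability: float
    fixation_intersection_variability: float
    fixation_fractal_dimension: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ALL_FEATURES}


@dataclasses.dataclass
class TrialRecord:
    """A feature vector together with the metadata ML and stats need."""

    subject_id: str
    group: str
    color_config: str
    features: FeatureVector


def conventional_features(
    segments: Sequence[EventSegment], sampling_rate: float
) -> dict[str, float]:
    """The nine conventional metrics from a trial's segment tiling.

    Counts are numbers of FIXATION/SACCADE segments, total durations are
    per-kind sums of segment durations, averages are total/count (0 for an
    absent kind), total reading time is the full trial duration and
    frequencies are count / total reading time.
    """
    if not segments:
        raise ValueError("cannot compute features of a zero-length trial")
    n_total = segments[-1].end
    total_time = n_total / sampling_rate
    out: dict[str, float] = {"total_reading_time": total_time}
    for kind, prefix in ((FIXATION, "fixation"), (SACCADE, "saccade")):
        runs = [s for s in segments if s.kind == kind]
        count = len(runs)
        total = sum(s.duration for s in runs)
        out[f"{prefix}_count"] = float(count)
        out[f"{prefix}_total_duration"] = total
        out[f"{prefix}_average_duration"] = total / count if count else 0.0
        out[f"{prefix}_frequency"] = count / total_time
    return out


def active_reading_time(
    segments: Sequence[EventSegment], sampling_rate: float
) -> float:
    """Time spent in fixation + saccade states, excluding blinks/missing."""
    n = sum(s.n_samples for s in segments if s.kind in (FIXATION, SACCADE))
    return n / sampling_rate


def saccade_variability(
    segments: Sequence[EventSegment], sampling_rate: float
) -> float:
    """Population std of onset-to-onset intervals between successive saccades.

    Trials with fewer than three saccades (fewer than two intervals) return 0
    so that every retained trial carries a defined value.
    """
    onsets = np.array([s.start for s in segments if s.kind == SACCADE], dtype=float)
    if len(onsets) < 3:
        return 0.0
    intervals = np.diff(onsets) / sampling_rate
    return float(np.std(intervals))


def extract_features(trial: GazeTrial) -> TrialRecord:
    """Compute the full 14-feature vector of one (retained) trial."""
    segments = segment_events(trial)
    fs = trial.sampling_rate
    values = conventional_features(segments, fs)
    values["active_reading_time"] = active_reading_time(segments, fs)
    values["saccade_variability"] = saccade_variability(segments, fs)
    record = complexity.complexity_record(trial)
    values["fixation_intersection_coefficient"] = (
        complexity.fixation_intersection_coefficient(record)
    )
    values["fixation_intersection_variability"] = (
        complexity.fixation_intersection_variability(record)
    )
    values["fixation_fractal_dimension"] = (
        complexity.fixation_fractal_dimension(record)
    )
    return TrialRecord(
        subject_id=trial.subject_id,
        group=trial.group,
        color_config=trial.color_config,
        features=FeatureVector(**values),
    )


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Feature table: metadata columns followed by the 14 feature columns."""
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "color_config": r.color_config,
            **r.features.as_dict(),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=METADATA_COLUMNS + ALL_FEATURES)


def features_from_trials(trials: Iterable[GazeTrial]) -> pd.DataFrame:
    """Extract features for a batch of trials, order-stable."""
    return records_to_frame(extract_features(t) for t in trials)


class GazeFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer mapping gaze trials to the 14-feature table.

    ``X`` is a sequence of :class:`~gazedys.trials.GazeTrial`; ``transform``
    returns a DataFrame of the 14 features, prefixed with the subject/group/
    color metadata columns when ``include_metadata`` is true.  Filtering by
    minimum reading time is deliberately *not* performed here (transformers
    must not drop rows); apply :func:`gazedys.trials.filter_trials` first.
    """

    def __init__(self, include_metadata: bool = True):
        self.include_metadata = include_metadata

    def fit(self, X: Sequence[GazeTrial], y=None) -> "GazeFeatureExtractor":
        for t in X:
            if not isinstance(t, GazeTrial):
                raise TypeError("X must be a sequence of GazeTrial objects")
        self.feature_names_ = list(ALL_FEATURES)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Sequence[GazeTrial]) -> pd.DataFrame:
        frame = features_from_trials(X)
        if not self.include_metadata:
            return frame[ALL_FEATURES]
        return frame

    def get_feature_names_out(self, input_features=None):
        return np.asarray(ALL_FEATURES, dtype=object)
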