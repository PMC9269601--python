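"""Gaze trial data model, tabular I/O and the reading-time exclusion filter.

A *trial* is one subject reading one text segment under one color
configuration.  It is fully described by three aligned per-sample sequences
-- horizontal gaze coordinate ``x`` (screen pixels), vertical coordinate
``y`` (screen pixels, origin top-left, increasing downward) and an event
status label (``FIXATION`` / ``SACCADE`` / ``BLINK``) -- plus subject and
condition metadata and the sampling rate of the tracker.

Trials are exchanged as plain UTF-8 CSV with one row per sample::

    subject_id,group,color_config,trial_id,sample_idx,x,y,event[,sampling_rate]

``sample_idx`` is a 0-based consecutive integer within a trial.  Missing
gaze during blinks is written as empty fields and stored in memory as NaN,
never as zeros.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FIXATION = "FIXATION"
SACCADE = "SACCADE"
BLINK = "BLINK"
EVENT_LABELS = (FIXATION, SACCADE, BLINK)

GROUP_CONTROL = "control"
GROUP_DYSLEXIC = "dyslexic"
GROUPS = (GROUP_CONTROL, GROUP_DYSLEXIC, "unknown")

#: Default tracker rate (samples/s) used when a file carries no rate column.
DEFAULT_SAMPLING_RATE = 60.0

#: Default minimum total reading time (s) below which a trial is excluded.
MIN_READING_TIME = 5.0

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "color_config",
    "trial_id",
    "sample_idx",
    "x",
    "y",
    "event",
    "sampling_rate",
]


@dataclasses.dataclass
class GazeTrial:
    """One reading trial: aligned gaze samples plus metadata.

    Invariants (checked on construction):

    * ``len(x) == len(y) == len(event) >= 1``
    * ``x``/``y`` are finite wherever the event label is not ``BLINK``;
      blink samples may carry NaN
    * ``sampling_rate > 0`` and the group/event vocabularies are respected
    """

    subject_id: str
    group: str
    color_config: str
    trial_id: str
    sampling_rate: float
    x: np.ndarray
    y: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.event = np.asarray(self.event, dtype=object)
        if not (self.x.ndim == self.y.ndim == self.event.ndim == 1):
            raise ValueError("x, y and event must be 1-D sequences")
        if not (len(self.x) == len(self.y) == len(self.event)):
            raise ValueError(
                f"trial {self.subject_id}/{self.trial_id}: x, y and event "
                f"lengths differ ({len(self.x)}, {len(self.y)}, {len(self.event)})"
            )
        if len(self.x) < 1:
            raise ValueError(f"trial {self.subject_id}/{self.trial_id} is empty")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        unknown = set(self.event) - set(EVENT_LABELS)
        if unknown:
            raise ValueError(f"unknown event labels {sorted(unknown)}")
        seen = self.event != BLINK
        if not (np.isfinite(self.x[seen]).all() and np.isfinite(self.y[seen]).all()):
            raise ValueError(
                f"trial {self.subject_id}/{self.trial_id}: non-finite gaze "
                "coordinates on a FIXATION/SACCADE sample"
            )

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Total trial duration in seconds (sample count / sampling rate)."""
        return self.n_samples / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        """One row per sample, in the CSV dialect column order."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "color_config": self.color_config,
                "trial_id": self.trial_id,
                "sample_idx": np.arange(self.n_samples),
                "x": self.x,
                "y": self.y,
                "event": self.event,
                "sampling_rate": self.sampling_rate,
            }
        )


def _fail_row(path, row_label, message) -> None:
    # +2: one for the header line, one for 0- vs 1-based counting.
    raise ValueError(f"{path}: line {row_label + 2}: {message}")


def read_trials(
    path,
    dialect: Mapping[str, str] | None = None,
    default_sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list[GazeTrial]:
    """Read trials from the CSV dialect described in the module docstring.

    Parameters
    ----------
    path : str or file-like
        CSV file with the trial dialect header.
    dialect : mapping, optional
        Maps event tokens found in the file onto the canonical labels
        (``FIXATION``/``SACCADE``/``BLINK``).  Defaults to the identity map
        on the canonical labels; any token outside the map is a validation
        error naming the offending line.
    default_sampling_rate : float
        Used for files without a ``sampling_rate`` column.
    """
    token_map = dict(dialect) if dialect is not None else {t: t for t in EVENT_LABELS}
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str},
                     skip_blank_lines=False, float_precision="round_trip")
    required = [c for c in TRIAL_COLUMNS if c != "sampling_rate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    for col in ("x", "y", "sample_idx"):
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            _fail_row(path, int(np.flatnonzero(bad.to_numpy())[0]),
                      f"cannot parse {col}={raw[bad].iloc[0]!r}")
        df[col] = converted

    unknown = ~df["event"].isin(token_map)
    if unknown.any():
        _fail_row(path, int(np.flatnonzero(unknown.to_numpy())[0]),
                  f"unknown event token {df['event'][unknown].iloc[0]!r}")
    df["event"] = df["event"].map(token_map)

    missing_xy = (df["x"].isna() | df["y"].isna()) & (df["event"] != BLINK)
    if missing_xy.any():
        _fail_row(path, int(np.flatnonzero(missing_xy.to_numpy())[0]),
                  "missing x/y on a non-BLINK sample")

    trials: list[GazeTrial] = []
    for (subject_id, trial_id), chunk in df.groupby(["subject_id", "trial_id"], sort=False):
        chunk = chunk.sort_values("sample_idx", kind="stable")
        idx = chunk["sample_idx"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(
                f"{path}: trial {subject_id}/{trial_id}: sample_idx is not "
                "0-based and consecutive"
            )
        if "sampling_rate" in chunk.columns:
            rates = chunk["sampling_rate"].astype(float).unique()
            if len(rates) != 1:
                raise ValueError(
                    f"{path}: trial {subject_id}/{trial_id}: inconsistent "
                    f"sampling_rate values {sorted(rates)}"
                )
            rate = float(rates[0])
        else:
            rate = float(default_sampling_rate)
        for col in ("group", "color_config"):
            if chunk[col].nunique() != 1:
                raise ValueError(
                    f"{path}: trial {subject_id}/{trial_id}: inconsistent {col}"
                )
        trials.append(
            GazeTrial(
                subject_id=str(subject_id),
                group=str(chunk["group"].iloc[0]),
                color_config=str(chunk["color_config"].iloc[0]),
                trial_id=str(trial_id),
                sampling_rate=rate,
                x=chunk["x"].to_numpy(),
                y=chunk["y"].to_numpy(),
                event=chunk["event"].to_numpy(),
            )
        )
    return trials


def write_trials(trials: Iterable[GazeTrial], path) -> None:
    """Write trials to CSV, losslessly round-trippable by :func:`read_trials`."""
    frames = [t.to_frame() for t in trials]
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=TRIAL_COLUMNS)
    # %.17g guarantees a lossless float round-trip through the text format
    out.to_csv(path, index=False, float_format="%.17g")


def filter_trials(
    trials: Sequence[GazeTrial], min_reading_time: float = MIN_READING_TIME
) -> tuple[list[GazeTrial], list[GazeTrial]]:
    """Partition trials by the minimum-reading-time exclusion rule.

    A trial is retained iff its total duration (sample count divided by
    sampling rate) is at least ``min_reading_time`` seconds; trials below
    the threshold reflect insufficient focus on the text and are excluded
    from every downstream analysis.  The boundary case (duration exactly
    equal to the threshold) is retained.
    """
    retained = [t for t in trials if t.duration >= min_reading_time]
    excluded = [t for t in trials if t.duration < min_reading_time]
    return retained, excluded
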