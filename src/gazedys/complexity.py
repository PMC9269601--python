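"""Fixation-gaze complexity features.

Dyslexic readers show chaotic, self-overlapping gaze traces *within*
fixations.  This module quantifies that with three trial-level features:

* **Fixation intersection coefficient (FIC)** -- the mean, over a trial's
  fixations, of the number of self-intersections of each fixation polyline.
* **Fixation intersection variability** -- the population standard deviation
  of the same per-fixation counts.
* **Fixation fractal dimension (FFD)** -- the mean box-counting dimension of
  the figure drawn by each fixation polyline (about 1 for a smooth trace,
  approaching 2 for a plane-filling scribble).

Self-intersections are counted as unordered pairs of non-adjacent polyline
segments whose *closed* segments intersect; segment pairs sharing a polyline
vertex (adjacent pairs) are never counted, and a collinear-overlap pair
counts once.  The box-counting estimator uses a dyadic ladder of grids
anchored at the polyline bounding box; see :func:`box_counting_dimension`.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .events import fixation_polylines, segment_events
from .trials import GazeTrial

#: Absolute tolerance for the collinearity / on-segment predicates.
GEOM_EPS = 1e-9


def _cross(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _sign(d: np.ndarray, eps: float) -> np.ndarray:
    s = np.sign(d)
    s[np.abs(d) <= eps] = 0.0
    return s


def _on_bbox(a: np.ndarray, b: np.ndarray, p: np.ndarray, eps: float) -> np.ndarray:
    """Is p inside the axis-aligned bounding box of segment (a, b)?"""
    lo = np.minimum(a, b) - eps
    hi = np.maximum(a, b) + eps
    return ((p >= lo) & (p <= hi)).all(axis=-1)


def count_self_intersections(polyline, eps: float = GEOM_EPS) -> int:
    """Number of self-intersections of an open polyline.

    Counts unordered pairs of non-adjacent segments whose closed segments
    intersect (proper crossings, endpoint touches and collinear overlaps all
    count as one per pair).  Polylines with fewer than 4 points have no
    non-adjacent segment pair and return 0.
    """
    pts = np.asarray(polyline, dtype=float)
    if len(pts) < 4:
        return 0
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be a sequence of (x, y) points")
    if not np.isfinite(pts).all():
        raise ValueError("polyline contains non-finite points")
    a, b = pts[:-1], pts[1:]
    i, j = np.triu_indices(len(a), k=2)  # non-adjacent pairs only
    p, q = a[i], b[i]
    r, s = a[j], b[j]
    d1 = _cross(s - r, p - r)
    d2 = _cross(s - r, q - r)
    d3 = _cross(q - p, r - p)
    d4 = _cross(q - p, s - p)
    s1, s2, s3, s4 = (_sign(d, eps) for d in (d1, d2, d3, d4))
    proper = (s1 * s2 < 0) & (s3 * s4 < 0)
    touch = (
        ((s1 == 0) & _on_bbox(r, s, p, eps))
        | ((s2 == 0) & _on_bbox(r, s, q, eps))
        | ((s3 == 0) & _on_bbox(p, q, r, eps))
        | ((s4 == 0) & _on_bbox(p, q, s, eps))
    )
    return int(np.count_nonzero(proper | touch))


def _densify(pts: np.ndarray, max_spacing: float = 0.5) -> np.ndarray:
    """Interpolate extra points so consecutive samples are <= max_spacing apart."""
    pieces = [pts[:1]]
    for k in range(len(pts) - 1):
        seg = pts[k + 1] - pts[k]
        length = float(np.hypot(*seg))
        n = max(1, int(np.ceil(length / max_spacing)))
        frac = np.arange(1, n + 1)[:, None] / n
        pieces.append(pts[k] + frac * seg)
    return np.concatenate(pieces)


def box_counting_dimension(polyline) -> float:
    """Box-counting fractal dimension of the figure drawn by a polyline.

    The grid is anchored at the bounding-box top-left; the base scale is
    ``S = max(width, height, 4)`` px, padded up to 16 px so the dyadic ladder
    ``S/2, S/4, ...`` always offers at least three scales before stopping at
    ``max(2 px, S/64)``.  The polyline is densified to <= 0.5 px point
    spacing, occupied boxes are counted at each scale and the dimension is
    the OLS slope of log N(s) against log(1/s) over the whole ladder.

    Degenerate polylines (< 2 distinct points) return 0 by convention; the
    estimate is clipped to [0, 2.2] to bound estimator overshoot.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or (len(pts) and pts.shape[1] != 2):
        raise ValueError("polyline must be a sequence of (x, y) points")
    if len(pts) < 2 or len(np.unique(pts, axis=0)) < 2:
        return 0.0
    if not np.isfinite(pts).all():
        raise ValueError("polyline contains non-finite points")
    origin = pts.min(axis=0)
    extent = pts.max(axis=0) - origin
    base = max(float(extent.max()), 4.0)
    if base < 16.0:  # guarantee >= 3 dyadic scales with boxes >= 2 px
        base = 16.0
    floor = max(2.0, base / 64.0)
    scales = []
    s = base / 2.0
    while s >= floor - 1e-12:
        scales.append(s)
        s /= 2.0
    # quantize to 1e-6 px so bin assignment is immune to the last-bit float
    # jitter a rigid translation introduces in (pts - origin)
    dense = np.round(_densify(pts - origin), 6)
    counts = []
    for s in scales:
        idx = np.floor(dense / s).astype(np.int64)
        # points on the far bounding-box edge belong to the last box
        np.clip(idx, 0, max(int(np.ceil(base / s)) - 1, 0), out=idx)
        counts.append(len(np.unique(idx[:, 0] << 32 | idx[:, 1])))
    slope = np.polyfit(np.log(1.0 / np.asarray(scales)), np.log(counts), 1)[0]
    return float(np.clip(slope, 0.0, 2.2))


@dataclasses.dataclass
class FixationComplexityRecord:
    """Per-fixation complexity measurements for one trial.

    ``fi[j]`` is the self-intersection count and ``fd[j]`` the box-counting
    dimension of fixation ``j``; ``n`` is the trial's fixation count.
    """

    fi: np.ndarray
    fd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.fi = np.asarray(self.fi, dtype=int)
        self.fd = np.asarray(self.fd, dtype=float)
        if len(self.fi) != self.n or len(self.fd) != self.n:
            raise ValueError("fi and fd must have one entry per fixation")
        if (self.fi < 0).any():
            raise ValueError("self-intersection counts must be >= 0")
        if ((self.fd < 0) | (self.fd > 2.2)).any():
            raise ValueError("fractal-dimension estimates must lie in [0, 2.2]")


def fixation_intersection_coefficient(record: FixationComplexityRecord) -> float:
    """Mean per-fixation self-intersection count (0 for a fixation-free trial)."""
    return float(np.mean(record.fi)) if record.n else 0.0


def fixation_intersection_variability(record: FixationComplexityRecord) -> float:
    """Population standard deviation of the per-fixation intersection counts."""
    return float(np.std(record.fi)) if record.n > 1 else 0.0


def fixation_fractal_dimension(record: FixationComplexityRecord) -> float:
    """Mean per-fixation box-counting dimension (0 for a fixation-free trial)."""
    return float(np.mean(record.fd)) if record.n else 0.0


def complexity_record(trial: GazeTrial) -> FixationComplexityRecord:
    """Compute per-fixation intersection counts and fractal dimensions."""
    polylines = fixation_polylines(trial, segment_events(trial))
    fi = [count_self_intersections(p) for p in polylines]
    fd = [box_counting_dimension(p) for p in polylines]
    return FixationComplexityRecord(fi=np.array(fi, dtype=int),
                                    fd=np.array(fd, dtype=float),
                                    n=len(polylines))
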