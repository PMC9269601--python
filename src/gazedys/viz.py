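"""Scanpath rendering of a reading trial.

A trial is drawn as the sequence of lines connecting consecutive gaze
samples, with four encoding rules:

* line color encodes the sample-to-sample distance through a jet colormap
  spanning 0-200 px (longer jumps clip to the top color);
* lines within fixations are solid, lines touching a saccade sample are
  dashed;
* the last valid gaze point before and the first after each blink are marked
  with red stars (the blink itself draws nothing);
* opacity decays linearly with sample index ``t`` as
  ``0.9 - 0.8 * min(1, t / (MRT * Ts))``, i.e. from 0.9 at trial onset to
  0.1 at the maximum reading time MRT (default 40 s at Ts = 60 Hz).

The y axis is drawn downward to match screen raster coordinates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from matplotlib import colormaps
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.collections import LineCollection
from matplotlib.figure import Figure

from .events import blink_boundary_points, segment_events
from .trials import BLINK, FIXATION, GazeTrial


@dataclasses.dataclass
class RenderConfig:
    """Scanpath rendering parameters.

    ``mrt`` is the maximum reading time in seconds and ``ts`` the sampling
    rate assumed by the opacity decay; ``colormap_max_len`` is the line
    length (px) mapped to the top of the jet colormap.
    """

    mrt: float = 40.0
    ts: float = 60.0
    colormap_max_len: float = 200.0
    figsize: tuple[float, float] = (9.6, 5.4)
    dpi: int = 100
    line_width: float = 1.2
    star_size: float = 90.0

    def __post_init__(self) -> None:
        if not (self.mrt > 0 and self.ts > 0 and self.colormap_max_len > 0):
            raise ValueError("mrt, ts and colormap_max_len must be positive")


_JET = colormaps["jet"]


def opacity_at(t, cfg: RenderConfig | None = None):
    """Line opacity at sample index ``t``: ``0.9 - 0.8 * min(1, t/(mrt*ts))``.

    Piecewise linear and non-increasing, from 0.9 at the first sample down
    to 0.1 at (and beyond) the maximum reading time.
    """
    cfg = cfg or RenderConfig()
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("sample index must be >= 0")
    value = 0.9 - 0.8 * np.minimum(1.0, t / (cfg.mrt * cfg.ts))
    return float(value) if value.ndim == 0 else value


def segment_color(length: float, cfg: RenderConfig | None = None) -> tuple[float, float, float]:
    """Jet colormap evaluated at the (clipped) line length in pixels."""
    cfg = cfg or RenderConfig()
    if length < 0:
        raise ValueError("length must be >= 0")
    frac = min(float(length), cfg.colormap_max_len) / cfg.colormap_max_len
    return tuple(_JET(frac)[:3])


def render_trial(trial: GazeTrial, cfg: RenderConfig | None = None, path=None) -> Figure:
    """Render one trial to a matplotlib figure (and optionally a PNG file).

    One line per consecutive sample pair, skipping pairs with a blink/missing
    endpoint; solid when both endpoints are fixation samples, dashed
    otherwise; red stars at the blink boundary points.  Rendering is fully
    deterministic for a given trial and configuration.
    """
    cfg = cfg or RenderConfig()
    x, y, ev = trial.x, trial.y, trial.event
    n = trial.n_samples

    fig = Figure(figsize=cfg.figsize, dpi=cfg.dpi)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)

    if n >= 2:
        first = np.arange(n - 1)
        ok = (ev[:-1] != BLINK) & (ev[1:] != BLINK)
        first = first[ok]
        if len(first):
            p0 = np.column_stack([x[first], y[first]])
            p1 = np.column_stack([x[first + 1], y[first + 1]])
            lengths = np.hypot(*(p1 - p0).T)
            frac = np.minimum(lengths, cfg.colormap_max_len) / cfg.colormap_max_len
            rgba = _JET(frac)
            rgba[:, 3] = 0.9 - 0.8 * np.minimum(1.0, first / (cfg.mrt * cfg.ts))
            segs = np.stack([p0, p1], axis=1)
            solid = (ev[first] == FIXATION) & (ev[first + 1] == FIXATION)
            for mask, style in ((solid, "solid"), (~solid, "dashed")):
                if mask.any():
                    ax.add_collection(
                        LineCollection(segs[mask], colors=rgba[mask],
                                       linewidths=cfg.line_width, linestyles=style)
                    )

    stars = [p for pair in blink_boundary_points(trial, segment_events(trial))
             for p in pair if p is not None]
    if stars:
        pts = np.asarray(stars)
        ax.scatter(pts[:, 0], pts[:, 1], marker="*", s=cfg.star_size,
                   color="red", zorder=3)

    finite = np.isfinite(x) & np.isfinite(y)
    if finite.any():
        ax.set_xlim(x[finite].min() - 20, x[finite].max() + 20)
        ax.set_ylim(y[finite].min() - 20, y[finite].max() + 20)
    ax.invert_yaxis()  # screen raster: y grows downward
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"{trial.subject_id} / {trial.trial_id} ({trial.group})")

    if path is not None:
        fig.savefig(path, format="png", dpi=cfg.dpi,
                    metadata={"Software": "gazedys"})
    return fig
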