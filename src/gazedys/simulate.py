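"""Synthetic reading-gaze generator.

Emulates the structure of a colored-background reading study: each subject
reads one text segment per color configuration while a 60 Hz tracker labels
every sample fixation, saccade or blink/missing.  A trial alternates
fixation clusters (a bounded, direction-persistent random walk around a word
anchor) with short saccadic bridges sweeping the text lines left to right
(with occasional regressions), plus Poisson blink gaps stored as missing
coordinates.

Group structure: the default profile injects the class contrast *only*
through the fixation-trace complexity dials -- dyslexic-like subjects get a
larger intra-fixation step size (``jitter_sigma``) and a higher
direction-reversal probability (``turn_prob``), which produces the tangled,
self-intersecting fixation traces the complexity features quantify.  Dwell
times, inter-saccade variability, regression rate and blink behavior are
identical across groups by default, so temporal and count features carry no
class signal; every dial is nevertheless settable per group.  Lognormal
per-subject random effects scale jitter and dwell multiplicatively, inducing
within-subject correlation across colors.  Colors do not modulate behavior:
color-pair comparisons are null by construction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .trials import BLINK, FIXATION, SACCADE, GazeTrial

#: The 13 color-configuration tokens (referent white background, 7 further
#: colored backgrounds, 5 colored overlays).
DEFAULT_COLORS = (
    "white_bg", "yellow_bg", "orange_bg", "turquoise_bg", "blue_bg",
    "green_bg", "purple_bg", "pink_bg",
    "yellow_ov", "orange_ov", "turquoise_ov", "blue_ov", "green_ov",
)


@dataclasses.dataclass
class GroupProfile:
    """Per-group generator parameters.

    dwell_mean/dwell_sigma : mean and sd of fixation dwell time (s); the sd
        is also the inter-saccade-interval variability dial, since saccade
        onsets are spaced by dwells.
    jitter_sigma : intra-fixation random-walk step scale (px/sample).
    turn_prob : probability per sample of a sharp direction reversal inside
        a fixation; with the step scale, this is the complexity dial.
    regression_prob : probability of regressing two words back after a word.
    """

    dwell_mean: float = 0.25
    dwell_sigma: float = 0.05
    jitter_sigma: float = 0.6
    turn_prob: float = 0.08
    regression_prob: float = 0.08

    def validate(self) -> None:
        if self.dwell_mean <= 0 or self.dwell_sigma < 0 or self.jitter_sigma < 0:
            raise ValueError("dwell/jitter parameters must be non-negative "
                             "(dwell_mean strictly positive)")
        if not (0 <= self.turn_prob <= 1 and 0 <= self.regression_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


#: Default dyslexic-like profile: larger, more frequently reversing
#: intra-fixation steps; all temporal dials equal to the control profile.
DYSLEXIC_PROFILE = GroupProfile(jitter_sigma=2.2, turn_prob=0.45)


@dataclasses.dataclass
class SimConfig:
    """Study-level generator configuration (defaults emulate the screening
    study layout: 15 + 15 subjects, 13 colors, 60 Hz, 40 s reading cap)."""

    n_control: int = 15
    n_dyslexic: int = 15
    colors: Sequence[str] = DEFAULT_COLORS
    sampling_rate: float = 60.0
    control: GroupProfile = dataclasses.field(default_factory=GroupProfile)
    dyslexic: GroupProfile = dataclasses.field(default_factory=lambda: dataclasses.replace(DYSLEXIC_PROFILE))
    # text layout (screen px, y downward)
    n_lines: int = 6
    line_y0: float = 120.0
    line_spacing: float = 64.0
    x_start: float = 120.0
    x_end: float = 840.0
    words_per_line: int = 8
    fixation_radius: float = 12.0
    # blinks
    blink_rate: float = 3.0  # events/minute
    blink_duration: float = 0.2  # seconds
    # subject-level random effects (lognormal sigma on jitter and dwell)
    subject_sigma: float = 0.15
    max_reading_time: float = 40.0
    # optional degradation dials
    short_trial_rate: float = 0.0  # fraction of trials truncated below 5 s
    n_dropout: int = 0  # trials removed entirely from the dataset

    def validate(self) -> None:
        if self.n_control < 0 or self.n_dyslexic < 0:
            raise ValueError("subject counts must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.blink_rate < 0 or self.blink_duration < 0 or self.subject_sigma < 0:
            raise ValueError("blink and random-effect parameters must be >= 0")
        if not 0 <= self.short_trial_rate <= 1:
            raise ValueError("short_trial_rate must lie in [0, 1]")
        if self.max_reading_time <= 0:
            raise ValueError("max_reading_time must be > 0")
        self.control.validate()
        self.dyslexic.validate()
        if self.dyslexic.jitter_sigma < self.control.jitter_sigma:
            raise ValueError("default-profile contract: dyslexic jitter_sigma "
                             "must be >= control jitter_sigma")


@dataclasses.dataclass
class SubjectEffects:
    """Multiplicative per-subject random effects on jitter and dwell."""

    jitter_mult: float = 1.0
    dwell_mult: float = 1.0


def draw_subject_effects(cfg: SimConfig, rng: np.random.Generator) -> SubjectEffects:
    return SubjectEffects(
        jitter_mult=float(np.exp(rng.normal(0.0, cfg.subject_sigma))),
        dwell_mult=float(np.exp(rng.normal(0.0, cfg.subject_sigma))),
    )


def fixation_walk(
    rng: np.random.Generator,
    anchor: np.ndarray,
    n_samples: int,
    jitter_sigma: float,
    turn_prob: float,
    radius: float,
) -> np.ndarray:
    """Bounded direction-persistent random walk around a word anchor.

    Between reversals the heading diffuses slowly, producing a smooth
    drifting trace; each reversal resamples the heading uniformly, and a
    soft reflecting boundary pulls the walk back inside ``radius`` px of the
    anchor.  Larger steps and more reversals fold the trace over itself,
    which is what raises the self-intersection count and fractal dimension.
    """
    pts = np.empty((n_samples, 2))
    pos = anchor + rng.normal(0.0, 1.5, size=2)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    for k in range(n_samples):
        pts[k] = pos
        if rng.random() < turn_prob:
            theta = rng.uniform(0.0, 2.0 * np.pi)
        else:
            theta += rng.normal(0.0, 0.3)
        step = abs(rng.normal(jitter_sigma, 0.5 * jitter_sigma))
        pos = pos + step * np.array([np.cos(theta), np.sin(theta)])
        offset = pos - anchor
        dist = float(np.hypot(*offset))
        if dist > radius:
            pos = anchor + offset * (0.8 * radius / dist)
            theta = rng.uniform(0.0, 2.0 * np.pi)
    return pts


def _word_anchors(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    xs = np.linspace(cfg.x_start, cfg.x_end, cfg.words_per_line)
    anchors = []
    for line in range(cfg.n_lines):
        y = cfg.line_y0 + line * cfg.line_spacing
        for x in xs:
            anchors.append((x + rng.normal(0, 3.0), y + rng.normal(0, 2.0)))
    return np.asarray(anchors)


def _word_sequence(cfg: SimConfig, profile: GroupProfile, rng: np.random.Generator) -> list[int]:
    order: list[int] = []
    n_words = cfg.n_lines * cfg.words_per_line
    for w in range(n_words):
        order.append(w)
        if w >= 2 and rng.random() < profile.regression_prob:
            order.append(w - 2)  # brief regression, then resume forward
    return order


def simulate_trial(
    effects: SubjectEffects,
    group: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    subject_id: str = "s00",
    color: str = "white_bg",
    short: bool = False,
) -> GazeTrial:
    """Generate one labeled reading trial.

    Fully deterministic given the generator state; with ``blink_rate == 0``
    no BLINK samples are emitted; duration is >= 5 s by construction (the
    default layout reads ~48 words at ~0.25 s dwell) unless ``short`` is
    set, in which case the trial is truncated to 2-4.5 s to exercise the
    reading-time exclusion filter.
    """
    cfg.validate()
    profile = cfg.dyslexic if group == "dyslexic" else cfg.control
    fs = cfg.sampling_rate
    jitter = profile.jitter_sigma * effects.jitter_mult
    anchors = _word_anchors(cfg, rng)
    order = _word_sequence(cfg, profile, rng)

    xs: list[np.ndarray] = []
    labels: list[str] = []
    prev_point: np.ndarray | None = None
    for word in order:
        anchor = anchors[word]
        if prev_point is not None:
            n_sac = int(rng.integers(2, 5))
            frac = np.arange(1, n_sac + 1)[:, None] / (n_sac + 1)
            bridge = prev_point + frac * (anchor - prev_point)
            bridge += rng.normal(0.0, 1.0, size=bridge.shape)
            xs.append(bridge)
            labels.extend([SACCADE] * n_sac)
        dwell = max(
            3.0 / fs,
            profile.dwell_mean * effects.dwell_mult + rng.normal(0.0, profile.dwell_sigma),
        )
        n_fix = max(3, int(round(dwell * fs)))
        walk = fixation_walk(rng, anchor, n_fix, jitter, profile.turn_prob,
                             cfg.fixation_radius)
        xs.append(walk)
        labels.extend([FIXATION] * n_fix)
        prev_point = walk[-1]

    points = np.concatenate(xs)
    event = np.asarray(labels, dtype=object)

    # Poisson blink gaps: windows of missing data replacing whatever they cover
    if cfg.blink_rate > 0 and cfg.blink_duration > 0:
        n = len(points)
        duration_min = n / fs / 60.0
        width = max(1, int(round(cfg.blink_duration * fs)))
        for start in rng.uniform(0, n - width, size=rng.poisson(cfg.blink_rate * duration_min)):
            lo = int(start)
            points[lo:lo + width] = np.nan
            event[lo:lo + width] = BLINK

    n_cap = int(cfg.max_reading_time * fs)
    if short:
        n_cap = min(n_cap, int(rng.uniform(2.0, 4.5) * fs))
    points = points[:n_cap]
    event = event[:n_cap]

    return GazeTrial(
        subject_id=subject_id,
        group=group,
        color_config=color,
        trial_id=color,
        sampling_rate=fs,
        x=points[:, 0],
        y=points[:, 1],
        event=event,
    )


def simulate_dataset(cfg: SimConfig | None = None, seed: int = 0) -> list[GazeTrial]:
    """Generate the full study: one trial per subject x color configuration.

    Subjects ``ctl01..`` and ``dys01..`` each read every color; per-subject
    random effects are drawn once and shared across that subject's trials.
    ``cfg.short_trial_rate`` marks random trials for sub-threshold
    truncation and ``cfg.n_dropout`` removes random trials outright,
    emulating incomplete studies.  Deterministic given ``seed``.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    trials: list[GazeTrial] = []
    roster = [("control", f"ctl{i + 1:02d}") for i in range(cfg.n_control)]
    roster += [("dyslexic", f"dys{i + 1:02d}") for i in range(cfg.n_dyslexic)]
    for group, subject_id in roster:
        effects = draw_subject_effects(cfg, rng)
        for color in cfg.colors:
            short = bool(rng.random() < cfg.short_trial_rate)
            trials.append(
                simulate_trial(effects, group, cfg, rng,
                               subject_id=subject_id, color=color, short=short)
            )
    if cfg.n_dropout:
        if cfg.n_dropout > len(trials):
            raise ValueError("n_dropout exceeds the number of generated trials")
        keep = np.ones(len(trials), dtype=bool)
        keep[rng.choice(len(trials), size=cfg.n_dropout, replace=False)] = False
        trials = [t for t, k in zip(trials, keep) if k]
    return trials
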