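"""Nonparametric analysis of group and color-configuration effects.

Three-stage protocol over the trial feature table:

1. **Mann-Whitney U** per color configuration, dyslexic vs control, testing
   a location difference of the feature between groups;
2. **Levene's test** (center = mean) per color configuration, testing a
   dispersion difference between groups;
3. **Wilcoxon signed-rank** within the dyslexic group, for every unordered
   pair of color configurations, testing whether one color shifts the
   feature relative to another in the same subjects.

Each subject contributes one value per color (their single trial under that
color; the mean if replicates ever occur).  Tests are two-sided; exact null
distributions are used when group sizes permit (both groups <= 20 and
tie-free for Mann-Whitney, <= 25 nonzero differences for Wilcoxon), falling
back to the tie-corrected normal approximation otherwise.  No multiple-testing correction is applied by default, matching
the raw-threshold reporting convention; a Holm adjustment is available via
:func:`holm_adjust`.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trials import GROUP_CONTROL, GROUP_DYSLEXIC

#: Short aliases accepted wherever a feature name is expected.
FEATURE_ALIASES = {
    "fic": "fixation_intersection_coefficient",
    "fiv": "fixation_intersection_variability",
    "ffd": "fixation_fractal_dimension",
    "art": "active_reading_time",
    "sv": "saccade_variability",
}


@dataclasses.dataclass
class StatResult:
    """One test outcome; ``color_b`` is set only for paired color tests."""

    feature: str
    test: str  # "mann_whitney" | "levene" | "wilcoxon"
    color_a: str
    color_b: str | None
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    computable: bool = True


def resolve_feature(name: str) -> str:
    return FEATURE_ALIASES.get(name.lower(), name)


def _subject_values(frame: pd.DataFrame, feature: str) -> pd.DataFrame:
    """One value per (subject, group, color): the subject's trial value."""
    return (
        frame.groupby(["subject_id", "group", "color_config"], sort=False)[feature]
        .mean()
        .reset_index()
    )


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for independent samples.

    Exact null distribution when both samples have <= 20 observations and
    the pooled data are tie-free; otherwise the normal approximation with
    tie correction.  Returns ``(U of the first sample, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = len(x) <= 20 and len(y) <= 20 and not _has_ties(np.concatenate([x, y]))
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired samples, zeros dropped.

    Exact sign-flip distribution when <= 25 nonzero differences remain;
    tie-corrected normal approximation otherwise.  Raises ``ValueError``
    when no nonzero difference exists.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        raise ValueError("all paired differences are zero")
    exact = len(nonzero) <= 25
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                       method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)


def between_group_tests(
    frame: pd.DataFrame,
    feature: str,
    colors: Sequence[str] | None = None,
    levene_center: str = "mean",
) -> list[StatResult]:
    """Mann-Whitney and Levene tests per color, dyslexic vs control.

    Colors where either group is empty (or, for Levene, has fewer than two
    values) yield results flagged not-computable rather than raising.
    """
    feature = resolve_feature(feature)
    values = _subject_values(frame, feature)
    if colors is None:
        colors = list(dict.fromkeys(frame["color_config"]))
    out: list[StatResult] = []
    for color in colors:
        cell = values[values["color_config"] == color]
        dys = cell.loc[cell["group"] == GROUP_DYSLEXIC, feature].to_numpy()
        ctl = cell.loc[cell["group"] == GROUP_CONTROL, feature].to_numpy()
        base = dict(feature=feature, color_a=color, color_b=None,
                    n_a=len(dys), n_b=len(ctl))
        if len(dys) == 0 or len(ctl) == 0:
            for test in ("mann_whitney", "levene"):
                out.append(StatResult(test=test, statistic=math.nan,
                                      p_value=math.nan, computable=False, **base))
            continue
        stat, p = mann_whitney(dys, ctl)
        out.append(StatResult(test="mann_whitney", statistic=stat, p_value=p, **base))
        if min(len(dys), len(ctl)) < 2:
            out.append(StatResult(test="levene", statistic=math.nan,
                                  p_value=math.nan, computable=False, **base))
        else:
            stat, p = sps.levene(dys, ctl, center=levene_center)
            out.append(StatResult(test="levene", statistic=float(stat),
                                  p_value=float(p), **base))
    return out


def within_group_pairwise(
    frame: pd.DataFrame,
    feature: str,
    group: str = GROUP_DYSLEXIC,
    colors: Sequence[str] | None = None,
) -> list[StatResult]:
    """Wilcoxon signed-rank over every unordered pair of colors, one group.

    Subjects enter a pair only if they have a value under both colors
    (missingness from excluded trials is handled pairwise).  Pairs with
    fewer than two usable subjects, or with all paired differences zero,
    are flagged not-computable.
    """
    feature = resolve_feature(feature)
    if group not in (GROUP_CONTROL, GROUP_DYSLEXIC):
        raise ValueError(f"unknown group token {group!r}")
    values = _subject_values(frame, feature)
    values = values[values["group"] == group]
    if colors is None:
        colors = list(dict.fromkeys(frame["color_config"]))
    if len(colors) < 2:
        raise ValueError("pairwise color analysis needs >= 2 color configurations")
    wide = values.pivot(index="subject_id", columns="color_config", values=feature)
    out: list[StatResult] = []
    for color_a, color_b in itertools.combinations(colors, 2):
        if color_a in wide.columns and color_b in wide.columns:
            pair = wide[[color_a, color_b]].dropna()
        else:
            pair = pd.DataFrame(columns=[color_a, color_b])
        n = len(pair)
        base = dict(feature=feature, test="wilcoxon",
                    color_a=color_a, color_b=color_b, n_a=n, n_b=n)
        if n < 2:
            out.append(StatResult(statistic=math.nan, p_value=math.nan,
                                  computable=False, **base))
            continue
        try:
            stat, p = wilcoxon_signed_rank(pair[color_a].to_numpy(),
                                           pair[color_b].to_numpy())
        except ValueError:
            out.append(StatResult(statistic=math.nan, p_value=math.nan,
                                  computable=False, **base))
            continue
        out.append(StatResult(statistic=stat, p_value=p, **base))
    return out


def holm_adjust(results: Sequence[StatResult]) -> list[float]:
    """Holm step-down adjusted p-values for the computable results.

    Returns one adjusted p per input result (NaN where not computable);
    inputs are not modified.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.array([r.p_value for r in results], dtype=float)
    ok = np.array([r.computable for r in results], dtype=bool) & np.isfinite(p)
    adjusted = np.full(len(p), math.nan)
    if ok.any():
        adjusted[ok] = multipletests(p[ok], method="holm")[1]
    return adjusted.tolist()


def results_to_frame(results: Sequence[StatResult]) -> pd.DataFrame:
    """Tabular form: feature,test,color_a,color_b,n_a,n_b,statistic,p_value,computable."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=["feature", "test", "color_a", "color_b", "n_a", "n_b",
                 "statistic", "p_value", "computable"],
    )
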