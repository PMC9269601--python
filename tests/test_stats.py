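"""Nonparametric group and color-configuration tests against exact oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gazedys.stats import (
    between_group_tests,
    holm_adjust,
    mann_whitney,
    resolve_feature,
    results_to_frame,
    wilcoxon_signed_rank,
    within_group_pairwise,
)


def stats_frame(dys, ctl, colors=("white_bg",), feature="fic_value"):
    """Feature table with given per-subject values replicated per color."""
    rows = []
    for color in colors:
        for i, v in enumerate(dys):
            rows.append({"subject_id": f"d{i:02d}", "group": "dyslexic",
                         "color_config": color, feature: v})
        for i, v in enumerate(ctl):
            rows.append({"subject_id": f"c{i:02d}", "group": "control",
                         "color_config": color, feature: v})
    return pd.DataFrame(rows)


class TestMannWhitney:
    def test_exact_enumeration_oracle(self):
        # all 20 rank assignments of {1,2,3} vs {4,5,6}: U = 0 is one of the
        # two most extreme tables, exact two-sided p = 2 * 1/20 = 0.1
        stat, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=9), rng.normal(1.0, 1.0, size=9)
        _, p_raw = mann_whitney(x, y)
        _, p_exp = mann_whitney(np.exp(x), np.exp(y))
        _, p_cub = mann_whitney(x ** 3, y ** 3)
        assert p_raw == pytest.approx(p_exp) == pytest.approx(p_cub)

    def test_exact_type_one_error_controlled_under_null(self):
        rng = np.random.default_rng(2024)
        n_rep = 1000
        rejections = sum(
            mann_whitney(rng.random(6), rng.random(6))[1] <= 0.05
            for _ in range(n_rep))
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep <= 0.05 + 2 * se


class TestWilcoxon:
    def test_exact_sign_flip_oracle(self):
        # six constant differences of -1: W = 0, exact p = 2/2^6 = 0.03125
        a = np.array([1.0, 2, 3, 4, 5, 6])
        stat, p = wilcoxon_signed_rank(a, a + 1)
        assert stat == 0.0
        assert p == pytest.approx(2 / 64)

    def test_all_zero_differences_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(a, a)


class TestBetweenGroupTests:
    def test_exact_mann_whitney_through_feature_table(self):
        frame = stats_frame([1, 2, 3], [4, 5, 6])
        mw = [r for r in between_group_tests(frame, "fic_value")
              if r.test == "mann_whitney"]
        assert len(mw) == 1
        assert mw[0].p_value == pytest.approx(0.1)
        assert (mw[0].n_a, mw[0].n_b) == (3, 3)

    def test_identical_groups_have_zero_levene_statistic(self):
        frame = stats_frame([1, 2, 3], [1, 2, 3])
        (lev,) = [r for r in between_group_tests(frame, "fic_value")
                  if r.test == "levene"]
        assert lev.statistic == pytest.approx(0.0)

    def test_empty_group_flagged_not_computable(self):
        frame = stats_frame([1, 2, 3], [])
        results = between_group_tests(frame, "fic_value")
        assert all(not r.computable for r in results)
        assert all(np.isnan(r.p_value) for r in results)

    def test_large_shift_is_significant_for_every_color(self):
        rng = np.random.default_rng(77)
        colors = [f"color{k}" for k in range(13)]
        rows = []
        for color in colors:
            for i in range(15):
                rows.append({"subject_id": f"d{i}", "group": "dyslexic",
                             "color_config": color, "v": rng.normal(5.0, 1.0)})
                rows.append({"subject_id": f"c{i}", "group": "control",
                             "color_config": color, "v": rng.normal(0.0, 1.0)})
        frame = pd.DataFrame(rows)
        mw = [r for r in between_group_tests(frame, "v") if r.test == "mann_whitney"]
        assert len(mw) == 13
        assert all(r.p_value < 0.001 for r in mw)


class TestWithinGroupPairwise:
    def test_all_color_pairs_enumerated(self):
        rng = np.random.default_rng(3)
        colors = [f"c{k:02d}" for k in range(13)]
        rows = [{"subject_id": f"d{i}", "group": "dyslexic", "color_config": col,
                 "v": rng.normal()} for i in range(10) for col in colors]
        results = within_group_pairwise(pd.DataFrame(rows), "v")
        assert len(results) == 78  # C(13, 2)
        assert all(r.color_b is not None for r in results)

    def test_constant_shift_detected_exactly(self):
        colors = ("a", "b")
        rows = []
        for i, v in enumerate([1.0, 2, 3, 4, 5, 6]):
            rows.append({"subject_id": f"d{i}", "group": "dyslexic",
                         "color_config": "a", "v": v})
            rows.append({"subject_id": f"d{i}", "group": "dyslexic",
                         "color_config": "b", "v": v + 1})
        (res,) = within_group_pairwise(pd.DataFrame(rows), "v", colors=colors)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.03125)

    def test_zero_differences_flagged_not_computable(self):
        rows = []
        for i in range(6):
            for color in ("a", "b"):
                rows.append({"subject_id": f"d{i}", "group": "dyslexic",
                             "color_config": color, "v": float(i)})
        (res,) = within_group_pairwise(pd.DataFrame(rows), "v", colors=("a", "b"))
        assert not res.computable

    def test_symmetric_in_color_order(self):
        rng = np.random.default_rng(8)
        rows = [{"subject_id": f"d{i}", "group": "dyslexic", "color_config": col,
                 "v": rng.normal()} for i in range(8) for col in ("a", "b")]
        frame = pd.DataFrame(rows)
        (ab,) = within_group_pairwise(frame, "v", colors=("a", "b"))
        (ba,) = within_group_pairwise(frame, "v", colors=("b", "a"))
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_unknown_group_rejected(self):
        frame = stats_frame([1, 2], [3, 4], colors=("a", "b"))
        with pytest.raises(ValueError, match="unknown group"):
            within_group_pairwise(frame, "fic_value", group="patients")

    def test_missing_subjects_handled_pairwise(self):
        # subject d5 lacks color b; the pair uses the remaining 5 subjects
        rng = np.random.default_rng(1)
        rows = [{"subject_id": f"d{i}", "group": "dyslexic", "color_config": col,
                 "v": rng.normal()} for i in range(6) for col in ("a", "b")]
        rows = [r for r in rows
                if not (r["subject_id"] == "d5" and r["color_config"] == "b")]
        (res,) = within_group_pairwise(pd.DataFrame(rows), "v", colors=("a", "b"))
        assert res.n_a == 5


class TestHelpers:
    def test_feature_aliases_resolve(self):
        assert resolve_feature("fic") == "fixation_intersection_coefficient"
        assert resolve_feature("FFD") == "fixation_fractal_dimension"
        assert resolve_feature("total_reading_time") == "total_reading_time"

    def test_holm_adjustment_is_monotone_and_bounded(self):
        frame = stats_frame([1, 2, 3], [4, 5, 6],
                            colors=[f"c{k}" for k in range(5)])
        results = between_group_tests(frame, "fic_value")
        adjusted = holm_adjust(results)
        raw = [r.p_value for r in results]
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, raw))
        assert all(a <= 1.0 + 1e-12 for a in adjusted)

    def test_results_frame_columns(self):
        frame = stats_frame([1, 2, 3], [4, 5, 6])
        table = results_to_frame(between_group_tests(frame, "fic_value"))
        assert list(table.columns) == ["feature", "test", "color_a", "color_b",
                                       "n_a", "n_b", "statistic", "p_value",
                                       "computable"]
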