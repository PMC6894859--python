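"""Behavior-score aggregation and Fisher's exact window comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import scrunchkit as sk
from scrunchkit.scoring import (aggregate, compare_windows, fisher_exact,
                                latency_summary, validate_score_table)
from tests_oracles import fisher_enumeration


def score_rows(condition, replicate, reviewer, labels_per_worm):
    rows = []
    for worm, labels in enumerate(labels_per_worm, start=1):
        for interval, label in enumerate(labels, start=1):
            rows.append((condition, replicate, reviewer, worm, interval, label))
    return rows


def table_from(reviewer_a, reviewer_b, condition="X", replicate=1):
    return pd.DataFrame(score_rows(condition, replicate, 1, reviewer_a)
                        + score_rows(condition, replicate, 2, reviewer_b),
                        columns=["condition", "replicate", "reviewer", "worm",
                                 "interval", "label"])


class TestAggregate:
    def test_reviewer_counts_averaged(self):
        # reviewer 1 sees 6/10 scrunching in interval 1, reviewer 2 sees 8/10
        a = [["S"] + ["N"] * 5 if w < 6 else ["N"] * 6 for w in range(10)]
        b = [["S"] + ["N"] * 5 if w < 8 else ["N"] * 6 for w in range(10)]
        curve = aggregate(table_from(a, b), "X")
        assert curve.pct_scrunching_mean[0] == pytest.approx(70.0)

    def test_identical_replicates_zero_sd(self):
        frames = []
        for rep in (1, 2, 3):
            a = [["S"] * 6 if w < 7 else ["N"] * 6 for w in range(10)]
            frames.append(table_from(a, a, replicate=rep))
        curve = aggregate(pd.concat(frames, ignore_index=True), "X")
        assert np.all(curve.pct_scrunching_mean == 70.0)
        assert np.all(curve.pct_scrunching_sd == 0.0)

    def test_missing_interval_error_names_gap(self):
        df = table_from([["S"] * 6] * 3, [["S"] * 6] * 3)
        df = df[~((df["reviewer"] == 1) & (df["interval"] == 4))]
        with pytest.raises(ValueError, match=r"\[4\]"):
            aggregate(df, "X")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reacting_at_least_scrunching_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(3))
        df = sk.generate_score_table(6, 2, probs, seed=seed)
        curve = aggregate(df, "condition")
        assert np.all(curve.pct_reacting_mean >= curve.pct_scrunching_mean - 1e-9)

    def test_permutation_invariance(self):
        df = sk.generate_score_table(8, 2, (0.5, 0.3, 0.2), seed=3)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(reviewer=3 - shuffled["reviewer"])
        base = aggregate(df, "condition")
        perm = aggregate(relabeled, "condition")
        np.testing.assert_allclose(base.pct_scrunching_mean, perm.pct_scrunching_mean)


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact(np.array([[5, 5], [5, 5]])).p_value == 1.0

    @pytest.mark.parametrize("table", [(8, 2, 2, 8), (10, 0, 0, 10), (3, 7, 6, 1),
                                       (1, 11, 9, 2), (4, 4, 4, 5)])
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        got = fisher_exact(np.array([[a, b], [c, d]]))
        assert got.p_value == pytest.approx(fisher_enumeration(a, b, c, d), rel=1e-9)

    def test_zero_margin_degenerate(self):
        res = fisher_exact(np.array([[0, 0], [3, 5]]))
        assert res.p_value == 1.0 and res.degenerate

    def test_odds_ratio_conventions(self):
        assert fisher_exact(np.array([[2, 3], [1, 4]])).odds_ratio == pytest.approx(8 / 3)
        assert np.isinf(fisher_exact(np.array([[2, 3], [0, 4]])).odds_ratio)
        assert np.isnan(fisher_exact(np.array([[0, 3], [0, 4]])).odds_ratio)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(np.array([[0.5, 1.0], [1.0, 2.0]]))


class TestCompareWindows:
    def test_reviewer_average_rounds_half_up(self):
        # 7 and 8 scrunching of 10 -> averaged 7.5 -> 8 positive
        a = [["N", "S"] + ["N"] * 4 if w < 7 else ["N"] * 6 for w in range(10)]
        b = [["N", "S"] + ["N"] * 4 if w < 8 else ["N"] * 6 for w in range(10)]
        none = [["N"] * 6 for _ in range(10)]
        df = pd.concat([table_from(a, b, "treated"), table_from(none, none, "control")],
                       ignore_index=True)
        test = compare_windows(df, "treated", "control", window="15-30")
        assert test.counts[0, 0] == 8 and test.counts[1, 0] == 0

    def test_extreme_separation_hits_enumeration_minimum(self):
        alls = [["S"] * 6 for _ in range(10)]
        none = [["N"] * 6 for _ in range(10)]
        df = pd.concat([table_from(alls, alls, "A"), table_from(none, none, "B")],
                       ignore_index=True)
        test = compare_windows(df, "A", "B", window="31-45")
        assert test.p_value == pytest.approx(fisher_enumeration(10, 0, 0, 10), rel=1e-9)

    def test_null_simulation_is_conservative(self):
        # identical generating conditions: the exact test's false-positive
        # rate stays at or below nominal, and typical p-values are large
        pvals = []
        for seed in range(100):
            a = sk.generate_score_table(10, 3, (0.5, 0.2, 0.3), seed=seed, condition="A")
            b = sk.generate_score_table(10, 3, (0.5, 0.2, 0.3), seed=10_000 + seed,
                                        condition="B")
            df = pd.concat([a, b], ignore_index=True)
            pvals.append(compare_windows(df, "A", "B", window="15-30").p_value)
        pvals = np.asarray(pvals)
        assert (pvals < 0.05).mean() <= 0.08  # nominal 5% + Monte-Carlo slack
        assert np.median(pvals) >= 0.3

    def test_react_outcome_includes_nonscrunching_reactions(self):
        reacts = [["N", "R"] + ["N"] * 4 for _ in range(10)]
        none = [["N"] * 6 for _ in range(10)]
        df = pd.concat([table_from(reacts, reacts, "A"), table_from(none, none, "B")],
                       ignore_index=True)
        scrunch = compare_windows(df, "A", "B", window="15-30", outcome="scrunch")
        react = compare_windows(df, "A", "B", window="15-30", outcome="react")
        assert scrunch.counts[0, 0] == 0 and react.counts[0, 0] == 10

    def test_unknown_window_rejected(self):
        df = sk.generate_score_table(4, 1, (0.5, 0.3, 0.2), seed=0)
        with pytest.raises(ValueError, match="window"):
            compare_windows(df, "condition", "condition", window="50-60")


class TestLatency:
    def make_curve(self, percentages):
        n = len(percentages)
        return sk.AggregateCurve(intervals=np.arange(1, n + 1),
                                 pct_scrunching_mean=np.asarray(percentages, float),
                                 pct_scrunching_sd=np.zeros(n),
                                 pct_reacting_mean=np.asarray(percentages, float),
                                 pct_reacting_sd=np.zeros(n), n_replicates=3)

    def test_first_interval_reaching_threshold(self):
        assert latency_summary(self.make_curve([0, 0, 60, 80, 90, 90]), 50) == 3

    def test_flat_zero_curve_has_no_latency(self):
        assert latency_summary(self.make_curve([0] * 6), 50) is None

    def test_earlier_onset_strictly_smaller_latency(self):
        early = self.make_curve([0, 70, 80, 90, 90, 90])
        late = self.make_curve([0, 0, 0, 70, 80, 90])
        assert latency_summary(early, 50) < latency_summary(late, 50)


def test_schema_validation_rejects_bad_tables():
    df = sk.generate_score_table(3, 1, (0.4, 0.3, 0.3), seed=0)
    with pytest.raises(ValueError, match="interval"):
        validate_score_table(df.assign(interval=df["interval"].replace(6, 7)))
    with pytest.raises(ValueError, match="labels"):
        validate_score_table(df.assign(label="Q"))
    with pytest.raises(ValueError, match="duplicate"):
        validate_score_table(pd.concat([df, df.iloc[[0]]], ignore_index=True))
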