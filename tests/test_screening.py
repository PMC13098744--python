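import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from momix.core import ParameterError
from momix.screening import (
    bh_adjust,
    correlation_reduce,
    normality_fraction,
    paired_unpaired_tests,
    screen_features,
)


def exact_mannwhitney_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of labelings."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in idx if i not in combo]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def exact_signed_rank_p(diffs):
    """Two-sided exact Wilcoxon signed-rank p by sign-pattern enumeration."""
    d = np.asarray(diffs, dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


def make_table(values_a, values_b, paired=False):
    """One-feature table with class labels and (optionally) paired patients."""
    n_a, n_b = len(values_a), len(values_b)
    idx = [f"s{i}" for i in range(n_a + n_b)]
    table = pd.DataFrame({"af.f": list(values_a) + list(values_b)}, index=idx)
    labels = pd.Series(["normal"] * n_a + ["cancer"] * n_b, index=idx)
    if paired:
        assert n_a == n_b
        patients = pd.Series([f"p{i}" for i in range(n_a)] * 2, index=idx)
    else:
        patients = pd.Series([f"p{i}" for i in range(n_a + n_b)], index=idx)
    return table, labels, patients


class TestNormalityFraction:
    def test_gaussian_data_flagged_normal_about_95_percent(self):
        flagged = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame({"af.f": rng.standard_normal(200)})
            table.index = [f"s{i}" for i in range(200)]
            labels = pd.Series(["normal"] * 100 + ["cancer"] * 100, index=table.index)
            flags, _ = normality_fraction(table, labels)
            flagged += bool(flags.iloc[0].all())
        assert 0.88 <= flagged / reps <= 0.99

    def test_exponential_data_flagged_non_normal(self):
        hits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame({"af.f": rng.exponential(1.0, 100)})
            table.index = [f"s{i}" for i in range(100)]
            labels = pd.Series(["normal"] * 50 + ["cancer"] * 50, index=table.index)
            flags, _ = normality_fraction(table, labels)
            hits += not flags.iloc[0].any()
        assert hits / reps >= 0.95

    def test_constant_data_flag_missing(self):
        table = pd.DataFrame({"af.f": [1.0] * 10})
        table.index = [f"s{i}" for i in range(10)]
        labels = pd.Series(["normal"] * 5 + ["cancer"] * 5, index=table.index)
        flags, frac = normality_fraction(table, labels)
        assert flags.iloc[0].isna().all() and math.isnan(frac)


class TestPairedUnpairedTests:
    def test_small_unpaired_example_exact_third(self):
        table, labels, patients = make_table([1.0, 2.0], [3.0, 4.0])
        res = paired_unpaired_tests(table, labels, patients)
        assert res.loc["af.f", "p_unpaired"] == pytest.approx(1 / 3)

    def test_paired_differences_example_quarter(self):
        # within-patient differences 1, 2, 3 -> exact two-sided p = 0.25
        table, labels, patients = make_table([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], paired=True)
        res = paired_unpaired_tests(table, labels, patients)
        assert res.loc["af.f", "p_paired"] == pytest.approx(0.25)
        assert res.loc["af.f", "n_pairs"] == 3

    def test_identical_groups_p_one(self):
        table, labels, patients = make_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        with pytest.warns(UserWarning, match="zero"):
            res = paired_unpaired_tests(table, labels, patients)
        assert res.loc["af.f", "p_paired"] == 1.0
        assert res.loc["af.f", "p_unpaired"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 3), (8, 8), (6, 2)])
    def test_mannwhitney_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2)
            table, labels, patients = make_table(x, y)
            res = paired_unpaired_tests(table, labels, patients)
            assert res.loc["af.f", "p_unpaired"] == pytest.approx(
                exact_mannwhitney_p(x, y), abs=1e-12
            )

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_signed_rank_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            diffs = rng.standard_normal(n)
            a = rng.standard_normal(n)
            table, labels, patients = make_table(a + diffs, a, paired=True)
            res = paired_unpaired_tests(table, labels, patients)
            assert res.loc["af.f", "p_paired"] == pytest.approx(
                exact_signed_rank_p(diffs), abs=1e-12
            )


class TestBHAdjust:
    def test_hand_evaluated_step_up_vector(self):
        adjusted, sig = bh_adjust([0.005, 0.011, 0.02, 0.04, 0.13], q=0.1)
        np.testing.assert_allclose(adjusted, [0.025, 0.0275, 0.1 / 3, 0.05, 0.13])
        assert list(sig) == [True, True, True, True, False]

    def test_single_p_unchanged(self):
        adjusted, _ = bh_adjust([0.03])
        assert adjusted[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        adjusted, _ = bh_adjust([0.2] * 6)
        np.testing.assert_allclose(adjusted, 0.2)

    def test_monotone_along_sorted_raw_order(self, rng):
        p = rng.uniform(0, 1, 40)
        adjusted, _ = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.1, 1.5])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adjusted_values_bounded_and_monotone(self, p):
        adjusted, _ = bh_adjust(p)
        assert ((adjusted >= 0) & (adjusted <= 1)).all()
        assert (adjusted >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adjusted[order]) >= -1e-15).all()


class TestCorrelationReduce:
    def test_exact_copy_removed_keeping_lower_p(self, rng):
        f1 = rng.standard_normal(20)
        table = pd.DataFrame({"af.f1": f1, "af.f2": f1.copy(), "af.f3": rng.standard_normal(20)})
        ranking = pd.Series({"af.f1": 0.01, "af.f2": 0.04, "af.f3": 0.5})
        retained, log = correlation_reduce(table, ranking)
        assert set(retained) == {"af.f1", "af.f3"}
        assert log[0][0] == "af.f2" and log[0][1] == "af.f1"

    def test_uncorrelated_features_all_retained(self, rng):
        table = pd.DataFrame(rng.standard_normal((200, 8)), columns=[f"af.f{i}" for i in range(8)])
        ranking = pd.Series(rng.uniform(0, 1, 8), index=table.columns)
        retained, log = correlation_reduce(table, ranking)
        assert len(retained) == 8 and not log

    def test_matches_brute_force_on_planted_blocks(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 40
            base = rng.standard_normal((n, 3))
            cols = {}
            for j in range(12):
                block = j % 3
                cols[f"af.f{j:02d}"] = base[:, block] + 0.15 * rng.standard_normal(n)
            table = pd.DataFrame(cols)
            ranking = pd.Series(rng.uniform(0, 1, 12), index=table.columns)
            retained, log = correlation_reduce(table, ranking, threshold=0.85)

            # independent re-implementation of the same removal rule
            alive = list(table.columns)
            corr = table.corr().abs()
            while True:
                best, best_pair = 0.0, None
                for a, b in itertools.combinations(sorted(alive), 2):
                    r = corr.loc[a, b]
                    if r > 0.85 and r > best + 1e-15:
                        best, best_pair = r, (a, b)
                if best_pair is None:
                    break
                a, b = best_pair
                alive.remove(a if ranking[a] > ranking[b] else b)
            assert set(retained) == set(alive)
            # retained + removed partition the input
            removed = {entry[0] for entry in log}
            assert removed | set(retained) == set(table.columns)
            assert not removed & set(retained)

    def test_postcondition_max_correlation_below_threshold(self, rng):
        base = rng.standard_normal((30, 2))
        table = pd.DataFrame(
            {f"af.f{j}": base[:, j % 2] + 0.2 * rng.standard_normal(30) for j in range(10)}
        )
        ranking = pd.Series(rng.uniform(0, 1, 10), index=table.columns)
        retained, _ = correlation_reduce(table, ranking, threshold=0.85)
        sub = table[retained].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.85 + 1e-12

    def test_sparse_feature_excluded_but_retained(self, rng):
        table = pd.DataFrame(rng.standard_normal((10, 3)), columns=["af.a", "af.b", "af.c"])
        table.loc[table.index[2:], "af.c"] = np.nan  # only 2 observations
        ranking = pd.Series(0.5, index=table.columns)
        retained, _ = correlation_reduce(table, ranking)
        assert "af.c" in retained


class TestScreenFeatures:
    def test_per_modality_reduction_and_report_shape(self, rng):
        n = 24
        idx = [f"s{i}" for i in range(n)]
        shared = rng.standard_normal(n)
        table = pd.DataFrame(
            {
                "af.a": shared,
                "af.b": shared + 0.01 * rng.standard_normal(n),  # redundant with af.a
                "hsi.c": shared,  # same signal, different modality: kept
                "oct.d": rng.standard_normal(n),
            },
            index=idx,
        )
        labels = pd.Series(["normal"] * 12 + ["cancer"] * 12, index=idx)
        patients = pd.Series([f"p{i}" for i in range(12)] * 2, index=idx)
        result = screen_features(table, labels, patients)
        assert "hsi.c" in result.retained
        assert ("af.a" in result.retained) != ("af.b" in result.retained)
        removed = [f for f in table.columns if f not in result.retained]
        for f in removed:
            cause = result.report.loc[f, "removal_cause"]
            assert cause.startswith("correlated_with:")
        assert set(result.report.columns) >= {
            "p_paired", "p_unpaired", "p_paired_adj", "p_unpaired_adj",
            "retained", "removal_cause", "modality",
        }
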