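import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from marshres.landscape import generate_metric_table
from marshres.scoring import (
    ADAPTIVE_METRICS,
    CATEGORIES,
    CONDITION_METRICS,
    METRICS,
    MetricDirections,
    VULNERABILITY_METRICS,
    category_score,
    category_sum,
    decile_breaks,
    rank_value,
    rank_values,
    score_metrics,
    score_table,
    total_score,
)

import _oracle


class TestDecileBreaks:
    def test_one_to_ten(self):
        # frozen from the independent type-7 oracle
        expected = [_oracle.quantile_type7(list(range(1, 11)), i / 10) for i in range(1, 10)]
        assert expected == pytest.approx([1.9, 2.8, 3.7, 4.6, 5.5, 6.4, 7.3, 8.2, 9.1])
        assert decile_breaks(range(1, 11)) == pytest.approx(expected)

    def test_constant_data(self):
        assert np.all(decile_breaks([7.0] * 5) == 7.0)

    def test_two_values_symmetric(self):
        breaks = decile_breaks([0.0, 100.0])
        assert np.all(breaks > 0) and np.all(breaks < 100)
        assert breaks.sum() == pytest.approx(9 * 50.0)
        assert breaks[4] == pytest.approx(50.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            decile_breaks([np.nan, np.nan])

    def test_missing_ignored(self):
        assert decile_breaks([1.0, np.nan, 3.0]) == pytest.approx(decile_breaks([1.0, 3.0]))


class TestRankValue:
    def test_below_all_breaks(self):
        breaks = np.arange(1.0, 10.0)
        assert rank_value(0.0, breaks) == 1

    def test_above_all_breaks(self):
        breaks = np.arange(1.0, 10.0)
        assert rank_value(100.0, breaks) == 10

    def test_degenerate_breaks_tie_convention(self):
        breaks = np.full(9, 5.0)
        assert rank_value(5.0, breaks) == 1  # tie falls in the lower bin
        assert rank_value(5.0 + 1e-9, breaks) == 10

    def test_missing_value(self):
        assert np.isnan(rank_value(np.nan, np.arange(9.0)))

    @given(st.floats(-100, 100), st.lists(st.floats(-50, 50), min_size=9, max_size=9))
    def test_matches_oracle(self, v, breaks):
        breaks = sorted(breaks)
        assert rank_value(v, np.array(breaks)) == _oracle.rank(v, breaks)

    def test_vectorized_matches_scalar(self, rng):
        breaks = np.sort(rng.normal(0, 1, 9))
        vals = rng.normal(0, 1.5, 40)
        vec = rank_values(vals, breaks)
        assert vec.tolist() == [rank_value(v, breaks) for v in vals]


def _cohort(seed, n):
    return generate_metric_table(seed=seed, n_units=n, group_labels=())


class TestScoreMetrics:
    def test_extremes(self):
        t = _cohort(1, 12)
        t.loc[t.index[0], "pct_impervious"] = 1000.0  # cohort maximum, negative metric
        t.loc[t.index[1], "area_to_edge_ratio"] = -5.0  # cohort minimum, positive metric
        s = score_metrics(t)
        assert s.loc[t.index[0], "metric_score_pct_impervious"] == -10
        assert s.loc[t.index[1], "metric_score_area_to_edge_ratio"] == 1

    def test_ten_distinct_values_permutation(self, rng):
        t = _cohort(2, 10)
        vals = rng.permutation(10).astype(float) * 3.7 + 1
        t["pct_natural"] = vals
        s = score_metrics(t)
        got = sorted(s["metric_score_pct_natural"])
        # frozen via the oracle: ten distinct values spread across ten bins
        expected = sorted(
            _oracle.rank(v, _oracle.decile_breaks(list(vals))) for v in vals
        )
        assert got == expected == list(range(1, 11))

    def test_signed_magnitude_equals_rank(self):
        t = _cohort(3, 25)
        s = score_metrics(t)
        for m in METRICS:
            assert np.allclose(
                np.abs(s[f"metric_score_{m}"]), s[f"metric_rank_{m}"], equal_nan=True
            )

    def test_single_unit_refused(self):
        with pytest.raises(ValueError):
            score_metrics(_cohort(1, 1))

    def test_missing_column_rejected(self):
        t = _cohort(1, 5).drop(columns=["connectedness"])
        with pytest.raises(ValueError, match="connectedness"):
            score_metrics(t)

    def test_missing_value_propagates(self):
        t = _cohort(4, 8)
        t.loc[t.index[2], "tidal_range_m"] = np.nan
        s = score_metrics(t)
        assert np.isnan(s.loc[t.index[2], "metric_score_tidal_range_m"])
        assert np.isfinite(s.loc[t.index[3], "metric_score_tidal_range_m"])


class TestCategorySum:
    def test_adaptive_weights(self):
        scores = pd.DataFrame(
            {
                "metric_score_pct_hardened": [-4.0],
                "metric_score_shoreline_complexity": [5.0],
                "metric_score_migration_ratio": [6.0],
                "metric_score_connectedness": [7.0],
            }
        )
        assert category_sum(scores, "adaptive").iloc[0] == pytest.approx(18.0)

    def test_condition_unweighted(self):
        scores = pd.DataFrame(
            {
                f"metric_score_{m}": [v]
                for m, v in zip(CONDITION_METRICS, [3.0, -2.0, -1.0, 4.0, -5.0])
            }
        )
        assert category_sum(scores, "condition").iloc[0] == pytest.approx(-1.0)

    def test_vulnerability_sum(self):
        scores = pd.DataFrame(
            {
                f"metric_score_{m}": [v]
                for m, v in zip(VULNERABILITY_METRICS, [-8.0, 2.0, -9.0, -7.0])
            }
        )
        assert category_sum(scores, "vulnerability").iloc[0] == pytest.approx(-22.0)

    def test_missing_metric_nans_the_sum(self):
        scores = pd.DataFrame(
            {
                f"metric_score_{m}": [1.0]
                for m in ADAPTIVE_METRICS
            }
        )
        scores.loc[0, "metric_score_migration_ratio"] = np.nan
        assert np.isnan(category_sum(scores, "adaptive").iloc[0])


class TestCategoryScore:
    def test_worst_vulnerability_gets_minus_ten(self):
        sums = pd.Series([-30.0, -10.0, -5.0, -22.0])
        scores = category_score(sums, "vulnerability")
        assert scores.iloc[0] == -10  # least favourable sum
        assert scores.iloc[2] == -1  # most favourable

    def test_best_condition_gets_ten(self):
        sums = pd.Series([10.0, 30.0, 5.0, -2.0])
        scores = category_score(sums, "condition")
        assert scores.iloc[1] == 10

    def test_two_unit_cohort(self):
        # derived: with n=2 the nine breaks interpolate strictly between the
        # two sums, so the lower unit ranks 1 and the upper 10
        sums = pd.Series([4.0, 9.0])
        scores = category_score(sums, "adaptive")
        assert sorted(scores) == [1, 10]

    def test_vulnerability_range(self, rng):
        sums = pd.Series(rng.normal(-15, 5, 30))
        scores = category_score(sums, "vulnerability")
        assert scores.between(-10, -1).all()

    def test_insufficient_cohort(self):
        with pytest.raises(ValueError):
            category_score(pd.Series([1.0, np.nan]), "condition")


class TestTotalScore:
    def _frame(self, triples):
        return pd.DataFrame(
            triples, columns=["score_condition", "score_vulnerability", "score_adaptive"]
        )

    def test_sum_arithmetic(self):
        frame = self._frame([(10, -1, 10), (1, -10, 1), (7, -3, 8)])
        total_sum, ts = total_score(frame)
        assert total_sum.tolist() == [19.0, -8.0, 12.0]
        assert ts.iloc[0] == 10 and ts.iloc[1] == 1

    def test_missing_category_nans_total(self):
        frame = self._frame([(10, -1, 10), (1, -10, 1), (np.nan, -3, 8)])
        total_sum, ts = total_score(frame)
        assert np.isnan(total_sum.iloc[2]) and np.isnan(ts.iloc[2])

    def test_bounds(self):
        frame = self._frame([(10, -1, 10), (1, -10, 1)])
        total_sum, _ = total_score(frame)
        assert total_sum.between(-8, 19).all()


class TestPipelineProperties:
    def test_oracle_equivalence_small_cohorts(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(2, 51))
            t = _cohort(int(rng.integers(0, 2**31)), n)
            s = score_table(t)
            expected = _oracle.score_cohort(
                {u: {m: t.loc[u, m] for m in METRICS} for u in t.index}
            )
            for u in t.index:
                for m in METRICS:
                    assert s.loc[u, f"metric_score_{m}"] == expected[u][f"score_{m}"]
                for cat in CATEGORIES:
                    assert s.loc[u, f"sum_{cat}"] == pytest.approx(expected[u][f"sum_{cat}"])
                    assert s.loc[u, f"score_{cat}"] == expected[u][f"score_{cat}"]
                assert s.loc[u, "total_score"] == expected[u]["total_score"]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.sampled_from(METRICS))
    def test_rank_invariance_under_monotone_transform(self, seed, metric):
        t = _cohort(seed, 15)
        s0 = score_metrics(t)
        t2 = t.copy()
        t2[metric] = 3.0 * t2[metric] + 7.0  # strictly increasing
        s1 = score_metrics(t2)
        assert s0[f"metric_rank_{metric}"].tolist() == s1[f"metric_rank_{metric}"].tolist()

    def test_rank_invariance_exp_transform(self):
        t = _cohort(17, 20)
        s0 = score_metrics(t)
        t2 = t.copy()
        t2["soil_erodibility"] = np.exp(t2["soil_erodibility"])
        s1 = score_metrics(t2)
        assert (
            s0["metric_rank_soil_erodibility"].tolist()
            == s1["metric_rank_soil_erodibility"].tolist()
        )

    def test_permutation_invariance(self, rng):
        t = _cohort(5, 20)
        shuffled = t.sample(frac=1.0, random_state=7)
        a = score_table(t).sort_index()
        b = score_table(shuffled).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_dominance(self):
        dirs = MetricDirections()
        t = _cohort(6, 12)
        better, worse = t.index[0], t.index[1]
        for m in METRICS:
            lo, hi = t[m].min(), t[m].max()
            if dirs.signs[m] > 0:
                t.loc[better, m], t.loc[worse, m] = hi + 1.0, lo - 1.0
            else:
                t.loc[better, m], t.loc[worse, m] = max(lo - 1.0, 0.0), hi + 1.0
        s = score_table(t, dirs)
        for cat in CATEGORIES:
            assert s.loc[better, f"sum_{cat}"] > s.loc[worse, f"sum_{cat}"]
        assert s.loc[better, "total_sum"] >= s.loc[worse, "total_sum"]

    def test_bounds_everywhere(self):
        t = _cohort(8, 40)
        s = score_table(t)
        for m in METRICS:
            assert s[f"metric_rank_{m}"].between(1, 10).all()
        assert s["score_condition"].between(1, 10).all()
        assert s["score_adaptive"].between(1, 10).all()
        assert s["score_vulnerability"].between(-10, -1).all()
        assert s["total_sum"].between(-8, 19).all()
        assert s["total_score"].between(1, 10).all()

    def test_group_columns_carried_through(self):
        t = generate_metric_table(seed=9, n_units=10)
        s = score_table(t)
        assert "region" in s.columns


class TestMetricDirections:
    def test_defaults_match_published_signs(self):
        dirs = MetricDirections()
        negative = {
            "unveg_edge_ratio", "pct_impervious", "pct_agricultural",
            "soil_erodibility", "pct_below_mhhw", "pct_below_mtl", "pct_hardened",
        }
        for m in METRICS:
            assert dirs.signs[m] == (-1 if m in negative else +1)
        assert dirs.weights["pct_hardened"] == 1.5
        assert dirs.weights["migration_ratio"] == 2.0
        assert all(dirs.weights[m] == 1.0 for m in METRICS if m not in ("pct_hardened", "migration_ratio"))

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            MetricDirections(signs={"pct_natural": 2})

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            MetricDirections(weights={"pct_natural": 0.0})
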