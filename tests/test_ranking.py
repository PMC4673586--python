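"""ANOVA F values, ranking, and signed preference scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ggaplect import (
    encode_dataset,
    f_value,
    f_values,
    preference_heatmap_data,
    preference_scores,
    rank_features,
)
from ggaplect.ranking import AnovaRankSelector, ConstantFeaturesError, ranking_to_tsv
from ggaplect.synthetic import planted_feature_indices


class TestFValue:
    def test_perfect_separation_gives_infinity_sentinel(self):
        # groups (1,1) vs (2,2): SS_W = 0, SS_B = 4*(0.5)^2 = 1 > 0
        res = f_value(np.array([1.0, 1.0, 2.0, 2.0]), np.array([1, 1, 0, 0]))
        assert res["ss_within"] == 0.0
        assert res["ss_between"] == pytest.approx(1.0)
        assert res["F"] == np.inf

    def test_constant_column_is_zero(self):
        res = f_value(np.full(6, 0.25), np.array([1, 1, 1, 0, 0, 0]))
        assert res["F"] == 0.0

    def test_hand_computed_sums_of_squares(self):
        # groups (0, 1) and (1, 2, 3): means 0.5 and 2, grand mean 1.4
        col = np.array([0.0, 1.0, 1.0, 2.0, 3.0])
        y = np.array([1, 1, 0, 0, 0])
        res = f_value(col, y)
        assert res["ss_between"] == pytest.approx(2 * 0.9**2 + 3 * 0.6**2)
        assert res["ss_within"] == pytest.approx(0.5 + 2.0)
        assert res["F"] == pytest.approx((res["ss_between"] / 1) / (res["ss_within"] / 3))

    def test_equals_squared_t_statistic(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 50))
        y = np.array([1] * 18 + [0] * 22)
        table = f_values(X, y)
        t = stats.ttest_ind(X[y == 1], X[y == 0], equal_var=True).statistic
        np.testing.assert_allclose(table.F, t**2, rtol=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 20))
        y = np.array([1] * 12 + [0] * 18)
        table = f_values(X, y)
        ref = stats.f_oneway(X[y == 1], X[y == 0]).statistic
        np.testing.assert_allclose(table.F, ref, rtol=1e-9)

    def test_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(2)
        X = rng.random((25, 30))
        y = (rng.random(25) < 0.4).astype(int)
        table = f_values(X, y)
        ss_total = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
        np.testing.assert_allclose(
            table.ss_between + table.ss_within, ss_total, atol=1e-9
        )

    @settings(deadline=None, max_examples=30)
    @given(st.floats(min_value=0.1, max_value=1000.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        col = rng.random(20)
        y = np.array([1] * 9 + [0] * 11)
        a = f_value(col, y)["F"]
        b = f_value(col * scale, y)["F"]
        assert a == pytest.approx(b, rel=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f_value(np.arange(4.0), np.ones(4, dtype=int))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            f_value(np.array([1.0, 2.0]), np.array([1, 0]))

    def test_label_permutation_null_calibration(self):
        # no-signal data: F should follow F(1, N-2); ~5% exceed the 95th pct
        rng = np.random.default_rng(4)
        n, d = 60, 400
        X = rng.random((n, d))
        exceed = []
        crit = stats.f.ppf(0.95, 1, n - 2)
        for _ in range(25):
            y = rng.permutation(np.array([1] * 30 + [0] * 30))
            exceed.append(np.mean(f_values(X, y).F > crit))
        assert 0.02 < np.mean(exceed) < 0.09


class TestRankFeatures:
    def test_single_informative_column_ranks_first(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.01, size=(20, 12))
        y = np.array([1] * 10 + [0] * 10)
        X[:, 7] += y * 5.0
        table = f_values(X, y)
        assert table.order[0] == 7
        assert table.ranks[7] == 1

    def test_ties_broken_by_ascending_index(self):
        rng = np.random.default_rng(6)
        col = rng.random(10)
        X = np.column_stack([col, col, rng.random(10), col])
        y = np.array([1] * 5 + [0] * 5)
        table = f_values(X, y)
        dup_ranks = table.ranks[[0, 1, 3]]
        assert list(np.sort(dup_ranks)) == list(dup_ranks)  # 0 before 1 before 3

    def test_planted_features_rank_high(self, planted_dataset):
        spec, dataset, _ = planted_dataset
        table = rank_features(encode_dataset(dataset, spec.gap))
        ranks = table.ranks[planted_feature_indices(spec)]
        assert ranks.max() <= 20


class TestPreferenceScores:
    @pytest.fixture
    def table_and_matrix(self, planted_dataset):
        spec, dataset, _ = planted_dataset
        mat = encode_dataset(dataset, spec.gap)
        return rank_features(mat), mat

    def test_range_and_endpoints(self, table_and_matrix):
        table, mat = table_and_matrix
        pref = preference_scores(table, mat)
        assert np.all(np.abs(pref.f0) <= 1.0 + 1e-12)
        top = table.order[0]
        assert abs(pref.f0[top]) == pytest.approx(1.0)
        bottom = table.order[-1]
        assert pref.f0[bottom] == pytest.approx(0.0)

    def test_sign_tracks_class_means(self, table_and_matrix):
        table, mat = table_and_matrix
        pref = preference_scores(table, mat)
        nz = pref.f0 != 0
        np.testing.assert_array_equal(
            np.sign(pref.f0[nz]), np.sign((pref.mean_pos - pref.mean_neg)[nz])
        )

    def test_planted_pairs_prefer_positives(self, planted_dataset, table_and_matrix):
        spec, _, _ = planted_dataset
        table, mat = table_and_matrix
        pref = preference_scores(table, mat)
        planted = planted_feature_indices(spec)
        # every planted pair is enriched in positives (F0 > 0) and the
        # strongest class-preferring feature is one of the planted pairs
        assert np.all(pref.f0[planted] > 0)
        assert np.argmax(np.abs(pref.f0)) in planted
        assert np.sum(np.abs(pref.f0) > 0.5) >= 1

    def test_all_constant_rejected(self):
        X = np.full((6, 5), 0.2)
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(ConstantFeaturesError):
            preference_scores(f_values(X, y), X, y)

    def test_heatmap_grid(self, table_and_matrix):
        from ggaplect import dipeptide_index

        table, mat = table_and_matrix
        pref = preference_scores(table, mat)
        grid = preference_heatmap_data(pref)
        assert grid.shape == (20, 20)
        assert grid.loc["L", "R"] == pref.f0[dipeptide_index("L", "R")]

    def test_heatmap_tsv_round_trip(self, table_and_matrix, tmp_path):
        import pandas as pd

        table, mat = table_and_matrix
        grid = preference_heatmap_data(preference_scores(table, mat))
        path = tmp_path / "grid.tsv"
        grid.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=0)
        np.testing.assert_allclose(back.values, grid.values)

    def test_tsv_export_schema(self, table_and_matrix, tmp_path):
        table, mat = table_and_matrix
        pref = preference_scores(table, mat)
        path = tmp_path / "ranking.tsv"
        ranking_to_tsv(table, pref, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == [
            "dipeptide", "F", "SS_B", "SS_W", "rank", "F0", "mean_pos", "mean_neg",
        ]


class TestAnovaRankSelector:
    def test_nested_selection(self):
        rng = np.random.default_rng(7)
        X = rng.random((30, 40))
        y = np.array([1] * 15 + [0] * 15)
        s5 = AnovaRankSelector(k=5).fit(X, y)
        s9 = AnovaRankSelector(k=9).fit(X, y)
        np.testing.assert_array_equal(
            s5.support_indices_, s9.support_indices_[:5]
        )
        assert s5.transform(X).shape == (30, 5)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.random((20, 10))
        y = np.array([1] * 10 + [0] * 10)
        sel = AnovaRankSelector(k=3).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            sel.transform(X[:, :5])
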