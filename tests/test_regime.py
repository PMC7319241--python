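"""Regime detection: DTW, Ward clustering, association and ANOVA tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oeflab.regime import (
    DTWWardClustering,
    association_lrt,
    combine_regimes,
    dtw_distance,
    dtw_matrix,
    metric_anova,
    series_matrix,
    ward_cluster,
)


def dtw_brute_force(x, y):
    """Exhaustive enumeration of all monotone warping paths (tiny series)."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(x[i] - y[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestDTW:
    def test_identical_series_zero(self, rng):
        x = rng.normal(size=30)
        assert dtw_distance(x, x) == 0.0

    def test_single_cell(self):
        assert dtw_distance([0.0], [3.5]) == 3.5

    def test_zero_cost_alignment(self):
        assert dtw_distance([0, 0, 1], [0, 1]) == 0.0

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(1, 6))
            y = rng.normal(size=rng.integers(1, 6))
            assert dtw_distance(x, y) == pytest.approx(dtw_brute_force(x, y), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        x=st.lists(st.floats(-5, 5), min_size=1, max_size=12),
        y=st.lists(st.floats(-5, 5), min_size=1, max_size=12),
    )
    def test_symmetry_and_nonnegativity(self, x, y):
        d = dtw_distance(x, y)
        assert d >= 0.0
        assert d == pytest.approx(dtw_distance(y, x), abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    def test_window_constraint_never_decreases_cost(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert dtw_distance(x, y, window=2) >= dtw_distance(x, y) - 1e-12


class TestDTWMatrix:
    def test_identical_series_off_diagonal_zero(self):
        D = dtw_matrix([[1, 2, 3], [1, 2, 3]], normalize=False)
        assert D[0, 1] == 0.0

    def test_symmetric_zero_diagonal(self, rng):
        D = dtw_matrix(rng.normal(size=(3, 8)))
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_entries_match_exhaustive_oracle(self, rng):
        series = rng.normal(size=(5, 6))
        D = dtw_matrix(series, normalize=False)
        for i, j in itertools.combinations(range(5), 2):
            assert D[i, j] == pytest.approx(
                dtw_brute_force(series[i], series[j]), abs=1e-12
            )

    def test_constant_series_standardizes_to_zeros(self):
        D = dtw_matrix([[2.0, 2.0, 2.0], [0.0, 0.0, 0.0]], normalize=True)
        assert D[0, 1] == 0.0


class TestWardClustering:
    def test_two_separated_groups_recovered(self):
        series = np.array([[0, 0, 0.0]] * 3 + [[5, 5, 5.0]] * 3)
        D = dtw_matrix(series, normalize=False)
        labels, Z = ward_cluster(D, k=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_two_series_two_clusters(self):
        D = dtw_matrix([[0, 1.0], [3, 4.0]], normalize=False)
        labels, _ = ward_cluster(D, k=2)
        assert sorted(labels.tolist()) == [1, 2]

    def test_k_larger_than_n_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError):
            ward_cluster(D, k=3)

    def test_estimator_anchoring(self):
        high = np.tile(np.linspace(9.5, 10.5, 5), (2, 1))
        low = np.tile(np.linspace(1.0, 0.0, 5), (3, 1))
        X = np.vstack([high, low])
        model = DTWWardClustering(k=2, normalize=False, anchor="high").fit(X)
        assert list(model.labels_[:2]) == [1, 1]
        assert list(model.labels_[2:]) == [2, 2, 2]
        low = DTWWardClustering(k=2, normalize=False, anchor="low").fit(X)
        assert list(low.labels_[:2]) == [2, 2]

    def test_planted_regimes_recovered(self, experiment_batch):
        from sklearn.metrics import adjusted_rand_score

        table = experiment_batch[0]
        ids, X = series_matrix(table, "O_liq")
        truth = table.groupby("microcosm_id", sort=False)["regime"].first().loc[ids]
        labels = DTWWardClustering(k=2).fit_predict(X)
        assert adjusted_rand_score(truth.to_numpy(), labels) >= 0.8


class TestPipelineDirection:
    def test_low_do_replicates_show_larger_hysteresis_and_down_nonlinearity(
        self, experiment_batch
    ):
        """Persistent low-DO microcosms have larger hysteresis and larger
        descending-phase nonlinearity than functionally extinct ones, for
        oxygen and total biomass alike."""
        from oeflab.metrics import compute_metrics, paths_from_table

        sums = {
            (var, reg): []
            for var in ("O_liq", "total_biomass")
            for reg in ("low_do", "recovery")
        }
        for table in experiment_batch[:6]:
            regimes = table.groupby("microcosm_id")["regime"].first()
            for var in ("O_liq", "total_biomass"):
                for path in paths_from_table(table, var):
                    m = compute_metrics(path)
                    sums[(var, regimes[path.id])].append(
                        (m.hysteresis, m.nonlinearity_down)
                    )
        for var in ("O_liq", "total_biomass"):
            low = np.mean(sums[(var, "low_do")], axis=0)
            rec = np.mean(sums[(var, "recovery")], axis=0)
            assert low[0] > rec[0]  # hysteresis
            assert low[1] > rec[1]  # descending-phase nonlinearity


class TestCombineRegimes:
    def test_all_first_cluster(self):
        assert list(combine_regimes([1, 1], [1, 1])) == ["A", "A"]

    def test_code_table(self):
        codes = combine_regimes([1, 2, 2, 1], [1, 1, 2, 2])
        assert list(codes) == ["A", "B", "C", "other"]

    def test_invalid_labels(self):
        with pytest.raises(ValueError):
            combine_regimes([0, 1], [1, 1])


class TestAssociationLRT:
    def test_equal_proportions_zero_deviance(self):
        out = association_lrt([1, 0, 1, 0], ["a", "a", "b", "b"])
        assert out.deviance == pytest.approx(0.0, abs=1e-12)
        assert out.df == 1

    def test_perfect_separation_closed_form(self):
        y = [1] * 5 + [0] * 5
        g = ["a"] * 5 + ["b"] * 5
        out = association_lrt(y, g)
        assert out.deviance == pytest.approx(20 * np.log(2), rel=1e-9)
        assert out.df == 1

    def test_five_group_hand_table(self):
        # groups of 6 with successes (0, 1, 1, 2, 5): deviance assembled
        # from the grouped Bernoulli log-likelihood by hand
        counts = [0, 1, 1, 2, 5]
        y = sum(([1] * k + [0] * (6 - k) for k in counts), [])
        g = sum(([t] * 6 for t in "abcde"), [])

        def ll(k, n):
            out = 0.0
            if k:
                out += k * np.log(k / n)
            if n - k:
                out += (n - k) * np.log((n - k) / n)
            return out

        expected = 2 * (sum(ll(k, 6) for k in counts) - ll(sum(counts), 30))
        out = association_lrt(y, g)
        assert out.deviance == pytest.approx(expected, abs=1e-9)
        assert out.df == 4

    def test_matches_glm_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(5):
            g = rng.choice(list("abcd"), size=40)
            y = (rng.random(40) < 0.3 + 0.3 * (g == "a")).astype(float)
            if y.min() == y.max() or len(np.unique(g)) < 2:
                continue
            X = pd.get_dummies(pd.Series(g), drop_first=True, dtype=float)
            X = sm.add_constant(X)
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
            expected = 2 * (full.llf - null.llf)
            out = association_lrt(y, g)
            assert out.deviance == pytest.approx(expected, abs=1e-6)

    def test_label_and_level_invariance(self):
        y = [1, 0, 1, 1, 0, 0]
        g = ["a", "a", "b", "b", "c", "c"]
        base = association_lrt(y, g).deviance
        flipped = association_lrt([1 - v for v in y], g).deviance
        permuted = association_lrt(y, ["c", "c", "a", "a", "b", "b"]).deviance
        assert flipped == pytest.approx(base, abs=1e-12)
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            association_lrt([0, 1], ["a", "a"])


class TestMetricAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        from scipy.stats import ttest_ind

        y = rng.normal(size=16)
        g = np.repeat(["a", "b"], 8)
        table = metric_anova(y, g)
        t = ttest_ind(y[:8], y[8:]).statistic
        assert table.loc["C(trt)", "F"] == pytest.approx(t**2, rel=1e-9)

    def test_one_way_matches_hand_sums_of_squares(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(list("abcde"), 6)
        table = metric_anova(y, g)
        grand = y.mean()
        ss_between = sum(6 * (y[g == lv].mean() - grand) ** 2 for lv in "abcde")
        ss_within = sum(((y[g == lv] - y[g == lv].mean()) ** 2).sum() for lv in "abcde")
        f_hand = (ss_between / 4) / (ss_within / 25)
        assert table.loc["C(trt)", "F"] == pytest.approx(f_hand, rel=1e-9)

    def test_ancova_f_is_nested_rss_comparison(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(list("abcde"), 6)
        c = rng.choice(["c1", "c2"], size=30)
        table = metric_anova(y, g, cluster=c)

        def rss(*factors):
            cols = [np.ones(len(y))]
            for f in factors:
                cols.append(pd.get_dummies(pd.Series(f), drop_first=True).to_numpy(float))
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ beta) ** 2).sum())

        rss_full = rss(g, c)
        df_resid = 30 - 1 - 4 - 1
        f_cluster = (rss(g) - rss_full) / (rss_full / df_resid)
        f_treat = ((rss(c) - rss_full) / 4) / (rss_full / df_resid)
        assert table.loc["C(clus)", "F"] == pytest.approx(f_cluster, rel=1e-9)
        assert table.loc["C(trt)", "F"] == pytest.approx(f_treat, rel=1e-9)

    def test_aliased_factor_rejected(self):
        y = np.arange(12.0)
        g = np.repeat(["a", "b"], 6)
        with pytest.raises(ValueError):
            metric_anova(y, g, cluster=g)  # cluster identical to treatment

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            metric_anova(np.arange(4.0), ["a"] * 4)
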