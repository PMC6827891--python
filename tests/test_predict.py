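"""DTW similarity, exact signed-rank test, bootstrap and the biomarker model."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import wilcoxon

from drynet.predict import (
    bootstrap_set_test,
    classify_cell_line,
    drynb_fit,
    dtw_distance,
    exact_signed_rank_p,
    roc_auc,
)
from drynet.preprocess import TimeCourseMatrix

TIMES = np.array([0.0, 6.0, 12.0, 24.0, 48.0])


def dtw_oracle(a, b):
    """Exhaustive enumeration of all admissible warping paths (tiny series)."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
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


def signed_rank_oracle(d, alternative):
    """All 2^n sign assignments of the rank sum, ties -> average ranks."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in product([False, True], repeat=n)]
    ws = np.array(ws)
    if alternative == "less":
        return np.mean(ws <= w_obs + 1e-12)
    return np.mean(ws >= w_obs - 1e-12)


class TestDTW:
    def test_identical_series_distance_zero(self, rng):
        x = rng.random(6)
        assert dtw_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_length_one_unnormalized_is_absolute_difference(self):
        assert dtw_distance([3.0], [7.5], normalize=False) == pytest.approx(4.5)

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(25):
            a, b = rng.random(4), rng.random(4)
            assert dtw_distance(a, b, normalize=False) == pytest.approx(
                dtw_oracle(a, b))

    def test_never_exceeds_no_warp_cost(self, rng):
        for _ in range(20):
            a, b = rng.random(5), rng.random(5)
            assert dtw_distance(a, b, normalize=False) <= np.abs(a - b).sum() + 1e-12

    def test_symmetric(self, rng):
        a, b = rng.random(6), rng.random(4)
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_znormalized_mode_ignores_scale_and_offset(self, rng):
        a, b = rng.random(5), rng.random(5)
        assert dtw_distance(5 * a + 3, b) == pytest.approx(dtw_distance(a, b))

    def test_empty_series_error(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestExactSignedRank:
    def test_five_same_sign_pairs_give_minimal_p(self):
        assert exact_signed_rank_p([-1, -2, -3, -4, -5], "less") == pytest.approx(
            0.03125)

    def test_single_pair_gives_half(self):
        assert exact_signed_rank_p([-2.0], "less") == pytest.approx(0.5)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_all_same_sign_is_two_to_minus_n(self, n):
        d = -np.arange(1.0, n + 1)
        assert exact_signed_rank_p(d, "less") == pytest.approx(2.0 ** (-n))

    def test_mixed_signs_match_bruteforce_enumeration(self, rng):
        for _ in range(10):
            d = rng.normal(size=8)
            for alt in ("less", "greater"):
                assert exact_signed_rank_p(d, alt) == pytest.approx(
                    signed_rank_oracle(d, alt))

    def test_ties_match_bruteforce(self):
        d = np.array([-1.0, -1.0, 2.0, -3.0, 2.0])
        for alt in ("less", "greater"):
            assert exact_signed_rank_p(d, alt) == pytest.approx(
                signed_rank_oracle(d, alt))

    def test_agrees_with_scipy_exact(self, rng):
        # independent reference implementation, tie-free draws
        for _ in range(5):
            d = rng.normal(size=9)
            p = exact_signed_rank_p(d, "less")
            ref = wilcoxon(d, alternative="less", method="exact").pvalue
            assert p == pytest.approx(ref)

    def test_all_zero_differences_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            assert exact_signed_rank_p([0.0, 0.0], "less") == 1.0


def _matrix(rows, genes):
    return TimeCourseMatrix(genes, TIMES, np.asarray(rows, float))


def make_trio(rng, n_genes=5, shift=25.0):
    """Sensitive-like test line, sensitive and resistant references."""
    genes = [f"g{i}" for i in range(n_genes)]
    sens, res, test = [], [], []
    for _ in range(n_genes):
        base = rng.uniform(10, 30)
        up = base + np.linspace(0, shift, 5) + rng.normal(0, 0.5, 5)
        pulse = base + shift * np.exp(-((TIMES - 8) ** 2) / 40) + rng.normal(0, 0.5, 5)
        sens.append(up)
        res.append(pulse)
        test.append(base + np.linspace(0, shift, 5) + rng.normal(0, 0.5, 5))
    return (_matrix(np.abs(test), genes), _matrix(np.abs(sens), genes),
            _matrix(np.abs(res), genes), genes)


class TestClassifier:
    def test_identical_to_sensitive_yields_minimal_p(self, rng):
        test, sens, res, genes = make_trio(rng)
        report = classify_cell_line(sens, sens, res, genes)
        assert np.allclose(report.dist_sensitive, 0.0)
        assert report.p_value == pytest.approx(0.03125)
        assert report.label == "sensitive"
        assert report.d < 0

    def test_equidistant_by_symmetry_uncalled(self):
        genes = ["a", "b", "c", "d", "e"]
        ref = _matrix(np.tile(np.array([1, 2, 3, 4, 5.0]), (5, 1)), genes)
        test = _matrix(np.tile(np.array([5, 4, 3, 2, 1.0]), (5, 1)), genes)
        report = classify_cell_line(test, ref, ref, genes)
        assert report.d == pytest.approx(0.0)
        assert report.label == "uncalled"

    def test_simulated_trio_recovers_generating_condition(self, rng):
        hits = 0
        for k in range(20):
            test, sens, res, genes = make_trio(np.random.default_rng(k))
            if classify_cell_line(test, sens, res, genes).label == "sensitive":
                hits += 1
        assert hits >= 18  # >= 90%

    def test_missing_marker_listed_in_error(self, rng):
        test, sens, res, genes = make_trio(rng)
        with pytest.raises(KeyError, match="nope"):
            classify_cell_line(test, sens, res, genes + ["nope"])

    def test_alternative_metrics_available(self, rng):
        test, sens, res, genes = make_trio(rng)
        for metric in ("euclidean", "manhattan"):
            report = classify_cell_line(test, sens, res, genes, metric=metric)
            assert report.label == "sensitive"


class TestBootstrap:
    def test_extreme_observed_hits_add_one_bound(self, rng):
        test, sens, res, genes = make_trio(rng, n_genes=12)
        # markers = the 5 genes; pool restricted so null draws resample them
        p, d, null = bootstrap_set_test(genes[:5], genes, test, sens, res,
                                        n_iter=50, seed=0)
        assert null.shape == (50,)
        assert p >= 1.0 / 51.0

    def test_null_calibration_mean_near_half(self, rng):
        test, sens, res, genes = make_trio(rng, n_genes=10)
        ps = []
        for k in range(30):
            obs = list(np.random.default_rng(k).choice(genes, 5, replace=False))
            p, _, _ = bootstrap_set_test(obs, genes, test, sens, res,
                                         n_iter=60, seed=100 + k)
            ps.append(p)
        assert 0.25 < np.mean(ps) < 0.75

    def test_pool_smaller_than_set_error(self, rng):
        test, sens, res, genes = make_trio(rng)
        with pytest.raises(ValueError):
            bootstrap_set_test(genes, genes[:3], test, sens, res)


class TestDrynb:
    def make_cohort(self, rng, n=120, n_genes=12):
        genes = [f"g{i}" for i in range(n_genes)]
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n_genes, n))
        X[0] += 1.8 * y  # two truly predictive genes
        X[1] -= 1.8 * y
        importance = pd.Series(np.linspace(1.0, 0.1, n_genes), index=genes)
        return pd.DataFrame(X, index=genes), y, importance

    def test_planted_signal_selected_with_high_auc(self, rng):
        expr, y, imp = self.make_cohort(rng)
        train, test = np.arange(0, 90), np.arange(90, 120)
        model = drynb_fit(expr.iloc[:, train], y[train], imp, seed=0)
        assert {"g0", "g1"} <= set(model.selected)
        scores = model.score(expr.iloc[:, test])
        assert roc_auc(scores.to_numpy(), y[test]) > 0.9

    def test_uniform_importance_reduces_to_plain_l1(self, rng):
        expr, y, _ = self.make_cohort(rng)
        imp_u = pd.Series(1.0, index=expr.index)
        m1 = drynb_fit(expr, y, imp_u, seed=0)
        m2 = drynb_fit(expr, y, 2.5 * imp_u, seed=0)  # scale-free weighting
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-8)

    def test_permuted_labels_give_chance_auc(self):
        aucs = []
        for k in range(8):
            rng = np.random.default_rng(k)
            expr, y, imp = self.make_cohort(rng)
            y_perm = rng.permutation(y)
            train, test = np.arange(0, 90), np.arange(90, 120)
            model = drynb_fit(expr.iloc[:, train], y_perm[train], imp, seed=k)
            aucs.append(roc_auc(model.score(expr.iloc[:, test]).to_numpy(),
                                y_perm[test]))
        assert 0.35 < np.mean(aucs) < 0.65

    def test_single_class_labels_error(self, rng):
        expr, y, imp = self.make_cohort(rng)
        with pytest.raises(ValueError):
            drynb_fit(expr, np.zeros_like(y), imp)


class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_null_scores_near_half(self, rng):
        scores, labels = rng.random(2000), rng.integers(0, 2, 2000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])
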