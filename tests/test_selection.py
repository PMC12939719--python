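"""Wavelength selectors: SPA, Lasso, GA, Random Frog."""

from itertools import combinations

import numpy as np
import pytest

from salmonhsi.selection import (
    WavelengthSubset,
    collinearity_score,
    ga_fitness,
    ga_select,
    lasso_select,
    random_frog_select,
    spa_select,
)
from salmonhsi.synthetic import planted_signal_dataset


def _ols_rmse(X, y):
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sqrt(np.mean((y - A @ coef) ** 2)))


class TestSPA:
    def test_single_candidate_band(self, rng):
        X = rng.random((10, 1))
        y = rng.random(10)
        sub = spa_select(X, y, k_min=1, k_max=1)
        assert list(sub.band_indices) == [0]

    def test_duplicated_column_never_coselected(self, rng):
        X = rng.random((30, 6))
        X[:, 3] = X[:, 1]                       # exact duplicate
        y = X[:, 1] * 2 + rng.normal(0, 0.1, 30)
        sub = spa_select(X, y, k_min=2, k_max=4)
        assert not {1, 3} <= set(sub.band_indices)

    def test_rmsec_bounded_by_exhaustive_optimum(self, rng):
        """SPA >= the exhaustive-search optimum over all C(8, <=3) subsets."""
        X = rng.random((40, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.3, 40)
        sub = spa_select(X, y, k_min=1, k_max=3)
        spa_rmsec = sub.rmsec_trace[-1]
        best = min(
            _ols_rmse(X[:, list(c)], y)
            for k in (1, 2, 3) for c in combinations(range(8), k))
        assert spa_rmsec >= best - 1e-12
        # and equality holds when the projection chain contains the optimum
        opt_subsets = [set(c) for k in (1, 2, 3)
                       for c in combinations(range(8), k)
                       if _ols_rmse(X[:, list(c)], y) <= best + 1e-12]
        if set(sub.band_indices) in opt_subsets:
            assert spa_rmsec == pytest.approx(best, abs=1e-10)

    def test_trace_argmin_matches_returned_size(self, rng):
        X, y, _ = planted_signal_dataset(n_samples=80, seed=2)
        sub = spa_select(X, y, k_min=2, k_max=8)
        assert np.all(np.isfinite(sub.rmsec_trace))
        assert sub.size == int(np.argmin(sub.rmsec_trace)) + 2

    def test_row_order_invariance(self, rng):
        X, y, _ = planted_signal_dataset(n_samples=60, seed=3)
        perm = rng.permutation(60)
        a = spa_select(X, y, k_min=2, k_max=6)
        b = spa_select(X[perm], y[perm], k_min=2, k_max=6)
        assert np.array_equal(a.band_indices, b.band_indices)

    def test_planted_band_recovery(self):
        """SPA recovers >= 4 of 5 planted bands for the majority of seeds."""
        hits = []
        for seed in range(10):
            X, y, truth = planted_signal_dataset(seed=seed)
            sub = spa_select(X, y, k_min=3, k_max=10)
            hits.append(len(set(sub.band_indices)
                            & set(truth["planted_bands"].tolist())))
        assert np.median(hits) >= 4

    def test_low_collinearity_vs_random_subsets(self, rng):
        X, y, _ = planted_signal_dataset(n_samples=120, seed=5)
        sub = spa_select(X, y, k_min=4, k_max=6)
        spa_score = collinearity_score(X, sub.band_indices)
        random_scores = [
            collinearity_score(X, rng.choice(X.shape[1], sub.size, replace=False))
            for _ in range(100)]
        assert spa_score <= np.median(random_scores)


class TestLasso:
    def test_orthonormal_design_recovers_single_band(self, rng):
        # soft-thresholding on an orthonormal design keeps only the signal band
        q, _ = np.linalg.qr(rng.normal(size=(60, 8)))
        X = q * np.sqrt(60)
        y = 3.0 * X[:, 5]
        sub = lasso_select(X, y, alpha_grid=np.geomspace(1.0, 1e-3, 12), seed=0)
        assert 5 in sub.band_indices
        final_support = set(sub.band_indices)
        assert final_support == {5}

    def test_full_shrinkage_is_error(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        with pytest.raises(ValueError, match="smaller alphas"):
            lasso_select(X, y, alpha_grid=np.array([1e6]))

    def test_grouped_cv_accepts_groups(self, rng):
        X, y, _ = planted_signal_dataset(n_samples=60, seed=1)
        groups = np.repeat(np.arange(30), 2)
        sub = lasso_select(X, y, groups=groups, seed=0)
        assert sub.size >= 1


class TestGA:
    def test_fitness_matches_direct_refit_oracle(self, rng):
        X, y, _ = planted_signal_dataset(n_samples=60, seed=4)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[[2, 10, 30]] = True
        from salmonhsi.selection import _grouped_cv_rmse
        expected = -_grouped_cv_rmse(X[:, mask], y, None, seed=0)
        assert ga_fitness(X, y, mask, seed=0) == pytest.approx(expected)

    def test_deterministic_under_seed(self):
        X, y, _ = planted_signal_dataset(n_samples=60, n_bands=20,
                                         planted_bands=(2, 9, 15), seed=6)
        a = ga_select(X, y, pop_size=10, generations=5, seed=42)
        b = ga_select(X, y, pop_size=10, generations=5, seed=42)
        assert np.array_equal(a.band_indices, b.band_indices)

    def test_planted_recovery_majority(self):
        hits = []
        for seed in range(10):
            X, y, truth = planted_signal_dataset(n_samples=100, seed=seed)
            sub = ga_select(X, y, pop_size=16, generations=12, seed=seed)
            hits.append(len(set(sub.band_indices)
                            & set(truth["planted_bands"].tolist())))
        assert np.median(hits) >= 3

    def test_parameter_validation(self, rng):
        X, y = rng.random((20, 5)), rng.random(20)
        with pytest.raises(ValueError, match="pop_size"):
            ga_select(X, y, pop_size=2)
        with pytest.raises(ValueError, match="rates"):
            ga_select(X, y, crossover_rate=1.5)


class TestRandomFrog:
    def test_informative_band_has_higher_frequency(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = 2.0 * X[:, 0]                       # noiseless function of band 0
        sub = random_frog_select(X, y, n_iter=300, q_init=1, seed=1)
        assert sub.frequencies[0] > sub.frequencies[1]

    def test_deterministic_under_seed(self):
        X, y, _ = planted_signal_dataset(n_samples=50, n_bands=15,
                                         planted_bands=(3, 8), seed=7)
        a = random_frog_select(X, y, n_iter=150, q_init=3, seed=9)
        b = random_frog_select(X, y, n_iter=150, q_init=3, seed=9)
        assert np.allclose(a.frequencies, b.frequencies)

    def test_null_response_no_spurious_certainty(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 12))
        y = rng.normal(size=60)                  # independent of X
        sub = random_frog_select(X, y, n_iter=400, q_init=4, seed=2)
        med = np.median(sub.frequencies)
        if med > 0:
            assert sub.frequencies.max() <= 3.0 * med

    def test_validates_iterations(self, rng):
        with pytest.raises(ValueError, match="n_iter"):
            random_frog_select(rng.random((30, 4)), rng.random(30), n_iter=10)


class TestCollinearityScore:
    def test_orthogonal_columns(self):
        # zero-mean Walsh-function columns are exactly uncorrelated
        X = np.array([[1, 1, 1], [-1, 1, -1], [1, -1, -1], [-1, -1, 1]],
                     dtype=float)
        assert collinearity_score(X, [0, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_pair_is_one(self, rng):
        X = rng.random((20, 3))
        X[:, 2] = X[:, 0]
        assert collinearity_score(X, [0, 2]) == pytest.approx(1.0)

    def test_matches_pairwise_loop_oracle(self, rng):
        X = rng.random((25, 6))
        expected = max(
            abs(np.corrcoef(X[:, i], X[:, j])[0, 1])
            for i, j in combinations(range(6), 2))
        assert collinearity_score(X, range(6)) == pytest.approx(expected)

    def test_constant_column_rejected(self, rng):
        X = rng.random((10, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="constant"):
            collinearity_score(X, [0, 1])


def test_subset_invariants(rng):
    with pytest.raises(ValueError, match="unique"):
        WavelengthSubset(np.array([1, 1, 2]), None, [0.5], "spa")
    with pytest.raises(ValueError, match="ascending"):
        WavelengthSubset(np.array([3, 1]), None, [0.5], "spa")
    sub = WavelengthSubset(np.arange(30), None, [0.1], "spa")
    assert sub.reduction_percent(158) == pytest.approx(81.0, abs=0.05)
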