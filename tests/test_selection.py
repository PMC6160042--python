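from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

from faimspipe.selection import (
    SelectionSpec,
    _glm_aic,
    filter_select,
    pca_reduce,
    ranksum_p,
    ranksum_p_columns,
    sd_exclude,
    stepwise_select,
)
from .conftest import table_from


def enumerated_ranksum_p(a, b):
    """Brute-force two-sided p: enumerate every assignment of ranks to
    group A under the null and count |W - mean| at least as extreme."""
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, len(a)
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    stats = [sum(c) for c in combinations(range(1, n + 1), n1)]
    d = abs(w_obs - mu)
    return np.mean([abs(w - mu) >= d - 1e-12 for w in stats])


class TestRanksum:
    def test_derived_one_third(self):
        assert ranksum_p([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_derived_null_mean_gives_one(self):
        assert ranksum_p([1, 4], [2, 3]) == pytest.approx(1.0)

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert ranksum_p(a, b) == pytest.approx(ranksum_p(b, a))

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 6), (6, 2)])
    def test_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            assert ranksum_p(a, b) == pytest.approx(enumerated_ranksum_p(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_p([], [1.0])

    def test_vectorised_matches_scalar_large_groups(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 20))
        X[:, 5] = np.round(X[:, 5])  # inject ties in one column
        mask = np.zeros(60, dtype=bool)
        mask[:26] = True
        p_vec = ranksum_p_columns(X, mask)
        for j in range(20):
            assert p_vec[j] == pytest.approx(ranksum_p(X[mask, j], X[~mask, j]))


class TestSdExclude:
    def test_zero_variance_removed_at_sigma_zero(self):
        t = table_from(np.column_stack([np.zeros(4), [0.0, 1, 2, 3]]))
        assert sd_exclude(t, 0.0) == ["f1"]

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=6)
        col = (col - col.mean()) / col.std(ddof=1)  # SD exactly 1
        t = table_from(col[:, None])
        assert sd_exclude(t, 0.5) == ["f0"]
        with pytest.raises(ValueError, match="sigma"):
            sd_exclude(t, 1.5)


class TestFilterSelect:
    def test_separating_feature_ranks_first(self):
        rng = np.random.default_rng(3)
        labels = ["case"] * 6 + ["control"] * 6
        X = rng.normal(size=(12, 4))
        X[:, 2] = np.arange(12.0)  # perfectly separates given label order
        t = table_from(X)
        assert filter_select(t, labels, 1) == ["f2"]

    def test_nkeep_at_feature_count_returns_all(self):
        rng = np.random.default_rng(4)
        t = table_from(rng.normal(size=(8, 3)))
        labels = ["case"] * 4 + ["control"] * 4
        assert sorted(filter_select(t, labels, 3)) == ["f0", "f1", "f2"]

    def test_matches_per_feature_enumeration(self):
        rng = np.random.default_rng(5)
        labels = ["case"] * 4 + ["control"] * 4
        X = rng.normal(size=(8, 5))
        t = table_from(X)
        mask = np.array([l == "case" for l in labels])
        p = [enumerated_ranksum_p(X[mask, j], X[~mask, j]) for j in range(5)]
        expected = [f"f{j}" for j in np.argsort(p, kind="stable")[:2]]
        assert filter_select(t, labels, 2) == expected

    def test_single_class_rejected(self):
        t = table_from(np.zeros((4, 2)) + np.arange(4)[:, None])
        with pytest.raises(ValueError, match="class"):
            filter_select(t, ["case"] * 4, 1)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(6)
        labels = ["case"] * 5 + ["control"] * 5
        X = rng.normal(size=(10, 6))
        t = table_from(X)
        perm = rng.permutation(6)
        t2 = t.take_features(perm)
        sel1 = set(filter_select(t, labels, 3))
        sel2 = set(filter_select(t2, labels, 3))
        assert sel1 == sel2


class TestPCA:
    def test_line_data_still_two_components(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=10)
        X = np.column_stack([base, 2 * base, -base])  # rank-1 data
        train, test = table_from(X[:6]), table_from(X[6:])
        tr, te = pca_reduce(train, test, SelectionSpec(use_pca=True))
        assert tr.n_features == 2 and te.n_features == 2

    def test_isotropic_needs_all_three(self):
        # exactly isotropic sample covariance: orthonormal centred columns
        rng = np.random.default_rng(8)
        n = 8
        M = rng.normal(size=(n, 3))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = Q[:, :3] * np.sqrt(n - 1)
        eigvals = np.linalg.eigvalsh(np.cov(X.T))
        assert np.allclose(eigvals, 1.0)  # eigenvalue oracle: all equal
        tr, _ = pca_reduce(table_from(X), table_from(X), SelectionSpec(use_pca=True))
        assert tr.n_features == 3

    def test_training_scores_centred(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 5))
        tr, _ = pca_reduce(table_from(X[:8]), table_from(X[8:]), SelectionSpec(use_pca=True))
        np.testing.assert_allclose(tr.values.mean(axis=0), 0.0, atol=1e-10)

    def test_all_components_preserve_distances(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(9, 4))
        tr, _ = pca_reduce(
            table_from(X), table_from(X), SelectionSpec(use_pca=True, pca_var_threshold=1.0)
        )
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(tr.values), pdist(X - X.mean(axis=0)), atol=1e-8)


def exhaustive_best_subset_aic(X, y, max_size=None):
    m = X.shape[1]
    best = (np.inf, ())
    for k in range(1, (max_size or m) + 1):
        for subset in combinations(range(m), k):
            try:
                aic = _glm_aic(X[:, subset], y)
            except Exception:
                continue
            if aic < best[0]:
                best = (aic, subset)
    return best


class TestStepwise:
    def _informative_problem(self, seed=11, n=40, m=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, m))
        y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        X[:, 2] += np.where(y == "case", 1.5, -1.5) + rng.normal(0, 0.5, n)
        return X, y

    def test_recovers_informative_feature(self):
        X, y = self._informative_problem()
        t = table_from(X)
        sel = stepwise_select(t, y, SelectionSpec(method="wrapper"), seed=0)
        assert "f2" in sel
        # exhaustive oracle agrees the informative feature belongs
        _, best = exhaustive_best_subset_aic(X, (np.asarray(y) == "case").astype(float))
        assert 2 in best

    def test_collinear_duplicate_not_added(self):
        X, y = self._informative_problem(seed=12, m=3)
        ybin = (np.asarray(y) == "case").astype(float)
        aic_single = _glm_aic(X[:, [2]], ybin)
        aic_dup = _glm_aic(X[:, [2, 2]], ybin)
        assert aic_dup > aic_single  # likelihood unchanged, k increases
        Xd = np.column_stack([X, X[:, 2]])
        sel = stepwise_select(table_from(Xd), y, SelectionSpec(method="wrapper"), seed=1)
        assert not ("f2" in sel and "f3" in sel)

    def test_empty_table_rejected(self):
        t = table_from(np.zeros((4, 1))[:, :0])
        with pytest.raises(ValueError):
            stepwise_select(t, ["case", "case", "control", "control"])


class TestCalibration:
    def test_min_p_follows_sidak_under_null(self):
        # with m independent null features, P(min p <= q) = 1 - (1-q)^m
        rng = np.random.default_rng(13)
        m, n1, n2, reps = 8, 8, 8, 300
        labels = np.array([True] * n1 + [False] * n2)
        min_ps = []
        for _ in range(reps):
            X = rng.normal(size=(n1 + n2, m))
            min_ps.append(ranksum_p_columns(X, labels).min())
        min_ps = np.array(min_ps)
        for q in (0.05, 0.15):
            expected = 1 - (1 - q) ** m
            observed = (min_ps <= q).mean()
            se = np.sqrt(expected * (1 - expected) / reps)
            # extra slack absorbs the discreteness of the exact p lattice
            assert abs(observed - expected) < 4 * se + 0.03
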