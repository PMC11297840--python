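"""Split statistics, permutation tests and tree growth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prtrees.ctree import (
    TreeConfig,
    apply_tree,
    correlation_statistic,
    find_best_split,
    grow_tree,
    permutation_pvalue,
    select_split_variable,
    transform_covariate,
    tree_from_json,
    tree_to_json,
)
from prtrees.pseudo import InvalidInputError, PseudoValueMatrix, TimeGrid


def make_pv(values):
    values = np.asarray(values, dtype=float)
    return PseudoValueMatrix(values=values, grid=TimeGrid(points=np.arange(1.0, values.shape[1] + 1)))


class TestCorrelationStatistic:
    def test_hand_computed_pearson_type(self):
        # K = 1, continuous covariate on 5 points: the standardized statistic
        # is (sum x*theta - m*xbar*tbar) / sqrt(Sx * St / (m-1))
        x = np.array([0.1, 0.5, -0.3, 1.2, 0.7])
        theta = np.array([[0.2], [0.9], [-0.1], [1.4], [0.6]])
        m = 5
        num = (x * theta[:, 0]).sum() - m * x.mean() * theta.mean()
        sx = ((x - x.mean()) ** 2).sum()
        st = ((theta[:, 0] - theta.mean()) ** 2).sum()
        expected = num / np.sqrt(sx * st / (m - 1))
        z, max_abs = correlation_statistic(theta, x)
        assert z[0, 0] == pytest.approx(expected)
        assert max_abs == pytest.approx(abs(expected))

    def test_null_standardization(self, rng):
        # independent covariate: standardized elements approximately N(0,1)
        n, K, reps = 200, 4, 300
        zs = []
        theta = rng.normal(size=(n, K))
        for _ in range(reps):
            zs.append(correlation_statistic(theta, rng.permutation(n).astype(float))[0][0, 0])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.15
        assert abs(zs.std() - 1) < 0.15

    def test_self_covariate_maximizes_first_column(self, rng):
        theta = rng.normal(size=(80, 3))
        z, _ = correlation_statistic(theta, theta[:, 0])
        assert np.nanargmax(np.abs(z[0])) == 0

    def test_constant_covariate_flagged(self, rng):
        theta = rng.normal(size=(10, 2))
        z, max_abs = correlation_statistic(theta, np.ones(10))
        assert max_abs == -np.inf
        assert np.isnan(z).all()


class TestPermutationPvalue:
    def test_lower_bound_when_observed_exceeds_all(self, rng):
        n = 200
        theta = np.linspace(0, 1, n).reshape(-1, 1) + rng.normal(0, 0.01, (n, 1))
        p = permutation_pvalue(theta, theta[:, 0] + rng.normal(0, 0.01, n), n_perm=199, rng=rng)
        assert p == pytest.approx(1 / 200)

    def test_null_uniformity(self, rng):
        # under independence, the p-value distribution is near uniform
        n, reps, n_perm = 30, 400, 199
        pvals = []
        for _ in range(reps):
            theta = rng.normal(size=(n, 2))
            pvals.append(permutation_pvalue(theta, rng.normal(size=n), n_perm=n_perm, rng=rng))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_on_informative_covariate(self, rng):
        hits = 0
        reps, n_perm = 25, 199
        for _ in range(reps):
            x = rng.normal(size=200)
            theta = (x[:, None] + rng.normal(0, 0.3, (200, 2)))
            if permutation_pvalue(theta, x, n_perm=n_perm, rng=rng) == 1 / (1 + n_perm):
                hits += 1
        assert hits == reps


class TestSelectSplitVariable:
    def test_informative_single_candidate(self, rng):
        x = rng.normal(size=150)
        theta = x[:, None] + rng.normal(0, 0.2, (150, 2))
        blocks = [transform_covariate(x, "continuous")[0]]
        j, p = select_split_variable(theta, blocks, ["x1"], 199, rng, alpha=0.05)
        assert j == 0
        assert p == pytest.approx(1 / 200)

    def test_pure_noise_mostly_returns_none(self, rng):
        none_count = 0
        reps = 60
        for _ in range(reps):
            theta = rng.normal(size=(40, 2))
            blocks = [transform_covariate(rng.normal(size=40), "continuous")[0] for _ in range(3)]
            j, _ = select_split_variable(theta, blocks, list("abc"), 99, rng, alpha=0.05)
            none_count += j is None
        # unadjusted minimum over 3 tests: expect roughly >= 85% stops
        assert none_count / reps > 0.7


class TestFindBestSplit:
    def test_recovers_step_threshold(self, rng):
        x = rng.uniform(size=120)
        xi0 = 0.55
        theta = np.where(x[:, None] > xi0, 1.0, -1.0) + rng.normal(0, 0.01, (120, 2))
        left_mask, info = find_best_split(theta, x, "continuous", min_size=5)
        xs = np.sort(x)
        below = xs[xs <= xi0].max()
        above = xs[xs > xi0].min()
        assert below <= info["threshold"] <= above
        assert np.array_equal(left_mask, x <= info["threshold"])

    def test_binary_covariate_single_partition(self, rng):
        x = np.array([0.0] * 10 + [1.0] * 10)
        theta = rng.normal(size=(20, 2))
        left_mask, info = find_best_split(theta, x, "continuous", min_size=2)
        assert info["threshold"] == pytest.approx(0.5)
        assert left_mask.sum() == 10

    def test_matches_bruteforce_enumeration(self, rng):
        # exhaustive oracle over all distinct-value cuts, n <= 20
        for _ in range(30):
            m = int(rng.integers(8, 21))
            x = np.round(rng.uniform(size=m), 1)
            theta = rng.normal(size=(m, 3))
            res = find_best_split(theta, x, "continuous", min_size=2)
            tbar = theta.mean(axis=0)
            v = ((theta - tbar) ** 2).mean(axis=0)
            best_score, best_thr = -np.inf, None
            for thr in np.unique(x)[:-1]:
                left = x <= thr
                nr = m - left.sum()
                if left.sum() < 2 or nr < 2:
                    continue
                scores = []
                for k in range(3):
                    if v[k] <= 1e-12:
                        continue
                    sd = np.sqrt(nr * (m - nr) / (m - 1) * v[k])
                    scores.append(abs((theta[~left, k].sum() - nr * tbar[k]) / sd))
                if scores and max(scores) > best_score:
                    best_score, best_thr = max(scores), thr
            if best_thr is None:
                assert res is None
            else:
                _, info = res
                assert info["score"] == pytest.approx(best_score)

    def test_unordered_factor_bruteforce(self, rng):
        from itertools import combinations

        cats = list("abcd")
        x = np.array([cats[i % 4] for i in range(24)])
        theta = rng.normal(size=(24, 2))
        left_mask, info = find_best_split(theta, x, "unordered", min_size=2)
        m = 24
        tbar = theta.mean(axis=0)
        v = ((theta - tbar) ** 2).mean(axis=0)
        best = -np.inf
        for r in range(1, 4):
            for comb in combinations(cats, r):
                left = np.isin(x, comb)
                nr = m - left.sum()
                if left.sum() < 2 or nr < 2:
                    continue
                sds = np.sqrt(nr * (m - nr) / (m - 1) * v)
                sc = np.abs((theta[~left].sum(axis=0) - nr * tbar) / sds).max()
                best = max(best, sc)
        assert info["score"] == pytest.approx(best)

    def test_too_many_categories_rejected(self, rng):
        x = np.array([f"c{i}" for i in range(12)] * 3)
        theta = rng.normal(size=(36, 2))
        with pytest.raises(InvalidInputError):
            find_best_split(theta, x, "unordered", min_size=1)

    def test_min_size_respected(self, rng):
        x = np.arange(10, dtype=float)
        theta = rng.normal(size=(10, 2))
        res = find_best_split(theta, x, "continuous", min_size=4)
        left_mask, _ = res
        assert 4 <= left_mask.sum() <= 6


class TestGrowTree:
    def _signal_data(self, rng, n=150):
        cov = pd.DataFrame({
            "x1": rng.uniform(size=n),
            "x2": rng.normal(size=n),
        })
        theta = np.where(cov.x1.to_numpy()[:, None] > 0.5, 1.0, 0.0) + rng.normal(0, 0.2, (n, 3))
        return cov, make_pv(theta)

    def test_depth_zero_single_node(self, rng):
        cov, pv = self._signal_data(rng)
        tree = grow_tree(cov, {}, pv, TreeConfig(max_depth=0, seed=1))
        assert tree.is_terminal
        assert len(tree.members) == pv.n

    def test_signal_split_found_and_partition_exact(self, rng):
        cov, pv = self._signal_data(rng)
        tree = grow_tree(cov, {}, pv, TreeConfig(max_depth=2, n_perm=199, seed=1))
        assert not tree.is_terminal
        assert tree.split.variable == "x1"
        left, right = tree.children
        assert set(left.members) | set(right.members) == set(tree.members)
        assert not (set(left.members) & set(right.members))

    def test_min_node_size_terminal_nodes(self, rng):
        cov, pv = self._signal_data(rng, n=60)
        cfg = TreeConfig(max_depth=4, n_perm=99, min_node_size=10, seed=2)
        tree = grow_tree(cov, {}, pv, cfg)
        for node in tree.terminal_nodes():
            assert len(node.members) >= 10

    def test_pure_noise_rarely_splits(self, rng):
        split_count = 0
        reps = 40
        for _ in range(reps):
            cov = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
            pv = make_pv(rng.normal(size=(50, 2)))
            tree = grow_tree(cov, {}, pv, TreeConfig(max_depth=2, n_perm=99, seed=None))
            split_count += not tree.is_terminal
        # unadjusted 5% level over two covariates: expect well under 30% splits
        assert split_count / reps < 0.3

    def test_determinism_and_serialization(self, rng):
        cov, pv = self._signal_data(rng)
        cfg = TreeConfig(max_depth=2, n_perm=199, seed=11)
        t1 = grow_tree(cov, {}, pv, cfg)
        t2 = grow_tree(cov, {}, pv, cfg)
        assert tree_to_json(t1) == tree_to_json(t2)
        t3 = tree_from_json(tree_to_json(t1))
        np.testing.assert_array_equal(apply_tree(t1, cov), apply_tree(t3, cov))

    def test_routing_unseen_level_raises(self, rng):
        n = 60
        cov = pd.DataFrame({"g": np.array(list("ab"))[rng.integers(0, 2, n)]})
        theta = np.where(cov.g.to_numpy()[:, None] == "a", 1.0, -1.0) + rng.normal(0, 0.05, (n, 2))
        tree = grow_tree(cov, {"g": "unordered"}, make_pv(theta), TreeConfig(max_depth=1, n_perm=99, seed=0))
        assert not tree.is_terminal
        with pytest.raises(InvalidInputError):
            apply_tree(tree, pd.DataFrame({"g": ["c"]}))
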