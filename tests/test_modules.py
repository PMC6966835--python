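"""Signed adjacency, TOM, module detection, eigengenes, traits and hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score

from nutrinet.modules import (UNASSIGNED, detect_modules, kleinberg_hub_scores,
                              module_eigengene, signed_adjacency,
                              tom_similarity, trait_association)


def block_expression(rng, n_blocks=2, block_size=50, n_noise=0, n_samples=20,
                     rho=0.8, factors=None):
    """Expression with planted correlated blocks plus unstructured genes."""
    rows, labels = [], []
    if factors is None:
        factors = rng.normal(size=(n_blocks, n_samples))
    for b in range(n_blocks):
        for _ in range(block_size):
            rows.append(np.sqrt(rho) * factors[b]
                        + np.sqrt(1 - rho) * rng.normal(size=n_samples))
            labels.append(f"block{b}")
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append("noise")
    ids = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids), pd.Series(labels, index=ids)


class TestSignedAdjacency:
    def test_extreme_and_zero_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame(
            [x, 2 * x, -x, [1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]],
            index=list("abcde"))
        a = signed_adjacency(expr, beta=16)
        assert a.at["a", "b"] == pytest.approx(1.0)            # r = 1
        assert a.at["a", "c"] == pytest.approx(0.0, abs=1e-15)  # r = -1
        assert a.at["d", "e"] == pytest.approx(0.5 ** 16)       # r = 0

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        a = signed_adjacency(pd.DataFrame(rng.normal(size=(5, 8))))
        np.testing.assert_allclose(np.diag(a), 1.0)


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Double-loop topological overlap oracle."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTOM:
    def test_isolated_perfect_pair(self):
        a = pd.DataFrame(np.eye(3))
        a.iloc[0, 1] = a.iloc[1, 0] = 1.0
        tom = tom_similarity(a)
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_diagonal_convention(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.testing.assert_allclose(np.diag(tom_similarity(pd.DataFrame(a))), 1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, size=(10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        np.testing.assert_allclose(tom, tom_oracle(a), atol=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.uniform(0, 1, size=(12, 12))
            a = (a + a.T) / 2
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_rejects_out_of_range_adjacency(self):
        with pytest.raises(ValueError):
            tom_similarity(pd.DataFrame([[1.0, 2.0], [2.0, 1.0]]))


class TestModuleEigengene:
    def test_identical_profiles_perfectly_represented(self):
        rng = np.random.default_rng(4)
        profile = rng.normal(size=10)
        expr = pd.DataFrame([profile, profile * 2 + 1, profile * 0.5 - 3],
                            index=list("abc"))
        me = module_eigengene(expr, list("abc"))
        assert abs(np.corrcoef(me, profile)[0, 1]) == pytest.approx(1.0)

    def test_orientation_non_negative_mean_correlation(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(6, 12)))
        me = module_eigengene(expr, expr.index)
        cors = [np.corrcoef(expr.loc[g], me)[0, 1] for g in expr.index]
        assert np.mean(cors) >= 0

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(3, 9)))
        me = module_eigengene(expr, expr.index).to_numpy()
        z = expr.to_numpy()
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        u, s, vt = np.linalg.svd(z)
        oracle = vt[0] / np.std(vt[0], ddof=1)
        assert (np.allclose(me, oracle, atol=1e-9)
                or np.allclose(me, -oracle, atol=1e-9))

    def test_unit_variance(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(5, 14)))
        me = module_eigengene(expr, expr.index)
        assert me.std(ddof=1) == pytest.approx(1.0)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(8)
        expr, truth = block_expression(rng, n_blocks=2, block_size=50, n_noise=40)
        tom = tom_similarity(signed_adjacency(expr, beta=16))
        labels = detect_modules(1 - tom, expr=expr, min_module_size=30)
        planted = truth[truth != "noise"]
        ari = adjusted_rand_score(planted, labels.loc[planted.index])
        assert ari > 0.9
        assert len([m for m in labels.unique() if m != UNASSIGNED]) >= 2

    def test_too_few_genes_all_unassigned(self):
        rng = np.random.default_rng(9)
        expr, _ = block_expression(rng, n_blocks=1, block_size=20, n_noise=0)
        tom = tom_similarity(signed_adjacency(expr))
        labels = detect_modules(1 - tom, min_module_size=30)
        assert (labels == UNASSIGNED).all()

    def test_highly_correlated_blocks_merge(self):
        rng = np.random.default_rng(10)
        shared = rng.normal(size=20)
        f1 = shared + 0.33 * rng.normal(size=20)   # eigengene cor ~0.95
        f2 = shared + 0.33 * rng.normal(size=20)
        expr, _ = block_expression(rng, n_blocks=2, block_size=40,
                                   factors=np.vstack([f1, f2]), rho=0.9)
        tom = tom_similarity(signed_adjacency(expr, beta=16))
        merged = detect_modules(1 - tom, expr=expr, min_module_size=30,
                                merge_height=0.25, cut_height=0.9)
        mods = [m for m in merged.unique() if m != UNASSIGNED]
        assert len(mods) == 1


class TestTraitAssociation:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        r, p = trait_association(x, x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_exact_half_correlation_student_p(self):
        # construct a pair with r exactly 0.5 at n = 23
        rng = np.random.default_rng(11)
        x = rng.normal(size=23)
        z = rng.normal(size=23)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (z @ x) / (x @ x)
        z /= z.std()
        y = 0.5 * x + np.sqrt(1 - 0.25) * z
        r, p = trait_association(x, y)
        assert r == pytest.approx(0.5, abs=1e-12)
        # t = 0.5 * sqrt(21) / sqrt(0.75) = 2.6458
        assert p == pytest.approx(0.0151, abs=5e-4)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(12)
        ps = [trait_association(rng.normal(size=23), rng.normal(size=23))[1]
              for _ in range(400)]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            trait_association(np.ones(10), np.arange(10.0))

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan, 6.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 1.0, 12.0])
        r, _ = trait_association(x, y)
        assert r == pytest.approx(1.0)


class TestKleinbergHubs:
    def _df(self, a):
        ids = [f"n{i}" for i in range(a.shape[0])]
        return pd.DataFrame(a, index=ids, columns=ids)

    def test_star_graph(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1.0
        h = kleinberg_hub_scores(self._df(a))
        assert h.iloc[0] == pytest.approx(1.0)
        assert (h.iloc[1:] < 1.0).all()
        np.testing.assert_allclose(h.iloc[1:], h.iloc[1])

    def test_complete_graph_all_unit(self):
        a = np.ones((4, 4))
        np.testing.assert_allclose(kleinberg_hub_scores(self._df(a)), 1.0)

    def test_matches_networkx_hits(self):
        import networkx as nx

        rng = np.random.default_rng(13)
        a = rng.uniform(0, 1, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        ours = kleinberg_hub_scores(self._df(a))
        g = nx.from_numpy_array(a)
        hubs, _ = nx.hits(g, max_iter=1000, tol=1e-12)
        ref = np.array([hubs[i] for i in range(8)])
        ref = ref / ref.max()
        np.testing.assert_allclose(ours.to_numpy(), ref, atol=1e-8)

    def test_empty_graph_scores_zero(self):
        h = kleinberg_hub_scores(self._df(np.zeros((3, 3))))
        np.testing.assert_allclose(h, 0.0)
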