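import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from katzmda.data import AssociationDataset
from katzmda.evaluation import (
    KatzScorer,
    PageRankScorer,
    RandomScorer,
    RWRScorer,
    kfold,
    loocv,
    make_scorer,
    pagerank_score,
    roc_auc,
    rwr_score,
)
from katzmda.katz import build_hetero
from katzmda.semantic import semantic_similarity_matrix


class OracleScorer:
    """Perfect scorer: 1 exactly on the pairs masked out of M, 0 elsewhere."""

    name = "oracle"

    def __init__(self, full_M):
        self.full_M = full_M

    def __call__(self, M):
        return (self.full_M - M).T


class SpyScorer:
    """Records the matrices it is asked to score."""

    name = "spy"

    def __init__(self, inner):
        self.inner = inner
        self.seen = []

    def __call__(self, M):
        self.seen.append(M.copy())
        return self.inner(M)


class TestRocAuc:
    def test_all_rank_one(self):
        _, auc = roc_auc([1, 1, 1], 10)
        assert auc == 1.0

    def test_single_rank_two_of_three(self):
        _, auc = roc_auc([2], 3)
        assert auc == 0.5

    def test_uniform_ranks_near_half(self):
        rng = np.random.default_rng(0)
        ranks = rng.integers(1, 51, size=10_000)
        _, auc = roc_auc(ranks, 50)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_empty_ranks_error(self):
        with pytest.raises(ValueError, match="no held-out"):
            roc_auc([], 5)

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError, match="ranks must lie"):
            roc_auc([6], 5)

    def test_roc_endpoints_and_monotone(self):
        roc, _ = roc_auc([3, 1, 7], 8)
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)
        fprs, tprs = zip(*roc)
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))
        assert all(a <= b for a, b in zip(tprs, tprs[1:]))

    @pytest.mark.parametrize("n_pos,n_neg", [(1, 5), (3, 10), (6, 19)])
    def test_matches_pairwise_mann_whitney(self, n_pos, n_neg):
        """AUC from ranks equals exhaustive pairwise comparison (with ties)."""
        rng = np.random.default_rng(n_pos * 100 + n_neg)
        for _ in range(20):
            pos = rng.integers(0, 6, size=n_pos).astype(float)
            neg = np.sort(rng.integers(0, 6, size=n_neg).astype(float))
            ranks = [
                (neg > s).sum() + (neg == s).sum() / 2 + 1 for s in pos
            ]
            _, auc = roc_auc(ranks, n_neg + 1)
            wins = sum(
                1.0 if p > n else 0.5 if p == n else 0.0
                for p, n in itertools.product(pos, neg)
            )
            assert auc == pytest.approx(wins / (n_pos * n_neg), abs=1e-12)
            # independent library oracle on the pooled score lists
            labels = [1] * n_pos + [0] * n_neg
            assert auc == pytest.approx(
                roc_auc_score(labels, np.concatenate([pos, neg])), abs=1e-12
            )


class TestLoocv:
    def test_perfect_scorer_auc_one(self, tiny_dataset):
        res = loocv(tiny_dataset, OracleScorer(tiny_dataset.M))
        assert res.auc_mean == 1.0
        assert all(r == 1.0 for r in res.ranks)

    def test_random_scorer_near_half(self):
        rng = np.random.default_rng(42)
        pairs = {(f"d{i}", f"m{j}") for i in range(10) for j in range(20)
                 if rng.random() < 0.5}
        ds = AssociationDataset.from_pairs(sorted(pairs))
        res = loocv(ds, RandomScorer(seed=7))
        assert 0.45 <= res.auc_mean <= 0.55

    def test_masking_never_leaks(self, tiny_dataset):
        spy = SpyScorer(OracleScorer(tiny_dataset.M))
        loocv(tiny_dataset, spy)
        n = len(tiny_dataset.pairs)
        assert len(spy.seen) == n
        assert all(M.sum() == n - 1 for M in spy.seen)

    def test_needs_two_pairs(self):
        ds = AssociationDataset.from_pairs([("d1", "m1")])
        with pytest.raises(ValueError, match="at least 2"):
            loocv(ds, RandomScorer())

    def test_balanced_negatives_shrinks_candidates(self, preset_world):
        dataset, _, _, dss = preset_world
        sc = KatzScorer(dss=dss)
        res = kfold(dataset, sc, k_folds=5, seed=3, balance_negatives=True)
        assert res.n_candidates == len(dataset.pairs) + 1


class TestKfold:
    def test_determinism_under_seed(self, tiny_dataset):
        r1 = kfold(tiny_dataset, OracleScorer(tiny_dataset.M), k_folds=2, seed=5)
        r2 = kfold(tiny_dataset, OracleScorer(tiny_dataset.M), k_folds=2, seed=5)
        assert r1.folds == r2.folds and r1.ranks == r2.ranks

    def test_k_equals_pairs_reduces_to_loocv(self, tiny_dataset):
        sc = OracleScorer(tiny_dataset.M)
        kf = kfold(tiny_dataset, sc, k_folds=len(tiny_dataset.pairs), seed=1)
        lo = loocv(tiny_dataset, sc)
        assert sorted(kf.ranks) == sorted(lo.ranks)
        assert kf.n_candidates == lo.n_candidates

    def test_k_too_large_errors(self, tiny_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            kfold(tiny_dataset, OracleScorer(tiny_dataset.M), k_folds=6)

    def test_fold_masking_counts(self, preset_world):
        dataset, _, _, dss = preset_world
        spy = SpyScorer(OracleScorer(dataset.M))
        kfold(dataset, spy, k_folds=5, seed=0)
        n = len(dataset.pairs)
        sizes = [int(n - M.sum()) for M in spy.seen]
        assert sum(sizes) == n and len(sizes) == 5
        assert max(sizes) - min(sizes) <= 1

    def test_repeats_multiply_folds(self, tiny_dataset):
        res = kfold(tiny_dataset, OracleScorer(tiny_dataset.M), k_folds=2, repeats=3, seed=0)
        assert len(res.folds) == 6

    def test_similarity_recomputed_inside_fold(self):
        """Masking a disease's only association must change its GIP profile."""
        ds = AssociationDataset.from_pairs(
            [("d1", "m1"), ("d2", "m1"), ("d2", "m2"), ("d3", "m2")]
        )
        dss = np.eye(3)
        sc = KatzScorer(dss=dss)
        net_full = sc.network(ds.M)
        M_masked = ds.M.copy()
        M_masked[0, 0] = 0.0  # d1 loses its only association
        net_masked = sc.network(M_masked)
        gd_full = net_full.SD[0, 1]
        gd_masked = net_masked.SD[0, 1]
        assert gd_full != pytest.approx(gd_masked)
        # frozen (static-similarity) mode keeps the old similarities
        sc.freeze(ds.M)
        net_frozen = sc.network(M_masked)
        np.testing.assert_allclose(net_frozen.SD, net_full.SD)


class TestRwr:
    @pytest.fixture()
    def small_net(self, tiny_dataset):
        dss = np.eye(tiny_dataset.n_diseases)
        sc = KatzScorer(dss=dss)
        return sc.network(tiny_dataset.M)

    def test_restart_one_returns_seed(self, small_net):
        res = rwr_score(small_net, restart_prob=1.0)
        np.testing.assert_allclose(res.Z, 0.0)
        np.testing.assert_allclose(res.params["column_mass"], 1.0)

    def test_probability_conserved(self, small_net):
        res = rwr_score(small_net, restart_prob=0.7)
        np.testing.assert_allclose(res.params["column_mass"], 1.0, atol=1e-9)

    def test_two_node_closed_form(self):
        # one metabolite, one disease, Mstar = [[1, 1], [1, 1]] -> W uniform;
        # solve p = 0.3 W p + 0.7 e directly
        net = build_hetero(np.eye(1), np.eye(1), np.array([[1.0]]))
        res = rwr_score(net, restart_prob=0.7)
        W = net.Mstar / net.Mstar.sum(axis=0)
        p = np.linalg.solve(np.eye(2) - 0.3 * W, 0.7 * np.array([0.0, 1.0]))
        assert res.Z[0, 0] == pytest.approx(p[0], abs=1e-9)

    def test_nonconvergence_raises(self, small_net):
        with pytest.raises(RuntimeError, match="converge"):
            rwr_score(small_net, restart_prob=0.1, max_iter=1, tol=1e-15)


class TestPageRank:
    def test_uniform_graph_uniform_scores(self):
        net = build_hetero(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)))
        res = pagerank_score(net, damping=0.85)
        np.testing.assert_allclose(res.Z, res.Z[0, 0], atol=1e-9)

    def test_damping_zero_returns_personalization(self):
        net = build_hetero(np.eye(2), np.eye(2), np.ones((2, 2)))
        res = pagerank_score(net, damping=0.0)
        np.testing.assert_allclose(res.Z, 0.0)

    def test_matches_networkx_personalized_pagerank(self):
        rng = np.random.default_rng(8)
        M = (rng.random((3, 4)) < 0.6).astype(float)
        M[0, 0] = 1
        net = build_hetero(np.eye(4), np.eye(3), M)
        res = pagerank_score(net, damping=0.85, tol=1e-12)
        g = nx.from_numpy_array(net.Mstar)
        for j in range(3):
            pr = nx.pagerank(
                g, alpha=0.85, personalization={4 + j: 1.0}, tol=1e-12, max_iter=500
            )
            np.testing.assert_allclose(
                res.Z[:, j], [pr[i] for i in range(4)], atol=1e-6
            )


class TestScorers:
    def test_make_scorer_names(self, preset_world):
        _, _, _, dss = preset_world
        for name, cls in (("katz", KatzScorer), ("rwr", RWRScorer), ("pagerank", PageRankScorer)):
            assert isinstance(make_scorer(name, dss), cls)
        with pytest.raises(ValueError):
            make_scorer("svd", dss)

    def test_closed_form_scorer_close_to_truncated_tail(self, preset_world):
        dataset, _, _, dss = preset_world
        sc = KatzScorer(dss=dss)
        rho = np.abs(np.linalg.eigvalsh(sc.network(dataset.M).Mstar)).max()
        delta = 0.05 / rho  # truncation error bounded by (delta*rho)^5 / (1 - delta*rho)
        z_tr = KatzScorer(dss=dss, delta=delta, k=4)(dataset.M)
        z_cl = KatzScorer(dss=dss, delta=delta, closed_form=True)(dataset.M)
        assert np.abs(z_tr - z_cl).max() < 1e-6
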