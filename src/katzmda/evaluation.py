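"""Cross-validation protocols, ROC/AUC computation, and diffusion baselines.

Leave-one-out CV masks each known association in turn, rebuilds the GIP
similarities and the integrated disease similarity from the masked matrix,
rescores, and records the rank of the held-out pair among all unknown
pairs.  K-fold CV masks a random k-th of the known pairs jointly and scores
each fold's positives against the unknown pairs.  AUC uses the
Mann-Whitney formulation on mid-ranks (ties counted half), with an ROC
curve traced by sweeping a rank threshold.

Two diffusion baselines run on the same heterogeneous network: random walk
with restart (RWR), iterating p <- (1-r) W p + r e on the column-normalized
M*, and personalized PageRank.  Both score metabolites by their mass in the
stationary vector seeded at a disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import AssociationDataset
from .gip import (
    DEFAULT_A,
    DEFAULT_B,
    DEFAULT_GAMMA,
    DEFAULT_OMEGA_PRIME,
    gip_kernel,
    integrate_disease_similarity,
    logistic_transform,
)
from .katz import (
    DEFAULT_DELTA_KATZ,
    DEFAULT_K,
    HeteroNetwork,
    ScoreMatrix,
    build_hetero,
    katz_closed,
    katz_truncated,
)

logger = logging.getLogger("katzmda")

__all__ = [
    "EvalResult",
    "KatzScorer",
    "RWRScorer",
    "PageRankScorer",
    "RandomScorer",
    "PermutedScorer",
    "make_scorer",
    "loocv",
    "kfold",
    "roc_auc",
    "rwr_score",
    "pagerank_score",
    "DEFAULT_RESTART",
]

#: Restart probability for the RWR baseline (values from the cited baseline
#: are not printed; this is the common network-propagation default).
DEFAULT_RESTART = 0.7
DEFAULT_DAMPING = 0.85


@dataclass
class EvalResult:
    """Outcome of one cross-validation run."""

    method: str
    protocol: str
    folds: list[float]
    auc_mean: float
    auc_std: float
    roc: list[tuple[float, float]]
    ranks: list[float]
    n_candidates: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "protocol": self.protocol,
            "params": self.params,
            "folds": self.folds,
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "roc": self.roc,
        }


# ---------------------------------------------------------------------------
# Scoring pipelines: callables mapping a (possibly masked) disease x
# metabolite adjacency to a metabolite x disease score matrix.
# ---------------------------------------------------------------------------


@dataclass
class _SimilarityPipeline:
    """Shared similarity stage: adjacency -> (SM, SD) -> heterogeneous network."""

    dss: np.ndarray  # n_d x n_d semantic similarity, fixed across folds
    gamma: float = DEFAULT_GAMMA
    omega_prime: float = DEFAULT_OMEGA_PRIME
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    integration_kernel: str = "gdl"
    _frozen: HeteroNetwork | None = field(default=None, repr=False)

    def network(self, M: np.ndarray) -> HeteroNetwork:
        if self._frozen is not None:
            # static-similarity mode: reuse SM/SD from the unmasked matrix,
            # swapping in the masked adjacency block only
            return build_hetero(self._frozen.SM, self._frozen.SD, M)
        SM = gip_kernel(M, "metabolite", self.omega_prime)
        GD = gip_kernel(M, "disease", self.omega_prime)
        GDL = logistic_transform(GD, self.a, self.b)
        SD = integrate_disease_similarity(self.dss, GDL, GD, self.gamma, self.integration_kernel)
        return build_hetero(SM, SD, M)

    def freeze(self, M: np.ndarray) -> None:
        """Fix SM/SD to the similarities of ``M`` (information-leaking variant)."""
        self._frozen = None
        self._frozen = self.network(M)


@dataclass
class KatzScorer(_SimilarityPipeline):
    """Full KATZ pipeline: similarities from M, then truncated or closed-form scores."""

    delta: float = DEFAULT_DELTA_KATZ
    k: int = DEFAULT_K
    closed_form: bool = False
    name: str = "katz"

    def __call__(self, M: np.ndarray) -> np.ndarray:
        net = self.network(M)
        if self.closed_form:
            return katz_closed(net, self.delta).Z
        return katz_truncated(net, self.delta, self.k).Z


@dataclass
class RWRScorer(_SimilarityPipeline):
    """Random-walk-with-restart baseline on the same heterogeneous network."""

    restart_prob: float = DEFAULT_RESTART
    max_iter: int = 1000
    tol: float = 1e-10
    name: str = "rwr"

    def __call__(self, M: np.ndarray) -> np.ndarray:
        net = self.network(M)
        return rwr_score(net, self.restart_prob, self.max_iter, self.tol).Z


@dataclass
class PageRankScorer(_SimilarityPipeline):
    """Personalized-PageRank baseline on the same heterogeneous network."""

    damping: float = DEFAULT_DAMPING
    max_iter: int = 1000
    tol: float = 1e-10
    name: str = "pagerank"

    def __call__(self, M: np.ndarray) -> np.ndarray:
        net = self.network(M)
        return pagerank_score(net, self.damping, self.max_iter, self.tol).Z


class RandomScorer:
    """Null scorer: i.i.d. uniform scores, fresh draw per call (seeded)."""

    name = "random"

    def __init__(self, seed: int = 0) -> None:
        self._rng = np.random.default_rng(seed)

    def __call__(self, M: np.ndarray) -> np.ndarray:
        n_d, n_m = M.shape
        return self._rng.random((n_m, n_d))


class PermutedScorer:
    """Label-permuted null: runs a base scorer, then permutes metabolite rows."""

    def __init__(self, base: Callable[[np.ndarray], np.ndarray], seed: int = 0) -> None:
        self.base = base
        self.name = f"{getattr(base, 'name', 'scorer')}-permuted"
        self._rng = np.random.default_rng(seed)

    def __call__(self, M: np.ndarray) -> np.ndarray:
        Z = self.base(M)
        return Z[self._rng.permutation(Z.shape[0]), :]


def make_scorer(method: str, dss: np.ndarray, **params) -> Callable[[np.ndarray], np.ndarray]:
    """Factory for the three scoring methods by name ('katz', 'rwr', 'pagerank')."""
    cls = {"katz": KatzScorer, "rwr": RWRScorer, "pagerank": PageRankScorer}.get(method)
    if cls is None:
        raise ValueError(f"unknown method {method!r}")
    return cls(dss=dss, **params)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _midrank(score: float, neg_sorted: np.ndarray) -> float:
    """Rank of one positive among itself plus sorted negative scores.

    Mid-rank: strictly-greater count + half the tied count + 1.
    """
    n = len(neg_sorted)
    lo = np.searchsorted(neg_sorted, score, side="left")
    hi = np.searchsorted(neg_sorted, score, side="right")
    greater = n - hi
    ties = hi - lo
    return greater + ties / 2.0 + 1.0


def roc_auc(
    positive_ranks: Sequence[float], n_candidates: int
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and AUC from held-out positives' ranks.

    Each rank is the (possibly fractional, mid-rank) position of one
    held-out positive in its candidate set of ``n_candidates`` entries
    (the positive itself plus ``n_candidates - 1`` negatives).  The AUC is
    the Mann-Whitney probability that a positive outranks a random
    negative, averaged over trials; the ROC is traced by sweeping an
    integer rank threshold.
    """
    ranks = np.asarray(positive_ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("no held-out positives: cannot compute ROC/AUC")
    if n_candidates < 2:
        raise ValueError("need at least 2 candidates")
    if ranks.min() < 1.0 or ranks.max() > n_candidates:
        raise ValueError(f"ranks must lie in [1, {n_candidates}]")
    n = n_candidates
    auc = float(np.mean((n - ranks) / (n - 1)))
    thresholds = np.unique(np.concatenate(([0.0], np.ceil(ranks), [float(n)])))
    roc: list[tuple[float, float]] = []
    for t in thresholds:
        hit = ranks <= t
        tpr = float(hit.mean())
        fpr = float(np.mean((np.minimum(t, n) - hit) / (n - 1)))
        roc.append((fpr, tpr))
    roc.sort()
    return roc, auc


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------


def _pair_indices(dataset: AssociationDataset) -> list[tuple[int, int]]:
    d_idx, m_idx = dataset.disease_index, dataset.metabolite_index
    return sorted((d_idx[d], m_idx[m]) for d, m in dataset.pairs)


def _negative_scores(
    Z: np.ndarray, unknown_mask: np.ndarray, balance: int | None, rng: np.random.Generator | None
) -> np.ndarray:
    """Sorted scores of the negative (unknown) candidate pairs."""
    neg = Z.T[unknown_mask]  # Z is metabolite x disease; mask is disease x metabolite
    if balance is not None and balance < neg.size:
        neg = rng.choice(neg, size=balance, replace=False)
    neg.sort()
    return neg


def loocv(
    dataset: AssociationDataset,
    scorer: Callable[[np.ndarray], np.ndarray],
    balance_negatives: bool = False,
    seed: int = 0,
) -> EvalResult:
    """Leave-one-out cross validation over every known association.

    Each known pair is zeroed in turn; the scorer sees the masked matrix
    (similarities recompute from it unless the scorer was frozen) and the
    pair's rank among itself plus all unknown pairs is recorded.  With
    ``balance_negatives`` the candidate negatives are subsampled (seeded)
    to the number of known pairs.
    """
    pairs = _pair_indices(dataset)
    if len(pairs) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    unknown = dataset.M == 0
    rng = np.random.default_rng(seed)
    balance = len(pairs) if balance_negatives else None
    ranks: list[float] = []
    n_cand = None
    for i, j in pairs:
        M_masked = dataset.M.copy()
        M_masked[i, j] = 0.0
        Z = scorer(M_masked)
        neg = _negative_scores(Z, unknown, balance, rng)
        ranks.append(_midrank(float(Z[j, i]), neg))
        n_cand = len(neg) + 1
    roc, auc = roc_auc(ranks, n_cand)
    return EvalResult(
        method=getattr(scorer, "name", "scorer"),
        protocol="loocv",
        folds=[auc],
        auc_mean=auc,
        auc_std=0.0,
        roc=roc,
        ranks=ranks,
        n_candidates=n_cand,
    )


def kfold(
    dataset: AssociationDataset,
    scorer: Callable[[np.ndarray], np.ndarray],
    k_folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    balance_negatives: bool = False,
) -> EvalResult:
    """Repeated k-fold cross validation over the known associations.

    The known pairs are shuffled by a seeded RNG and split into ``k_folds``
    near-equal parts; each part is masked jointly, the scorer rescores from
    the masked matrix, and the fold AUC compares held-out positives against
    all unknown pairs.  Mean and standard deviation are taken across
    folds x repeats.
    """
    pairs = _pair_indices(dataset)
    if k_folds > len(pairs):
        raise ValueError(f"k_folds={k_folds} exceeds the {len(pairs)} known pairs")
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    unknown = dataset.M == 0
    rng = np.random.default_rng(seed)
    balance = len(pairs) if balance_negatives else None
    fold_aucs: list[float] = []
    all_ranks: list[float] = []
    n_cand = None
    for _ in range(repeats):
        order = rng.permutation(len(pairs))
        for part in np.array_split(order, k_folds):
            M_masked = dataset.M.copy()
            for idx in part:
                i, j = pairs[idx]
                M_masked[i, j] = 0.0
            Z = scorer(M_masked)
            neg = _negative_scores(Z, unknown, balance, rng)
            fold_ranks = [_midrank(float(Z[pairs[idx][1], pairs[idx][0]]), neg) for idx in part]
            n_cand = len(neg) + 1
            _, fold_auc = roc_auc(fold_ranks, n_cand)
            fold_aucs.append(fold_auc)
            all_ranks.extend(fold_ranks)
    roc, _ = roc_auc(all_ranks, n_cand)
    fold_arr = np.asarray(fold_aucs)
    return EvalResult(
        method=getattr(scorer, "name", "scorer"),
        protocol=f"{k_folds}fold",
        folds=list(map(float, fold_aucs)),
        auc_mean=float(fold_arr.mean()),
        auc_std=float(fold_arr.std(ddof=1)) if len(fold_arr) > 1 else 0.0,
        roc=roc,
        ranks=all_ranks,
        n_candidates=n_cand,
    )


# ---------------------------------------------------------------------------
# Diffusion baselines
# ---------------------------------------------------------------------------


def _column_stochastic(Mstar: np.ndarray) -> np.ndarray:
    col_sums = Mstar.sum(axis=0)
    if np.any(col_sums <= 0):
        raise ValueError("M* has a non-positive column sum; cannot normalize transitions")
    return Mstar / col_sums


def rwr_score(
    net: HeteroNetwork,
    restart_prob: float = DEFAULT_RESTART,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> ScoreMatrix:
    """Random walk with restart, one stationary vector per seed disease.

    Iterates p <- (1-r) W p + r e on the column-normalized M* until the L1
    change drops below ``tol``; metabolite entries of p are the scores.
    Probability is conserved (each column of the score stack plus the
    disease mass sums to 1).
    """
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart_prob must lie in (0, 1]")
    W = _column_stochastic(net.Mstar)
    n_m, n_d = net.n_metabolites, net.n_diseases
    E = np.zeros((n_m + n_d, n_d))
    E[n_m:, :] = np.eye(n_d)  # seed at each disease node
    P = E.copy()
    for it in range(max_iter):
        P_next = (1.0 - restart_prob) * (W @ P) + restart_prob * E
        resid = np.abs(P_next - P).sum(axis=0).max()
        P = P_next
        if resid < tol:
            break
    else:
        raise RuntimeError(f"RWR did not converge in {max_iter} iterations (residual {resid:.3g})")
    return ScoreMatrix(
        Z=P[:n_m, :],
        params={
            "method": "rwr",
            "restart_prob": restart_prob,
            "iterations": it + 1,
            "column_mass": P.sum(axis=0),
        },
    )


def pagerank_score(
    net: HeteroNetwork,
    damping: float = DEFAULT_DAMPING,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> ScoreMatrix:
    """Personalized PageRank on the M*-weighted graph, one vector per disease.

    Iterates p <- d W p + (1-d) v with v the seed-disease personalization;
    metabolite entries of the fixed point are the scores.
    """
    if not 0.0 <= damping < 1.0:
        raise ValueError("damping must lie in [0, 1)")
    W = _column_stochastic(net.Mstar)
    n_m, n_d = net.n_metabolites, net.n_diseases
    V = np.zeros((n_m + n_d, n_d))
    V[n_m:, :] = np.eye(n_d)
    P = V.copy()
    for it in range(max_iter):
        P_next = damping * (W @ P) + (1.0 - damping) * V
        resid = np.abs(P_next - P).sum(axis=0).max()
        P = P_next
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"PageRank did not converge in {max_iter} iterations (residual {resid:.3g})"
        )
    return ScoreMatrix(
        Z=P[:n_m, :],
        params={
            "method": "pagerank",
            "damping": damping,
            "iterations": it + 1,
            "column_mass": P.sum(axis=0),
        },
    )
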