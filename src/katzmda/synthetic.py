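"""Seeded synthetic datasets with planted cluster structure.

The generator emulates the essential topology a KATZ-style scorer
exploits: diseases and metabolites fall into latent clusters, associations
are dense within a cluster (``within_cluster_assoc_prob``) and sparse
across clusters (``background_assoc_prob``), and same-cluster diseases
share a chain of ancestor terms in their DAGs so their semantic similarity
is high while cross-cluster diseases share only the global root.  Masked
within-cluster pairs are therefore recoverable through 2-step paths via
similar diseases or shared metabolite neighbours.

All draws come from a single seeded ``numpy.random.Generator`` in a fixed
order (association Bernoulli draws row-major over the disease x metabolite
grid, then per-node repair draws), so a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AssociationDataset, DiseaseDAG

__all__ = ["SyntheticConfig", "generate", "generate_dag_pair"]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-cluster bipartite world.

    Defaults describe a small benchmark with strong planted signal:
    30 diseases x 90 metabolites in 3 balanced clusters, within-cluster
    association probability 0.5 against a 0.02 background.
    """

    n_d: int = 30
    n_m: int = 90
    n_clusters: int = 3
    within_cluster_assoc_prob: float = 0.5
    background_assoc_prob: float = 0.02
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("within_cluster_assoc_prob", "background_assoc_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.within_cluster_assoc_prob <= self.background_assoc_prob:
            raise ValueError("within-cluster probability must exceed the background")
        if self.n_clusters > min(self.n_d, self.n_m):
            raise ValueError("more clusters than diseases or metabolites")
        if self.n_clusters < 1 or self.n_d < 1 or self.n_m < 1:
            raise ValueError("n_d, n_m, n_clusters must be positive")


def _cluster_of(index: int, n_items: int, n_clusters: int) -> int:
    # balanced contiguous blocks
    return int(index * n_clusters // n_items)


def _disease_dag(disease: str, cluster: int, depth: int) -> DiseaseDAG:
    """Chain DAG: ROOT -> cluster terms -> disease, shared within a cluster."""
    chain = ["ROOT"] + [f"C{cluster}_L{level}" for level in range(1, depth + 1)] + [disease]
    nodes = set(chain)
    edges = {(chain[i], chain[i + 1]) for i in range(len(chain) - 1)}
    return DiseaseDAG(disease, nodes, edges)


def generate(
    config: SyntheticConfig | None = None,
) -> tuple[AssociationDataset, dict[str, DiseaseDAG], set[tuple[str, str]]]:
    """Generate (dataset, DAGs, truth) under the planted-cluster model.

    ``truth`` is the set of within-cluster pairs that the Bernoulli draws
    left out of the dataset: the plantable positives a good scorer should
    rank highly when evaluated on them.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    diseases = [f"d{i:03d}" for i in range(cfg.n_d)]
    metabolites = [f"m{j:03d}" for j in range(cfg.n_m)]
    d_cluster = np.array([_cluster_of(i, cfg.n_d, cfg.n_clusters) for i in range(cfg.n_d)])
    m_cluster = np.array([_cluster_of(j, cfg.n_m, cfg.n_clusters) for j in range(cfg.n_m)])

    same = d_cluster[:, None] == m_cluster[None, :]
    prob = np.where(same, cfg.within_cluster_assoc_prob, cfg.background_assoc_prob)
    M = (rng.random((cfg.n_d, cfg.n_m)) < prob).astype(float)

    # repair: every node must carry at least one association; attach lonely
    # nodes to a random same-cluster partner
    for i in range(cfg.n_d):
        if M[i].sum() == 0:
            candidates = np.flatnonzero(m_cluster == d_cluster[i])
            M[i, rng.choice(candidates)] = 1.0
    for j in range(cfg.n_m):
        if M[:, j].sum() == 0:
            candidates = np.flatnonzero(d_cluster == m_cluster[j])
            M[rng.choice(candidates), j] = 1.0

    pairs = {
        (diseases[i], metabolites[j])
        for i, j in zip(*np.nonzero(M))
    }
    if not pairs:
        raise ValueError("synthetic configuration produced an empty pair set")
    dataset = AssociationDataset.from_pairs(
        sorted(pairs, key=lambda p: (diseases.index(p[0]), metabolites.index(p[1])))
    )
    dags = {d: _disease_dag(d, int(d_cluster[i]), cfg.dag_depth) for i, d in enumerate(diseases)}
    truth = {
        (diseases[i], metabolites[j])
        for i in range(cfg.n_d)
        for j in range(cfg.n_m)
        if same[i, j] and M[i, j] == 0
    }
    return dataset, dags, truth


def generate_dag_pair(
    shared_depth: int, private_depth: int, delta: float = 0.5
) -> tuple[DiseaseDAG, DiseaseDAG, float]:
    """Two chain DAGs with a shared ancestor prefix, plus their exact similarity.

    The shared prefix has ``shared_depth`` terms; below it each disease hangs
    on a private chain of ``private_depth`` terms ending at the disease
    itself (``private_depth == 0`` makes both DAGs identical, similarity 1;
    ``shared_depth == 0`` makes them fully disjoint, similarity 0).  The
    expected similarity comes from the closed-form geometric sums of decay
    powers, independent of the recursive implementation.
    """
    if shared_depth < 0 or private_depth < 0:
        raise ValueError("depths must be nonnegative")
    if shared_depth == 0 and private_depth == 0:
        raise ValueError("at least one of shared_depth, private_depth must be positive")
    shared = [f"S{i}" for i in range(1, shared_depth + 1)]

    def chain_dag(label: str) -> DiseaseDAG:
        if private_depth == 0:
            chain = shared[:]  # disease IS the last shared term
        else:
            chain = shared + [f"{label}_P{i}" for i in range(1, private_depth)] + [label]
        nodes = set(chain)
        edges = {(chain[i], chain[i + 1]) for i in range(len(chain) - 1)}
        return DiseaseDAG(chain[-1], nodes, edges)

    dag1, dag2 = chain_dag("D1"), chain_dag("D2")
    # contributions along a chain of length L above the disease: delta^depth
    if private_depth == 0:
        expected = 1.0
    else:
        # per disease: self + private ancestors + shared ancestors
        dv = sum(delta**p for p in range(private_depth + shared_depth))
        shared_sum = sum(delta ** (private_depth + s) for s in range(shared_depth))
        expected = (2.0 * shared_sum) / (2.0 * dv) if shared_depth else 0.0
    return dag1, dag2, expected
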