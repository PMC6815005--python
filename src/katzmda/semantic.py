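"""Disease semantic similarity from MeSH-style disease DAGs.

Each disease D carries a DAG of ancestor terms.  The semantic contribution
of a term d to D decays with distance from D:

    D_D(D) = 1
    D_D(d) = max{ delta * D_D(d') : d' a child of d within T(D) },  d != D

with decay factor ``delta`` in (0, 1).  The semantic value DV(D) is the sum
of contributions over T(D), and the pairwise similarity of diseases i and j
is the Wang-style ratio

    DSS(i, j) = sum_{t in T(i) ∩ T(j)} (D_i(t) + D_j(t)) / (DV(i) + DV(j)).

DSS is symmetric, lies in [0, 1], and equals 1 on the diagonal.  Diseases
with no DAG on file get an all-zero row/column (diagonal included) so the
downstream similarity integration falls back to the GIP kernel for them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import DiseaseDAG

logger = logging.getLogger("katzmda")

__all__ = [
    "SemanticContribution",
    "semantic_contributions",
    "semantic_similarity",
    "semantic_similarity_matrix",
    "DEFAULT_DELTA",
]

#: Decay factor for ancestor contributions; the convention of the Wang
#: semantic-similarity lineage.
DEFAULT_DELTA = 0.5


@dataclass
class SemanticContribution:
    """Per-term contributions D_D(d) and the semantic value DV(D) of one disease."""

    disease_id: str
    contrib: dict[str, float]
    dv: float


def semantic_contributions(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> SemanticContribution:
    """Compute D_D(d) for every term in T(D) by memoized recursion.

    Terms in the DAG that are not ancestors of the disease (no directed path
    down to D) contribute nothing; they are dropped with a warning.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    root = dag.disease_id
    # T(D): root plus every node with a directed path to it
    ancestors = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for p in dag.parents(node):
            if p not in ancestors:
                ancestors.add(p)
                frontier.append(p)
    dropped = dag.nodes - ancestors
    if dropped:
        warnings.warn(
            f"DAG for {root!r}: {len(dropped)} term(s) unreachable from the "
            f"disease excluded from T(D): {sorted(dropped)}"
        )

    contrib: dict[str, float] = {}

    def value(term: str) -> float:
        if term in contrib:
            return contrib[term]
        if term == root:
            v = 1.0
        else:
            kids = [c for c in dag.children(term) if c in ancestors]
            v = delta * max(value(c) for c in kids)
        contrib[term] = v
        return v

    for term in ancestors:
        value(term)
    return SemanticContribution(root, contrib, float(sum(contrib.values())))


def semantic_similarity(sc_i: SemanticContribution, sc_j: SemanticContribution) -> float:
    """Pairwise Wang semantic similarity of two diseases (same delta assumed)."""
    shared = sc_i.contrib.keys() & sc_j.contrib.keys()
    if not shared:
        return 0.0
    num = sum(sc_i.contrib[t] + sc_j.contrib[t] for t in shared)
    return num / (sc_i.dv + sc_j.dv)


def semantic_similarity_matrix(
    dags: Mapping[str, DiseaseDAG],
    disease_ids: Sequence[str],
    delta: float = DEFAULT_DELTA,
) -> np.ndarray:
    """Assemble the n_d x n_d DSS matrix over ``disease_ids``.

    Diseases missing from ``dags`` get all-zero rows and columns (their
    diagonal too), which flags them for the GIP fallback branch during
    similarity integration.
    """
    n = len(disease_ids)
    missing = [d for d in disease_ids if d not in dags]
    if missing:
        logger.warning("no DAG for %d disease(s); DSS rows zeroed: %s", len(missing), missing[:5])
    scs = {d: semantic_contributions(dags[d], delta) for d in disease_ids if d in dags}
    dss = np.zeros((n, n))
    for i, di in enumerate(disease_ids):
        if di not in scs:
            continue
        for j in range(i, n):
            dj = disease_ids[j]
            if dj not in scs:
                continue
            dss[i, j] = dss[j, i] = semantic_similarity(scs[di], scs[dj])
    return dss
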