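"""Association tables, disease DAGs, and the bipartite adjacency matrix.

The prediction pipeline starts from a two-column table of known
disease-metabolite associations and, per disease, a directed acyclic graph
(DAG) of ancestor terms in the style of a MeSH disease tree.  This module
reads and writes both formats and materializes the 0/1 adjacency matrix
``M`` (diseases x metabolites) that every similarity and scoring step
consumes.

Node universes are taken from the association file itself: a disease or
metabolite with zero associations is not representable, mirroring a network
built only from curated positive pairs.  Identifiers are compared
case-sensitively after stripping surrounding whitespace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("katzmda")

__all__ = [
    "AssociationDataset",
    "DiseaseDAG",
    "load_associations",
    "write_associations",
    "load_dags",
    "write_dags",
    "adjacency",
    "toy_association_path",
    "toy_dag_path",
]


class DataError(ValueError):
    """Raised for malformed association tables or DAG files."""


@dataclass
class AssociationDataset:
    """A bipartite set of disease-metabolite associations.

    Attributes
    ----------
    disease_ids : list of str
        Unique disease identifiers in first-appearance order.
    metabolite_ids : list of str
        Unique metabolite identifiers in first-appearance order.
    pairs : set of (str, str)
        Known ``(disease_id, metabolite_id)`` associations, deduplicated.
    M : ndarray of shape (n_diseases, n_metabolites)
        0/1 adjacency matrix; ``M[i, j] == 1`` iff the pair is known.
    """

    disease_ids: list[str]
    metabolite_ids: list[str]
    pairs: set[tuple[str, str]]
    M: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise DataError("association dataset must contain at least one pair")
        if self.M.shape != (len(self.disease_ids), len(self.metabolite_ids)):
            raise DataError(
                f"adjacency shape {self.M.shape} inconsistent with "
                f"{len(self.disease_ids)} diseases x {len(self.metabolite_ids)} metabolites"
            )
        if int(self.M.sum()) != len(self.pairs):
            raise DataError("adjacency entries do not match the pair set")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def disease_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.disease_ids)}

    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.metabolite_ids)}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationDataset":
        """Build a dataset from an iterable of (disease, metabolite) pairs.

        Row/column ordering follows first appearance; duplicates collapse.
        """
        disease_ids: list[str] = []
        metabolite_ids: list[str] = []
        d_idx: dict[str, int] = {}
        m_idx: dict[str, int] = {}
        pair_set: set[tuple[str, str]] = set()
        ordered: list[tuple[str, str]] = []
        for d, m in pairs:
            d, m = d.strip(), m.strip()
            if (d, m) in pair_set:
                continue
            pair_set.add((d, m))
            ordered.append((d, m))
            if d not in d_idx:
                d_idx[d] = len(disease_ids)
                disease_ids.append(d)
            if m not in m_idx:
                m_idx[m] = len(metabolite_ids)
                metabolite_ids.append(m)
        if not pair_set:
            raise DataError("no association pairs provided")
        M = np.zeros((len(disease_ids), len(metabolite_ids)))
        for d, m in ordered:
            M[d_idx[d], m_idx[m]] = 1.0
        return cls(disease_ids, metabolite_ids, pair_set, M)


@dataclass
class DiseaseDAG:
    """The DAG of a disease plus all its ancestor terms.

    ``nodes`` is the term set T(D) (the disease itself and its ancestors);
    ``edges`` are (parent, child) pairs pointing from the more general to the
    more specific term.  The graph must be acyclic.
    """

    disease_id: str
    nodes: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise DataError(
                    f"DAG for {self.disease_id!r}: edge ({p!r}, {c!r}) "
                    "references a term outside the node set"
                )
        if self.disease_id not in self.nodes:
            raise DataError(f"DAG for {self.disease_id!r} does not contain the disease itself")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise DataError(f"cycle detected in DAG for disease {self.disease_id!r}")

    def children(self, term: str) -> set[str]:
        return {c for p, c in self.edges if p == term}

    def parents(self, term: str) -> set[str]:
        return {p for p, c in self.edges if c == term}


def _read_table(path: str | Path, dialect: str, n_cols: int, header: bool) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise DataError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    df = pd.read_csv(
        path, sep=sep, header=0 if header else None, dtype=str,
        skip_blank_lines=True, comment="#",
    )
    if df.empty:
        raise DataError(f"{path}: file contains no data rows")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad) and df.shape[1] >= n_cols:
        line0 = int(bad[0]) + (2 if header else 1)
        raise DataError(f"{path}: malformed row at line {line0} (expected {n_cols} fields)")
    if df.shape[1] < n_cols:
        raise DataError(f"{path}: expected at least {n_cols} columns, found {df.shape[1]}")
    return df.iloc[:, :n_cols]


def load_associations(
    path: str | Path, dialect: str = "csv", header: bool = True
) -> AssociationDataset:
    """Read a two-column (disease_id, metabolite_id) association table.

    Duplicate rows are collapsed with a logged warning; row and column
    ordering of the adjacency matrix follows first appearance in the file.
    """
    df = _read_table(path, dialect, 2, header)
    raw = [(str(a).strip(), str(b).strip()) for a, b in df.itertuples(index=False)]
    n_dup = len(raw) - len(set(raw))
    if n_dup:
        warnings.warn(f"{path}: {n_dup} duplicate association row(s) collapsed")
        logger.warning("%s: %d duplicate association row(s) collapsed", path, n_dup)
    return AssociationDataset.from_pairs(raw)


def write_associations(dataset: AssociationDataset, path: str | Path, dialect: str = "csv") -> None:
    """Write the pair set as a two-column table (header included)."""
    sep = "," if dialect == "csv" else "\t"
    idx_d, idx_m = dataset.disease_index, dataset.metabolite_index
    rows = sorted(dataset.pairs, key=lambda p: (idx_d[p[0]], idx_m[p[1]]))
    pd.DataFrame(rows, columns=["disease_id", "metabolite_id"]).to_csv(
        path, sep=sep, index=False
    )


def load_dags(path: str | Path, dialect: str = "csv", header: bool = True) -> dict[str, DiseaseDAG]:
    """Read per-disease DAGs from an edge-list table.

    Rows are ``(disease_id, parent_term, child_term)``.  A row with
    ``parent_term == child_term`` (or an empty parent) declares a node with
    no incident edge, so a single-node DAG is one row ``d,d,d``.  A cycle in
    any disease's edge set raises an error naming the disease.
    """
    df = _read_table(path, dialect, 3, header)
    nodes: dict[str, set[str]] = {}
    edges: dict[str, set[tuple[str, str]]] = {}
    for d, p, c in df.itertuples(index=False):
        d = str(d).strip()
        p = "" if pd.isna(p) else str(p).strip()
        c = "" if pd.isna(c) else str(c).strip()
        nodes.setdefault(d, set()).add(d)
        edges.setdefault(d, set())
        if not c:
            c = d
        if p and p != c:
            nodes[d].update((p, c))
            edges[d].add((p, c))
        else:
            nodes[d].add(c)
    return {d: DiseaseDAG(d, nodes[d], edges[d]) for d in nodes}


def write_dags(dags: Mapping[str, DiseaseDAG], path: str | Path, dialect: str = "csv") -> None:
    """Write DAGs in the edge-list dialect `load_dags` reads."""
    sep = "," if dialect == "csv" else "\t"
    rows: list[tuple[str, str, str]] = []
    for d in sorted(dags):
        dag = dags[d]
        if dag.edges:
            rows.extend((d, p, c) for p, c in sorted(dag.edges))
        else:
            rows.append((d, d, d))
        # nodes untouched by any edge still need a declaring row
        touched = {t for e in dag.edges for t in e}
        for orphan in sorted(dag.nodes - touched - {d} if dag.edges else set()):
            rows.append((d, orphan, orphan))
    pd.DataFrame(rows, columns=["disease_id", "parent_term", "child_term"]).to_csv(
        path, sep=sep, index=False
    )


def adjacency(dataset: AssociationDataset) -> np.ndarray:
    """Return the 0/1 adjacency matrix M (diseases x metabolites).

    The sum of entries equals the number of known pairs.
    """
    return dataset.M.copy()


def toy_association_path() -> Path:
    """Path to the bundled toy association table (20 diseases x 60 metabolites, 150 pairs)."""
    return Path(str(resources.files("katzmda") / "fixtures" / "toy_associations.csv"))


def toy_dag_path() -> Path:
    """Path to the bundled toy DAG edge list matching the toy associations."""
    return Path(str(resources.files("katzmda") / "fixtures" / "toy_dags.csv"))
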