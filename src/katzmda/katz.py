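"""Heterogeneous network assembly and KATZ association scoring.

Metabolite similarity SM, disease similarity SD and the bipartite adjacency
matrix are stacked into one symmetric block matrix

    M* = [[SM,   M'],
          [M'^T, SD]]

with M' oriented metabolite-rows x disease-columns.  The KATZ score of a
metabolite-disease pair is the path-count sum over all connecting walks,
weight delta^l for a walk of length l: the metabolite x disease block of
sum_{l=1..k} delta^l M*^l (truncated, k in {2,3,4}) or of
(I - delta M*)^-1 - I (closed form, convergent when delta < 1/rho(M*)).

For k = 2 the truncated score expands to delta*M' + delta^2*(SM M' + M' SD);
higher orders are computed from explicit matrix powers, whose block
expansions pick up the path-type terms (M' M'^T M', SM^2 M', ...) exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.linalg

from .data import AssociationDataset

logger = logging.getLogger("katzmda")

__all__ = [
    "HeteroNetwork",
    "ScoreMatrix",
    "DeltaBound",
    "build_hetero",
    "katz_truncated",
    "katz_closed",
    "delta_bound",
    "rank_candidates",
    "DEFAULT_DELTA_KATZ",
    "DEFAULT_K",
]

DEFAULT_DELTA_KATZ = 0.1
DEFAULT_K = 2
_SYM_TOL = 1e-8


@dataclass
class HeteroNetwork:
    """Similarity blocks and their assembly into the block matrix M*."""

    SM: np.ndarray = field(repr=False)  # n_m x n_m
    SD: np.ndarray = field(repr=False)  # n_d x n_d
    M_md: np.ndarray = field(repr=False)  # n_m x n_d, metabolite rows
    Mstar: np.ndarray = field(repr=False)

    @property
    def n_metabolites(self) -> int:
        return self.SM.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.SD.shape[0]


@dataclass
class ScoreMatrix:
    """KATZ scores Z (metabolite x disease) plus the parameters that produced them."""

    Z: np.ndarray = field(repr=False)
    params: dict


class DeltaBound(NamedTuple):
    """Safe KATZ attenuation bound 1/rho(M*) and the literal 1/||M||_2^2 reference."""

    spectral: float
    paper_norm: float


def build_hetero(SM: np.ndarray, SD: np.ndarray, M: np.ndarray) -> HeteroNetwork:
    """Assemble M* from similarity blocks and the disease x metabolite adjacency.

    ``M`` follows the data module's disease-rows convention and is transposed
    here so the metabolite block comes first.
    """
    SM, SD, M = (np.asarray(x, dtype=float) for x in (SM, SD, M))
    n_d, n_m = M.shape
    if n_m == 0 or n_d == 0:
        raise ValueError("empty node set: need at least one metabolite and one disease")
    if SM.shape != (n_m, n_m) or SD.shape != (n_d, n_d):
        raise ValueError(
            f"block shapes inconsistent: SM {SM.shape}, SD {SD.shape}, M {M.shape}"
        )
    for name, S in (("SM", SM), ("SD", SD)):
        if np.abs(S - S.T).max() > _SYM_TOL:
            raise ValueError(f"{name} is not symmetric within {_SYM_TOL}")
    M_md = M.T
    Mstar = np.block([[SM, M_md], [M_md.T, SD]])
    return HeteroNetwork(SM=SM, SD=SD, M_md=M_md, Mstar=Mstar)


def katz_truncated(
    net: HeteroNetwork, delta: float = DEFAULT_DELTA_KATZ, k: int = DEFAULT_K
) -> ScoreMatrix:
    """Truncated KATZ score: metabolite x disease block of sum_{l<=k} delta^l M*^l."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    if k not in (2, 3, 4):
        raise ValueError(f"k must be one of 2, 3, 4; got {k}")
    n_m = net.n_metabolites
    power = np.eye(net.Mstar.shape[0])
    total = np.zeros_like(net.Mstar)
    for l in range(1, k + 1):
        power = power @ net.Mstar
        total += delta**l * power
    Z = total[:n_m, n_m:]
    return ScoreMatrix(Z=Z, params={"method": "katz_truncated", "delta": delta, "k": k})


def katz_closed(net: HeteroNetwork, delta: float = DEFAULT_DELTA_KATZ) -> ScoreMatrix:
    """Closed-form KATZ score: metabolite x disease block of (I - delta M*)^-1 - I.

    Requires delta * rho(M*) < 1 (rho the spectral radius); equals the
    k -> infinity limit of the truncated series.  A warning is issued when
    delta also exceeds the looser literal bound 1/||M||_2^2.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    bound = delta_bound(net)
    rho = 1.0 / bound.spectral
    if delta * rho >= 1.0:
        raise ValueError(
            f"series divergent: delta={delta} >= 1/rho(M*)={bound.spectral:.6g}"
        )
    if delta >= bound.paper_norm:
        warnings.warn(
            f"delta={delta} exceeds the literal 1/||M||^2 bound {bound.paper_norm:.6g} "
            "(closed form still convergent by the spectral criterion)"
        )
    n = net.Mstar.shape[0]
    n_m = net.n_metabolites
    # (I - delta M*)^-1 - I via a linear solve, not an explicit inverse
    resolvent = scipy.linalg.solve(np.eye(n) - delta * net.Mstar, np.eye(n), assume_a="sym")
    Z = (resolvent - np.eye(n))[:n_m, n_m:]
    return ScoreMatrix(Z=Z, params={"method": "katz_closed", "delta": delta})


def delta_bound(net: HeteroNetwork) -> DeltaBound:
    """Convergence bounds for the KATZ attenuation factor.

    ``spectral`` is 1/rho(M*), the exact convergence threshold of the series.
    ``paper_norm`` is the literal 1/||M||_2^2 computed on the bipartite
    adjacency, reported for reference since the prescription leaves the norm
    and matrix ambiguous.
    """
    rho = float(np.abs(scipy.linalg.eigvalsh(net.Mstar)).max())
    spectral = np.inf if rho == 0.0 else 1.0 / rho
    sigma = float(np.linalg.norm(net.M_md, 2))
    paper = np.inf if sigma == 0.0 else 1.0 / sigma**2
    logger.info("delta bounds: spectral %.6g, literal 1/||M||^2 %.6g", spectral, paper)
    return DeltaBound(spectral=spectral, paper_norm=paper)


def rank_candidates(
    scores: ScoreMatrix, dataset: AssociationDataset, disease_id: str, top: int | None = None
) -> list[tuple[str, float]]:
    """Rank candidate metabolites for one disease by descending KATZ score.

    Metabolites already associated with the disease are excluded; ties break
    lexicographically on the metabolite id (stable and deterministic).
    """
    d_idx = dataset.disease_index
    if disease_id not in d_idx:
        raise KeyError(f"unknown disease id {disease_id!r}")
    j = d_idx[disease_id]
    known = {m for d, m in dataset.pairs if d == disease_id}
    col = scores.Z[:, j]
    ranked = sorted(
        ((m, float(col[i])) for i, m in enumerate(dataset.metabolite_ids) if m not in known),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:top] if top is not None else ranked
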