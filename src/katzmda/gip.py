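"""Gaussian interaction profile (GIP) kernel similarities and disease-similarity integration.

The interaction profile IP(u) of a node is its 0/1 row (disease) or column
(metabolite) of the association matrix.  The GIP kernel is the RBF kernel on
profiles,

    K(u, v) = exp(-omega * ||IP(u) - IP(v)||^2),

with bandwidth normalized by the mean squared profile norm:
omega = omega' / mean_u ||IP(u)||^2, omega' = 1 by convention.

Disease GIP similarity is additionally sharpened through a logistic map
GDL = 1 / (1 + exp(a*GD + b)) with a = -15, b = log(9999), so that a raw
similarity of 0 maps to 1e-4 and of 1 to ~0.997.  The integrated disease
similarity combines semantic similarity DSS with the GIP-derived matrix:
where DSS is zero (no DAG information) it falls back to GDL outright,
elsewhere it is the convex-style blend (1-gamma)*DSS + gamma*G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GipParams",
    "gip_kernel",
    "logistic_transform",
    "integrate_disease_similarity",
    "DEFAULT_OMEGA_PRIME",
    "DEFAULT_A",
    "DEFAULT_B",
    "DEFAULT_GAMMA",
]

DEFAULT_OMEGA_PRIME = 1.0
DEFAULT_A = -15.0
DEFAULT_B = float(np.log(9999.0))
DEFAULT_GAMMA = 0.1


@dataclass
class GipParams:
    """Tunable parameters of the GIP similarity stage."""

    omega_prime: float = DEFAULT_OMEGA_PRIME
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.omega_prime <= 0:
            raise ValueError("omega_prime must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


def gip_kernel(M: np.ndarray, axis: str, omega_prime: float = DEFAULT_OMEGA_PRIME) -> np.ndarray:
    """GIP kernel over rows (axis='disease') or columns (axis='metabolite') of M.

    Returns a symmetric matrix with exact unit diagonal.  Raises on an
    all-zero M, where the bandwidth normalizer is undefined.
    """
    M = np.asarray(M, dtype=float)
    if axis == "disease":
        profiles = M
    elif axis == "metabolite":
        profiles = M.T
    else:
        raise ValueError(f"axis must be 'disease' or 'metabolite', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise ValueError("all-zero association matrix: GIP bandwidth undefined")
    omega = omega_prime / mean_sq
    # ||u - v||^2 = ||u||^2 + ||v||^2 - 2 u.v, clipped against rounding
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.clip(d2, 0.0, None, out=d2)
    K = np.exp(-omega * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


def logistic_transform(GD: np.ndarray, a: float = DEFAULT_A, b: float = DEFAULT_B) -> np.ndarray:
    """Elementwise logistic sharpening 1 / (1 + exp(a*GD + b)).

    Strictly increasing in GD for a < 0; symmetric inputs stay symmetric.
    The exponent is clipped to avoid overflow for extreme arguments.
    """
    z = np.clip(a * np.asarray(GD, dtype=float) + b, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def integrate_disease_similarity(
    DSS: np.ndarray,
    GDL: np.ndarray,
    GD: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    kernel: str = "gdl",
) -> np.ndarray:
    """Combine semantic and GIP disease similarities into SD.

    Where DSS(i, j) == 0 the entry is GDL(i, j); elsewhere it is
    (1 - gamma)*DSS + gamma*G, where G is GDL (default) or the raw GD when
    ``kernel='gd'``.
    """
    DSS, GDL, GD = (np.asarray(x, dtype=float) for x in (DSS, GDL, GD))
    if not (DSS.shape == GDL.shape == GD.shape) or DSS.shape[0] != DSS.shape[1]:
        raise ValueError(
            f"shape mismatch: DSS {DSS.shape}, GDL {GDL.shape}, GD {GD.shape}"
        )
    if kernel == "gdl":
        G = GDL
    elif kernel == "gd":
        G = GD
    else:
        raise ValueError(f"kernel must be 'gdl' or 'gd', got {kernel!r}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    blended = (1.0 - gamma) * DSS + gamma * G
    return np.where(DSS == 0.0, GDL, blended)
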