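"""Information-flow propagation over the bi-layer networks.

Each matrix of the heterogeneous network is blended with its two-hop
counterpart, weighted by a hyperparameter ``gamma`` in [0, 1]:

    within a layer     X' = g*X + g^2 * (X @ X)
    across two layers  X' = g*X + g^2 * (S_left @ X + X @ S_right)

where ``S_left``/``S_right`` are the similarity matrices of the row and
column entity types.  The one-hop term keeps the original edge, the
g^2-weighted products add paths through one intermediate node.  No
normalization is applied, so propagated values are not confined to [0, 1];
downstream consumers must not assume it.

The six propagated matrices (L', D', A', (A^T)', B', (C^T)') feed the
topological feature matrix of each lncRNA-disease pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import HeterogeneousNetwork

__all__ = [
    "PropagationConfig",
    "PropagatedNetwork",
    "propagate_intra",
    "propagate_bipartite",
    "propagate_network",
]

DEFAULT_GAMMA = 0.2


@dataclass(frozen=True)
class PropagationConfig:
    """Propagation hyperparameters; ``gamma`` balances one-hop vs two-hop."""

    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class PropagatedNetwork:
    """The six propagated matrices and the gamma they were computed with."""

    Lp: np.ndarray   # lncRNA-lncRNA
    Dp: np.ndarray   # disease-disease
    Ap: np.ndarray   # lncRNA-disease
    ATp: np.ndarray  # disease-lncRNA (transpose of Ap for symmetric L, D)
    Bp: np.ndarray   # lncRNA-miRNA
    CTp: np.ndarray  # disease-miRNA
    gamma: float


def propagate_intra(X: np.ndarray, gamma: float) -> np.ndarray:
    """g*X + g^2*(X @ X) for a square within-layer matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {X.shape}")
    return gamma * X + gamma**2 * (X @ X)


def propagate_bipartite(X: np.ndarray, left_sim: np.ndarray, right_sim: np.ndarray, gamma: float) -> np.ndarray:
    """g*X + g^2*(left_sim @ X + X @ right_sim) for a cross-layer matrix."""
    X = np.asarray(X, dtype=float)
    left_sim = np.asarray(left_sim, dtype=float)
    right_sim = np.asarray(right_sim, dtype=float)
    p, q = X.shape
    if left_sim.shape != (p, p):
        raise ValueError(f"left_sim shape {left_sim.shape} does not match rows {p}")
    if right_sim.shape != (q, q):
        raise ValueError(f"right_sim shape {right_sim.shape} does not match columns {q}")
    return gamma * X + gamma**2 * (left_sim @ X + X @ right_sim)


def propagate_network(net: HeterogeneousNetwork, cfg: PropagationConfig | None = None) -> PropagatedNetwork:
    """Compute all six propagated matrices of a heterogeneous network."""
    cfg = cfg or PropagationConfig()
    g = cfg.gamma
    return PropagatedNetwork(
        Lp=propagate_intra(net.L, g),
        Dp=propagate_intra(net.D, g),
        Ap=propagate_bipartite(net.A, net.L, net.D, g),
        ATp=propagate_bipartite(net.A.T, net.D, net.L, g),
        Bp=propagate_bipartite(net.B, net.L, net.M, g),
        CTp=propagate_bipartite(net.C.T, net.D, net.M, g),
        gamma=g,
    )
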