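"""Per-pair feature matrices for the dual-channel scorer.

Each lncRNA-disease pair (i, j) is described by two 2 x (nl+nd+nm)
matrices sharing one column-block layout [lncRNA | disease | miRNA]:

* the raw feature matrix S, read straight off the source network —
  row 1 = [L[i, :] | A[i, :] | B[i, :]]   (the lncRNA's view),
  row 2 = [A[:, j]^T | D[j, :] | C[:, j]^T]  (the disease's view);
* the topological matrix T with the same layout read off the propagated
  network — row 1 = [L'[i, :] | A'[i, :] | B'[i, :]],
  row 2 = [(A^T)'[j, :] | D'[j, :] | (C^T)'[j, :]].

Column k refers to the same entity in both rows and both matrices, so a
2 x 2 convolution window sees the lncRNA-side and disease-side evidence
about the same (pair of) entities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import HeterogeneousNetwork
from .propagation import PropagatedNetwork

__all__ = [
    "PairFeature",
    "LabeledPairSet",
    "build_left_feature",
    "build_right_feature",
    "build_pair_set",
    "batch_features",
]


@dataclass(frozen=True)
class PairFeature:
    S: np.ndarray  # 2 x (nl+nd+nm) raw features
    T: np.ndarray  # 2 x (nl+nd+nm) propagated features
    lnc_index: int
    disease_index: int


@dataclass(frozen=True)
class LabeledPairSet:
    """Deduplicated labeled pairs plus their materialized feature batches."""

    pairs: list[tuple[int, int]]
    labels: np.ndarray           # (n,) in {0, 1}
    S: np.ndarray                # (n, 2, W)
    T: np.ndarray                # (n, 2, W)

    def __len__(self) -> int:
        return len(self.pairs)


def _check_indices(net: HeterogeneousNetwork, i: int, j: int) -> None:
    if not 0 <= i < net.nl:
        raise IndexError(f"lncRNA index {i} out of range [0, {net.nl})")
    if not 0 <= j < net.nd:
        raise IndexError(f"disease index {j} out of range [0, {net.nd})")


def build_left_feature(net: HeterogeneousNetwork, i: int, j: int) -> np.ndarray:
    """Raw 2 x (nl+nd+nm) feature matrix S of pair (i, j)."""
    _check_indices(net, i, j)
    row1 = np.concatenate([net.L[i, :], net.A[i, :], net.B[i, :]])
    row2 = np.concatenate([net.A[:, j], net.D[j, :], net.C[:, j]])
    return np.stack([row1, row2])


def build_right_feature(propnet: PropagatedNetwork, i: int, j: int) -> np.ndarray:
    """Propagated 2 x (nl+nd+nm) feature matrix T of pair (i, j)."""
    row1 = np.concatenate([propnet.Lp[i, :], propnet.Ap[i, :], propnet.Bp[i, :]])
    row2 = np.concatenate([propnet.ATp[j, :], propnet.Dp[j, :], propnet.CTp[j, :]])
    return np.stack([row1, row2])


def batch_features(
    net: HeterogeneousNetwork,
    propnet: PropagatedNetwork,
    pairs: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized S and T batches of shape (n_pairs, 2, nl+nd+nm).

    Row 1 depends only on the lncRNA and row 2 only on the disease, so the
    per-entity rows are precomputed once and gathered per pair.
    """
    lnc_rows_S = np.concatenate([net.L, net.A, net.B], axis=1)
    dis_rows_S = np.concatenate([net.A.T, net.D, net.C.T], axis=1)
    lnc_rows_T = np.concatenate([propnet.Lp, propnet.Ap, propnet.Bp], axis=1)
    dis_rows_T = np.concatenate([propnet.ATp, propnet.Dp, propnet.CTp], axis=1)
    idx_l = np.asarray([p[0] for p in pairs], dtype=int)
    idx_d = np.asarray([p[1] for p in pairs], dtype=int)
    S = np.stack([lnc_rows_S[idx_l], dis_rows_S[idx_d]], axis=1)
    T = np.stack([lnc_rows_T[idx_l], dis_rows_T[idx_d]], axis=1)
    return S, T


def build_pair_set(
    net: HeterogeneousNetwork,
    propnet: PropagatedNetwork,
    pairs: Sequence[tuple[int, int]],
    labels: Sequence[int],
) -> LabeledPairSet:
    """Materialize a labeled batch of pair features in deterministic order."""
    pairs = [tuple(p) for p in pairs]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate pairs in pair set")
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(pairs),) or not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be one binary label per pair")
    for i, j in pairs:
        _check_indices(net, i, j)
    S, T = batch_features(net, propnet, pairs)
    return LabeledPairSet(pairs=pairs, labels=labels, S=S, T=T)
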