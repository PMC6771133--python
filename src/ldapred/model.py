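"""Dual-channel convolutional scorer for lncRNA-disease pairs.

Each channel consumes one of the two 2 x W pair matrices (raw features S
on the left, propagated topology T on the right) and applies

    zero-pad(1) -> 2x2 conv (nconv1/nconv3 maps, ReLU)
    -> 2x2 max pool (stride 2)
    -> zero-pad(1) -> 2x2 conv (nconv2/nconv4 maps, ReLU)
    -> 2x2 max pool -> flatten -> dense to 2 raw scores.

The "wide" convolutions pad one row/column of zeros on every side so the
2x2 filters also cover boundary columns.  With a 2-row input the first
pool collapses the height to 1; the second conv then works on the padded
3-row map.  Pool windows that do not fit (odd widths) are truncated.

Per channel, a softmax over the 2-vector of raw scores gives the
associated-class probability and a cross-entropy loss.  The channels are
trained jointly on the summed loss l1 + l2 with one Adam optimizer; the
fusion weight lambda enters only at inference:

    fused = lambda * p_left + (1 - lambda) * p_right.

The implementation is pure NumPy with analytic gradients, which keeps the
forward/backward passes exactly reproducible and directly checkable
against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import HeterogeneousNetwork
from .features import LabeledPairSet, batch_features
from .propagation import PropagatedNetwork

__all__ = [
    "ModelConfig",
    "DualCNNModel",
    "PairScore",
    "channel_forward",
    "fuse_scores",
    "loss",
    "train",
    "predict_pairs",
    "predict_disease",
]

_EPS = 1e-12
# class layout of the 2-vector of raw scores: index 1 = associated
_POS = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``nconv1``/``nconv2`` are the filter counts of the left channel's two
    convolutions, ``nconv3``/``nconv4`` those of the right channel.  The
    2x2 filter and pool sizes are shared by both channels, as is the joint
    Adam optimizer.  ``lambda_weight`` is the inference-time fusion weight
    of the left channel's probability.  ``neg_ratio`` is the number of
    negatives sampled per positive in each training epoch.
    """

    filter_height: int = 2
    filter_width: int = 2
    nconv1: int = 8
    nconv2: int = 16
    nconv3: int = 8
    nconv4: int = 16
    pool_size: int = 2
    pool_stride: int = 2
    lambda_weight: float = 0.7
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    neg_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must be in [0, 1]")
        for name in ("nconv1", "nconv2", "nconv3", "nconv4", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (self.filter_height, self.filter_width) != (2, 2) or (self.pool_size, self.pool_stride) != (2, 2):
            raise NotImplementedError("only 2x2 filters with 2x2/stride-2 pooling are supported")


@dataclass(frozen=True)
class PairScore:
    score1: np.ndarray  # left-channel raw 2-vector
    score2: np.ndarray  # right-channel raw 2-vector
    fused: float        # lambda-weighted associated-class probability


# ---------------------------------------------------------------------------
# primitive layers (batched, with caches for backprop)

def _pad1(X: np.ndarray) -> np.ndarray:
    """Zero-pad 1 on both spatial dims of an (N, C, H, W) map."""
    return np.pad(X, ((0, 0), (0, 0), (1, 1), (1, 1)))


def _conv2x2(P: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 2x2 convolution of (N, C, H, W) with filters (K, C, 2, 2)."""
    win = np.lib.stride_tricks.sliding_window_view(P, (2, 2), axis=(2, 3))
    return np.einsum("ncijab,kcab->nkij", win, W, optimize=True) + b[None, :, None, None]


def _conv2x2_backward(P: np.ndarray, W: np.ndarray, dZ: np.ndarray):
    win = np.lib.stride_tricks.sliding_window_view(P, (2, 2), axis=(2, 3))
    dW = np.einsum("nkij,ncijab->kcab", dZ, win, optimize=True)
    db = dZ.sum(axis=(0, 2, 3))
    dP = np.zeros_like(P)
    Ho, Wo = dZ.shape[2], dZ.shape[3]
    for a in range(2):
        for bb in range(2):
            dP[:, :, a:a + Ho, bb:bb + Wo] += np.einsum("nkij,kc->ncij", dZ, W[:, :, a, bb], optimize=True)
    return dW, db, dP


def _pool2x2(A: np.ndarray):
    """2x2/stride-2 max pool with truncation; returns output and argmax cache."""
    N, K, H, W = A.shape
    Ho, Wo = H // 2, W // 2
    trimmed = A[:, :, : Ho * 2, : Wo * 2]
    blocks = trimmed.reshape(N, K, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, K, Ho, Wo, 4)
    arg = blocks.argmax(axis=-1)  # first max wins: deterministic tie rule
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _pool2x2_backward(dOut: np.ndarray, arg: np.ndarray, in_shape: tuple) -> np.ndarray:
    N, K, H, W = in_shape
    Ho, Wo = H // 2, W // 2
    dBlocks = np.zeros((N, K, Ho, Wo, 4))
    np.put_along_axis(dBlocks, arg[..., None], dOut[..., None], axis=-1)
    dTrim = dBlocks.reshape(N, K, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, K, Ho * 2, Wo * 2)
    dA = np.zeros(in_shape)
    dA[:, :, : Ho * 2, : Wo * 2] = dTrim
    return dA


class _Channel:
    """One conv-pool-conv-pool-dense channel with analytic gradients."""

    def __init__(self, n1: int, n2: int, input_width: int, rng: np.random.Generator):
        self.n1, self.n2, self.W = n1, n2, input_width
        # He initialization, fan-in of the 2x2 receptive field
        self.params = {
            "W1": rng.standard_normal((n1, 1, 2, 2)) * np.sqrt(2.0 / 4),
            "b1": np.zeros(n1),
            "W2": rng.standard_normal((n2, n1, 2, 2)) * np.sqrt(2.0 / (4 * n1)),
            "b2": np.zeros(n2),
        }
        flat = n2 * self._flat_width(input_width)
        self.params["Wd"] = rng.standard_normal((2, flat)) * np.sqrt(2.0 / flat)
        self.params["bd"] = np.zeros(2)
        self._cache: dict | None = None

    @staticmethod
    def _flat_width(W: int) -> int:
        w1 = (W + 2) - 1          # after pad + 2x2 conv
        w1p = w1 // 2             # after pool
        w2 = (w1p + 2) - 1        # after pad + conv
        return w2 // 2            # after pool (height collapses to 1)

    def forward(self, X: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """Raw 2-vector scores for a batch X of shape (N, 2, W)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (2, self.W):
            raise ValueError(f"expected features of shape (N, 2, {self.W}), got {X.shape}")
        p = self.params
        P0 = _pad1(X[:, None, :, :])
        Z1 = _conv2x2(P0, p["W1"], p["b1"])
        A1 = np.maximum(Z1, 0.0)
        P1_out, arg1 = _pool2x2(A1)
        P1 = _pad1(P1_out)
        Z2 = _conv2x2(P1, p["W2"], p["b2"])
        A2 = np.maximum(Z2, 0.0)
        P2_out, arg2 = _pool2x2(A2)
        flat = P2_out.reshape(P2_out.shape[0], -1)
        scores = flat @ p["Wd"].T + p["bd"]
        if keep_cache:
            self._cache = dict(P0=P0, Z1=Z1, A1=A1, arg1=arg1, P1=P1, Z2=Z2, A2=A2,
                               arg2=arg2, P2_shape=P2_out.shape, flat=flat)
        return scores

    def backward(self, dScores: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients given d(loss)/d(raw scores), shape (N, 2)."""
        c = self._cache
        if c is None:
            raise RuntimeError("forward(keep_cache=True) must precede backward()")
        p = self.params
        grads = {"Wd": dScores.T @ c["flat"], "bd": dScores.sum(axis=0)}
        dFlat = dScores @ p["Wd"]
        dP2 = dFlat.reshape(c["P2_shape"])
        dA2 = _pool2x2_backward(dP2, c["arg2"], c["A2"].shape)
        dZ2 = dA2 * (c["Z2"] > 0)
        dW2, db2, dP1 = _conv2x2_backward(c["P1"], p["W2"], dZ2)
        grads["W2"], grads["b2"] = dW2, db2
        dP1_out = dP1[:, :, 1:-1, 1:-1]  # un-pad
        dA1 = _pool2x2_backward(dP1_out, c["arg1"], c["A1"].shape)
        dZ1 = dA1 * (c["Z1"] > 0)
        dW1, db1, _ = _conv2x2_backward(c["P0"], p["W1"], dZ1)
        grads["W1"], grads["b1"] = dW1, db1
        return grads


# ---------------------------------------------------------------------------
# scoring, loss, fusion

def _softmax2(scores: np.ndarray) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def _p_assoc(scores: np.ndarray) -> np.ndarray:
    return _softmax2(scores)[..., _POS]


def channel_forward(channel: "_Channel", feature: np.ndarray) -> np.ndarray:
    """Raw 2-vector of (unassociated, associated) scores for one 2 x W feature."""
    return channel.forward(np.asarray(feature)[None])[0]


def fuse_scores(score1: np.ndarray, score2: np.ndarray, lambda_weight: float) -> float:
    """Convex combination of the two channels' associated-class probabilities."""
    p1 = float(_p_assoc(np.asarray(score1)))
    p2 = float(_p_assoc(np.asarray(score2)))
    return lambda_weight * p1 + (1.0 - lambda_weight) * p2


def loss(score1: np.ndarray, score2: np.ndarray, label: int) -> tuple[float, float]:
    """Per-channel softmax cross-entropy of one pair's raw score vectors."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    out = []
    for s in (score1, score2):
        p = np.clip(_p_assoc(np.asarray(s)), _EPS, 1.0 - _EPS)
        out.append(float(-(label * np.log(p) + (1 - label) * np.log(1.0 - p))))
    return out[0], out[1]


class DualCNNModel:
    """Two independent channels sharing a config; trained jointly on l1+l2."""

    def __init__(self, config: ModelConfig, input_width: int):
        self.config = config
        self.input_width = input_width
        rng = np.random.default_rng(config.seed)
        self.left = _Channel(config.nconv1, config.nconv2, input_width, rng)
        self.right = _Channel(config.nconv3, config.nconv4, input_width, rng)
        self.trained = False
        self.loss_trace: list[float] = []

    # -- batched loss + gradients (mean over the batch) --------------------
    def _batch_loss_and_grads(self, S: np.ndarray, T: np.ndarray, y: np.ndarray, with_grads: bool = True):
        n = len(y)
        target = np.stack([1.0 - y, y.astype(float)], axis=1)  # columns: (neg, pos)
        total = 0.0
        grads = {}
        for name, ch, X in (("left", self.left, S), ("right", self.right, T)):
            scores = ch.forward(X, keep_cache=with_grads)
            p = _softmax2(scores)
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            total += float(-(target * np.log(pc)).sum() / n)
            if with_grads:
                grads[name] = ch.backward((p - target) / n)
        return total, grads

    def batch_loss(self, S: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
        """Mean of l1 + l2 over a batch (no gradient bookkeeping)."""
        return self._batch_loss_and_grads(S, T, np.asarray(y), with_grads=False)[0]

    # -- inference ----------------------------------------------------------
    def predict_proba(self, S: np.ndarray, T: np.ndarray) -> np.ndarray:
        """Fused associated-class probabilities, shape (N,)."""
        if not self.trained:
            raise RuntimeError("model has not been trained")
        lam = self.config.lambda_weight
        p1 = _p_assoc(self.left.forward(S))
        p2 = _p_assoc(self.right.forward(T))
        return lam * p1 + (1.0 - lam) * p2


def train(model: DualCNNModel, train_set: LabeledPairSet, config: ModelConfig | None = None) -> list[float]:
    """Train both channels jointly with Adam on the summed loss.

    Each epoch uses every positive pair and ``neg_ratio`` negatives per
    positive sampled uniformly (without replacement) from the negative
    pairs of ``train_set``.  Fully deterministic given ``config.seed``.
    Returns the per-epoch mean loss trace.
    """
    cfg = config or model.config
    y = train_set.labels
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed + 1)

    # Adam state per channel
    state = {name: {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in ch.params.items()}
             for name, ch in (("left", model.left), ("right", model.right))}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    trace: list[float] = []
    n_neg_epoch = min(len(neg), max(1, int(round(cfg.neg_ratio * len(pos)))))
    for _ in range(cfg.epochs):
        chosen = np.concatenate([pos, rng.choice(neg, size=n_neg_epoch, replace=False)])
        rng.shuffle(chosen)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(chosen), cfg.batch_size):
            idx = chosen[start:start + cfg.batch_size]
            lval, grads = model._batch_loss_and_grads(train_set.S[idx], train_set.T[idx], y[idx])
            epoch_loss += lval
            n_batches += 1
            t += 1
            for name, ch in (("left", model.left), ("right", model.right)):
                for k, g in grads[name].items():
                    m, v = state[name][k]
                    m[:] = b1 * m + (1 - b1) * g
                    v[:] = b2 * v + (1 - b2) * g * g
                    mh = m / (1 - b1**t)
                    vh = v / (1 - b2**t)
                    ch.params[k] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
        trace.append(epoch_loss / n_batches)
    model.trained = True
    model.loss_trace = trace
    return trace


def predict_pairs(
    model: DualCNNModel,
    net: HeterogeneousNetwork,
    propnet: PropagatedNetwork,
    pairs: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Fused probabilities for arbitrary lncRNA-disease pairs."""
    S, T = batch_features(net, propnet, pairs)
    return model.predict_proba(S, T)


def predict_disease(
    model: DualCNNModel,
    net: HeterogeneousNetwork,
    propnet: PropagatedNetwork,
    disease_index: int,
) -> np.ndarray:
    """Fused probabilities of every lncRNA against one disease (length nl)."""
    if not 0 <= disease_index < net.nd:
        raise IndexError(f"disease index {disease_index} out of range")
    pairs = [(i, disease_index) for i in range(net.nl)]
    return predict_pairs(model, net, propnet, pairs)
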