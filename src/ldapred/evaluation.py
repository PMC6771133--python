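"""Cross-validated, per-disease evaluation of the pair scorer.

Known lncRNA-disease associations are partitioned into five folds.  For
each fold the held-out associations are removed from the association
matrix, the lncRNA similarity is recomputed from the masked matrix, the
propagation is rerun, and the model retrained — so no quantity seen in
training carries held-out information.

Each disease is then evaluated within its own candidate list: its held-out
positives are ranked against the lncRNAs that have no known association
with it anywhere in the dataset (training positives are excluded from the
ranking).  ROC-AUC, AUPR and recall@k are computed per disease and
macro-averaged over diseases, mirroring how candidate prioritization is
consumed: one ranked list per disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data_io import HeterogeneousNetwork
from .features import build_pair_set
from .model import DualCNNModel, ModelConfig, predict_pairs, train
from .propagation import PropagationConfig, propagate_network
from .similarity import functional_similarity_matrix, mask_associations

logger = logging.getLogger(__name__)

DEFAULT_KS = tuple(range(30, 241, 30))

__all__ = [
    "FoldAssignment",
    "EvaluationResult",
    "five_fold_split",
    "auc",
    "aupr",
    "recall_at_k",
    "paired_wilcoxon",
    "cross_validate",
]


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded partition of the known associations into near-equal folds."""

    pairs: list[tuple[int, int]]
    fold_ids: np.ndarray  # one id in [0, n_folds) per pair
    n_folds: int
    seed: int

    def test_pairs(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in zip(self.pairs, self.fold_ids) if f == fold]

    def train_pairs(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in zip(self.pairs, self.fold_ids) if f != fold]


@dataclass(frozen=True)
class EvaluationResult:
    folds: FoldAssignment
    per_disease_auc: dict[int, float]
    per_disease_aupr: dict[int, float]
    recall_at_k: dict[int, float]      # k -> macro-averaged recall
    macro_auc: float
    macro_aupr: float


def five_fold_split(positive_pairs, seed: int, n_folds: int = 5) -> FoldAssignment:
    """Uniform random partition of association pairs into near-equal folds."""
    pairs = [tuple(p) for p in positive_pairs]
    if len(pairs) < n_folds:
        raise ValueError(f"need at least {n_folds} positives, got {len(pairs)}")
    rng = np.random.default_rng(seed)
    fold_ids = np.empty(len(pairs), dtype=int)
    fold_ids[rng.permutation(len(pairs))] = np.arange(len(pairs)) % n_folds
    return FoldAssignment(pairs=pairs, fold_ids=fold_ids, n_folds=n_folds, seed=seed)


def auc(scores, labels) -> float:
    """ROC-AUC via the rank statistic: P(score_pos > score_neg) + 0.5 P(tie).

    Returns NaN when one class is absent (the caller decides how to treat
    the missing value).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, step-wise (non-interpolated).

    Thresholds sweep the distinct score values in descending order; the
    area is sum over thresholds of (delta recall) x precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied-score block
    distinct = np.flatnonzero(np.append(s[1:] != s[:-1], True))
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return float(np.sum(np.diff(recall, prepend=0.0) * precision))


def recall_at_k(scores, labels, ks=DEFAULT_KS) -> np.ndarray:
    """Fraction of all positives found in the top-k of the descending ranking.

    Ties are broken by ascending index so the ranking is deterministic.
    A k exceeding the list length is truncated to it (with a warning).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranked = labels[order]
    cum = np.concatenate([[0], np.cumsum(ranked)])
    out = []
    for k in ks:
        if k > len(scores):
            logger.warning("recall@k: k=%d exceeds %d scored items; using all", k, len(scores))
            k = len(scores)
        out.append(cum[k] / n_pos if n_pos else float("nan"))
    return np.asarray(out)


def paired_wilcoxon(metric_a, metric_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-disease metrics.

    Zero differences are dropped.  The exact null distribution is used for
    n <= 25 retained pairs, the tie-corrected normal approximation beyond.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors must have equal length")
    diffs = a - b
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        logger.warning("paired_wilcoxon: all differences are zero; returning p=1")
        return 1.0
    has_ties = len(np.unique(np.abs(diffs))) < len(diffs)
    method = "exact" if (len(diffs) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method)
    return float(res.pvalue)


def _nanmean(values: dict[int, float]) -> float:
    arr = np.array(list(values.values()), dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if len(arr) else float("nan")


def cross_validate(
    net: HeterogeneousNetwork,
    model_config: ModelConfig,
    propagation_config: PropagationConfig | None = None,
    seed: int = 0,
    ks=DEFAULT_KS,
    include_train_positives: bool = False,
    n_folds: int = 5,
) -> EvaluationResult:
    """Leakage-safe k-fold cross-validation over the known associations.

    Per fold: mask the held-out associations out of A, recompute the
    lncRNA similarity L from the masked A (the miRNA layer is untouched),
    rerun propagation, train a fresh model, then score each disease's
    held-out positives against its never-associated lncRNAs.  Per-disease
    metrics are averaged over the folds in which the disease has at least
    one held-out positive, then macro-averaged over diseases.
    """
    prop_cfg = propagation_config or PropagationConfig()
    A_full = net.A
    positives = [tuple(p) for p in np.argwhere(A_full == 1)]
    folds = five_fold_split(positives, seed=seed, n_folds=n_folds)
    pos_set = set(positives)
    all_pairs = [(i, j) for i in range(net.nl) for j in range(net.nd)]

    auc_by_disease: dict[int, list[float]] = {}
    aupr_by_disease: dict[int, list[float]] = {}
    recall_rows: dict[int, list[np.ndarray]] = {}

    for fold in range(folds.n_folds):
        test_pairs = folds.test_pairs(fold)
        train_pos = folds.train_pairs(fold)
        A_masked = mask_associations(A_full, test_pairs)
        L_masked = functional_similarity_matrix(A_masked, net.D)
        net_fold = net.with_association_matrix(A_masked, L=L_masked)
        propnet = propagate_network(net_fold, prop_cfg)

        neg_pool = [p for p in all_pairs if p not in pos_set]
        train_pairs = train_pos + neg_pool
        labels = [1] * len(train_pos) + [0] * len(neg_pool)
        train_set = build_pair_set(net_fold, propnet, train_pairs, labels)

        fold_cfg = replace(model_config, seed=model_config.seed + 1000 * fold)
        model = DualCNNModel(fold_cfg, input_width=net.nl + net.nd + net.nm)
        train(model, train_set, fold_cfg)
        logger.info("fold %d: trained (final loss %.4f)", fold, model.loss_trace[-1])

        score_all = predict_pairs(model, net_fold, propnet, all_pairs).reshape(net.nl, net.nd)

        test_by_disease: dict[int, list[int]] = {}
        for i, j in test_pairs:
            test_by_disease.setdefault(j, []).append(i)
        for j, pos_lncs in test_by_disease.items():
            never = np.flatnonzero(A_full[:, j] == 0)
            if include_train_positives:
                cand = np.concatenate([pos_lncs, np.flatnonzero(A_full[:, j] == 1)])
                cand = np.unique(cand)
            else:
                cand = np.concatenate([pos_lncs, never])
            lab = np.isin(cand, pos_lncs).astype(int)
            sc = score_all[cand, j]
            auc_by_disease.setdefault(j, []).append(auc(sc, lab))
            aupr_by_disease.setdefault(j, []).append(aupr(sc, lab))
            recall_rows.setdefault(j, []).append(recall_at_k(sc, lab, ks))

    per_auc = {j: float(np.nanmean(v)) for j, v in auc_by_disease.items()}
    per_aupr = {j: float(np.nanmean(v)) for j, v in aupr_by_disease.items()}
    recall_table = {}
    if recall_rows:
        per_disease_recall = np.stack([np.mean(rows, axis=0) for rows in recall_rows.values()])
        recall_table = {int(k): float(v) for k, v in zip(ks, per_disease_recall.mean(axis=0))}
    return EvaluationResult(
        folds=folds,
        per_disease_auc=per_auc,
        per_disease_aupr=per_aupr,
        recall_at_k=recall_table,
        macro_auc=_nanmean(per_auc),
        macro_aupr=_nanmean(per_aupr),
    )
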