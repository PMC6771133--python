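"""Functional similarity of lncRNAs/miRNAs from their associated-disease sets.

Two RNAs are considered functionally similar when the diseases they are
associated with are semantically similar.  The score between two disease
sets is the best-match average (BMA): every disease in one set is matched
to its most similar disease in the other set, and the matched values are
averaged over both directions,

    sim(Sa, Sb) = ( sum_{d in Sa} max_{d' in Sb} D[d, d']
                  + sum_{d in Sb} max_{d' in Sa} D[d, d'] ) / (|Sa| + |Sb|).

An empty set yields similarity 0 (not NaN) so the resulting matrices stay
valid inputs to the propagation step.

During cross-validation held-out lncRNA-disease associations must not leak
into the lncRNA similarity matrix; :func:`mask_associations` produces the
masked association matrix the similarity is recomputed from.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "disease_set_similarity",
    "functional_similarity_matrix",
    "mask_associations",
]


def disease_set_similarity(Sa: Iterable[int], Sb: Iterable[int], D: np.ndarray) -> float:
    """Best-match-average similarity of two disease index sets under ``D``."""
    a = sorted(set(Sa))
    b = sorted(set(Sb))
    if not a or not b:
        return 0.0
    cross = D[np.ix_(a, b)]
    return float((cross.max(axis=1).sum() + cross.max(axis=0).sum()) / (len(a) + len(b)))


def functional_similarity_matrix(assoc: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Pairwise BMA similarity of the rows of a binary entity x disease matrix.

    Entry (i, j) is :func:`disease_set_similarity` of the disease sets of
    rows i and j.  The result is symmetric with unit diagonal, entries in
    [0, 1] whenever ``D`` is.  Entities with no associated disease get zero
    similarity to everything (diagonal stays 1).
    """
    assoc = np.asarray(assoc, dtype=float)
    if assoc.shape[1] != D.shape[0]:
        raise ValueError("assoc columns must align with D")
    n = assoc.shape[0]
    masks = assoc > 0
    sizes = masks.sum(axis=1)
    sim = np.zeros((n, n))
    # row-wise best match: for each entity pair (i, j), each disease of i is
    # matched against j's set. Computed as max over D columns restricted to
    # j's diseases, which vectorizes over i's diseases.
    for j in range(n):
        if sizes[j] == 0:
            continue
        best_vs_j = D[:, masks[j]].max(axis=1)  # best match of every disease into j's set
        for i in range(j):
            if sizes[i] == 0:
                continue
            fwd = best_vs_j[masks[i]].sum()
            back = D[np.ix_(masks[j], masks[i])].max(axis=1).sum()
            sim[i, j] = sim[j, i] = (fwd + back) / (sizes[i] + sizes[j])
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def mask_associations(A: np.ndarray, held_out_pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """Copy of ``A`` with the held-out entries zeroed.

    Every held-out pair must currently be a 1; anything else signals a
    fold-bookkeeping bug upstream and raises.
    """
    A = np.asarray(A, dtype=float)
    masked = A.copy()
    for i, j in held_out_pairs:
        if masked[i, j] != 1.0:
            raise ValueError(f"pair ({i}, {j}) is not a present association (value {masked[i, j]!r})")
        masked[i, j] = 0.0
    return masked
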