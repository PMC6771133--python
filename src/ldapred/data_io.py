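"""Reading edge lists and similarity matrices and assembling the heterogeneous network.

The pipeline operates on three entity namespaces (lncRNA, disease, miRNA)
tied together by six matrices:

* ``L``, ``D``, ``M`` — within-type similarity matrices (symmetric, unit
  diagonal, values in [0, 1]);
* ``A`` (lncRNA x disease), ``B`` (lncRNA x miRNA), ``C`` (miRNA x disease)
  — binary association/interaction matrices.

Entity name matching is case-sensitive exact string match throughout:
curated databases use distinct canonical symbols and silent case-folding
would hide identifier errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-8

__all__ = [
    "EntityIndex",
    "HeterogeneousNetwork",
    "load_edge_list",
    "load_similarity_matrix",
    "write_similarity_matrix",
    "assemble_network",
    "load_network",
    "write_ranked_predictions",
]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list files."""


@dataclass
class EntityIndex:
    """An ordered, immutable-after-construction namespace of entity names.

    Every matrix axis of the same role shares this index, so positions are
    comparable across ``L``/``A``/``B`` etc.
    """

    names: list[str]
    role: str
    _positions: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.role not in {"lncRNA", "disease", "miRNA"}:
            raise ValueError(f"unknown role {self.role!r}")
        if len(set(self.names)) != len(self.names):
            dupes = [n for n in self.names if self.names.count(n) > 1]
            raise ValueError(f"duplicate entity names in {self.role} index: {sorted(set(dupes))}")
        self.names = list(self.names)
        self._positions = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._positions

    def position(self, name: str) -> int:
        try:
            return self._positions[name]
        except KeyError:
            raise KeyError(f"{name!r} not in {self.role} index") from None

    def _append(self, name: str) -> int:
        # build-mode extension used by load_edge_list only
        if name in self._positions:
            raise ValueError(f"{name!r} already present")
        self.names.append(name)
        self._positions[name] = len(self.names) - 1
        return self._positions[name]


@dataclass
class HeterogeneousNetwork:
    """The six aligned matrices plus the three entity indices.

    Invariants (enforced by :func:`assemble_network`): L, D, M symmetric
    with unit diagonal and values in [0, 1]; A, B, C binary; all shapes
    consistent with the indices.
    """

    L: np.ndarray
    D: np.ndarray
    M: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    lnc_index: EntityIndex
    disease_index: EntityIndex
    mirna_index: EntityIndex

    @property
    def nl(self) -> int:
        return len(self.lnc_index)

    @property
    def nd(self) -> int:
        return len(self.disease_index)

    @property
    def nm(self) -> int:
        return len(self.mirna_index)

    def with_association_matrix(self, A: np.ndarray, L: np.ndarray | None = None) -> "HeterogeneousNetwork":
        """Copy of the network with ``A`` (and optionally ``L``) replaced.

        Used during cross-validation where held-out associations are masked
        out of ``A`` and the lncRNA similarity is recomputed from the mask.
        """
        return assemble_network(
            L=self.L if L is None else L,
            D=self.D,
            M=self.M,
            A=A,
            B=self.B,
            C=self.C,
            lnc_index=self.lnc_index,
            disease_index=self.disease_index,
            mirna_index=self.mirna_index,
        )


def _iter_pair_lines(path: Path) -> Iterable[tuple[int, str, str]]:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    n_data = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeListError(f"{path}:{lineno}: expected two {sep!r}-separated names, got {line!r}")
            n_data += 1
            yield lineno, parts[0].strip(), parts[1].strip()
    if n_data == 0:
        raise EdgeListError(f"{path}: no edges found")


def load_edge_list(
    path: str | Path,
    row_index: EntityIndex,
    col_index: EntityIndex,
    strict: bool = False,
) -> np.ndarray:
    """Read a two-column edge list into a binary association matrix.

    Each line names one (row-entity, column-entity) pair; duplicates
    collapse to a single 1.  In build mode (``strict=False``) unseen names
    extend the corresponding index; in strict mode they raise.
    """
    path = Path(path)
    pairs: list[tuple[int, int]] = []
    for lineno, rname, cname in _iter_pair_lines(path):
        for name, index in ((rname, row_index), (cname, col_index)):
            if name not in index:
                if strict:
                    raise KeyError(f"{path}:{lineno}: unknown {index.role} name {name!r}")
                index._append(name)
        pairs.append((row_index.position(rname), col_index.position(cname)))
    mat = np.zeros((len(row_index), len(col_index)))
    rows, cols = zip(*pairs)
    mat[rows, cols] = 1.0
    return mat


def load_similarity_matrix(path: str | Path, role: str, strict: bool = True) -> tuple[EntityIndex, np.ndarray]:
    """Read a named square similarity matrix from TSV.

    The header row and first column must carry identical entity names.
    Asymmetries up to 1e-8 are symmetrized by averaging with the transpose;
    larger ones are an error.  The diagonal is forced to 1.  Out-of-range
    values raise in strict mode and are clipped (with a warning) otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    names = [str(n) for n in df.columns]
    row_names = [str(n) for n in df.index]
    if len(names) != len(row_names):
        raise ValueError(f"{path}: matrix is not square ({len(row_names)}x{len(names)})")
    if names != row_names:
        raise ValueError(f"{path}: header names and first-column names disagree")
    mat = df.to_numpy(dtype=float)
    asym = np.abs(mat - mat.T).max() if mat.size else 0.0
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance (max |X-X.T| = {asym:.3g})")
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    if mat.min() < 0.0 or mat.max() > 1.0:
        if strict:
            raise ValueError(f"{path}: similarity values outside [0, 1] (range [{mat.min():.3g}, {mat.max():.3g}])")
        logger.warning("%s: clipping similarity values to [0, 1] (range was [%.3g, %.3g])", path, mat.min(), mat.max())
        mat = np.clip(mat, 0.0, 1.0)
    return EntityIndex(names=names, role=role), mat


def write_similarity_matrix(path: str | Path, index: EntityIndex, mat: np.ndarray) -> None:
    """Write a named square matrix in the TSV layout ``load_similarity_matrix`` reads."""
    pd.DataFrame(mat, index=index.names, columns=index.names).to_csv(path, sep="\t")


def _check_similarity(name: str, X: np.ndarray, n: int, tol: float = 1e-8) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape != (n, n):
        raise ValueError(f"{name}: expected shape ({n}, {n}), got {X.shape}")
    if np.abs(X - X.T).max() > tol:
        raise ValueError(f"{name}: not symmetric (max |X-X.T| = {np.abs(X - X.T).max():.3g})")
    if np.abs(np.diag(X) - 1.0).max() > tol:
        raise ValueError(f"{name}: diagonal is not 1")
    if X.min() < -tol or X.max() > 1.0 + tol:
        raise ValueError(f"{name}: values outside [0, 1]")
    return X


def _check_binary(name: str, X: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape != shape:
        raise ValueError(f"{name}: expected shape {shape}, got {X.shape}")
    if not np.isin(X, (0.0, 1.0)).all():
        bad = X[~np.isin(X, (0.0, 1.0))]
        raise ValueError(f"{name}: non-binary entries, e.g. {bad.flat[0]!r}")
    return X


def assemble_network(
    L: np.ndarray,
    D: np.ndarray,
    M: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    lnc_index: EntityIndex,
    disease_index: EntityIndex,
    mirna_index: EntityIndex,
) -> HeterogeneousNetwork:
    """Validate the six matrices against the indices and build the network."""
    nl, nd, nm = len(lnc_index), len(disease_index), len(mirna_index)
    return HeterogeneousNetwork(
        L=_check_similarity("L", L, nl),
        D=_check_similarity("D", D, nd),
        M=_check_similarity("M", M, nm),
        A=_check_binary("A", A, (nl, nd)),
        B=_check_binary("B", B, (nl, nm)),
        C=_check_binary("C", C, (nm, nd)),
        lnc_index=lnc_index,
        disease_index=disease_index,
        mirna_index=mirna_index,
    )


def load_network(
    lncrna_disease: str | Path,
    lncrna_mirna: str | Path,
    mirna_disease: str | Path,
    disease_similarity: str | Path,
    lncrna_names: Sequence[str] | None = None,
    mirna_names: Sequence[str] | None = None,
) -> HeterogeneousNetwork:
    """Assemble a full network from the three edge lists and the disease matrix.

    The disease namespace is fixed by the similarity matrix (edge lists may
    not introduce new diseases).  lncRNA/miRNA namespaces are either passed
    explicitly or built up in file order.  The lncRNA and miRNA similarity
    matrices are derived from the loaded associations via the
    best-match-average functional similarity.
    """
    from .similarity import functional_similarity_matrix

    disease_index, D = load_similarity_matrix(disease_similarity, role="disease")
    lnc_index = EntityIndex(list(lncrna_names) if lncrna_names else [], "lncRNA")
    mirna_index = EntityIndex(list(mirna_names) if mirna_names else [], "miRNA")
    strict = lncrna_names is not None and mirna_names is not None  # fixed namespaces imply strict matching
    A = load_edge_list(lncrna_disease, lnc_index, disease_index, strict=strict)
    B = load_edge_list(lncrna_mirna, lnc_index, mirna_index, strict=strict)
    C = load_edge_list(mirna_disease, mirna_index, disease_index, strict=strict)
    # earlier-loaded matrices may be short if later files introduced entities
    A = np.pad(A, ((0, len(lnc_index) - A.shape[0]), (0, 0)))
    B = np.pad(B, ((0, len(lnc_index) - B.shape[0]), (0, len(mirna_index) - B.shape[1])))
    C = np.pad(C, ((0, len(mirna_index) - C.shape[0]), (0, 0)))
    L = functional_similarity_matrix(A, D)
    M = functional_similarity_matrix(C, D)
    return assemble_network(L, D, M, A, B, C, lnc_index, disease_index, mirna_index)


def write_ranked_predictions(
    disease_name: str,
    scores: Sequence[float],
    known_mask: Sequence[bool],
    lnc_index: EntityIndex,
    path: str | Path,
    top_n: int | None = None,
) -> None:
    """Write the per-disease candidate ranking as TSV.

    Columns: rank, lncRNA name, score, is_known.  Sorted by descending
    score; ties broken by ascending entity-index position so output is
    deterministic.  Known positives are flagged, not removed, so the file
    shows the full ranked list.
    """
    scores = np.asarray(scores, dtype=float)
    known = np.asarray(known_mask, dtype=bool)
    if scores.shape != (len(lnc_index),) or known.shape != scores.shape:
        raise ValueError("scores/known_mask length must equal the number of lncRNAs")
    order = np.lexsort((np.arange(len(scores)), -scores))
    if top_n is not None:
        if top_n > len(order):
            logger.warning("top_n=%d exceeds the %d available lncRNAs; writing all", top_n, len(order))
        order = order[:top_n]
    with open(path, "w") as fh:
        fh.write(f"# disease: {disease_name}\n")
        fh.write("rank\tlncRNA\tscore\tis_known\n")
        for rank, idx in enumerate(order, start=1):
            fh.write(f"{rank}\t{lnc_index.names[idx]}\t{scores[idx]:.6g}\t{int(known[idx])}\n")
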