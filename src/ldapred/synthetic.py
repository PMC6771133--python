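"""Synthetic heterogeneous networks with planted lncRNA-disease signal.

The generator emulates the statistical structure the predictor exploits:
entities of all three types are assigned round-robin to a handful of
clusters ("disease modules").  Diseases in the same cluster are highly
similar; lncRNAs and miRNAs are preferentially associated with the
diseases of their own cluster, plus a sprinkle of uniform noise edges.
The miRNA layer carries the same cluster structure (lncRNA-miRNA and
miRNA-disease edges inside blocks), so the two-hop paths through miRNAs
are informative, not just the direct lncRNA-disease block.

The within-block associations drawn are returned separately as the
planted positive pairs, so downstream tests can distinguish signal edges
from noise edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_io import EntityIndex, HeterogeneousNetwork, assemble_network, write_similarity_matrix
from .similarity import functional_similarity_matrix

__all__ = ["SyntheticSpec", "generate", "write_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block network generator.

    Defaults give four clusters over 60 lncRNAs x 40 diseases x 30 miRNAs
    with dense within-block associations (p=0.6) against sparse uniform
    noise (p=0.02) — a clearly learnable but not trivial planted signal.
    """

    nl: int = 60
    nd: int = 40
    nm: int = 30
    n_clusters: int = 4
    within_block_assoc_prob: float = 0.6
    cross_block_noise_prob: float = 0.02
    disease_within_sim: float = 0.8
    disease_cross_sim: float = 0.1
    mirna_bridge_prob: float = 0.6
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("within_block_assoc_prob", "cross_block_noise_prob",
                     "disease_within_sim", "disease_cross_sim", "mirna_bridge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.nl, self.nd, self.nm) <= 0:
            raise ValueError("entity counts must be positive")
        if not 1 <= self.n_clusters <= min(self.nl, self.nd, self.nm):
            raise ValueError("n_clusters must be in [1, min(nl, nd, nm)] so no block is empty")


def _clusters(n: int, k: int) -> np.ndarray:
    return np.arange(n) % k


def _planted_bipartite(
    rng: np.random.Generator,
    rows: np.ndarray,
    cols: np.ndarray,
    p_within: float,
    p_noise: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a binary matrix: Bernoulli(p_within) on-block, p_noise off-block.

    Returns the matrix and the boolean mask of within-block edges drawn
    (the planted edges).
    """
    same = rows[:, None] == cols[None, :]
    u = rng.random(same.shape)
    planted = same & (u < p_within)
    noise = ~same & (u < p_noise)
    return (planted | noise).astype(float), planted


def generate(spec: SyntheticSpec) -> tuple[HeterogeneousNetwork, list[tuple[int, int]]]:
    """Draw a seeded network; returns it with the planted positive pair list."""
    rng = np.random.default_rng(spec.seed)
    cl_l = _clusters(spec.nl, spec.n_clusters)
    cl_d = _clusters(spec.nd, spec.n_clusters)
    cl_m = _clusters(spec.nm, spec.n_clusters)

    D = np.where(cl_d[:, None] == cl_d[None, :], spec.disease_within_sim, spec.disease_cross_sim)
    np.fill_diagonal(D, 1.0)

    A, planted_mask = _planted_bipartite(rng, cl_l, cl_d, spec.within_block_assoc_prob, spec.cross_block_noise_prob)
    B, _ = _planted_bipartite(rng, cl_l, cl_m, spec.mirna_bridge_prob, spec.cross_block_noise_prob)
    C, _ = _planted_bipartite(rng, cl_m, cl_d, spec.mirna_bridge_prob, spec.cross_block_noise_prob)

    L = functional_similarity_matrix(A, D)
    M = functional_similarity_matrix(C, D)

    net = assemble_network(
        L=L, D=D, M=M, A=A, B=B, C=C,
        lnc_index=EntityIndex([f"lnc{i:03d}" for i in range(spec.nl)], "lncRNA"),
        disease_index=EntityIndex([f"dis{i:03d}" for i in range(spec.nd)], "disease"),
        mirna_index=EntityIndex([f"mir{i:03d}" for i in range(spec.nm)], "miRNA"),
    )
    planted = [tuple(p) for p in np.argwhere(planted_mask)]
    return net, planted


def write_fixture(directory: str | Path, spec: SyntheticSpec) -> Path:
    """Materialize a generated network as the on-disk input formats.

    Emits the three edge lists, the disease similarity matrix, and a
    manifest recording the spec and the planted pairs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    net, planted = generate(spec)

    def _write_edges(path: Path, mat: np.ndarray, rows: EntityIndex, cols: EntityIndex) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {rows.role}\t{cols.role}\n")
            for i, j in np.argwhere(mat == 1):
                fh.write(f"{rows.names[i]}\t{cols.names[j]}\n")

    _write_edges(directory / "lncrna_disease.tsv", net.A, net.lnc_index, net.disease_index)
    _write_edges(directory / "lncrna_mirna.tsv", net.B, net.lnc_index, net.mirna_index)
    _write_edges(directory / "mirna_disease.tsv", net.C, net.mirna_index, net.disease_index)
    write_similarity_matrix(directory / "disease_similarity.tsv", net.disease_index, net.D)
    manifest = {
        "spec": asdict(spec),
        "seed": spec.seed,
        "planted_pairs": [[int(i), int(j)] for i, j in planted],
        "lncrnas": net.lnc_index.names,
        "diseases": net.disease_index.names,
        "mirnas": net.mirna_index.names,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory
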