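# Methods

## Problem and model

`ldapred` prioritizes candidate disease-associated long non-coding RNAs
(lncRNAs). The input is a heterogeneous network over three entity types —
lncRNAs, diseases and miRNAs — described by six matrices: within-type
similarities `L` (lncRNA), `D` (disease, semantic similarity supplied as
input) and `M` (miRNA), and binary cross-type matrices `A` (lncRNA–disease
associations), `B` (lncRNA–miRNA interactions) and `C` (miRNA–disease
associations). The output is, per disease, a ranking of all lncRNAs by a
predicted association probability.

Each lncRNA–disease pair (i, j) is represented by two 2 × (nl+nd+nm)
matrices with a shared column-block layout `[lncRNA | disease | miRNA]`:

* **Raw evidence matrix S.** Row 1 is the lncRNA's view of the network,
  `[L[i,:] | A[i,:] | B[i,:]]`; row 2 is the disease's view,
  `[A[:,j]ᵀ | D[j,:] | C[:,j]ᵀ]`. Column k holds lncRNA-side and
  disease-side evidence about the same entity, so a 2 × 2 convolution
  window sees co-occurrence patterns (e.g. a lncRNA similar to i that is
  associated with j).
* **Topological matrix T.** Same layout, but read from
  information-flow-propagated matrices blending one-hop and two-hop paths:
  within a layer `X' = γX + γ²(X·X)`, across two layers
  `X' = γX + γ²(S_left·X + X·S_right)` where `S_left`/`S_right` are the
  row/column types' similarity matrices. No normalization is applied, so
  propagated entries are not confined to [0, 1]; with binary inputs and
  the default γ they stay small (order γ = 0.2 for one-hop, γ² = 0.04 per
  two-hop path). When `L` and `D` are symmetric, the propagated
  disease→lncRNA matrix is exactly the transpose of the propagated
  lncRNA→disease matrix; this identity is asserted in tests at 1e-12.

`L` and `M` are derived from associated-disease sets by best-match-average
(BMA) similarity: for disease sets Sa, Sb,
`sim = (Σ_{d∈Sa} max_{d'∈Sb} D[d,d'] + Σ_{d∈Sb} max_{d'∈Sa} D[d,d']) / (|Sa|+|Sb|)`.
Empty sets yield similarity 0 (not NaN) so downstream matrix algebra stays
well-defined.

## Dual-channel CNN

Two structurally identical channels score S and T independently:

    zero-pad(1) → 2×2 conv (8 maps, ReLU) → 2×2 max-pool (stride 2)
    → zero-pad(1) → 2×2 conv (16 maps, ReLU) → 2×2 max-pool
    → flatten → dense → 2 raw scores (unassociated, associated)

The padding implements "wide" convolution — one zero row/column on every
side, the minimum that lets a 2×2 filter cover boundary columns. With a
2-row input the first pool collapses the height to 1; the second
conv/pool then act on the padded 3-row map. Pool windows that do not fit
(odd widths) are truncated; the argmax tie rule is "first index wins".

Per channel, a softmax over the raw 2-vector gives the associated-class
probability and a cross-entropy loss (probabilities clamped to
[1e-12, 1−1e-12]). The channels are trained **jointly** on the summed
loss l1 + l2 with a single Adam optimizer. The fusion weight λ enters
only at inference:

    fused score = λ · p_left + (1 − λ) · p_right,  default λ = 0.7.

Fusing softmax probabilities (rather than raw dense outputs) was a design
choice: the per-channel losses are defined on softmax probabilities, and
ranking needs a probability-scale score; this is noted as a potential
deviation from alternatives that fuse raw scores.

The network is implemented in pure NumPy (float64) with hand-written
analytic backpropagation. This makes the forward/backward passes exactly
reproducible from a seed and directly checkable: the test suite verifies
analytic gradients against central finite differences (1e-5 step) to
better than 1e-4 relative error on a one-filter miniature model. Gradient
checks randomize biases away from zero because zero-initialized biases
plus zero padding place pre-activations exactly at the ReLU kink, where a
central difference measures the subgradient average rather than either
one-sided derivative — a property of the check, not a defect.

### Training defaults

| parameter | default | notes |
|---|---|---|
| γ (propagation) | 0.2 | one-hop weight; two-hop paths get γ² |
| λ (fusion) | 0.7 | left (raw-evidence) channel weight |
| filters | 8 then 16 per channel, 2×2 | both channels identical |
| optimizer | Adam, lr 1e-3 | β = (0.9, 0.999) |
| epochs / batch | 100 / 32 | |
| negative sampling | 1 negative per positive per epoch | uniform, seeded, without replacement from all unassociated pairs |

Class balancing is a configuration knob (`neg_ratio`): every unassociated
pair is a potential negative, and each epoch draws a fresh uniform sample,
so over many epochs the model sees a broad slice of the negative pool
while each epoch stays balanced. He initialization scaled to the 2×2
receptive field; biases start at zero.

## Evaluation protocol

Five-fold cross-validation partitions the known association **pairs**
(not diseases) into near-equal seeded folds. Per fold:

1. held-out associations are set to 0 in `A`;
2. `L` is recomputed from the masked `A` (leakage masking — `M` is
   computed once from the full miRNA–disease matrix `C`, which is never
   held out);
3. propagation is rerun on the masked network (`A` enters the propagated
   matrices, so this too would leak otherwise);
4. a fresh model is trained; held-out pairs therefore also have a 0 in
   their own feature matrices.

Each disease is evaluated inside its own candidate list: held-out
positives ranked against lncRNAs with no known association to that
disease anywhere in the data (training positives are excluded from the
ranking to avoid trivially inflating AUC; a flag restores them). ROC-AUC
is computed by the rank statistic (ties averaged), AUPR by the step-wise
non-interpolated method, recall@k over the deterministic descending
ranking (ties broken by entity index). Per-disease values are averaged
over the folds in which the disease has a held-out positive, then
macro-averaged over diseases; diseases with no held-out positive in a
fold are excluded from that fold's average. Method comparisons on
per-disease metric vectors use the two-sided Wilcoxon signed-rank test
(zero differences dropped; exact null for n ≤ 25 without ties, otherwise
the tie-corrected normal approximation).

## Synthetic study conditions

The generator plants a learnable signal with the structure the method
exploits. Entities of all three types are assigned round-robin to
`n_clusters` modules. Disease similarity is block-structured (0.8 within,
0.1 across, unit diagonal) — generated directly as a matrix because the
pipeline consumes `D` as a matrix; no ontology machinery would add
testable behavior. `A`, `B` and `C` are Bernoulli samples: dense within
blocks, sparse uniform noise elsewhere. The miRNA layer shares the block
structure (bridge probability 0.6) so that the two-hop lncRNA→miRNA→
disease paths carry signal and the right channel is genuinely exercised.

Defaults: 60 lncRNAs × 40 diseases × 30 miRNAs, 4 clusters, within-block
association probability 0.6, noise 0.02, seed 7 — roughly 380
associations, a scale at which full five-fold CV with per-fold similarity
recomputation and retraining runs in a few minutes on one CPU. Under
these conditions the pipeline reaches macro AUC ≥ 0.85, while a
label-shuffled control stays near 0.5; both are asserted in the test
suite and recomputed by `scripts/acceptance.py`.

What the synthetic conditions do **not** emulate: the heavy-tailed degree
distributions of curated association databases, name vocabularies,
disease-ontology-derived similarity structure, and dataset-scale class
imbalance (the real corpus has ~2700 positives among ~100 000 candidate
pairs). Passing the planted-signal checks shows the machinery recovers
block-structured co-association signal leak-free; it does not certify
headline performance on curated data.

## Numerical choices and edge cases

* All linear algebra is dense float64; entity counts of a few thousand
  per role are well within one CPU's reach, and dense products are what
  the exact triple-loop test oracles check against (≤ 1e-12).
* AUC/AUPR return NaN (flagged missing) when a class is absent; such
  disease–fold cells are dropped from macro averages. Constant scores
  give AUC 0.5 via the tie rule.
* recall@k with k beyond the list length truncates to the list (logged).
* Similarity file I/O symmetrizes asymmetries ≤ 1e-8 by averaging and
  rejects larger ones; out-of-range values are an error in strict mode,
  clipped with a warning otherwise.
* Ranking ties are broken by ascending entity index everywhere, so every
  output file is byte-reproducible from a seed.

## Known limitations

* No ≥3-hop propagation or restart/random-walk variants; no attention or
  graph-convolution architectures.
* The miRNA similarity is never masked during lncRNA–disease CV; if the
  evaluation were extended to miRNA-layer prediction this would leak.
* The NumPy CNN is CPU-only and single-threaded beyond BLAS; it is sized
  for the dataset scales above, not for large hyperparameter sweeps.
* Disease semantic similarity is consumed as an input matrix; computing
  it from an ontology DAG is out of scope.
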