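# Methods

## Model and assumptions

The pipeline treats disease-gene prioritization as proximity ranking on a
heterogeneous network G = (V, E, W) with two node types (diseases, genes)
and three edge types (disease–disease, gene–gene, disease–gene). All input
edge weights are 1: the layers are treated as presence/absence evidence of
equal reliability. The core assumption is that network neighborhoods carry
the association signal — genes of the same disease cluster in the
interactome, and similar diseases share genes — so a low-dimensional
embedding trained to preserve walk neighborhoods, followed by propagation
on a network rebuilt from embedding similarities, should rank held-out
associations highly.

### Biased walks

The second-order walk scores a step from `cur` to `next`, given the
previous node `prev`, as w(cur, next)·π where π = 1/p if next = prev, 1 if
next is adjacent to prev, 1/q otherwise (the clamped-distance form of the
bias; distances are computed locally from adjacency, no global BFS).
Scores are normalized over the neighbors of `cur`. The first step of a
walk, which has no `prev`, uses first-order probabilities ∝ w. Walks run on
all three layers merged into one graph, so disease and gene vectors live in
the same space — the reconstruction step requires exactly that. Isolated
start nodes yield length-1 walks.

### Embedding

Skip-gram with negative sampling over all (center, context) pairs within a
window along each walk. Two parameter matrices are trained (center and
context), matching the asymmetric factorization of the conditional
co-occurrence model; the center matrix is the returned representation.
Center vectors initialize uniformly in [−0.5/d, 0.5/d], context vectors at
zero. Negatives are drawn from the corpus unigram distribution raised to
0.75; a draw that collides with the true context is resampled. The per-pair
SGD loop is a numba kernel with an explicit xorshift RNG, single-threaded,
so training is bitwise reproducible for a given seed. The logit is clipped
to [−10, 10] and the scalar gradient coefficient to |g| ≤ 10 before the
update, which keeps vectors finite without altering ordinary updates
(learning rates in use never approach the clip).

### Reconstruction

Within each layer, the k most cosine-similar peers of every node are kept
(ties to the lower node id), the per-node selections are union-symmetrized
— preserving every node's stated k nearest neighbors — and the cosine
value becomes the edge weight. Negative cosines are clamped to 0 (and the
resulting zero-weight edges dropped) because the propagation matrix must be
non-negative; a `binarize` flag restores uniform 0/1 weights. Keeping the
cosine magnitudes is deliberate: the column normalization of the next stage
consumes weights, so reconstruction strength carries through to the
transfer matrix. The bipartite block H_G is always the original filtered
association network; only the within-layer blocks are rebuilt.

### Propagation

Each block is column-normalized (zero columns left zero), the blocks are
combined with inter-layer jump probability β, and the combined matrix is
column-renormalized into the transfer matrix T. This renormalization
implements the rule that a node without a cross-layer link keeps all its
mass within its own layer (its pre-repair column sums to 1−β), and a fully
isolated node receives a unit self-loop so T is exactly column-stochastic
— the self-loop repair keeps the trapped mass local instead of
redistributing it globally. The restart iteration
q_{t+1} = (1−α)T·q_t + α·q₀ contracts geometrically with factor ≤ 1−α; it
is checked in the tests against the closed-form fixed point
q = α(I − (1−α)T)^{-1}q₀ (dense solve, guarded to ≤ 2000 nodes).
The diagonal renormalizer of the transfer step is defined as the column
sums of the combined block matrix; this is the only reading that yields a
column-stochastic T consistent with left-multiplication of q.

## Parameters

| parameter | default | meaning |
|---|---|---|
| p, q | 1, 1 | walk return / in–out bias (1,1 = first-order walk) |
| num_walks, walk_length | 10, 80 | walks per node and their length |
| d | 128 | embedding dimension |
| window | 10 | context radius defining walk neighborhoods |
| negatives | 5 | negative samples per pair |
| epochs | 5 | passes over the pair stream |
| learning_rate | 0.025 → 1e-4 | linear decay over all updates |
| recon_k | 10 | cosine neighbors kept per node in enhanced layers |
| dd_knn_k | 5 | kNN degree when sparsifying a dense disease-similarity table |
| β | 0.5 | inter-layer jump probability |
| α | 0.7 | restart probability |
| η | 0.5 | seed mass on the disease layer (rest uniform on known genes; all mass on the disease if none) |
| tol, max_iter | 1e-10 (L1), 1000 | restart-walk convergence |

Walk, trainer and propagation defaults follow common practice for biased
random-walk embeddings and two-layer restart walks; all are exposed through
the estimator constructor, the YAML config and CLI flags. Ranking excludes
the seed disease's training genes, the standard prioritization protocol.

## Synthetic data: what it emulates and what it does not

The generator plants a modular structure: genes are split evenly into
modules, gene–gene edges follow a stochastic block model (default 100
diseases, 500 genes, 10 modules, within-module rate 0.3, between 0.01),
each disease is assigned a home module and draws 8 associations from it
with a 10% noise fraction rewired uniformly, and the disease–disease layer
is the kNN graph (k = 5) of Jaccard overlap between association sets. This
reproduces the features the method exploits — modular interactome,
co-association structure, disease similarity correlated with shared genes
— with known ground truth.

It does **not** reproduce scale-free degree distributions, study bias
(well-studied genes having more edges), incomplete and noisy interactomes,
disease-similarity scores derived from text rather than shared genes, or
the size of real datasets (tens of thousands of associations). Passing the
recovery tests therefore shows the pipeline correctly extracts planted
modular signal at desk scale; it does not certify performance on real
disease data.

The recovery experiment hides 30% of each disease's associations (always
keeping at least one), refits the full pipeline on the observed network,
and evaluates hidden associations against the genome-wide control set
(all genes minus that disease's observed and hidden genes), macro-averaged
over diseases and over 3 generator seeds. This single-split protocol is
used rather than per-fold refitting at full scale because it measures the
same recovery property with one pipeline fit per seed; the k-fold driver
(`evaluate_cv`), which refits the estimator per fold, is exercised at
smaller problem sizes in the tests. A gene-degree baseline (the null model
that ranks hub genes first) and propagation on the raw, unreconstructed
two-layer network are run on identical splits for comparison; the
acceptance script reports all three side by side. On this generator the
raw-network walk is already near ceiling, so reconstruction's measured
advantage is approximately zero — the synthetic substrate does not
discriminate the two variants, and the comparison is reported rather than
gated.

## Numerical choices

- Ties in every top-k selection (kNN sparsification, enhanced networks,
  gene ranking, top-k metrics) break deterministically by ascending node
  id; AUROC uses mid-rank tie correction, AUPRC a grouped-threshold sweep.
- Duplicate edges in input files collapse keeping the maximum weight;
  self-loops in inputs are dropped with a warning.
- One global seed derives all stage seeds via `numpy.random.SeedSequence`
  (documented in `psne.estimator.derive_seeds`), so end-to-end runs are
  byte-reproducible; the embedding kernel is single-threaded by design —
  determinism is the tested contract and there is no multi-worker mode.
- Embedding training uses float32 accumulation in the kernel and returns
  float64 matrices; export round-trips are lossless at float64.
- Monte-Carlo walk-law checks use 360k steps so the sampling error
  (SE ≈ 0.002) sits well inside the ±0.01 comparison band.

## Known limitations

- The SGNS trainer is deliberately minimal (no subsampling of frequent
  nodes, no dynamic window shrinking); on very skewed degree distributions
  hub nodes may dominate the pair stream.
- Dense cosine similarity in the reconstruction step is O(n²d) per layer;
  fine at desk scale, but layers beyond ~50k nodes would need a
  blocked or approximate-neighbor implementation.
- `rwr_closed_form` is a test oracle, not a production path (dense solve,
  ≤ 2000 nodes).
- The evaluation's genome-wide control set treats all non-associated genes
  as negatives; undiscovered true associations in real data depress
  measured AUROC, as in any benchmark of this design.
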