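"""Skip-gram with negative sampling (SGNS) over the walk corpus.

Each node u gets a d-dimensional feature vector f(u) fitted so that the
dot product f(n)·f(u) is large for nodes n appearing near u in the walks
(the sampled neighborhood N_S(u)) and small for randomly drawn nodes.
Formally we maximize, over all (center, context) pairs within a window,

    log sigma(f'(ctx)·f(u)) + sum_{neg} log sigma(-f'(neg)·f(u)),

the standard negative-sampling surrogate of the softmax co-occurrence
likelihood whose partition function Z_u is intractable on large graphs.
Two parameter matrices are trained (center f and context f'); the center
matrix is the returned representation.

The per-pair stochastic gradient ascent loop is compiled with numba and
runs single-threaded with an explicit xorshift RNG, so training is
bitwise reproducible for a given seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from numba import njit

from .graph_model import NodeRef
from .walker import WalkCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SGNSParams:
    d: int = 128
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.window < 1 or self.negatives < 1 or self.epochs < 1:
            raise ValueError("window, negatives and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class Embedding:
    """|V| x d node feature matrix with a NodeRef row index."""

    nodes: list[NodeRef]
    vectors: np.ndarray           # center ("source") vectors — the representation
    context_vectors: np.ndarray   # the second parameter matrix of the model

    def __post_init__(self) -> None:
        self.node_index: dict[NodeRef, int] = {n: i for i, n in enumerate(self.nodes)}

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node: NodeRef) -> np.ndarray:
        return self.vectors[self.node_index[node]]

    def rows(self, nodes: list[NodeRef]) -> np.ndarray:
        return self.vectors[[self.node_index[n] for n in nodes]]

    # -- persistence ---------------------------------------------------
    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for n, row in zip(self.nodes, self.vectors):
                fh.write(str(n) + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @staticmethod
    def load_tsv(path: str | Path) -> "Embedding":
        nodes, rows = [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                nodes.append(NodeRef.parse(parts[0]))
                rows.append([float(x) for x in parts[1:]])
        vec = np.array(rows, dtype=np.float64)
        return Embedding(nodes, vec, np.zeros_like(vec))

    def save_npy(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.save(str(prefix) + ".vectors.npy", self.vectors)
        np.save(str(prefix) + ".context.npy", self.context_vectors)
        with open(str(prefix) + ".index.json", "w", encoding="utf-8") as fh:
            json.dump([str(n) for n in self.nodes], fh)

    @staticmethod
    def load_npy(prefix: str | Path) -> "Embedding":
        prefix = Path(prefix)
        vec = np.load(str(prefix) + ".vectors.npy")
        ctx = np.load(str(prefix) + ".context.npy")
        with open(str(prefix) + ".index.json", encoding="utf-8") as fh:
            nodes = [NodeRef.parse(s) for s in json.load(fh)]
        return Embedding(nodes, vec, ctx)


def extract_pairs(
    corpus: WalkCorpus, window: int
) -> Iterator[tuple[NodeRef, NodeRef]]:
    """Yield every (center, context) pair within the window radius."""
    if window < 1:
        raise ValueError("window must be >= 1")
    for walk in corpus.walks:
        L = len(walk)
        for i in range(L):
            for j in range(max(0, i - window), min(L, i + window + 1)):
                if j != i:
                    yield walk[i], walk[j]


def sgns_pair_objective(
    f_center: np.ndarray,
    f_context: np.ndarray,
    f_negatives: list[np.ndarray] | np.ndarray,
) -> float:
    """Negative-sampling objective for a single (center, context) pair."""
    def log_sigmoid(x: float) -> float:
        # numerically stable log sigma
        return -np.logaddexp(0.0, -x)

    val = log_sigmoid(float(np.dot(f_center, f_context)))
    for neg in np.atleast_2d(np.asarray(f_negatives, dtype=float)):
        val += log_sigmoid(-float(np.dot(neg, f_center)))
    return float(val)


# ---------------------------------------------------------------------
# numba training kernel
# ---------------------------------------------------------------------

@njit(cache=True)
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    return state * np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True)
def _sgns_train(
    centers: np.ndarray,       # int32 pair centers
    contexts: np.ndarray,      # int32 pair contexts
    syn0: np.ndarray,          # |V| x d float32 center matrix (updated in place)
    syn1: np.ndarray,          # |V| x d float32 context matrix
    neg_cdf: np.ndarray,       # float64 cumulative unigram^0.75 distribution
    negatives: int,
    lr0: float,
    lr_min: float,
    epochs: int,
    seed: int,
) -> np.ndarray:
    n_pairs = centers.shape[0]
    d = syn0.shape[1]
    total = epochs * n_pairs
    state = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    inv = 1.0 / 18446744073709551616.0  # 2**-64
    grad = np.zeros(d, dtype=np.float32)
    objective = np.zeros(epochs)
    t = 0
    for ep in range(epochs):
        obj = 0.0
        for i in range(n_pairs):
            lr = lr0 + (lr_min - lr0) * (t / total)
            c = centers[i]
            ctx = contexts[i]
            for j in range(d):
                grad[j] = 0.0
            for k in range(negatives + 1):
                if k == 0:
                    target = ctx
                    label = 1.0
                else:
                    target = ctx
                    while target == ctx:  # collisions with the true context resampled
                        state = _xorshift(state)
                        r = float(state) * inv
                        target = np.searchsorted(neg_cdf, r)
                        if target >= neg_cdf.shape[0]:
                            target = neg_cdf.shape[0] - 1
                    label = 0.0
                dot = 0.0
                for j in range(d):
                    dot += syn0[c, j] * syn1[target, j]
                if dot > 10.0:
                    dot = 10.0
                elif dot < -10.0:
                    dot = -10.0
                sig = 1.0 / (1.0 + np.exp(-dot))
                if label > 0.5:
                    obj += np.log(sig + 1e-12)
                else:
                    obj += np.log(1.0 - sig + 1e-12)
                g = (label - sig) * lr
                if g > 10.0:
                    g = 10.0
                elif g < -10.0:
                    g = -10.0
                for j in range(d):
                    grad[j] += np.float32(g) * syn1[target, j]
                    syn1[target, j] += np.float32(g) * syn0[c, j]
            for j in range(d):
                syn0[c, j] += grad[j]
            t += 1
        objective[ep] = obj / n_pairs
    return objective


def train_embeddings(corpus: WalkCorpus, params: SGNSParams) -> Embedding:
    """Fit node vectors by stochastic gradient ascent on the SGNS objective.

    Center vectors initialize uniformly in [-0.5/d, 0.5/d] (seeded),
    context vectors at zero.  Negatives are drawn from the corpus unigram
    distribution raised to the 0.75 power.  Deterministic per seed.
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    nodes: list[NodeRef] = []
    index: dict[NodeRef, int] = {}
    counts: list[int] = []
    for walk in corpus.walks:
        for n in walk:
            i = index.get(n)
            if i is None:
                index[n] = len(nodes)
                nodes.append(n)
                counts.append(1)
            else:
                counts[i] += 1
    # deterministic canonical order: sort nodes, remap
    order = sorted(range(len(nodes)), key=lambda i: nodes[i])
    remap = np.empty(len(nodes), dtype=np.int64)
    for new, old in enumerate(order):
        remap[old] = new
    sorted_nodes = [nodes[i] for i in order]
    sorted_counts = np.array([counts[i] for i in order], dtype=np.float64)
    index = {n: i for i, n in enumerate(sorted_nodes)}

    centers_l: list[int] = []
    contexts_l: list[int] = []
    for c, ctx in extract_pairs(corpus, params.window):
        centers_l.append(index[c])
        contexts_l.append(index[ctx])
    if not centers_l:
        raise ValueError("corpus yields no training pairs (all walks length 1?)")
    centers = np.array(centers_l, dtype=np.int32)
    contexts = np.array(contexts_l, dtype=np.int32)

    noise = sorted_counts ** 0.75
    neg_cdf = np.cumsum(noise / noise.sum())
    neg_cdf[-1] = 1.0

    n, d = len(sorted_nodes), params.d
    rng = np.random.default_rng(params.seed)
    syn0 = ((rng.random((n, d)) - 0.5) / d).astype(np.float32)
    syn1 = np.zeros((n, d), dtype=np.float32)

    objective = _sgns_train(
        centers, contexts, syn0, syn1, neg_cdf,
        params.negatives, params.learning_rate, params.min_learning_rate,
        params.epochs, params.seed,
    )
    for ep, val in enumerate(objective, start=1):
        logger.info("SGNS epoch %d/%d: mean objective %.4f", ep, params.epochs, val)
    if not np.all(np.isfinite(syn0)):
        raise FloatingPointError("non-finite values in trained vectors")
    emb = Embedding(
        sorted_nodes, syn0.astype(np.float64), syn1.astype(np.float64)
    )
    emb.epoch_objective = objective  # type: ignore[attr-defined]
    return emb
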