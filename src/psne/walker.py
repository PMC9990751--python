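"""Second-order biased random walks over the heterogeneous network.

The walk is node2vec-style: the probability of stepping from the current
node ``cur`` to a neighbor ``nxt`` depends on where the walk came from
(``prev``) through a search bias pi(prev, nxt) applied to the edge weight,

    pi = 1/p  if nxt == prev            (return)
         1    if nxt is adjacent to prev (common neighbor)
         1/q  otherwise                  (outward)

and the biased scores are normalized so each node's exit probabilities
sum to 1.  The walks over all three merged layers form the corpus the
embedding is trained on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph_model import NodeRef, WeightedGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkParams:
    """Hyperparameters of the biased walk.

    p : return parameter — large p discourages immediate backtracking.
    q : in-out parameter — q > 1 keeps the walk local (BFS-like),
        q < 1 pushes it outward (DFS-like).
    """

    p: float = 1.0
    q: float = 1.0
    num_walks_per_node: int = 10
    walk_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 1 or self.num_walks_per_node < 1:
            raise ValueError("walk_length and num_walks_per_node must be >= 1")


@dataclass
class WalkCorpus:
    """Random-walk node sequences plus the parameters that produced them."""

    walks: list[list[NodeRef]]
    provenance: WalkParams = field(default_factory=WalkParams)

    def __len__(self) -> int:
        return len(self.walks)

    def save(self, path) -> None:
        """One walk per line, space-separated node ids."""
        with open(path, "w", encoding="utf-8") as fh:
            for walk in self.walks:
                fh.write(" ".join(str(n) for n in walk) + "\n")

    @staticmethod
    def load(path) -> "WalkCorpus":
        walks = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                toks = line.split()
                if toks:
                    walks.append([NodeRef.parse(t) for t in toks])
        return WalkCorpus(walks)


def search_bias(d_prev_next: int, p: float, q: float) -> float:
    """Bias pi for a candidate at clamped distance {0,1,2} from prev."""
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    if d_prev_next == 0:
        return 1.0 / p
    if d_prev_next == 1:
        return 1.0
    if d_prev_next == 2:
        return 1.0 / q
    raise ValueError(f"distance must be in {{0,1,2}}, got {d_prev_next}")


def transition_distribution(
    G: WeightedGraph,
    prev: NodeRef | None,
    cur: NodeRef,
    params: WalkParams,
) -> dict[NodeRef, float]:
    """Normalized next-step distribution over the neighbors of ``cur``.

    With ``prev is None`` (first step of a walk) the distribution is the
    plain first-order one, proportional to edge weight.
    """
    nbrs = G.neighbors(cur)
    if not nbrs:
        raise ValueError(f"{cur} is isolated; no transition exists")
    if prev is None:
        total = sum(nbrs.values())
        return {v: w / total for v, w in nbrs.items()}
    prev_nbrs = G.neighbors(prev)
    scores: dict[NodeRef, float] = {}
    for v, w in nbrs.items():
        if v == prev:
            d = 0
        elif v in prev_nbrs:
            d = 1
        else:
            d = 2
        scores[v] = search_bias(d, params.p, params.q) * w
    total = sum(scores.values())
    return {v: s / total for v, s in scores.items()}


class _IndexedGraph:
    """Array view of a WeightedGraph for fast repeated sampling."""

    def __init__(self, G: WeightedGraph) -> None:
        self.nodes = G.nodes
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.nbrs: list[np.ndarray] = []
        self.weights: list[np.ndarray] = []
        self.nbr_sets: list[set[int]] = []
        for n in self.nodes:
            items = list(G.neighbors(n).items())
            idx = np.array([self.index[v] for v, _ in items], dtype=np.int64)
            w = np.array([w for _, w in items], dtype=float)
            self.nbrs.append(idx)
            self.weights.append(w)
            self.nbr_sets.append(set(idx.tolist()))


def _step(
    ig: _IndexedGraph,
    prev: int,
    cur: int,
    p: float,
    q: float,
    rng: np.random.Generator,
) -> int:
    nbrs = ig.nbrs[cur]
    w = ig.weights[cur]
    if prev >= 0:
        prev_set = ig.nbr_sets[prev]
        bias = np.empty_like(w)
        for j, v in enumerate(nbrs):
            if v == prev:
                bias[j] = 1.0 / p
            elif v in prev_set:
                bias[j] = 1.0
            else:
                bias[j] = 1.0 / q
        w = w * bias
    cdf = np.cumsum(w)
    r = rng.random() * cdf[-1]
    return int(nbrs[np.searchsorted(cdf, r, side="right")])


def generate_walks(G: WeightedGraph, params: WalkParams) -> WalkCorpus:
    """Run ``num_walks_per_node`` biased walks from every node.

    Node order is reshuffled each epoch with the seeded RNG.  A walk that
    starts at an isolated node has length 1.  Fully reproducible given
    (graph, params, seed).
    """
    if len(G) == 0:
        raise ValueError("graph is empty")
    ig = _IndexedGraph(G)
    rng = np.random.default_rng(params.seed)
    n = len(ig.nodes)
    walks: list[list[NodeRef]] = []
    for _ in range(params.num_walks_per_node):
        order = rng.permutation(n)
        for start in order:
            walk = [int(start)]
            prev = -1
            cur = int(start)
            while len(walk) < params.walk_length:
                if len(ig.nbrs[cur]) == 0:
                    break
                nxt = _step(ig, prev, cur, params.p, params.q, rng)
                walk.append(nxt)
                prev, cur = cur, nxt
            walks.append([ig.nodes[i] for i in walk])
    logger.info(
        "generated %d walks over %d nodes (p=%g, q=%g, length=%d)",
        len(walks), n, params.p, params.q, params.walk_length,
    )
    return WalkCorpus(walks, provenance=params)
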