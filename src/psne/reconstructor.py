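"""Enhanced-network reconstruction from embedding cosine similarities.

After embedding, the within-layer networks are rebuilt: for each disease
(resp. gene) the k most cosine-similar diseases (genes) are linked, the
per-node selections are union-symmetrized, and the cosine score becomes
the edge weight (negative cosines clamped to zero so the downstream
transition matrix stays non-negative).  The reconstructed disease layer
H_I and gene layer H_N are then assembled with the original bipartite
associations H_G into the two-layer block network

    D = [[H_I,   H_G],
         [H_G^T, H_N]]

on which the restart walk runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .embedder import Embedding
from .graph_model import NodeRef, WeightedGraph, save_edge_list

logger = logging.getLogger(__name__)


def cosine(s_i: np.ndarray, s_j: np.ndarray) -> float:
    """Cosine similarity of two embedding vectors, in [-1, 1]."""
    ni = float(np.linalg.norm(s_i))
    nj = float(np.linalg.norm(s_j))
    if ni == 0.0 or nj == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.dot(s_i, s_j) / (ni * nj))


def enhanced_network(
    emb: Embedding,
    nodes: list[NodeRef],
    k: int = 10,
    clamp_negative: bool = True,
    binarize: bool = False,
) -> WeightedGraph:
    """Rebuild a within-layer network from embedding similarities.

    Each node keeps its ``k`` most cosine-similar peers (ties broken by
    node-id order); selections are union-symmetrized.  Edge weight is the
    cosine score unless ``binarize``; negative scores clamp to 0 when
    ``clamp_negative`` and zero-weight edges are dropped.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the layer size {n}")
    if k < 1:
        raise ValueError("k must be positive")
    V = emb.rows(nodes)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding vector in layer")
    U = V / norms[:, None]
    C = U @ U.T
    np.clip(C, -1.0, 1.0, out=C)

    g = WeightedGraph(nodes)
    for i in range(n):
        scores = C[i].copy()
        scores[i] = -np.inf
        # ties -> lower node id; nodes are pre-sorted so index order = id order
        best = sorted(range(n), key=lambda j: (-scores[j], j))[:k]
        for j in best:
            w = float(C[i, j])
            if clamp_negative and w < 0:
                w = 0.0
            if binarize:
                w = 1.0 if w > 0 else 0.0
            if w != 0.0:  # zero-weight edges dropped
                g.add_edge(nodes[i], nodes[j], w)
    logger.info("enhanced network: %d nodes, %d edges (k=%d)", n, g.n_edges, k)
    return g


@dataclass
class TwoLayerNetwork:
    """Block structure of the disease/gene two-layer network.

    ``H_I`` is disease x disease, ``H_N`` gene x gene, ``H_G`` disease x
    gene; ``H_E`` is always the transpose of ``H_G``.  Node orderings fix
    the row/column semantics of every block.
    """

    diseases: list[NodeRef]
    genes: list[NodeRef]
    H_I: sp.csr_matrix
    H_N: sp.csr_matrix
    H_G: sp.csr_matrix
    disease_index: dict[NodeRef, int] = field(init=False)
    gene_index: dict[NodeRef, int] = field(init=False)

    def __post_init__(self) -> None:
        nd, ng = len(self.diseases), len(self.genes)
        self.H_I = sp.csr_matrix(self.H_I)
        self.H_N = sp.csr_matrix(self.H_N)
        self.H_G = sp.csr_matrix(self.H_G)
        if self.H_I.shape != (nd, nd):
            raise ValueError(f"H_I shape {self.H_I.shape} != ({nd}, {nd})")
        if self.H_N.shape != (ng, ng):
            raise ValueError(f"H_N shape {self.H_N.shape} != ({ng}, {ng})")
        if self.H_G.shape != (nd, ng):
            raise ValueError(f"H_G shape {self.H_G.shape} != ({nd}, {ng})")
        if (self.H_I.min() if self.H_I.nnz else 0) < 0 or (
            self.H_N.min() if self.H_N.nnz else 0
        ) < 0:
            raise ValueError("within-layer blocks must be non-negative")
        if (abs(self.H_I - self.H_I.T)).max() > 1e-10 if self.H_I.nnz else False:
            raise ValueError("H_I must be symmetric")
        if (abs(self.H_N - self.H_N.T)).max() > 1e-10 if self.H_N.nnz else False:
            raise ValueError("H_N must be symmetric")
        self.disease_index = {d: i for i, d in enumerate(self.diseases)}
        self.gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def H_E(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.H_G.T)

    @property
    def n_nodes(self) -> int:
        return len(self.diseases) + len(self.genes)

    @property
    def node_order(self) -> list[NodeRef]:
        return self.diseases + self.genes

    def dense_block_matrix(self) -> np.ndarray:
        """Materialize the full block matrix D (small networks only)."""
        top = np.hstack([self.H_I.toarray(), self.H_G.toarray()])
        bot = np.hstack([self.H_E.toarray(), self.H_N.toarray()])
        return np.vstack([top, bot])

    # -- persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, mat, rows, cols in (
            ("H_I", self.H_I, self.diseases, self.diseases),
            ("H_N", self.H_N, self.genes, self.genes),
            ("H_G", self.H_G, self.diseases, self.genes),
        ):
            coo = sp.coo_matrix(mat)
            with open(directory / f"{name}.tsv", "w", encoding="utf-8") as fh:
                for i, j, w in sorted(zip(coo.row, coo.col, coo.data)):
                    fh.write(f"{rows[i]}\t{cols[j]}\t{float(w)!r}\n")
        with open(directory / "meta.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "diseases": [str(d) for d in self.diseases],
                    "genes": [str(g) for g in self.genes],
                },
                fh,
            )

    @staticmethod
    def load(directory: str | Path) -> "TwoLayerNetwork":
        directory = Path(directory)
        with open(directory / "meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        diseases = [NodeRef.parse(s) for s in meta["diseases"]]
        genes = [NodeRef.parse(s) for s in meta["genes"]]
        d_idx = {d: i for i, d in enumerate(diseases)}
        g_idx = {g: i for i, g in enumerate(genes)}
        mats = {}
        for name, ridx, cidx in (
            ("H_I", d_idx, d_idx), ("H_N", g_idx, g_idx), ("H_G", d_idx, g_idx)
        ):
            rows, cols, vals = [], [], []
            with open(directory / f"{name}.tsv", encoding="utf-8") as fh:
                for line in fh:
                    a, b, w = line.rstrip("\n").split("\t")
                    rows.append(ridx[NodeRef.parse(a)])
                    cols.append(cidx[NodeRef.parse(b)])
                    vals.append(float(w))
            mats[name] = sp.csr_matrix(
                (vals, (rows, cols)), shape=(len(ridx), len(cidx))
            )
        return TwoLayerNetwork(diseases, genes, mats["H_I"], mats["H_N"], mats["H_G"])


def graph_to_matrix(
    g: WeightedGraph, rows: list[NodeRef], cols: list[NodeRef]
) -> sp.csr_matrix:
    """Adjacency of ``g`` restricted to the given row/column orderings."""
    ridx = {n: i for i, n in enumerate(rows)}
    cidx = {n: i for i, n in enumerate(cols)}
    ii, jj, vv = [], [], []
    for u, v, w in g.edges():
        for a, b in ((u, v), (v, u)):
            if a in ridx and b in cidx:
                ii.append(ridx[a])
                jj.append(cidx[b])
                vv.append(w)
    return sp.csr_matrix((vv, (ii, jj)), shape=(len(rows), len(cols)))


def assemble_two_layer(
    H_I: WeightedGraph | sp.spmatrix | np.ndarray,
    H_N: WeightedGraph | sp.spmatrix | np.ndarray,
    H_G: WeightedGraph | sp.spmatrix | np.ndarray,
    diseases: list[NodeRef],
    genes: list[NodeRef],
) -> TwoLayerNetwork:
    """Assemble the two-layer block network from layer graphs or matrices.

    H_G must be the original (filtered) disease-gene associations; only
    the within-layer blocks come from the reconstruction.
    """
    if isinstance(H_I, WeightedGraph):
        H_I = graph_to_matrix(H_I, diseases, diseases)
    if isinstance(H_N, WeightedGraph):
        H_N = graph_to_matrix(H_N, genes, genes)
    if isinstance(H_G, WeightedGraph):
        H_G = graph_to_matrix(H_G, diseases, genes)
    return TwoLayerNetwork(list(diseases), list(genes), H_I, H_N, H_G)


def save_enhanced(g: WeightedGraph, path: str | Path) -> None:
    """Weighted TSV edge-list export of an enhanced network."""
    save_edge_list(g, path)
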