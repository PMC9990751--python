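"""Node/edge data model, edge-list I/O, and input-network assembly rules.

The heterogeneous network couples three layers: a disease-disease
similarity layer, a gene-gene (protein interaction) layer, and a bipartite
disease-gene association layer.  Every node is identified by a
:class:`NodeRef` — a ``(namespace, local_id)`` pair where the namespace is
``"disease"`` or ``"gene"`` — and every edge carries weight 1 by
convention (raw similarity scores are consumed only for neighbor
selection, never as propagation weights).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
GENE = "gene"
_NAMESPACES = (DISEASE, GENE)


class NodeRef(NamedTuple):
    """Typed node identifier: a namespace plus an opaque local id."""

    namespace: str
    local_id: str

    def __str__(self) -> str:  # display form "disease:ID" / "gene:ID"
        return f"{self.namespace}:{self.local_id}"

    @classmethod
    def parse(cls, text: str) -> "NodeRef":
        ns, _, local = text.partition(":")
        if ns not in _NAMESPACES or not local:
            raise ValueError(f"cannot parse node reference {text!r}")
        return cls(ns, local)


def disease(local_id: str) -> NodeRef:
    return NodeRef(DISEASE, str(local_id))


def gene(local_id: str) -> NodeRef:
    return NodeRef(GENE, str(local_id))


class WeightedGraph:
    """Undirected weighted graph over :class:`NodeRef` nodes.

    Nodes are kept in insertion order; edges are stored once per direction
    in an adjacency dict.  Default edge weight is 1.  Self-loops are
    rejected at construction (the propagator installs its own repair
    loops on matrices, never here).
    """

    def __init__(self, nodes: Iterable[NodeRef] = ()) -> None:
        self._adj: dict[NodeRef, dict[NodeRef, float]] = {}
        for n in nodes:
            self.add_node(n)

    # -- construction -------------------------------------------------
    def add_node(self, node: NodeRef) -> None:
        self._adj.setdefault(node, {})

    def add_edge(self, u: NodeRef, v: NodeRef, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u}")
        self.add_node(u)
        self.add_node(v)
        # duplicate edges collapse keeping the max weight
        old = self._adj[u].get(v)
        if old is None or weight > old:
            self._adj[u][v] = weight
            self._adj[v][u] = weight

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list[NodeRef]:
        return list(self._adj)

    def __contains__(self, node: NodeRef) -> bool:
        return node in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def neighbors(self, node: NodeRef) -> dict[NodeRef, float]:
        return self._adj[node]

    def degree(self, node: NodeRef) -> int:
        return len(self._adj[node])

    def weight(self, u: NodeRef, v: NodeRef) -> float:
        return self._adj[u][v]

    def has_edge(self, u: NodeRef, v: NodeRef) -> bool:
        return u in self._adj and v in self._adj[u]

    def edges(self) -> Iterator[tuple[NodeRef, NodeRef, float]]:
        seen: set[tuple[NodeRef, NodeRef]] = set()
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                key = (u, v) if u <= v else (v, u)
                if key not in seen:
                    seen.add(key)
                    yield key[0], key[1], w

    def subgraph(self, keep: set[NodeRef]) -> "WeightedGraph":
        """Graph induced on ``keep`` (insertion order preserved)."""
        g = WeightedGraph(n for n in self._adj if n in keep)
        for u, v, w in self.edges():
            if u in keep and v in keep:
                g.add_edge(u, v, w)
        return g

    def copy(self) -> "WeightedGraph":
        return self.subgraph(set(self._adj))

    def drop_isolated(self) -> "WeightedGraph":
        keep = {n for n, nbrs in self._adj.items() if nbrs}
        dropped = len(self._adj) - len(keep)
        if dropped:
            logger.warning("dropping %d isolated node(s)", dropped)
        return self.subgraph(keep)

    def to_adjacency(self, order: list[NodeRef]) -> np.ndarray:
        """Dense adjacency in the given node order (tests / small nets)."""
        idx = {n: i for i, n in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for u, v, w in self.edges():
            if u in idx and v in idx:
                a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
        return a


class HetNet:
    """The three coupled layers with a shared typed node registry."""

    def __init__(self, dd: WeightedGraph, gg: WeightedGraph, dg: WeightedGraph) -> None:
        self.dd = dd
        self.gg = gg
        self.dg = dg
        self.diseases: list[NodeRef] = sorted(
            n for n in dg.nodes if n.namespace == DISEASE
        )
        genes = {n for n in dg.nodes if n.namespace == GENE}
        genes.update(gg.nodes)
        self.genes: list[NodeRef] = sorted(genes)
        self.validate()

    def validate(self) -> None:
        dg_genes = {n for n in self.dg.nodes if n.namespace == GENE}
        missing = dg_genes - set(self.gg.nodes)
        if missing:
            raise ValueError(
                f"{len(missing)} associated gene(s) absent from the gene layer"
            )
        bad_dd = [n for n in self.dd.nodes if n.namespace != DISEASE]
        bad_gg = [n for n in self.gg.nodes if n.namespace != GENE]
        if bad_dd or bad_gg:
            raise ValueError("layer contains nodes of the wrong namespace")

    def gene_set(self, d: NodeRef) -> frozenset[NodeRef]:
        """Genes associated with disease ``d`` in the bipartite layer."""
        if d not in self.dg:
            return frozenset()
        return frozenset(self.dg.neighbors(d))

    def merged(self) -> WeightedGraph:
        """All three layers merged into one graph (the walk substrate)."""
        g = WeightedGraph()
        for layer in (self.dd, self.gg, self.dg):
            for n in layer.nodes:
                g.add_node(n)
            for u, v, w in layer.edges():
                g.add_edge(u, v, w)
        return g

    def summary(self) -> dict[str, int]:
        return {
            "n_diseases": len(self.diseases),
            "n_genes": len(self.genes),
            "dd_edges": self.dd.n_edges,
            "gg_edges": self.gg.n_edges,
            "dg_edges": self.dg.n_edges,
        }


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def load_edge_list(path: str | Path, namespaces: tuple[str, str]) -> WeightedGraph:
    """Read a TSV edge list (source, target[, weight]) into a graph.

    ``namespaces`` assigns the namespace of the first and second column.
    Lines starting with ``#`` are comments.  Missing weight column means
    weight 1; duplicate edges collapse keeping the max weight.
    """
    ns_u, ns_v = namespaces
    for ns in (ns_u, ns_v):
        if ns not in _NAMESPACES:
            raise ValueError(f"unknown namespace {ns!r}")
    g = WeightedGraph()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate space-separated files
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            u = NodeRef(ns_u, parts[0].strip())
            v = NodeRef(ns_v, parts[1].strip())
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: bad weight at line {lineno}: {parts[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if u == v:
                logger.warning("%s: self-loop at line %d dropped", path, lineno)
                continue
            g.add_edge(u, v, w)
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: empty edge list")
    logger.info("%s: read %d rows -> %d nodes, %d edges", path, n_rows, len(g), g.n_edges)
    return g


def save_edge_list(g: WeightedGraph, path: str | Path) -> None:
    rows = [(u.local_id, v.local_id, w) for u, v, w in sorted(g.edges())]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def load_similarity_table(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a dense similarity matrix TSV with header row and index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity table is not square: {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


# ---------------------------------------------------------------------
# Assembly rules
# ---------------------------------------------------------------------

def filter_genes_to_interactome(
    dg: WeightedGraph, gg: WeightedGraph
) -> WeightedGraph:
    """Drop associations to genes absent from the protein network.

    Diseases left with zero associated genes are dropped as well.
    """
    gg_genes = set(gg.nodes)
    out = WeightedGraph()
    kept = dropped = 0
    for u, v, w in dg.edges():
        d, g = (u, v) if u.namespace == DISEASE else (v, u)
        if g in gg_genes:
            out.add_edge(d, g, w)
            kept += 1
        else:
            dropped += 1
    logger.info(
        "interactome filter: kept %d associations, dropped %d", kept, dropped
    )
    if kept == 0:
        logger.warning("interactome filter removed every association")
    return out


def dedup_diseases(
    dg: WeightedGraph, seed: int
) -> tuple[WeightedGraph, dict[NodeRef, NodeRef]]:
    """Among diseases with identical gene sets keep exactly one (seeded).

    Returns the reduced bipartite graph and a dropped->kept mapping.
    """
    rng = np.random.default_rng(seed)
    by_set: dict[frozenset[NodeRef], list[NodeRef]] = {}
    for n in dg.nodes:
        if n.namespace == DISEASE:
            by_set.setdefault(frozenset(dg.neighbors(n)), []).append(n)
    mapping: dict[NodeRef, NodeRef] = {}
    keep: set[NodeRef] = set()
    for gene_set, group in sorted(by_set.items(), key=lambda kv: sorted(kv[1])):
        group = sorted(group)
        chosen = group[int(rng.integers(len(group)))]
        keep.add(chosen)
        for other in group:
            if other != chosen:
                mapping[other] = chosen
    out = WeightedGraph()
    for u, v, w in dg.edges():
        d = u if u.namespace == DISEASE else v
        g = v if u.namespace == DISEASE else u
        if d in keep:
            out.add_edge(d, g, w)
    if mapping:
        logger.info("deduplicated %d disease(s) with identical gene sets", len(mapping))
    return out, mapping


def knn_sparsify(
    sim: np.ndarray, labels: list[str], k: int, namespace: str = DISEASE
) -> WeightedGraph:
    """kNN-sparsify a dense similarity matrix into a uniform-weight graph.

    For each node the ``k`` highest-similarity peers are kept (ties broken
    by node-id order), the selections are union-symmetrized, and every
    retained edge gets weight 1.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError(f"similarity table is not square: {sim.shape}")
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    if not np.allclose(sim, sim.T, atol=1e-8):
        raise ValueError("similarity table is not symmetric")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nodes {n}")
    if k < 1:
        raise ValueError("k must be positive")

    # deterministic tie-break: sort by (-similarity, label)
    label_order = np.argsort(np.argsort(labels))  # rank of each label
    nodes = [NodeRef(namespace, lab) for lab in labels]
    g = WeightedGraph(sorted(nodes))
    for i in range(n):
        scores = sim[i].copy()
        scores[i] = -np.inf  # diagonal ignored
        order = sorted(range(n), key=lambda j: (-scores[j], label_order[j]))
        for j in order[:k]:
            g.add_edge(nodes[i], nodes[j], 1.0)
    return g


def build_hetnet(
    dg: WeightedGraph,
    gg: WeightedGraph,
    dd: WeightedGraph,
    seed: int = 0,
) -> tuple[HetNet, dict]:
    """Assemble the heterogeneous network applying the input filters.

    Order of operations: restrict associations to interactome genes, then
    deduplicate diseases with identical gene sets, then restrict the
    disease-disease layer to surviving diseases.  Returns the network and
    a statistics dict (the JSON sidecar payload).
    """
    dg_f = filter_genes_to_interactome(dg, gg)
    if len(dg_f) == 0:
        raise ValueError("no associations left after interactome filtering")
    dg_f, dedup_map = dedup_diseases(dg_f, seed)
    surviving = {n for n in dg_f.nodes if n.namespace == DISEASE}
    dd_f = dd.subgraph(set(dd.nodes) & (surviving | set()))
    dd_f = dd_f.subgraph(surviving)
    net = HetNet(dd_f, gg, dg_f)
    stats = {
        "associations_in": dg.n_edges,
        "associations_kept": dg_f.n_edges,
        "diseases_deduped": len(dedup_map),
        "dedup_map": {str(a): str(b) for a, b in sorted(dedup_map.items())},
        **net.summary(),
    }
    logger.info("heterogeneous network assembled: %s", net.summary())
    return net, stats
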