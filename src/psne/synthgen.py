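"""Synthetic heterogeneous networks with planted disease-module structure.

The generator emulates the shape of the real inputs — a bipartite
disease-gene association layer coupled to a protein-interaction-like gene
layer and a kNN-sparsified disease-similarity layer — with a planted
partition: genes split into modules, gene-gene edges drawn densely inside
modules and sparsely between them (a stochastic block model), and each
disease drawing its associations from a single home module with a small
rewiring noise.  All edge weights are 1 and everything is seeded, so the
whole pipeline plus the held-out-association recovery property can be
tested without external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .graph_model import (
    DISEASE,
    GENE,
    HetNet,
    NodeRef,
    WeightedGraph,
    disease,
    gene,
    knn_sparsify,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    n_diseases: int = 100
    n_genes: int = 500
    n_modules: int = 10
    p_gg_in: float = 0.3
    p_gg_out: float = 0.01
    assoc_per_disease: int = 8
    assoc_noise: float = 0.1
    dd_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_modules:
            raise ValueError("need at least one gene per module")
        if not self.p_gg_in > self.p_gg_out:
            raise ValueError("p_gg_in must exceed p_gg_out")
        if not 0.0 <= self.assoc_noise < 1.0:
            raise ValueError("assoc_noise must lie in [0, 1)")
        if self.assoc_per_disease < 1 or self.n_diseases < 1:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    disease_module: dict[NodeRef, int]
    gene_module: dict[NodeRef, int]
    associations: dict[NodeRef, frozenset[NodeRef]]  # full, pre-holdout

    def save(self, path) -> None:
        payload = {
            "disease_module": {str(d): m for d, m in self.disease_module.items()},
            "gene_module": {str(g): m for g, m in self.gene_module.items()},
            "associations": {
                str(d): sorted(str(g) for g in gs)
                for d, gs in self.associations.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def load(path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return GroundTruth(
            {NodeRef.parse(k): v for k, v in payload["disease_module"].items()},
            {NodeRef.parse(k): v for k, v in payload["gene_module"].items()},
            {
                NodeRef.parse(k): frozenset(NodeRef.parse(g) for g in v)
                for k, v in payload["associations"].items()
            },
        )


def _jaccard_similarity(
    diseases: list[NodeRef], assoc: dict[NodeRef, frozenset[NodeRef]]
) -> np.ndarray:
    n = len(diseases)
    sim = np.zeros((n, n))
    sets = [assoc[d] for d in diseases]
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            sim[i, j] = sim[j, i] = len(sets[i] & sets[j]) / union if union else 0.0
    return sim


def generate(config: SynthConfig) -> tuple[HetNet, GroundTruth]:
    """Draw one synthetic heterogeneous network plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n_digits_g = len(str(config.n_genes - 1))
    n_digits_d = len(str(config.n_diseases - 1))
    genes = [gene(f"g{str(i).zfill(n_digits_g)}") for i in range(config.n_genes)]
    diseases = [disease(f"d{str(i).zfill(n_digits_d)}") for i in range(config.n_diseases)]

    # genes partitioned into modules as evenly as possible
    gene_module = {g: i % config.n_modules for i, g in enumerate(genes)}
    module_genes: dict[int, list[NodeRef]] = {m: [] for m in range(config.n_modules)}
    for g, m in gene_module.items():
        module_genes[m].append(g)
    if any(not gl for gl in module_genes.values()):
        raise ValueError("a module has no genes")

    # gene-gene layer: planted-partition (stochastic block model)
    gg = WeightedGraph(genes)
    for i in range(config.n_genes):
        for j in range(i + 1, config.n_genes):
            same = gene_module[genes[i]] == gene_module[genes[j]]
            p = config.p_gg_in if same else config.p_gg_out
            if rng.random() < p:
                gg.add_edge(genes[i], genes[j], 1.0)

    # disease-gene layer: each disease draws from its home module, with
    # a noise fraction rewired to uniformly random genes
    disease_module = {
        d: int(rng.integers(config.n_modules)) for d in diseases
    }
    associations: dict[NodeRef, frozenset[NodeRef]] = {}
    dg = WeightedGraph()
    for d in diseases:
        home = module_genes[disease_module[d]]
        size = min(config.assoc_per_disease, len(home))
        picked = [home[i] for i in rng.choice(len(home), size, replace=False)]
        n_rewire = int(
            rng.binomial(len(picked), config.assoc_noise)
        )
        if n_rewire:
            drop_idx = rng.choice(len(picked), n_rewire, replace=False)
            keep = [g for i, g in enumerate(picked) if i not in set(drop_idx.tolist())]
            pool = [g for g in genes if g not in set(keep)]
            new = [pool[i] for i in rng.choice(len(pool), n_rewire, replace=False)]
            picked = keep + new
        associations[d] = frozenset(picked)
        for g in picked:
            dg.add_edge(d, g, 1.0)

    # disease-disease layer: kNN on association-set overlap
    sim = _jaccard_similarity(diseases, associations)
    dd = knn_sparsify(sim, [d.local_id for d in diseases], config.dd_k, namespace=DISEASE)

    net = HetNet(dd, gg, dg)
    truth = GroundTruth(disease_module, gene_module, associations)
    logger.info("synthetic network: %s (config %s)", net.summary(), asdict(config))
    return net, truth


def holdout(
    truth: GroundTruth,
    fraction: float,
    seed: int,
    net: HetNet,
) -> tuple[HetNet, dict[NodeRef, frozenset[NodeRef]]]:
    """Hide a fraction of each disease's associations; return the observed
    network and the hidden recovery targets.

    At least one association per disease is always kept.  Diseases with a
    single association contribute nothing to the hidden set.  The gene and
    disease layers are taken unchanged from ``net``.
    """
    gg, dd = net.gg, net.dd
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    observed_dg = WeightedGraph()
    hidden: dict[NodeRef, frozenset[NodeRef]] = {}
    for d in sorted(truth.associations):
        genes_d = sorted(truth.associations[d])
        n_hide = min(int(round(fraction * len(genes_d))), len(genes_d) - 1)
        if n_hide <= 0:
            hidden[d] = frozenset()
            if len(genes_d) == 1:
                logger.info("%s has a single association; nothing hidden", d)
            for g in genes_d:
                observed_dg.add_edge(d, g, 1.0)
            continue
        hide_idx = set(rng.choice(len(genes_d), n_hide, replace=False).tolist())
        hid = frozenset(genes_d[i] for i in hide_idx)
        hidden[d] = hid
        for i, g in enumerate(genes_d):
            if i not in hide_idx:
                observed_dg.add_edge(d, g, 1.0)
    observed = HetNet(dd, gg, observed_dg)
    return observed, hidden
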