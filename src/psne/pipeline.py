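"""End-to-end orchestration: staged runs, caching, and evaluation drivers.

A run is described by a :class:`RunConfig` (serializable to YAML) and
executed stage by stage into an output directory::

    out_dir/00_input      synthetic inputs (simulate stage only)
    out_dir/01_net        assembled heterogeneous network + filter stats
    out_dir/02_walks      walk corpus
    out_dir/03_emb        trained embedding
    out_dir/04_twolayer   enhanced blocks and orderings
    out_dir/05_rank       one ranked TSV per disease
    out_dir/06_eval       metrics TSV + JSON summary

Stage seeds are derived deterministically from the single global seed via
``numpy.random.SeedSequence``, so a whole run is reproducible from the
config file alone.  Finished stages are reused unless ``force``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluator, graph_model, synthgen
from .embedder import Embedding
from .estimator import PSNE, DegreeBaseline, derive_seeds
from .evaluator import CVSplit, EvalResult, EvalSpec
from .graph_model import DISEASE, GENE, HetNet, NodeRef, WeightedGraph
from .propagator import RankedGeneList
from .reconstructor import TwoLayerNetwork

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build", "embed", "reconstruct", "predict", "evaluate")


@dataclass
class RunConfig:
    out_dir: str = "psne_run"
    seed: int = 0
    # inputs: either the three edge lists, or a synthetic config
    dg_path: str | None = None
    gg_path: str | None = None
    dd_path: str | None = None
    dd_dense: bool = False          # dd_path points to a dense similarity table
    dd_knn_k: int = 5
    synth: dict | None = None       # SynthConfig overrides; enables simulate
    holdout_fraction: float | None = None
    # stage hyperparameters (PSNE estimator kwargs)
    method: dict = field(default_factory=dict)
    # evaluation
    cv_folds: int = 5
    k_list: tuple[int, ...] = evaluator.DEFAULT_K_LIST

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "k_list" in data and data["k_list"] is not None:
            data["k_list"] = tuple(data["k_list"])
        return RunConfig(**data)


# ---------------------------------------------------------------------
# evaluation drivers
# ---------------------------------------------------------------------

def _fold_scores(
    est, net: HetNet, split_items
) -> dict[tuple[NodeRef, int], dict[NodeRef, float]]:
    """Score every (disease, fold) on an already-fitted estimator."""
    results: dict[tuple[NodeRef, int], dict[NodeRef, float]] = {}
    nd = len(est.two_layer_.diseases)
    gene_order = est.two_layer_.genes
    for d, fold_idx, train, test in split_items:
        if d not in est.two_layer_.disease_index:
            continue
        score = est.score_nodes(d, known_genes=train)
        gene_scores = {
            g: float(score.q[nd + i])
            for i, g in enumerate(gene_order)
            if g not in train
        }
        results[(d, fold_idx)] = gene_scores
    return results


def evaluate_holdout(
    observed: HetNet,
    hidden: dict[NodeRef, frozenset[NodeRef]],
    method_params: dict | None = None,
    spec: EvalSpec | None = None,
    estimator=None,
) -> EvalResult:
    """Recovery evaluation: train on the observed network, test on the
    hidden associations (one fold per disease)."""
    spec = spec or EvalSpec()
    est = estimator
    if est is None:
        est = PSNE(**(method_params or {}))
    if not hasattr(est, "transfer_") and not hasattr(est, "scores_"):
        est.fit(observed)
    folds = {
        d: [(observed.gene_set(d), frozenset(h))]
        for d, h in sorted(hidden.items())
        if h and d in observed.dg
    }
    split = CVSplit(folds, 1, 0)
    if isinstance(est, DegreeBaseline):
        results = {}
        for d, fold_idx, train, test in split.items():
            ranked = est.rank_genes(d, exclude=set(train))
            results[(d, fold_idx)] = ranked.scores()
    else:
        results = _fold_scores(est, observed, split.items())
    return evaluator.evaluate(results, spec, split, set(observed.genes))


def evaluate_cv(
    net: HetNet,
    method_params: dict | None = None,
    folds: int = 5,
    spec: EvalSpec | None = None,
    seed: int = 0,
    estimator_factory=None,
) -> EvalResult:
    """Full cross-validation: the estimator is refitted for every fold on a
    network with that fold's test associations removed."""
    spec = spec or EvalSpec()
    split = evaluator.cv_split(net.dg, folds, seed)
    results: dict[tuple[NodeRef, int], dict[NodeRef, float]] = {}
    for fold_idx in range(folds):
        dg_f = WeightedGraph()
        fold_items = []
        for d, fl in split.folds.items():
            if fold_idx >= len(fl):
                continue
            train, test = fl[fold_idx]
            for g in train:
                dg_f.add_edge(d, g, 1.0)
            if train and test:
                fold_items.append((d, fold_idx, train, test))
        if not fold_items:
            continue
        net_f = HetNet(net.dd.subgraph({n for n in dg_f.nodes if n.namespace == DISEASE}),
                       net.gg, dg_f)
        if estimator_factory is not None:
            est = estimator_factory()
        else:
            est = PSNE(**(method_params or {}))
        est.fit(net_f)
        if isinstance(est, DegreeBaseline):
            for d, fi, train, test in fold_items:
                ranked = est.rank_genes(d, exclude=set(train))
                results[(d, fi)] = ranked.scores()
        else:
            results.update(_fold_scores(est, net_f, fold_items))
    return evaluator.evaluate(results, spec, split, set(net.genes))


# ---------------------------------------------------------------------
# staged run
# ---------------------------------------------------------------------

def _load_inputs(cfg: RunConfig, out: Path) -> tuple[WeightedGraph, WeightedGraph, WeightedGraph]:
    sim_dir = out / "00_input"
    dg_path = cfg.dg_path or sim_dir / "dg.tsv"
    gg_path = cfg.gg_path or sim_dir / "gg.tsv"
    dd_path = cfg.dd_path or sim_dir / "dd.tsv"
    dg = graph_model.load_edge_list(dg_path, (DISEASE, GENE))
    gg = graph_model.load_edge_list(gg_path, (GENE, GENE))
    if cfg.dd_dense:
        sim, labels = graph_model.load_similarity_table(dd_path)
        dd = graph_model.knn_sparsify(sim, labels, cfg.dd_knn_k)
    else:
        dd = graph_model.load_edge_list(dd_path, (DISEASE, DISEASE))
    return dg, gg, dd


def run_pipeline(
    cfg: RunConfig,
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> Path:
    """Execute the requested stages in order; reuse finished artifacts.

    Raises if a requested stage's upstream artifact is missing, naming the
    stage to run first.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    seeds = dict(zip(
        ("simulate", "build", "method", "cv"), derive_seeds(cfg.seed, 4)
    ))

    if "simulate" in stages:
        sim_dir = out / "00_input"
        if force or not (sim_dir / "dg.tsv").exists():
            sim_dir.mkdir(exist_ok=True)
            synth_cfg = synthgen.SynthConfig(**{"seed": seeds["simulate"], **(cfg.synth or {})})
            net, truth = synthgen.generate(synth_cfg)
            if cfg.holdout_fraction:
                net, hidden = synthgen.holdout(
                    truth, cfg.holdout_fraction, seeds["simulate"] + 1, net
                )
                with open(sim_dir / "hidden.json", "w", encoding="utf-8") as fh:
                    json.dump(
                        {str(d): sorted(str(g) for g in h) for d, h in hidden.items()},
                        fh, indent=1,
                    )
            graph_model.save_edge_list(net.dg, sim_dir / "dg.tsv")
            graph_model.save_edge_list(net.gg, sim_dir / "gg.tsv")
            graph_model.save_edge_list(net.dd, sim_dir / "dd.tsv")
            truth.save(sim_dir / "truth.json")
            logger.info("simulate: wrote %s", sim_dir)

    net = None
    net_dir = out / "01_net"
    if "build" in stages:
        if force or not (net_dir / "dg.tsv").exists():
            dg, gg, dd = _load_inputs(cfg, out)
            net, stats = graph_model.build_hetnet(dg, gg, dd, seed=seeds["build"])
            net_dir.mkdir(exist_ok=True)
            graph_model.save_edge_list(net.dg, net_dir / "dg.tsv")
            graph_model.save_edge_list(net.gg, net_dir / "gg.tsv")
            graph_model.save_edge_list(net.dd, net_dir / "dd.tsv")
            with open(net_dir / "stats.json", "w", encoding="utf-8") as fh:
                json.dump(stats, fh, indent=1)
            logger.info("build: %s", {k: v for k, v in stats.items() if k != "dedup_map"})

    def _require(path: Path, producer: str):
        if not path.exists():
            raise FileNotFoundError(
                f"missing artifact {path}; run the '{producer}' stage first"
            )

    def _load_net() -> HetNet:
        _require(net_dir / "dg.tsv", "build")
        dg = graph_model.load_edge_list(net_dir / "dg.tsv", (DISEASE, GENE))
        gg = graph_model.load_edge_list(net_dir / "gg.tsv", (GENE, GENE))
        dd = graph_model.load_edge_list(net_dir / "dd.tsv", (DISEASE, DISEASE))
        return HetNet(dd, gg, dg)

    method = dict(cfg.method or {})
    method.setdefault("random_state", seeds["method"])

    emb_dir = out / "03_emb"
    if "embed" in stages and (force or not (emb_dir / "emb.index.json").exists()):
        if net is None:
            net = _load_net()
        from .walker import WalkParams, generate_walks
        from .embedder import SGNSParams, train_embeddings
        wseed, sseed = derive_seeds(method["random_state"], 2)
        corpus = generate_walks(net.merged(), WalkParams(
            p=method.get("p", 1.0), q=method.get("q", 1.0),
            num_walks_per_node=method.get("num_walks", 10),
            walk_length=method.get("walk_length", 80), seed=wseed,
        ))
        walks_dir = out / "02_walks"
        walks_dir.mkdir(exist_ok=True)
        corpus.save(walks_dir / "corpus.txt")
        emb = train_embeddings(corpus, SGNSParams(
            d=method.get("dim", 128), window=method.get("window", 10),
            negatives=method.get("negatives", 5), epochs=method.get("epochs", 5),
            learning_rate=method.get("learning_rate", 0.025), seed=sseed,
        ))
        emb_dir.mkdir(exist_ok=True)
        emb.save_npy(emb_dir / "emb")
        logger.info("embed: %d nodes x %d dims", len(emb.nodes), emb.d)

    two_dir = out / "04_twolayer"
    if "reconstruct" in stages and (force or not (two_dir / "meta.json").exists()):
        if net is None:
            net = _load_net()
        _require(emb_dir / "emb.index.json", "embed")
        from .reconstructor import assemble_two_layer, enhanced_network
        emb = Embedding.load_npy(emb_dir / "emb")
        k = method.get("recon_k", 10)
        H_I = enhanced_network(
            emb, net.diseases, k=min(k, len(net.diseases) - 1),
            clamp_negative=method.get("clamp_negative", True),
            binarize=method.get("binarize", False),
        )
        H_N = enhanced_network(
            emb, net.genes, k=min(k, len(net.genes) - 1),
            clamp_negative=method.get("clamp_negative", True),
            binarize=method.get("binarize", False),
        )
        two = assemble_two_layer(H_I, H_N, net.dg, net.diseases, net.genes)
        two.save(two_dir)
        logger.info("reconstruct: two-layer network with %d nodes", two.n_nodes)

    rank_dir = out / "05_rank"
    if "predict" in stages and (force or not rank_dir.exists()):
        if net is None:
            net = _load_net()
        _require(two_dir / "meta.json", "reconstruct")
        from . import propagator
        two = TwoLayerNetwork.load(two_dir)
        blocks = propagator.normalize_blocks(two)
        T = propagator.transfer(
            propagator.build_block_matrix(blocks, method.get("beta", 0.5))
        )
        rank_dir.mkdir(exist_ok=True)
        for d in two.diseases:
            known = net.gene_set(d)
            q0 = propagator.make_seed(two, d, known, method.get("eta", 0.5))
            score = propagator.rwr(
                T.T, q0, method.get("alpha", 0.7),
                method.get("tol", 1e-10), method.get("max_iter", 1000),
            )
            ranked = propagator.rank_genes(score, two, set(known), d)
            with open(rank_dir / f"{d.local_id}.tsv", "w", encoding="utf-8") as fh:
                fh.write("rank\tgene_id\tscore\tseed_disease\n")
                for r, (g, s) in enumerate(ranked.entries, start=1):
                    fh.write(f"{r}\t{g.local_id}\t{s!r}\t{d.local_id}\n")
        logger.info("predict: wrote %d ranked lists", len(two.diseases))

    eval_dir = out / "06_eval"
    if "evaluate" in stages and (force or not (eval_dir / "summary.json").exists()):
        if net is None:
            net = _load_net()
        spec = EvalSpec(tuple(cfg.k_list))
        hidden_path = out / "00_input" / "hidden.json"
        if hidden_path.exists():
            with open(hidden_path, encoding="utf-8") as fh:
                hidden = {
                    NodeRef.parse(k): frozenset(NodeRef.parse(g) for g in v)
                    for k, v in json.load(fh).items()
                }
            result = evaluate_holdout(net, hidden, method, spec)
        else:
            result = evaluate_cv(net, method, cfg.cv_folds, spec, seed=seeds["cv"])
        eval_dir.mkdir(exist_ok=True)
        with open(eval_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        import pandas as pd
        pd.DataFrame(result.per_fold).to_csv(
            eval_dir / "metrics.tsv", sep="\t", index=False
        )
        logger.info("evaluate: macro %s", result.macro)

    return out
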