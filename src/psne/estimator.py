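"""Estimator-style front end for the prioritization pipeline.

:class:`PSNE` follows the scikit-learn estimator protocol (constructor
stores hyperparameters, ``fit`` learns state into trailing-underscore
attributes, ``get_params``/``set_params`` work for grid search), except
that its input is a :class:`~psne.graph_model.HetNet` rather than a
feature matrix.  ``fit`` runs walks + embedding + reconstruction and
builds the transfer matrix once; ``predict``/``rank_genes`` then score
any number of seed diseases by restart walks, which are cheap.

:class:`DegreeBaseline` ranks genes by network degree regardless of the
seed disease — the null model any prioritizer must beat.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from . import propagator, reconstructor, walker
from .embedder import SGNSParams, train_embeddings
from .graph_model import HetNet, NodeRef
from .propagator import PropagationParams, RankedGeneList
from .walker import WalkParams

logger = logging.getLogger(__name__)


def derive_seeds(random_state: int, n: int) -> list[int]:
    """Derive per-stage seeds (< 2^31) from one global seed."""
    ss = np.random.SeedSequence(random_state)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


class PSNE(BaseEstimator):
    """Disease-gene prioritization by structure-preserving embedding.

    Parameters
    ----------
    p, q : biased-walk return and in-out parameters.
    num_walks, walk_length : walks started per node and their length.
    dim, window, negatives, epochs, learning_rate : SGNS training knobs.
    reconstruct : if False, skip the embedding/reconstruction and run the
        restart walk on the raw layers (the ablation control).
    recon_k : neighbors kept per node in the enhanced networks.
    clamp_negative, binarize : enhanced-network edge-weight policy.
    beta : inter-layer jump probability of the block matrix.
    alpha : restart probability.
    eta : seed-mass fraction on the disease layer.
    tol, max_iter : restart-walk convergence controls.
    random_state : global seed; stage seeds are derived from it.
    """

    def __init__(
        self,
        p: float = 1.0,
        q: float = 1.0,
        num_walks: int = 10,
        walk_length: int = 80,
        dim: int = 128,
        window: int = 10,
        negatives: int = 5,
        epochs: int = 5,
        learning_rate: float = 0.025,
        reconstruct: bool = True,
        recon_k: int = 10,
        clamp_negative: bool = True,
        binarize: bool = False,
        beta: float = 0.5,
        alpha: float = 0.7,
        eta: float = 0.5,
        tol: float = 1e-10,
        max_iter: int = 1000,
        random_state: int = 0,
    ) -> None:
        self.p = p
        self.q = q
        self.num_walks = num_walks
        self.walk_length = walk_length
        self.dim = dim
        self.window = window
        self.negatives = negatives
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.reconstruct = reconstruct
        self.recon_k = recon_k
        self.clamp_negative = clamp_negative
        self.binarize = binarize
        self.beta = beta
        self.alpha = alpha
        self.eta = eta
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, net: HetNet, y=None) -> "PSNE":
        """Embed the network and assemble the two-layer transfer matrix."""
        walk_seed, sgns_seed = derive_seeds(self.random_state, 2)
        self.net_ = net
        if self.reconstruct:
            corpus = walker.generate_walks(
                net.merged(),
                WalkParams(
                    p=self.p,
                    q=self.q,
                    num_walks_per_node=self.num_walks,
                    walk_length=self.walk_length,
                    seed=walk_seed,
                ),
            )
            self.embedding_ = train_embeddings(
                corpus,
                SGNSParams(
                    d=self.dim,
                    window=self.window,
                    negatives=self.negatives,
                    epochs=self.epochs,
                    learning_rate=self.learning_rate,
                    seed=sgns_seed,
                ),
            )
            k_d = min(self.recon_k, len(net.diseases) - 1)
            k_g = min(self.recon_k, len(net.genes) - 1)
            if k_d < self.recon_k or k_g < self.recon_k:
                logger.info("recon_k clamped to layer size - 1")
            H_I = reconstructor.enhanced_network(
                self.embedding_, net.diseases, k=k_d,
                clamp_negative=self.clamp_negative, binarize=self.binarize,
            )
            H_N = reconstructor.enhanced_network(
                self.embedding_, net.genes, k=k_g,
                clamp_negative=self.clamp_negative, binarize=self.binarize,
            )
        else:
            self.embedding_ = None
            H_I, H_N = net.dd, net.gg
        self.two_layer_ = reconstructor.assemble_two_layer(
            H_I, H_N, net.dg, net.diseases, net.genes
        )
        blocks = propagator.normalize_blocks(self.two_layer_)
        d_hat = propagator.build_block_matrix(blocks, self.beta)
        self.transfer_ = propagator.transfer(d_hat)
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "transfer_"):
            raise RuntimeError("estimator is not fitted; call fit(net) first")

    def propagation_params(self) -> PropagationParams:
        return PropagationParams(
            beta=self.beta, alpha=self.alpha, eta=self.eta,
            tol=self.tol, max_iter=self.max_iter,
        )

    def score_nodes(
        self,
        disease: NodeRef,
        known_genes: set[NodeRef] | frozenset[NodeRef] | None = None,
    ) -> propagator.ScoreVector:
        """Stationary probabilities for one seed disease.

        ``known_genes`` defaults to the disease's associated genes in the
        fitted network.
        """
        self._check_fitted()
        if known_genes is None:
            known_genes = self.net_.gene_set(disease)
        q0 = propagator.make_seed(self.two_layer_, disease, known_genes, self.eta)
        return propagator.rwr(
            self.transfer_.T, q0, self.alpha, self.tol, self.max_iter,
            nodes=self.two_layer_.node_order,
        )

    def rank_genes(
        self,
        disease: NodeRef,
        known_genes: set[NodeRef] | frozenset[NodeRef] | None = None,
        exclude: set[NodeRef] | frozenset[NodeRef] | None = None,
    ) -> RankedGeneList:
        """Ranked candidates for one disease, training genes excluded."""
        if known_genes is None:
            known_genes = self.net_.gene_set(disease) if hasattr(self, "net_") else frozenset()
        score = self.score_nodes(disease, known_genes)
        if exclude is None:
            exclude = set(known_genes)
        return propagator.rank_genes(score, self.two_layer_, exclude, disease)

    def predict(self, diseases: list[NodeRef]) -> list[RankedGeneList]:
        """Ranked gene lists for a batch of seed diseases."""
        return [self.rank_genes(d) for d in diseases]


class DegreeBaseline(BaseEstimator):
    """Rank genes by their degree in the merged network (disease-agnostic)."""

    def __init__(self, random_state: int = 0) -> None:
        self.random_state = random_state

    def fit(self, net: HetNet, y=None) -> "DegreeBaseline":
        self.net_ = net
        merged = net.merged()
        self.scores_ = {
            g: float(merged.degree(g)) if g in merged else 0.0 for g in net.genes
        }
        return self

    def rank_genes(
        self,
        disease: NodeRef,
        known_genes=None,
        exclude: set[NodeRef] | None = None,
    ) -> RankedGeneList:
        if exclude is None:
            exclude = set(self.net_.gene_set(disease))
        entries = sorted(
            ((g, s) for g, s in self.scores_.items() if g not in exclude),
            key=lambda e: (-e[1], e[0]),
        )
        return RankedGeneList(disease, entries)


def prioritize(
    net: HetNet, disease: NodeRef, **params
) -> RankedGeneList:
    """One-call convenience wrapper: fit PSNE on ``net``, rank for ``disease``."""
    return PSNE(**params).fit(net).rank_genes(disease)
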