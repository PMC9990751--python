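"""Two-layer random walk with restart on the block network.

Each block of the two-layer network is column-normalized, the blocks are
combined with inter-layer jump probability beta,

    D_hat = [[(1-beta) H_I^, beta H_G^],
             [beta H_E^,     (1-beta) H_N^]],

and the result is renormalized column-wise into the transfer matrix T
(a node with no cross-layer link keeps all its mass within its layer; a
fully isolated node gets a unit self-loop so T stays column-stochastic).
The walker then iterates

    q_{t+1} = (1 - alpha) T q_t + alpha q_0

to its fixed point; the stationary gene probabilities, sorted, are the
candidate ranking for the seeded disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph_model import NodeRef
from .reconstructor import TwoLayerNetwork

logger = logging.getLogger(__name__)

_DENSE_SOLVE_GUARD = 2000


@dataclass(frozen=True)
class PropagationParams:
    """Restart-walk hyperparameters.

    beta : inter-layer jump probability in [0, 1].
    alpha : restart probability in (0, 1).
    eta : fraction of seed mass placed on the disease layer.
    """

    beta: float = 0.5
    alpha: float = 0.7
    eta: float = 0.5
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive, max_iter >= 1")


@dataclass
class NormalizedBlocks:
    H_I: sp.csr_matrix
    H_N: sp.csr_matrix
    H_G: sp.csr_matrix
    H_E: sp.csr_matrix
    degrees: dict[str, np.ndarray]


@dataclass
class TransferMatrix:
    T: sp.csr_matrix
    column_sums_before_repair: np.ndarray
    n_dangling: int


@dataclass
class ScoreVector:
    q: np.ndarray
    nodes: list[NodeRef]
    iterations: int
    residual: float
    converged: bool

    def score(self, node: NodeRef) -> float:
        return float(self.q[self.nodes.index(node)])


def column_normalize(H: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Divide each nonzero column by its sum; zero columns stay zero."""
    H = sp.csr_matrix(H, dtype=float)
    if H.nnz and H.data.min() < 0:
        raise ValueError("matrix has negative entries")
    colsum = np.asarray(H.sum(axis=0)).ravel()
    scale = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    return sp.csr_matrix(H @ sp.diags(scale))


def normalize_blocks(net: TwoLayerNetwork) -> NormalizedBlocks:
    degrees = {
        "D_I": np.asarray(net.H_I.sum(axis=0)).ravel(),
        "D_N": np.asarray(net.H_N.sum(axis=0)).ravel(),
        "D_G": np.asarray(net.H_G.sum(axis=0)).ravel(),
        "D_E": np.asarray(net.H_E.sum(axis=0)).ravel(),
    }
    return NormalizedBlocks(
        H_I=column_normalize(net.H_I),
        H_N=column_normalize(net.H_N),
        H_G=column_normalize(net.H_G),
        H_E=column_normalize(net.H_E),
        degrees=degrees,
    )


def build_block_matrix(blocks: NormalizedBlocks, beta: float) -> sp.csr_matrix:
    """beta-weighted block matrix coupling the two normalized layers."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    return sp.csr_matrix(
        sp.bmat(
            [
                [(1.0 - beta) * blocks.H_I, beta * blocks.H_G],
                [beta * blocks.H_E, (1.0 - beta) * blocks.H_N],
            ],
            format="csr",
        )
    )


def transfer(D_hat: sp.spmatrix) -> TransferMatrix:
    """Renormalize the block matrix columns into a stochastic transfer matrix.

    Columns with zero sum (fully isolated nodes) receive a unit self-loop.
    Columns summing to 1-beta or beta (nodes lacking a cross-layer or
    within-layer link) are rescaled so all their mass stays on the
    available moves.
    """
    D_hat = sp.csr_matrix(D_hat, dtype=float)
    if D_hat.nnz and D_hat.data.min() < 0:
        raise ValueError("block matrix has negative entries")
    colsum = np.asarray(D_hat.sum(axis=0)).ravel()
    dangling = np.flatnonzero(colsum == 0)
    scale = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    T = D_hat @ sp.diags(scale)
    if dangling.size:
        repair = sp.csr_matrix(
            (np.ones(dangling.size), (dangling, dangling)), shape=D_hat.shape
        )
        T = T + repair
        logger.info("installed self-loops on %d dangling column(s)", dangling.size)
    return TransferMatrix(sp.csr_matrix(T), colsum, int(dangling.size))


def make_seed(
    net: TwoLayerNetwork,
    disease: NodeRef,
    known_genes: set[NodeRef] | frozenset[NodeRef] | None,
    eta: float = 0.5,
) -> np.ndarray:
    """Initial probability vector: eta on the seed disease, 1-eta spread
    uniformly over its known genes (all mass on the disease if none)."""
    if disease not in net.disease_index:
        raise KeyError(f"unknown disease {disease}")
    known_genes = set(known_genes or ())
    missing = known_genes - set(net.gene_index)
    if missing:
        raise KeyError(f"unknown gene(s): {sorted(missing)[:3]}")
    nd = len(net.diseases)
    q0 = np.zeros(net.n_nodes)
    if known_genes:
        q0[net.disease_index[disease]] = eta
        share = (1.0 - eta) / len(known_genes)
        for g in known_genes:
            q0[nd + net.gene_index[g]] = share
    else:
        q0[net.disease_index[disease]] = 1.0
    return q0


def rwr(
    T: sp.spmatrix,
    q0: np.ndarray,
    alpha: float,
    tol: float = 1e-10,
    max_iter: int = 1000,
    nodes: list[NodeRef] | None = None,
) -> ScoreVector:
    """Iterate the restart walk to its stationary distribution."""
    q0 = np.asarray(q0, dtype=float)
    if q0.min() < 0 or abs(q0.sum() - 1.0) > 1e-9:
        raise ValueError("q0 must be a probability vector")
    q = q0.copy()
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        q_next = (1.0 - alpha) * (T @ q) + alpha * q0
        residual = float(np.abs(q_next - q).sum())
        q = q_next
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        logger.warning(
            "restart walk did not converge in %d iterations (residual %.3e)",
            max_iter, residual,
        )
    return ScoreVector(q, nodes or [], it, residual, converged)


def rwr_closed_form(
    T: sp.spmatrix,
    q0: np.ndarray,
    alpha: float,
    nodes: list[NodeRef] | None = None,
) -> ScoreVector:
    """Direct solve of the fixed point (I - (1-alpha) T) q = alpha q0.

    Dense solve, guarded to networks of at most 2000 nodes; used as the
    independent oracle for the iterative walker.
    """
    n = T.shape[0]
    if n > _DENSE_SOLVE_GUARD:
        raise ValueError(f"closed-form solve limited to {_DENSE_SOLVE_GUARD} nodes")
    A = np.eye(n) - (1.0 - alpha) * sp.csr_matrix(T).toarray()
    q = np.linalg.solve(A, alpha * np.asarray(q0, dtype=float))
    return ScoreVector(q, nodes or [], 0, 0.0, True)


@dataclass
class RankedGeneList:
    disease: NodeRef
    entries: list[tuple[NodeRef, float]]  # (gene, score) descending

    def genes(self) -> list[NodeRef]:
        return [g for g, _ in self.entries]

    def scores(self) -> dict[NodeRef, float]:
        return {g: s for g, s in self.entries}


def rank_genes(
    score: ScoreVector | np.ndarray,
    net: TwoLayerNetwork,
    exclude: set[NodeRef] | frozenset[NodeRef] = frozenset(),
    disease: NodeRef | None = None,
) -> RankedGeneList:
    """Sort gene-layer probabilities into a candidate ranking.

    ``exclude`` removes the seed disease's training genes.  Ties break by
    ascending gene id.
    """
    q = score.q if isinstance(score, ScoreVector) else np.asarray(score)
    nd = len(net.diseases)
    entries = [
        (g, float(q[nd + i]))
        for i, g in enumerate(net.genes)
        if g not in exclude
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return RankedGeneList(disease or NodeRef("disease", "?"), entries)
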