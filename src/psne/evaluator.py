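"""Cross-validated evaluation: AUROC, AUPRC and top-k recall/precision.

The control set is genome-wide: for a given disease every gene except
that disease's training and testing genes is a negative.  AUROC uses the
tie-corrected Mann-Whitney form; AUPRC is the area under the grouped-
threshold precision-recall step curve; top-k recall and precision are

    Recall    = |T_d intersect R_d(k)| / |T_d|
    Precision = |T_d intersect R_d(k)| / |R_d(k)|

for the first k ranked candidates R_d(k) and test genes T_d.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .graph_model import DISEASE, NodeRef, WeightedGraph

logger = logging.getLogger(__name__)

DEFAULT_K_LIST = (1, 5, 10, 20, 50, 100, 200)


@dataclass(frozen=True)
class EvalSpec:
    k_list: tuple[int, ...] = DEFAULT_K_LIST

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.k_list, self.k_list[1:])):
            raise ValueError("k_list must be strictly increasing")
        if self.k_list and self.k_list[0] < 1:
            raise ValueError("k values must be positive")


@dataclass
class CVSplit:
    """Per-disease fold assignments of association pairs.

    ``folds[d]`` is a list of (train_genes, test_genes) tuples; diseases
    with fewer genes than requested folds fall back to leave-one-out.
    """

    folds: dict[NodeRef, list[tuple[frozenset[NodeRef], frozenset[NodeRef]]]]
    n_folds: int
    seed: int
    train_empty: set[NodeRef] = field(default_factory=set)

    def items(self):
        for d, fl in self.folds.items():
            for fold_idx, (train, test) in enumerate(fl):
                yield d, fold_idx, train, test


def cv_split(dg: WeightedGraph, folds: int, seed: int) -> CVSplit:
    """Partition each disease's genes into folds as evenly as possible."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    out: dict[NodeRef, list[tuple[frozenset, frozenset]]] = {}
    train_empty: set[NodeRef] = set()
    for d in sorted(n for n in dg.nodes if n.namespace == DISEASE):
        genes = sorted(dg.neighbors(d))
        perm = [genes[i] for i in rng.permutation(len(genes))]
        n_eff = min(folds, len(genes))  # leave-one-out fallback
        chunks = [perm[i::n_eff] for i in range(n_eff)]
        fold_list = []
        for c in chunks:
            test = frozenset(c)
            train = frozenset(genes) - test
            if not train:
                train_empty.add(d)
            fold_list.append((train, test))
        out[d] = fold_list
    return CVSplit(out, folds, seed, train_empty)


def _score_arrays(
    scores: dict[NodeRef, float], positives: set, controls: set
) -> tuple[np.ndarray, np.ndarray] | None:
    pos = [scores.get(g, 0.0) for g in sorted(positives)]
    ctl = [scores.get(g, 0.0) for g in sorted(controls)]
    if not pos or not ctl:
        return None
    return np.asarray(pos, dtype=float), np.asarray(ctl, dtype=float)


def auroc(
    scores: dict[NodeRef, float],
    positives: set[NodeRef],
    controls: set[NodeRef],
) -> float:
    """Tie-corrected Mann-Whitney AUROC.

    Equals (#pairs with positive scored above control + half the tied
    pairs) / (|P| * |C|).  Returns NaN when either set is empty.
    """
    if positives & controls:
        raise ValueError("positives and controls overlap")
    arrs = _score_arrays(scores, positives, controls)
    if arrs is None:
        logger.warning("AUROC undefined: empty positives or controls")
        return math.nan
    pos, ctl = arrs
    ranks = rankdata(np.concatenate([pos, ctl]))  # mid-ranks on ties
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(ctl)))


def auprc(
    scores: dict[NodeRef, float],
    positives: set[NodeRef],
    controls: set[NodeRef],
) -> float:
    """Area under the precision-recall step curve (ties grouped)."""
    if positives & controls:
        raise ValueError("positives and controls overlap")
    arrs = _score_arrays(scores, positives, controls)
    if arrs is None:
        logger.warning("AUPRC undefined: empty positives or controls")
        return math.nan
    pos, ctl = arrs
    s = np.concatenate([pos, ctl])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(ctl))])
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group tied scores: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    cut = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y)[cut]
    n_at = cut + 1.0
    precision = tp / n_at
    recall = tp / len(pos)
    prev_recall = 0.0
    area = 0.0
    for p, r in zip(precision, recall):
        area += (r - prev_recall) * p
        prev_recall = r
    return float(area)


def topk(
    scores: dict[NodeRef, float],
    T_d: set[NodeRef],
    k: int,
    candidates: list[NodeRef] | None = None,
) -> tuple[float, float]:
    """Recall and precision among the first k ranked candidates.

    ``candidates`` defaults to the keys of ``scores``; ties break by
    ascending gene id.  If fewer than k candidates exist, the precision
    divisor is the actual list length.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if not T_d:
        return math.nan, math.nan
    cand = candidates if candidates is not None else list(scores)
    ranked = sorted(cand, key=lambda g: (-scores.get(g, 0.0), g))
    top = ranked[:k]
    hits = len(T_d & set(top))
    return hits / len(T_d), hits / len(top) if top else math.nan


@dataclass
class EvalResult:
    per_fold: list[dict]          # one record per (disease, fold)
    macro: dict[str, float]       # mean over disease-folds
    pooled: dict[str, float]      # micro: all (score, label) pairs pooled
    k_list: tuple[int, ...]
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "macro": self.macro,
            "pooled": self.pooled,
            "n_disease_folds": len(self.per_fold),
            "n_skipped": self.n_skipped,
            "k_list": list(self.k_list),
        }


def evaluate(
    results: dict[tuple[NodeRef, int], dict[NodeRef, float]],
    spec: EvalSpec,
    split: CVSplit,
    all_genes: set[NodeRef],
) -> EvalResult:
    """Score every (disease, fold) ranking against the genome-wide controls.

    ``results`` maps (disease, fold index) to gene scores with training
    genes already excluded.  Positives are the fold's test genes; controls
    are all genes minus that disease's train and test genes.  Metrics are
    macro-averaged over disease-folds; a pooled (micro) aggregate over all
    scored pairs is reported alongside.
    """
    per_fold: list[dict] = []
    pooled_pos: list[float] = []
    pooled_ctl: list[float] = []
    n_skipped = 0
    for d, fold_idx, train, test in split.items():
        key = (d, fold_idx)
        if key not in results:
            n_skipped += 1
            logger.warning("no scores for %s fold %d; skipped", d, fold_idx)
            continue
        scores = results[key]
        positives = set(test)
        controls = all_genes - set(train) - positives
        rec: dict = {
            "disease": str(d),
            "fold": fold_idx,
            "n_test": len(positives),
            "n_controls": len(controls),
            "auroc": auroc(scores, positives, controls),
            "auprc": auprc(scores, positives, controls),
        }
        candidates = sorted(positives | controls)
        for k in spec.k_list:
            r, p = topk(scores, positives, k, candidates=candidates)
            rec[f"recall@{k}"] = r
            rec[f"precision@{k}"] = p
        per_fold.append(rec)
        pooled_pos.extend(scores.get(g, 0.0) for g in sorted(positives))
        pooled_ctl.extend(scores.get(g, 0.0) for g in sorted(controls))

    metric_keys = (
        ["auroc", "auprc"]
        + [f"recall@{k}" for k in spec.k_list]
        + [f"precision@{k}" for k in spec.k_list]
    )
    macro = {
        m: float(np.nanmean([r[m] for r in per_fold])) if per_fold else math.nan
        for m in metric_keys
    }
    pooled: dict[str, float] = {}
    if pooled_pos and pooled_ctl:
        idx_scores = {NodeRef("gene", str(i)): s for i, s in enumerate(pooled_pos)}
        n0 = len(pooled_pos)
        idx_scores.update(
            {NodeRef("gene", str(n0 + i)): s for i, s in enumerate(pooled_ctl)}
        )
        p_set = {NodeRef("gene", str(i)) for i in range(n0)}
        c_set = set(idx_scores) - p_set
        pooled["auroc"] = auroc(idx_scores, p_set, c_set)
        pooled["auprc"] = auprc(idx_scores, p_set, c_set)
    return EvalResult(per_fold, macro, pooled, spec.k_list, n_skipped)
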