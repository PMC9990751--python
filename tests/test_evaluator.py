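import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_graph
from psne.evaluator import (
    CVSplit,
    EvalSpec,
    auprc,
    auroc,
    cv_split,
    evaluate,
    topk,
)
from psne.graph_model import WeightedGraph, disease, gene


def brute_force_auroc(scores, positives, controls):
    """All-pairs oracle: P(score_p > score_c) + 0.5 P(tie)."""
    num = 0.0
    for p in positives:
        for c in controls:
            if scores[p] > scores[c]:
                num += 1.0
            elif scores[p] == scores[c]:
                num += 0.5
    return num / (len(positives) * len(controls))


class TestAuroc:
    def test_perfect_ranking(self):
        scores = {gene("p"): 1.0, gene("c1"): 0.2, gene("c2"): 0.1}
        assert auroc(scores, {gene("p")}, {gene("c1"), gene("c2")}) == 1.0

    def test_all_ties_half(self):
        scores = {gene(str(i)): 0.5 for i in range(6)}
        pos = {gene(str(i)) for i in range(3)}
        ctl = {gene(str(i)) for i in range(3, 6)}
        assert auroc(scores, pos, ctl) == 0.5

    def test_worked_pair_count(self):
        scores = {gene("p1"): 0.9, gene("p2"): 0.4, gene("c1"): 0.5, gene("c2"): 0.1}
        got = auroc(scores, {gene("p1"), gene("p2")}, {gene("c1"), gene("c2")})
        assert got == pytest.approx(0.75)

    def test_empty_returns_nan(self):
        assert math.isnan(auroc({gene("a"): 1.0}, {gene("a")}, set()))

    def test_overlap_errors(self):
        with pytest.raises(ValueError):
            auroc({gene("a"): 1.0}, {gene("a")}, {gene("a")})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_brute_force_oracle(self, data):
        n = data.draw(st.integers(2, 20))
        n_pos = data.draw(st.integers(1, n - 1))
        vals = data.draw(
            st.lists(st.integers(0, 5), min_size=n, max_size=n)  # ties likely
        )
        items = [gene(f"g{i}") for i in range(n)]
        scores = {g: float(v) for g, v in zip(items, vals)}
        pos, ctl = set(items[:n_pos]), set(items[n_pos:])
        assert auroc(scores, pos, ctl) == pytest.approx(
            brute_force_auroc(scores, pos, ctl), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        items = [gene(f"g{i}") for i in range(15)]
        scores = {g: float(rng.random()) for g in items}
        pos, ctl = set(items[:5]), set(items[5:])
        base = auroc(scores, pos, ctl)
        for f in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
            transformed = {g: float(f(s)) for g, s in scores.items()}
            assert auroc(transformed, pos, ctl) == pytest.approx(base, abs=1e-12)

    def test_cross_check_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        for _ in range(20):
            items = [gene(f"g{i}") for i in range(30)]
            scores = {g: float(rng.integers(0, 8)) for g in items}
            pos, ctl = set(items[:10]), set(items[10:])
            y = [1] * 10 + [0] * 20
            s = [scores[g] for g in items]
            assert auroc(scores, pos, ctl) == pytest.approx(roc_auc_score(y, s))


class TestAuprc:
    def test_perfect_ranking(self):
        scores = {gene("p"): 0.9, gene("c1"): 0.2, gene("c2"): 0.1}
        assert auprc(scores, {gene("p")}, {gene("c1"), gene("c2")}) == 1.0

    def test_single_positive_first_or_last(self):
        first = {gene("p"): 0.9, gene("c1"): 0.8, gene("c2"): 0.7}
        assert auprc(first, {gene("p")}, {gene("c1"), gene("c2")}) == 1.0
        last = {gene("p"): 0.1, gene("c1"): 0.8, gene("c2"): 0.7}
        assert auprc(last, {gene("p")}, {gene("c1"), gene("c2")}) == pytest.approx(1 / 3)

    def test_random_scorer_near_prevalence(self):
        rng = np.random.default_rng(0)
        items = [gene(f"g{i}") for i in range(400)]
        pos, ctl = set(items[:40]), set(items[40:])
        vals = []
        for _ in range(30):
            scores = {g: float(rng.random()) for g in items}
            vals.append(auprc(scores, pos, ctl))
        assert abs(np.mean(vals) - 0.1) < 0.03

    def test_cross_check_sklearn(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(13)
        for _ in range(20):
            items = [gene(f"g{i}") for i in range(25)]
            scores = {g: float(rng.integers(0, 6)) for g in items}
            pos, ctl = set(items[:8]), set(items[8:])
            y = [1 if g in pos else 0 for g in items]
            s = [scores[g] for g in items]
            assert auprc(scores, pos, ctl) == pytest.approx(
                average_precision_score(y, s), abs=1e-12
            )


class TestTopK:
    def test_worked_recall(self):
        # 2 of 4 test genes inside the top-k list
        scores = {gene(f"g{i}"): 1.0 / (i + 1) for i in range(10)}
        T_d = {gene("g0"), gene("g2"), gene("g7"), gene("g9")}
        recall, _ = topk(scores, T_d, k=3)
        assert recall == 0.5

    def test_k1_hit(self):
        scores = {gene("a"): 0.9, gene("b"): 0.1}
        recall, precision = topk(scores, {gene("a")}, k=1)
        assert precision == 1.0 and recall == 1.0

    def test_worked_set_arithmetic(self):
        ranking = ["g9", "g1", "g8", "g2", "g7", "g3"]
        scores = {gene(g): 1.0 / (i + 1) for i, g in enumerate(ranking)}
        T_d = {gene("g1"), gene("g2"), gene("g3")}
        recall, precision = topk(scores, T_d, k=5)
        assert recall == pytest.approx(2 / 3)
        assert precision == pytest.approx(2 / 5)

    def test_k_exceeds_candidates(self):
        scores = {gene("a"): 0.9, gene("b"): 0.1}
        recall, precision = topk(scores, {gene("b")}, k=10)
        assert recall == 1.0 and precision == 0.5  # divisor is |R_d(k)| = 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_recall_non_decreasing_precision_mass_non_decreasing(self, data):
        n = data.draw(st.integers(3, 25))
        n_pos = data.draw(st.integers(1, n - 1))
        vals = data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n))
        items = [gene(f"g{i}") for i in range(n)]
        scores = {g: float(v) for g, v in zip(items, vals)}
        T_d = set(items[:n_pos])
        prev_recall, prev_hits = -1.0, -1.0
        for k in range(1, n + 1):
            recall, precision = topk(scores, T_d, k)
            assert recall >= prev_recall
            assert precision * k >= prev_hits - 1e-12
            prev_recall, prev_hits = recall, precision * k


class TestCVSplit:
    def _dg(self, n_genes):
        dg = WeightedGraph()
        for i in range(n_genes):
            dg.add_edge(disease("d1"), gene(f"g{i}"))
        return dg

    def test_even_split(self):
        split = cv_split(self._dg(10), folds=5, seed=0)
        sizes = [len(test) for _, test in split.folds[disease("d1")]]
        assert sizes == [2] * 5

    def test_leave_one_out_fallback(self):
        split = cv_split(self._dg(3), folds=5, seed=0)
        fl = split.folds[disease("d1")]
        assert len(fl) == 3
        assert all(len(test) == 1 for _, test in fl)

    def test_partition_property_and_determinism(self):
        s1 = cv_split(self._dg(7), folds=3, seed=5)
        s2 = cv_split(self._dg(7), folds=3, seed=5)
        assert s1.folds == s2.folds
        all_genes = {gene(f"g{i}") for i in range(7)}
        for train, test in s1.folds[disease("d1")]:
            assert train | test == all_genes and not train & test

    def test_single_gene_disease_flagged(self):
        split = cv_split(self._dg(1), folds=5, seed=0)
        assert disease("d1") in split.train_empty


class TestEvaluate:
    def test_perfect_scores_all_ones(self):
        d = disease("d1")
        genes = [gene(f"g{i}") for i in range(10)]
        split = CVSplit({d: [(frozenset(genes[:2]), frozenset(genes[2:4]))]}, 1, 0)
        scores = {g: (1.0 if g in genes[2:4] else 0.0) for g in genes[2:]}
        res = evaluate({(d, 0): scores}, EvalSpec((1, 2, 5)), split, set(genes))
        assert res.macro["auroc"] == 1.0
        assert res.macro["auprc"] == 1.0
        assert res.macro["recall@2"] == 1.0

    def test_macro_average(self):
        d1, d2 = disease("d1"), disease("d2")
        genes = [gene(f"g{i}") for i in range(6)]
        split = CVSplit(
            {
                d1: [(frozenset(), frozenset({genes[0]}))],
                d2: [(frozenset(), frozenset({genes[1]}))],
            },
            1,
            0,
        )
        perfect = {g: (1.0 if g == genes[0] else 0.0) for g in genes}
        flat = {g: 0.5 for g in genes}
        res = evaluate(
            {(d1, 0): perfect, (d2, 0): flat}, EvalSpec((1,)), split, set(genes)
        )
        assert res.macro["auroc"] == pytest.approx(0.75)  # mean of 1.0 and 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        genes = [gene(f"g{i}") for i in range(300)]
        d = disease("d1")
        aurocs = []
        for rep in range(40):
            test = frozenset(genes[:10])
            split = CVSplit({d: [(frozenset(genes[10:15]), test)]}, 1, 0)
            scores = {g: float(rng.random()) for g in genes}
            res = evaluate({(d, 0): scores}, EvalSpec((5,)), split, set(genes))
            aurocs.append(res.macro["auroc"])
        assert abs(np.mean(aurocs) - 0.5) < 0.05

    def test_missing_fold_skipped_with_count(self):
        d = disease("d1")
        genes = [gene("g0"), gene("g1"), gene("g2")]
        split = CVSplit(
            {d: [(frozenset({genes[0]}), frozenset({genes[1]})),
                 (frozenset({genes[1]}), frozenset({genes[0]}))]},
            2,
            0,
        )
        scores = {genes[1]: 1.0, genes[2]: 0.0}
        res = evaluate({(d, 0): scores}, EvalSpec((1,)), split, set(genes))
        assert res.n_skipped == 1 and len(res.per_fold) == 1
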