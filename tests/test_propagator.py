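import numpy as np
import pytest
import scipy.sparse as sp

from conftest import random_two_layer
from psne.graph_model import disease, gene
from psne.propagator import (
    PropagationParams,
    build_block_matrix,
    column_normalize,
    make_seed,
    normalize_blocks,
    rank_genes,
    rwr,
    rwr_closed_form,
    transfer,
)
from psne.reconstructor import TwoLayerNetwork


class TestColumnNormalize:
    def test_hand_example(self):
        out = column_normalize(np.array([[1.0, 2.0], [3.0, 2.0]])).toarray()
        np.testing.assert_allclose(out, [[0.25, 0.5], [0.75, 0.5]])

    def test_idempotent_on_stochastic(self):
        m = np.array([[0.3, 1.0], [0.7, 0.0]])
        np.testing.assert_allclose(column_normalize(m).toarray(), m)

    def test_zero_column_preserved(self):
        m = np.array([[0.0, 2.0], [0.0, 2.0]])
        out = column_normalize(m).toarray()
        np.testing.assert_allclose(out[:, 0], 0.0)
        np.testing.assert_allclose(out[:, 1], 0.5)

    def test_negative_entry_errors(self):
        with pytest.raises(ValueError):
            column_normalize(np.array([[1.0, -0.1], [0.0, 1.0]]))


class TestBuildBlockMatrix:
    def _blocks(self):
        net = TwoLayerNetwork(
            [disease("d0")],
            [gene("g0")],
            sp.csr_matrix(np.array([[1.0]])),
            sp.csr_matrix(np.array([[1.0]])),
            sp.csr_matrix(np.array([[1.0]])),
        )
        return normalize_blocks(net)

    def test_beta_zero_block_diagonal(self):
        D = build_block_matrix(self._blocks(), beta=0.0).toarray()
        np.testing.assert_allclose(D, [[1.0, 0.0], [0.0, 1.0]])

    def test_beta_one_only_bipartite(self):
        D = build_block_matrix(self._blocks(), beta=1.0).toarray()
        np.testing.assert_allclose(D, [[0.0, 1.0], [1.0, 0.0]])

    def test_beta_half_direct_substitution(self):
        D = build_block_matrix(self._blocks(), beta=0.5).toarray()
        np.testing.assert_allclose(D, [[0.5, 0.5], [0.5, 0.5]])

    def test_bad_beta(self):
        with pytest.raises(ValueError):
            build_block_matrix(self._blocks(), beta=1.5)


class TestTransfer:
    def test_columns_rescaled(self):
        D = np.array([[0.5, 0.2], [0.0, 0.8]])
        T = transfer(sp.csr_matrix(D)).T.toarray()
        np.testing.assert_allclose(T, [[1.0, 0.2], [0.0, 0.8]])

    def test_no_bipartite_edges_keeps_intra_layer_mass(self):
        # disease d1 has no gene association: its column sums to 1-beta
        # before repair and walks intra-layer with total probability 1 after
        H_I = np.array([[0.0, 1.0], [1.0, 0.0]])
        H_G = np.array([[1.0, 0.0], [0.0, 0.0]])  # only d0 linked
        net = TwoLayerNetwork(
            [disease("d0"), disease("d1")],
            [gene("g0"), gene("g1")],
            sp.csr_matrix(H_I),
            sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])),
            sp.csr_matrix(H_G),
        )
        beta = 0.5
        D_hat = build_block_matrix(normalize_blocks(net), beta)
        tm = transfer(D_hat)
        col_d1 = tm.T.toarray()[:, 1]
        assert tm.column_sums_before_repair[1] == pytest.approx(1 - beta)
        assert col_d1.sum() == pytest.approx(1.0, abs=1e-12)
        assert col_d1[2:].sum() == 0.0  # no gene-layer mass

    def test_isolated_node_gets_self_loop(self):
        D = np.array([[0.0, 0.3], [0.0, 0.7]])
        tm = transfer(sp.csr_matrix(D))
        T = tm.T.toarray()
        assert tm.n_dangling == 1
        np.testing.assert_allclose(T[:, 0], [1.0, 0.0])

    def test_column_stochastic_on_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            net = random_two_layer(rng)
            T = transfer(build_block_matrix(normalize_blocks(net), beta=0.5)).T
            colsums = np.asarray(T.sum(axis=0)).ravel()
            np.testing.assert_allclose(colsums, 1.0, atol=1e-12)


class TestMakeSeed:
    def _net(self):
        return TwoLayerNetwork(
            [disease("d0"), disease("d1")],
            [gene("g0"), gene("g1"), gene("g2")],
            sp.csr_matrix((2, 2)),
            sp.csr_matrix((3, 3)),
            sp.csr_matrix(np.ones((2, 3))),
        )

    def test_eta_one_all_on_disease(self):
        q0 = make_seed(self._net(), disease("d0"), {gene("g0")}, eta=1.0)
        assert q0[0] == 1.0 and q0.sum() == 1.0

    def test_even_split_over_known_genes(self):
        q0 = make_seed(self._net(), disease("d1"), {gene("g0"), gene("g2")}, eta=0.5)
        assert q0[1] == 0.5
        assert q0[2] == 0.25 and q0[4] == 0.25

    def test_empty_known_genes_fallback(self):
        q0 = make_seed(self._net(), disease("d0"), set(), eta=0.5)
        assert q0[0] == 1.0

    def test_unknown_disease_errors(self):
        with pytest.raises(KeyError):
            make_seed(self._net(), disease("dX"), set(), eta=0.5)


class TestRWR:
    def test_identity_fixed_point(self):
        T = sp.identity(4, format="csr")
        q0 = np.array([0.5, 0.5, 0.0, 0.0])
        out = rwr(T, q0, alpha=0.3)
        np.testing.assert_allclose(out.q, q0, atol=1e-12)

    def test_two_node_swap_oracle(self):
        """Fixed point of the restart walk on a 2-cycle, alpha=0.5.

        Closed form alpha (I - (1-alpha) T)^{-1} q0 gives (2/3, 1/3)."""
        T = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        q0 = np.array([1.0, 0.0])
        it = rwr(T, q0, alpha=0.5)
        cf = rwr_closed_form(T, q0, alpha=0.5)
        np.testing.assert_allclose(cf.q, [2 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(it.q, cf.q, atol=1e-9)

    def test_closed_form_alpha_one_limit(self):
        T = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        q0 = np.array([0.25, 0.75])
        out = rwr_closed_form(T, q0, alpha=1.0 - 1e-15)
        np.testing.assert_allclose(out.q, q0, atol=1e-12)

    def test_mass_conserved_and_residual_contracts(self):
        rng = np.random.default_rng(3)
        net = random_two_layer(rng, n_d=10, n_g=40)
        T = transfer(build_block_matrix(normalize_blocks(net), 0.5)).T
        q0 = make_seed(net, net.diseases[0], {net.genes[0]}, 0.5)
        # re-run the iteration manually to watch the residual sequence
        alpha = 0.7
        q = q0.copy()
        residuals = []
        for _ in range(30):
            q_next = (1 - alpha) * (T @ q) + alpha * q0
            residuals.append(np.abs(q_next - q).sum())
            q = q_next
            assert q.sum() == pytest.approx(1.0, abs=1e-9)
        for a, b in zip(residuals[3:], residuals[4:]):
            assert b <= a + 1e-15

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            net = random_two_layer(rng)
            T = transfer(build_block_matrix(normalize_blocks(net), 0.5)).T
            q0 = make_seed(net, net.diseases[0], set(net.genes[:2]), 0.5)
            it = rwr(T, q0, alpha=0.7, tol=1e-14, max_iter=5000)
            cf = rwr_closed_form(T, q0, alpha=0.7)
            assert np.max(np.abs(it.q - cf.q)) <= 1e-8

    def test_size_guard(self):
        T = sp.identity(2001, format="csr")
        q0 = np.zeros(2001)
        q0[0] = 1.0
        with pytest.raises(ValueError):
            rwr_closed_form(T, q0, alpha=0.5)

    def test_layer_swap_symmetry(self):
        """Swapping the two layer blocks permutes q consistently."""
        rng = np.random.default_rng(8)
        net = random_two_layer(rng, n_d=6, n_g=9)
        beta = 0.4
        blocks = normalize_blocks(net)
        D1 = build_block_matrix(blocks, beta).toarray()
        nd = len(net.diseases)
        n = D1.shape[0]
        perm = np.r_[np.arange(nd, n), np.arange(nd)]  # genes first
        D2 = D1[np.ix_(perm, perm)]
        q0 = make_seed(net, net.diseases[2], set(net.genes[:3]), 0.5)
        r1 = rwr(transfer(sp.csr_matrix(D1)).T, q0, 0.7, tol=1e-13).q
        r2 = rwr(transfer(sp.csr_matrix(D2)).T, q0[perm], 0.7, tol=1e-13).q
        np.testing.assert_allclose(r2, r1[perm], atol=1e-10)


class TestRankGenes:
    def _net(self):
        return TwoLayerNetwork(
            [disease("d0")],
            [gene("g1"), gene("g2"), gene("g3")],
            sp.csr_matrix((1, 1)),
            sp.csr_matrix((3, 3)),
            sp.csr_matrix(np.ones((1, 3))),
        )

    def test_sorted_descending(self):
        ranked = rank_genes(np.array([0.6, 0.1, 0.3, 0.0]), self._net())
        assert ranked.genes() == [gene("g2"), gene("g1"), gene("g3")]

    def test_exclusion(self):
        ranked = rank_genes(
            np.array([0.6, 0.1, 0.3, 0.0]), self._net(), exclude={gene("g2")}
        )
        assert ranked.genes() == [gene("g1"), gene("g3")]

    def test_tie_broken_by_id(self):
        ranked = rank_genes(np.array([0.0, 0.2, 0.2, 0.1]), self._net())
        assert ranked.genes() == [gene("g1"), gene("g2"), gene("g3")]
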