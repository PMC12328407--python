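"""Label-graph statistics pipeline and attention refinement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meddgtn.dame import (AnnotationMatrix, AttentionHeadParams,
                          CorrelationGraph, DynamicGraph, attention_head,
                          attention_matrix, binarize, build_correlation_graph,
                          build_subgraph, complexity_estimate,
                          compose_adjacency, conditional_probabilities,
                          count_cooccurrence, reweight)
from meddgtn.synthdata import SynthSpec, sample_labels


def ann(values, labels=None):
    values = np.asarray(values)
    labels = labels or [f"l{i}" for i in range(values.shape[1])]
    return AnnotationMatrix(values=values, label_order=labels)


class TestCooccurrence:
    def test_three_sample_counts(self):
        M = count_cooccurrence(ann([[1, 1], [1, 0], [0, 1]], ["a", "b"]))
        assert M.counts.tolist() == [[2, 1], [1, 2]]

    def test_all_zero_annotations(self):
        M = count_cooccurrence(ann(np.zeros((5, 3), dtype=int)))
        assert not M.counts.any()

    def test_planted_blocks_match_pair_enumeration(self):
        spec = SynthSpec(C=6, n=200, blocks=[[0, 1, 2], [3, 4, 5]],
                         p_within=0.6, p_between=0.05, seed=11)
        a = sample_labels(spec)
        M = count_cooccurrence(a)
        # brute-force oracle: enumerate samples per pair
        for i in range(6):
            for j in range(6):
                expected = sum(int(r[i] and r[j]) for r in a.values)
                assert M.counts[i, j] == expected
        within = [M.counts[i, j] for i, j in itertools.combinations(range(3), 2)]
        between = [M.counts[i, j] for i in range(3) for j in range(3, 6)]
        assert np.mean(within) > np.mean(between)

    def test_symmetry_and_diagonal_exhaustive(self):
        # every binary 3x3 annotation matrix
        for bits in itertools.product((0, 1), repeat=9):
            values = np.array(bits).reshape(3, 3)
            M = count_cooccurrence(ann(values)).counts
            assert (M == M.T).all()
            assert (np.diag(M) == values.sum(axis=0)).all()
            assert all(M[i, j] <= min(M[i, i], M[j, j])
                       for i in range(3) for j in range(3))

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            ann([[0, 2]])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            ann(np.zeros((0, 2), dtype=int))


class TestConditionalProbabilities:
    def test_forced_arithmetic(self):
        M = count_cooccurrence(ann([[1, 1]] * 4 + [[1, 0]] * 6 + [[0, 1]]))
        probs = conditional_probabilities(M).probs
        assert np.allclose(probs, [[1.0, 0.4], [0.8, 1.0]])

    def test_diagonal_only_counts_give_identity(self):
        a = ann(np.eye(4, dtype=int))
        probs = conditional_probabilities(count_cooccurrence(a)).probs
        assert np.allclose(probs, np.eye(4))

    def test_matches_elementwise_division_oracle(self):
        spec = SynthSpec(C=6, n=200, blocks=[[0, 1, 2], [3, 4, 5]], seed=11)
        M = count_cooccurrence(sample_labels(spec))
        probs = conditional_probabilities(M).probs
        for i in range(6):
            for j in range(6):
                assert probs[i, j] == pytest.approx(
                    M.counts[i, j] / M.counts[i, i])
        assert not np.allclose(probs, probs.T)   # row conditioning asymmetry

    def test_zero_occurrence_label_isolated(self):
        a = ann([[1, 0], [1, 0]])
        probs = conditional_probabilities(count_cooccurrence(a)).probs
        assert probs[1].tolist() == [0.0, 1.0]


class TestBinarize:
    def test_boundary_maps_to_one(self):
        Mp = conditional_probabilities(count_cooccurrence(ann([[1, 1]])))
        Mp.probs = np.array([[1.0, 0.4], [0.39, 1.0]])
        A = binarize(Mp, 0.4)
        assert A.values.tolist() == [[1, 1], [0, 1]]

    def test_tau_zero_keeps_everything(self):
        Mp = conditional_probabilities(count_cooccurrence(ann([[1, 1]])))
        Mp.probs = np.array([[1.0, 0.0], [0.5, 1.0]])
        assert binarize(Mp, 0.0).values.min() == 1

    def test_matches_elementwise_oracle(self, rng):
        Mp = conditional_probabilities(count_cooccurrence(ann([[1, 1, 1]])))
        Mp.probs = rng.random((3, 3))
        A = binarize(Mp, 0.5).values
        assert (A == (Mp.probs >= 0.5).astype(int)).all()

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(0, 2 ** 16 - 1))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_tau(self, t1, t2, bits):
        lo, hi = sorted((t1, t2))
        probs = (np.array([(bits >> k) & 1 for k in range(16)])
                 .reshape(4, 4) * 0.7 + 0.15)
        Mp = conditional_probabilities(count_cooccurrence(ann([[1] * 4])))
        Mp.probs = probs
        assert (binarize(Mp, hi).values <= binarize(Mp, lo).values).all()

    def test_rejects_tau_out_of_range(self):
        Mp = conditional_probabilities(count_cooccurrence(ann([[1, 1]])))
        with pytest.raises(ValueError):
            binarize(Mp, 1.5)


class TestReweight:
    def _adjacency(self, values, tau=0.4):
        Mp = conditional_probabilities(count_cooccurrence(
            ann([[1] * len(values)])))
        Mp.probs = np.asarray(values, dtype=float)
        return binarize(Mp, tau)

    def test_two_neighbours_at_default_p(self):
        A = self._adjacency([[1, 1, 1], [1, 1, 0], [1, 0, 1]])
        N = reweight(A, 0.2)
        assert N.values[0].tolist() == pytest.approx([0.8, 0.1, 0.1])

    def test_p_zero_gives_identity(self):
        A = self._adjacency(np.ones((4, 4)))
        assert np.allclose(reweight(A, 0.0).values, np.eye(4))

    def test_offdiagonal_row_mass(self, rng):
        A = self._adjacency((rng.random((6, 6)) > 0.4).astype(float), 0.5)
        N = reweight(A, 0.5).values
        adj = A.values.copy()
        np.fill_diagonal(adj, 0)
        for i in range(6):
            offmass = N[i].sum() - N[i, i]
            expected = 0.5 if adj[i].sum() > 0 else 0.0
            assert offmass == pytest.approx(expected)
            assert N[i, i] == pytest.approx(0.5)

    def test_rejects_p_out_of_range(self):
        with pytest.raises(ValueError):
            reweight(self._adjacency(np.eye(2)), -0.1)


class TestAttention:
    def test_zero_scores_give_column_mean_of_v(self, rng):
        C, dh = 4, 3
        Wv = rng.standard_normal((C, dh))
        params = AttentionHeadParams(Wq=np.zeros((C, dh)),
                                     Wk=np.zeros((C, dh)), Wv=Wv)
        N = CorrelationGraph(np.eye(C), 0.2, list("abcd"))
        out = attention_head(N, params)
        v = np.eye(C) @ Wv
        assert np.allclose(out, np.tile(v.mean(axis=0), (C, 1)))

    def test_attention_rows_sum_to_one(self, rng):
        C, dh = 5, 4
        params = AttentionHeadParams(*(rng.standard_normal((C, dh))
                                       for _ in range(3)))
        att = attention_matrix(rng.random((C, C)), params)
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_dense_algebra_oracle(self):
        C, dh = 3, 2
        N = np.array([[0.8, 0.1, 0.1], [0.2, 0.6, 0.2], [0.0, 0.3, 0.7]])
        Wq = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        Wk = np.array([[0.5, -0.5], [1.0, 0.0], [0.0, 2.0]])
        Wv = np.array([[1.0, 2.0], [-1.0, 0.5], [0.0, 1.0]])
        out = attention_head(N, AttentionHeadParams(Wq, Wk, Wv))
        q, k, v = N @ Wq, N @ Wk, N @ Wv
        scores = q @ k.T / np.sqrt(dh)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        expected = (e / e.sum(axis=1, keepdims=True)) @ v
        assert np.allclose(out, expected)

    def test_shape_mismatch_rejected(self, rng):
        params = AttentionHeadParams(*(rng.standard_normal((3, 2))
                                       for _ in range(3)))
        with pytest.raises(ValueError):
            attention_head(np.eye(4), params)


class TestSubgraphsAndComposition:
    def test_subgraph_shape_contract(self, rng):
        C, dh = 4, 3
        heads = [AttentionHeadParams(*(rng.standard_normal((C, dh))
                                       for _ in range(3)))]
        G = build_subgraph(np.eye(C), heads, rng.standard_normal((dh, C)))
        assert G.values.shape == (C, C)

    def test_all_zero_parameters_give_zero_subgraph(self):
        C, dh = 3, 2
        heads = [AttentionHeadParams(np.zeros((C, dh)), np.zeros((C, dh)),
                                     np.zeros((C, dh)))]
        G = build_subgraph(np.eye(C), heads, np.zeros((dh, C)))
        assert not G.values.any()

    def test_matches_concat_project_oracle(self):
        rng = np.random.default_rng(5)
        C, h, dh = 4, 2, 3
        N = rng.random((C, C))
        heads = [AttentionHeadParams(*(rng.standard_normal((C, dh))
                                       for _ in range(3))) for _ in range(h)]
        Wo = rng.standard_normal((h * dh, C))
        G = build_subgraph(N, heads, Wo).values
        outs = []
        for p in heads:
            q, k, v = N @ p.Wq, N @ p.Wk, N @ p.Wv
            s = q @ k.T / np.sqrt(dh)
            e = np.exp(s - s.max(axis=1, keepdims=True))
            outs.append((e / e.sum(axis=1, keepdims=True)) @ v)
        expected = np.maximum(np.concatenate(outs, axis=1) @ Wo, 0.0)
        assert np.allclose(G, expected)

    def test_wrong_projection_dimension_rejected(self, rng):
        heads = [AttentionHeadParams(*(rng.standard_normal((3, 2))
                                       for _ in range(3)))]
        with pytest.raises(ValueError):
            build_subgraph(np.eye(3), heads, np.zeros((2, 4)))

    def test_single_factor_and_identity_products(self):
        g = np.array([[0.5, 0.5], [0.25, 0.75]])
        assert np.allclose(compose_adjacency([g]).values, g)
        assert np.allclose(compose_adjacency([np.eye(3)] * 2).values,
                           np.eye(3))

    def test_matches_chained_matmul_oracle(self, rng):
        mats = [rng.random((4, 4)) for _ in range(3)]
        P = compose_adjacency(mats, normalize=False).values
        assert np.allclose(P, mats[0] @ mats[1] @ mats[2])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compose_adjacency([])


class TestComplexity:
    @pytest.mark.parametrize("C,d,expected", [(20, 64, 25600),
                                              (60, 64, 230400), (1, 1, 1)])
    def test_attention_weight_counts(self, C, d, expected):
        assert complexity_estimate(C, d) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            complexity_estimate(0, 64)


class TestDynamicGraph:
    def test_planted_block_structure_recovered(self):
        spec = SynthSpec(C=8, n=500, p_within=0.6, p_between=0.05, seed=1)
        N = build_correlation_graph(sample_labels(spec))
        graph = DynamicGraph(8, rng=np.random.default_rng(2))
        P = graph.adjacency(N).values
        within = [P[i, j] for i in range(8) for j in range(8) if i != j
                  and spec.block_of(i) == spec.block_of(j)]
        between = [P[i, j] for i in range(8) for j in range(8)
                   if spec.block_of(i) != spec.block_of(j)]
        assert np.mean(within) > np.mean(between)
        assert (P >= 0).all() and np.isfinite(P).all()

    def test_adjacency_rows_normalized(self, rng):
        graph = DynamicGraph(5, k=2, heads=2, d_h=4, rng=rng)
        for g in range(graph.k):          # perturb gains so attention acts
            getattr(graph, f"gain_{g}").data[:] = 0.3
        P = graph.forward(rng.random((5, 5))).data
        rows = P.sum(axis=1)
        assert np.all((np.isclose(rows, 1.0, atol=1e-9)) | (rows == 0))
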