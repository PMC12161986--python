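import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellpipe.ppi_embedding import (
    SkipGramConfig,
    WalkParams,
    exact_transition_matrix,
    generate_walks,
    second_order_weight,
    train_skipgram,
)
from cellpipe.types import ContractViolation, InteractionNetwork, canonical_edge


def network_from_edges(edges, scores=None, extra_nodes=()):
    canon = frozenset(canonical_edge(a, b) for a, b in edges)
    nodes = frozenset({n for e in canon for n in e} | set(extra_nodes))
    sc = None
    if scores is not None:
        sc = {canonical_edge(a, b): s for (a, b), s in scores.items()}
    return InteractionNetwork(nodes, canon, sc)


def clique(names):
    return [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]


class TestSecondOrderWeight:
    # triangle A-B-C plus pendant D on B: from A->B, C is a common neighbor,
    # D is neither prev nor adjacent to prev
    net = network_from_edges([("A", "B"), ("B", "C"), ("A", "C"), ("B", "D")])

    def test_return_common_and_far(self):
        assert second_order_weight("A", "B", "A", 2.0, 0.5, self.net) == 0.5
        assert second_order_weight("A", "B", "C", 2.0, 0.5, self.net) == 1.0
        assert second_order_weight("A", "B", "D", 2.0, 0.5, self.net) == 2.0

    def test_first_order_degenerate(self):
        for nxt in ("A", "C", "D"):
            assert second_order_weight("A", "B", nxt, 1.0, 1.0, self.net) == 1.0

    def test_weighted_far_edge(self):
        net = network_from_edges(
            [("A", "B"), ("B", "D")], scores={("A", "B"): 0.9, ("B", "D"): 0.7}
        )
        w = second_order_weight("A", "B", "D", 1.0, 4.0, net, use_edge_scores=True)
        assert w == pytest.approx(0.175)

    def test_non_adjacent_is_contract_violation(self):
        with pytest.raises(ContractViolation):
            second_order_weight("A", "B", "Z", 1.0, 1.0, self.net)


class TestGenerateWalks:
    def test_path_graph_steps_adjacent(self):
        net = network_from_edges([("A", "B"), ("B", "C")])
        corpus = generate_walks(net, WalkParams(num_walks=4, walk_length=3, seed=0))
        adj = net.neighbors()
        for walk in corpus.walks:
            for a, b in zip(walk, walk[1:]):
                assert b in adj[a]

    def test_walk_count_includes_isolated(self):
        net = network_from_edges([("A", "B")], extra_nodes=["Z"])
        corpus = generate_walks(net, WalkParams(num_walks=3, walk_length=5, seed=0))
        assert len(corpus.walks) == 3 * 3
        assert ["Z"] in corpus.walks

    def test_same_seed_identical(self):
        net = network_from_edges(clique(["A", "B", "C", "D"]))
        p = WalkParams(num_walks=5, walk_length=10, seed=42)
        assert generate_walks(net, p).walks == generate_walks(net, p).walks

    def test_q_bias_controls_bridge_crossing(self):
        # two 5-cliques joined by one bridge; large q biases walks inward
        left = [f"L{i}" for i in range(5)]
        right = [f"R{i}" for i in range(5)]
        edges = clique(left) + clique(right) + [("L0", "R0")]
        net = network_from_edges(edges)
        bridge = canonical_edge("L0", "R0")

        def crossing_fraction(q):
            corpus = generate_walks(
                net, WalkParams(num_walks=100, walk_length=10, p=1.0, q=q, seed=7)
            )
            steps = cross = 0
            for walk in corpus.walks:
                for a, b in zip(walk, walk[1:]):
                    steps += 1
                    if canonical_edge(a, b) == bridge:
                        cross += 1
            return cross / steps

        assert crossing_fraction(10.0) < crossing_fraction(0.1)

    def test_empty_network_rejected(self):
        with pytest.raises(ContractViolation):
            generate_walks(
                InteractionNetwork(frozenset(), frozenset()), WalkParams(seed=0)
            )

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 8), p_edge=st.floats(0.3, 0.9))
    def test_adjacency_invariant_random_graphs(self, seed, n, p_edge):
        rng = np.random.default_rng(seed)
        names = [f"N{i}" for i in range(n)]
        edges = [
            (names[i], names[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p_edge
        ]
        if not edges:
            edges = [(names[0], names[1])]
        net = network_from_edges(edges, extra_nodes=names)
        corpus = generate_walks(
            net, WalkParams(num_walks=2, walk_length=6, p=0.5, q=2.0, seed=seed)
        )
        adj = net.neighbors()
        assert len(corpus.walks) == 2 * n
        for walk in corpus.walks:
            assert walk[0] in net.nodes
            for a, b in zip(walk, walk[1:]):
                assert b in adj[a]


class TestTransitionDistribution:
    def test_first_order_matches_exact_matrix_3sigma(self):
        # fixed 6-node graph, ~1e4 steps, p=q=1
        edges = [
            ("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "E"),
            ("E", "F"), ("C", "F"), ("B", "E"),
        ]
        net = network_from_edges(edges)
        nodes, T = exact_transition_matrix(net)
        idx = {n: i for i, n in enumerate(nodes)}
        corpus = generate_walks(net, WalkParams(num_walks=100, walk_length=18, seed=3))
        counts = np.zeros_like(T)
        for walk in corpus.walks:
            for a, b in zip(walk, walk[1:]):
                counts[idx[a], idx[b]] += 1
        total_steps = counts.sum()
        assert total_steps >= 10_000
        visits = counts.sum(axis=1)
        for i in range(len(nodes)):
            for j in range(len(nodes)):
                exp = visits[i] * T[i, j]
                if T[i, j] == 0:
                    assert counts[i, j] == 0
                else:
                    sigma = np.sqrt(visits[i] * T[i, j] * (1 - T[i, j]))
                    assert abs(counts[i, j] - exp) <= 3 * sigma + 1e-9


class TestSkipGram:
    def test_two_cliques_separate(self):
        left = [f"L{i}" for i in range(5)]
        right = [f"R{i}" for i in range(5)]
        net = network_from_edges(clique(left) + clique(right))
        corpus = generate_walks(net, WalkParams(num_walks=20, walk_length=10, seed=0))
        emb = train_skipgram(corpus, SkipGramConfig(dimension=16, epochs=5, seed=0))
        X = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
        S = X @ X.T
        idx = emb.index()
        li = [idx[n] for n in left]
        ri = [idx[n] for n in right]
        within = np.mean([S[a, b] for g in (li, ri) for a in g for b in g if a < b])
        between = np.mean([S[a, b] for a in li for b in ri])
        assert within > between

    def test_repeated_walks_finite_and_similarity_grows(self):
        corpus_walks = [["A", "B"] * 5] * 20
        from cellpipe.ppi_embedding import WalkCorpus

        def cos_after(epochs):
            corpus = WalkCorpus([list(w) for w in corpus_walks], WalkParams(seed=0))
            emb = train_skipgram(
                corpus, SkipGramConfig(dimension=8, window=2, epochs=epochs, seed=1)
            )
            v = emb.vectors
            assert np.all(np.isfinite(v))
            i, j = emb.index()["A"], emb.index()["B"]
            return float(
                v[i] @ v[j] / (np.linalg.norm(v[i]) * np.linalg.norm(v[j]))
            )

        assert cos_after(10) > cos_after(0) or cos_after(10) > 0.9

    def test_single_node_empty_context_keeps_init(self):
        from cellpipe.ppi_embedding import WalkCorpus

        corpus = WalkCorpus([["A"]], WalkParams(seed=0))
        cfg = SkipGramConfig(dimension=1, epochs=3, seed=5)
        emb = train_skipgram(corpus, cfg)
        rng = np.random.default_rng(5)
        init = (rng.random((1, 1)) - 0.5) / 1
        assert np.array_equal(emb.vectors, init)

    def test_determinism_bit_identical(self):
        net = network_from_edges(clique(["A", "B", "C", "D", "E"]))
        corpus = generate_walks(net, WalkParams(num_walks=5, walk_length=8, seed=2))
        cfg = SkipGramConfig(dimension=12, epochs=3, seed=9)
        e1 = train_skipgram(corpus, cfg)
        e2 = train_skipgram(corpus, cfg)
        assert e1 == e2

    def test_isolated_vocab_node_logged(self, caplog):
        from cellpipe.ppi_embedding import WalkCorpus

        corpus = WalkCorpus([["A", "B"], ["B", "A"]], WalkParams(seed=0))
        with caplog.at_level("WARNING"):
            emb = train_skipgram(
                corpus, SkipGramConfig(dimension=4, epochs=1, seed=0), vocabulary=["A", "B", "Z"]
            )
        assert "Z" in caplog.text
        assert set(emb.ids) == {"A", "B", "Z"}


class TestSeparationProperty:
    def test_sbm_within_vs_between_cosine(self):
        # 2-block SBM (p_in=0.4, p_out=0.02, 30+30); majority of seeded runs
        wins = 0
        runs = 6
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            names = [f"A{i}" for i in range(30)] + [f"B{i}" for i in range(30)]
            edges = []
            for i in range(60):
                for j in range(i + 1, 60):
                    p = 0.4 if (i < 30) == (j < 30) else 0.02
                    if rng.random() < p:
                        edges.append((names[i], names[j]))
            net = network_from_edges(edges, extra_nodes=names)
            corpus = generate_walks(
                net, WalkParams(num_walks=5, walk_length=15, seed=seed)
            )
            emb = train_skipgram(
                corpus, SkipGramConfig(dimension=16, epochs=3, seed=seed)
            )
            X = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
            S = X @ X.T
            idx = emb.index()
            ai = [idx[n] for n in names[:30] if n in idx]
            bi = [idx[n] for n in names[30:] if n in idx]
            within = np.mean(
                [S[a, b] for blk in (ai, bi) for a in blk for b in blk if a < b]
            )
            between = np.mean([S[a, b] for a in ai for b in bi])
            wins += within > between
        assert wins >= runs - 1
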