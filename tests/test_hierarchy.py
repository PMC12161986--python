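import numpy as np
import pytest

from cellpipe.hierarchy import (
    Community,
    PooledCommunity,
    build_dag,
    build_graph_stack,
    compute_persistence,
    containment_index,
    cosine_matrix,
    cpm_partition,
    dedupe_communities,
    detect_communities,
    jaccard,
    read_hierarchy,
    write_hierarchy,
)
from cellpipe.types import ContractViolation, EmbeddingSet

from .cpm_oracle import brute_force_cpm, canonical, clique_edges


def emb(ids, vectors):
    return EmbeddingSet(list(ids), np.asarray(vectors, dtype=float), "coembedding")


class TestCosineMatrix:
    def test_identical_vectors(self):
        m = cosine_matrix(emb(["A", "B"], [[1.0, 2.0], [2.0, 4.0]]))
        assert m.matrix[0, 1] == pytest.approx(1.0)

    def test_orthogonal(self):
        m = cosine_matrix(emb(["A", "B"], [[1.0, 0.0], [0.0, 1.0]]))
        assert m.matrix[0, 1] == pytest.approx(0.0)

    def test_closed_form(self):
        m = cosine_matrix(emb(["A", "B"], [[1.0, 1.0], [1.0, 0.0]]))
        assert m.matrix[0, 1] == pytest.approx(0.70710678, abs=1e-8)

    def test_zero_vector_error(self):
        with pytest.raises(ContractViolation):
            cosine_matrix(emb(["A", "B"], [[0.0, 0.0], [1.0, 0.0]]))

    def test_diag_and_symmetry(self, rng):
        m = cosine_matrix(emb([f"P{i}" for i in range(6)], rng.normal(size=(6, 4))))
        assert np.allclose(np.diag(m.matrix), 1.0)
        assert np.allclose(m.matrix, m.matrix.T)


class TestGraphStack:
    def test_full_fraction_complete_graph(self, rng):
        sim = cosine_matrix(emb(["A", "B", "C", "D"], rng.normal(size=(4, 3))))
        stack = build_graph_stack(sim, [1.0])
        assert stack.edge_lists[0].shape[0] == 6

    def test_single_top_pair(self):
        vecs = np.array([[1.0, 0.0], [1.0, 0.01], [0.0, 1.0], [-1.0, 0.5]])
        sim = cosine_matrix(emb(["A", "B", "C", "D"], vecs))
        stack = build_graph_stack(sim, [1 / 6])
        (edge,) = stack.edge_lists[0].tolist()
        assert sorted(edge) == [0, 1]  # A-B is the most similar pair

    def test_nesting_chain(self, rng):
        n = 20
        sim = cosine_matrix(emb([f"P{i}" for i in range(n)], rng.normal(size=(n, 8))))
        stack = build_graph_stack(sim, [0.05, 0.10, 0.25])
        sets = [
            {tuple(e) for e in el.tolist()} for el in stack.edge_lists
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_too_few_nodes(self, rng):
        sim = cosine_matrix(emb(["A", "B"], rng.normal(size=(2, 3))))
        with pytest.raises(ContractViolation):
            build_graph_stack(sim, [0.5])

    def test_bad_fractions(self, rng):
        sim = cosine_matrix(emb(["A", "B", "C"], rng.normal(size=(3, 3))))
        for bad in ([], [0.5, 0.5], [0.9, 0.3], [0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(ContractViolation):
                build_graph_stack(sim, bad)


class TestCpmAgainstOracle:
    def test_two_cliques_one_bridge(self):
        edges = clique_edges(range(5)) + clique_edges(range(5, 10)) + [(0, 5)]
        gammas = [0.3, 0.5, 0.9]
        oracle = brute_force_cpm(10, edges, gammas)
        for g in gammas:
            part = canonical(cpm_partition(10, edges, g, seed=0))
            best_q, optima = oracle[g]
            assert part in optima
        # at mid resolution both cliques are separate communities
        part = cpm_partition(10, edges, 0.5, seed=0)
        assert sorted(map(sorted, part)) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]

    def test_complete_graph_lowest_resolution(self):
        edges = clique_edges(range(6))
        part = cpm_partition(6, edges, 1e-3, seed=0)
        assert len(part) == 1 and sorted(part[0]) == list(range(6))


class TestDetectCommunities:
    def make_stack(self, vectors, ids, fractions):
        return build_graph_stack(cosine_matrix(emb(ids, vectors)), fractions)

    def test_two_cliques_in_pool(self, rng):
        # two tight orthogonal groups of 5
        base = np.array([[1.0, 0.0], [0.0, 1.0]])
        vecs = np.vstack(
            [base[i // 5] + rng.normal(scale=0.01, size=2) for i in range(10)]
        )
        ids = [f"P{i}" for i in range(10)]
        stack = self.make_stack(vecs, ids, [0.5, 1.0])
        pool = detect_communities(stack, resolutions=[0.5], min_size=4, seed=0)
        sets = {c.members for c in pool}
        assert frozenset(ids[:5]) in sets
        assert frozenset(ids[5:]) in sets

    def test_min_size_suppresses_triangle(self, rng):
        vecs = np.vstack(
            [
                np.tile([1.0, 0.0], (3, 1)) + rng.normal(scale=0.01, size=(3, 2)),
                np.tile([0.0, 1.0], (5, 1)) + rng.normal(scale=0.01, size=(5, 2)),
            ]
        )
        ids = [f"P{i}" for i in range(8)]
        stack = self.make_stack(vecs, ids, [1.0])
        pool = detect_communities(stack, resolutions=[0.9], min_size=4, seed=0)
        assert all(len(c.members) >= 4 for c in pool)
        assert not any(c.members == frozenset(ids[:3]) for c in pool)

    def test_deterministic(self, rng):
        vecs = rng.normal(size=(12, 4))
        ids = [f"P{i}" for i in range(12)]
        stack = self.make_stack(vecs, ids, [0.3, 0.6])
        p1 = detect_communities(stack, resolutions=[0.1, 1.0], seed=5)
        p2 = detect_communities(stack, resolutions=[0.1, 1.0], seed=5)
        assert p1 == p2


class TestPersistence:
    def pc(self, cell, members):
        return PooledCommunity(cell, 0, 1.0, frozenset(members))

    def test_identical_across_five_cells(self):
        pool = [self.pc(c, "ABCDEF") for c in range(5)]
        out = compute_persistence(pool, jaccard_tau=0.75, rho_min=1)
        assert len(out) == 1
        assert out[0].persistence == 5

    def test_jaccard_above_tau_same_chain(self):
        a = set("ABCDEFGHIJ")  # {A..J}
        b = (a - {"J"}) | {"K"}  # {A..I,K}, Jaccard 9/11
        assert jaccard(frozenset(a), frozenset(b)) == pytest.approx(9 / 11)
        pool = [self.pc(0, a), self.pc(1, b)]
        out = compute_persistence(pool, jaccard_tau=0.75, rho_min=1)
        assert len(out) == 1
        assert out[0].persistence == 2
        assert out[0].members == frozenset(a)  # larger-or-lex-smaller representative

    def test_short_chain_dropped(self):
        pool = [self.pc(0, "ABCD"), self.pc(1, "ABCD")]
        assert compute_persistence(pool, rho_min=3) == []

    def test_gap_breaks_chain(self):
        pool = [self.pc(0, "ABCD"), self.pc(2, "ABCD")]
        out = compute_persistence(pool, rho_min=1)
        assert sorted(c.persistence for c in out) == [1, 1]

    def test_dissimilar_sets_do_not_chain(self):
        pool = [self.pc(0, "ABCD"), self.pc(1, "WXYZ")]
        out = compute_persistence(pool, rho_min=1)
        assert len(out) == 2
        assert all(c.persistence == 1 for c in out)


class TestContainmentAndDag:
    def test_containment_examples(self):
        assert containment_index(frozenset("AB"), frozenset("ABC")) == 1.0
        assert containment_index(frozenset("AB"), frozenset("CD")) == 0.0
        assert containment_index(frozenset("ABCD"), frozenset("ABCX")) == 0.75

    def c(self, members, persistence=3):
        return Community(frozenset(members), persistence, (0, 1.0))

    def test_chain_dag(self):
        dag = build_dag(
            [self.c("ABCDEFGH"), self.c("ABCD"), self.c("AB")], list("ABCDEFGH"), 0.75
        )
        names = {frozenset(n.members): k for k, n in dag.nodes.items()}
        big, mid, small = (
            names[frozenset("ABCDEFGH")],
            names[frozenset("ABCD")],
            names[frozenset("AB")],
        )
        assert set(dag.edges) == {("Root", big), (big, mid), (mid, small)}

    def test_disjoint_children_of_root(self):
        dag = build_dag([self.c("ABCD"), self.c("EFGH")], list("ABCDEFGH"), 0.75)
        assert all(p == "Root" for p, _ in dag.edges)

    def test_minimal_parent_no_shortcut(self):
        dag = build_dag(
            [self.c("ABCDEF"), self.c("ABCD"), self.c("ABC")], list("ABCDEF"), 0.75
        )
        names = {frozenset(n.members): k for k, n in dag.nodes.items()}
        child = names[frozenset("ABC")]
        assert dag.parents(child) == [names[frozenset("ABCD")]]

    def test_dedupe(self):
        comms = [self.c("ABCDEFGHIJ", 5), self.c("ABCDEFGHIK", 2), self.c("XYZW", 4)]
        kept = dedupe_communities(comms, dedupe_tau=0.8)
        assert len(kept) == 2
        assert frozenset("ABCDEFGHIJ") in {k.members for k in kept}

    def test_validate_rejects_orphans(self):
        from cellpipe.hierarchy import DagNode, HierarchyDAG

        dag = HierarchyDAG(
            {"Root": DagNode("Root", frozenset("AB"), 0), "C0": DagNode("C0", frozenset("A"), 1)},
            [],
        )
        with pytest.raises(ContractViolation):
            dag.validate()


class TestWriteRead:
    def dag3(self):
        return build_dag(
            [
                Community(frozenset("ABCD"), 4, (0, 1.0)),
                Community(frozenset("AB"), 3, (0, 1.0)),
            ],
            list("ABCD"),
            0.75,
        )

    def test_edge_rows_include_root(self, tmp_path):
        write_hierarchy(self.dag3(), tmp_path)
        rows = (tmp_path / "hierarchy_edges.tsv").read_text().splitlines()
        assert len(rows) == 2
        assert all(r.endswith("\tcontains") for r in rows)

    def test_nodes_round_trip(self, tmp_path):
        dag = self.dag3()
        write_hierarchy(dag, tmp_path)
        back = read_hierarchy(tmp_path)
        assert {n.members for n in back.nodes.values()} == {
            n.members for n in dag.nodes.values()
        }
        assert sorted(back.edges) == sorted(dag.edges)

    def test_multi_parent_duplicated_in_json(self, tmp_path):
        import json

        # child contained (>= 0.75) in two incomparable parents
        dag = build_dag(
            [
                Community(frozenset("ABCDE"), 4, (0, 1.0)),
                Community(frozenset("ABCDF"), 4, (0, 1.0)),
                Community(frozenset("ABCD"), 3, (0, 1.0)),
            ],
            list("ABCDEF"),
            0.75,
        )
        child = [k for k, n in dag.nodes.items() if n.members == frozenset("ABCD")][0]
        assert len(dag.parents(child)) == 2
        write_hierarchy(dag, tmp_path)
        doc = json.loads((tmp_path / "hierarchy.json").read_text())
        blob = json.dumps(doc)
        assert blob.count(f'"name": "{child}"') == 2
        assert '"duplicate": true' in blob


class TestEndToEndHierarchy:
    def test_planted_recovery_and_determinism(self, demo150_chain, demo150_dag):
        from cellpipe.hierarchy import build_hierarchy
        from cellpipe.synthetic import recovery_score, truth_sets

        planted, _, _, _, result = demo150_chain
        dag = demo150_dag
        ra = recovery_score(dag, truth_sets(planted, "assembly"), threshold=0.5)
        assert ra.fraction_recovered >= 0.8
        # determinism: same seed, identical DAG
        dag2 = build_hierarchy(result.embedding, seed=7)
        assert {k: v.members for k, v in dag.nodes.items()} == {
            k: v.members for k, v in dag2.nodes.items()
        }
        assert sorted(dag.edges) == sorted(dag2.edges)
        # every community is a subset of the universe; root covers everything
        universe = dag.nodes[dag.root].members
        for node in dag.non_root_nodes():
            assert node.members <= universe
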