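"""Multi-scale assembly hierarchy construction.

Cosine similarities of the unified embedding → a nested stack of threshold
graphs at increasing edge densities → CPM partitioning swept over a
log-spaced resolution ladder in every (threshold, resolution) cell →
persistence filtering of communities re-identified across consecutive sweep
cells → deduplication → a containment DAG rooted at the full protein set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np

from .types import CellpipeError, ContractViolation, EmbeddingSet

logger = logging.getLogger(__name__)

DEFAULT_EDGE_FRACTIONS = (0.002, 0.005, 0.01, 0.02, 0.04, 0.07, 0.10, 0.20, 0.35, 0.50)


def default_resolutions(n: int = 40) -> np.ndarray:
    """Log-spaced CPM resolution ladder in [1e-3, 10]."""
    return np.logspace(-3, 1, n)


@dataclass
class SimilarityMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ContractViolation("similarity matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ContractViolation("similarity matrix not symmetric")
        if self.matrix.min() < -1.0 - 1e-9 or self.matrix.max() > 1.0 + 1e-9:
            raise ContractViolation("similarity entries outside [-1, 1]")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ContractViolation("similarity diagonal must be 1")


@dataclass
class GraphStack:
    ids: list[str]
    fractions: list[float]
    edge_lists: list[np.ndarray]  # (m, 2) int arrays into ids, canonical order

    def graph(self, level: int) -> ig.Graph:
        g = ig.Graph(n=len(self.ids), edges=[tuple(e) for e in self.edge_lists[level]])
        g.vs["name"] = self.ids
        return g


@dataclass(frozen=True)
class Community:
    members: frozenset[str]
    persistence: int
    origin: tuple[int, float]  # (threshold index, resolution) of first detection

    def __post_init__(self) -> None:
        if self.persistence < 1:
            raise ContractViolation("persistence must be >= 1")
        if not self.members:
            raise ContractViolation("community must be non-empty")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass
class DagNode:
    name: str
    members: frozenset[str]
    persistence: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HierarchyDAG:
    nodes: dict[str, DagNode]
    edges: list[tuple[str, str]]  # (parent, child)
    root: str = "Root"

    def children(self, name: str) -> list[str]:
        return sorted(c for p, c in self.edges if p == name)

    def parents(self, name: str) -> list[str]:
        return sorted(p for p, c in self.edges if c == name)

    def non_root_nodes(self) -> list[DagNode]:
        return [n for k, n in sorted(self.nodes.items()) if k != self.root]

    def validate(self) -> None:
        if self.root not in self.nodes:
            raise ContractViolation("missing root node")
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise ContractViolation(f"dangling edge {p}->{c}")
        for name in self.nodes:
            if name != self.root and not self.parents(name):
                raise ContractViolation(f"non-root node {name} has no parent")
        # acyclicity via DFS
        state: dict[str, int] = {}

        def dfs(u: str) -> None:
            state[u] = 1
            for v in self.children(u):
                if state.get(v, 0) == 1:
                    raise ContractViolation("hierarchy contains a cycle")
                if state.get(v, 0) == 0:
                    dfs(v)
            state[u] = 2

        dfs(self.root)


def cosine_matrix(emb: EmbeddingSet) -> SimilarityMatrix:
    """Pairwise cosine similarities; unit diagonal enforced exactly."""
    norms = np.linalg.norm(emb.vectors, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ContractViolation(
            f"zero vector(s): {', '.join(emb.ids[i] for i in zero[:5])}"
        )
    X = emb.vectors / norms[:, None]
    M = np.clip(X @ X.T, -1.0, 1.0)
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(list(emb.ids), M)


def build_graph_stack(
    sim: SimilarityMatrix, edge_fractions: Sequence[float] = DEFAULT_EDGE_FRACTIONS
) -> GraphStack:
    """Keep the top ⌈f·n(n−1)/2⌉ pairs per fraction; stricter cuts nest in looser.

    Ties in similarity break lexicographically on the id pair.
    """
    n = len(sim.ids)
    if n < 3:
        raise ContractViolation(f"need >= 3 proteins to build a graph stack, got {n}")
    fr = list(edge_fractions)
    if not fr or any(not (0 < f <= 1) for f in fr) or any(
        fr[i] >= fr[i + 1] for i in range(len(fr) - 1)
    ):
        raise ContractViolation("edge_fractions must be strictly increasing in (0, 1]")
    iu, ju = np.triu_indices(n, k=1)
    sims = sim.matrix[iu, ju]
    # order by similarity desc, ties by lexicographic id pair (ids sorted order
    # == index order only if ids sorted; sort keys built explicitly)
    id_arr = np.array(sim.ids)
    pair_a = id_arr[iu]
    pair_b = id_arr[ju]
    order = np.lexsort((pair_b, pair_a, -sims))
    n_pairs = sims.size
    edge_lists = []
    for f in fr:
        m = min(n_pairs, int(np.ceil(f * n_pairs)))
        sel = order[:m]
        edge_lists.append(np.stack([iu[sel], ju[sel]], axis=1))
    return GraphStack(list(sim.ids), fr, edge_lists)


@dataclass(frozen=True)
class PooledCommunity:
    cell: int  # flat sweep-cell index (threshold-major, then resolution)
    threshold_index: int
    resolution: float
    members: frozenset[str]


def _leiden_cpm(
    g: ig.Graph, resolution: float, seed: int, restarts: int = 3
) -> list[list[int]]:
    """Best-of-``restarts`` CPM Leiden partition (deterministic given seed)."""
    best = None
    best_q = -np.inf
    for r in range(restarts):
        part = leidenalg.find_partition(
            g,
            leidenalg.CPMVertexPartition,
            resolution_parameter=resolution,
            seed=seed + r,
            n_iterations=-1,
        )
        q = part.quality()
        if q > best_q + 1e-12:
            best_q = q
            best = part
    return [sorted(c) for c in best]


def cpm_partition(
    n: int, edges: Sequence[tuple[int, int]], resolution: float, seed: int = 0, restarts: int = 3
) -> list[list[int]]:
    """CPM Leiden partition of an explicit edge list (exposed for oracles)."""
    g = ig.Graph(n=n, edges=list(edges))
    return _leiden_cpm(g, resolution, seed=seed, restarts=restarts)


def detect_communities(
    stack: GraphStack,
    resolutions: Sequence[float] | None = None,
    min_size: int = 4,
    seed: int = 0,
    restarts: int = 3,
) -> list[PooledCommunity]:
    """Run CPM partitioning at every (threshold, resolution) sweep cell.

    The pool holds every member set of size >= min_size tagged with its cell.
    Cells are ordered threshold-major (all resolutions within a threshold,
    then the next threshold), matching the persistence-chain ordering.
    """
    res = np.asarray(
        resolutions if resolutions is not None else default_resolutions(), dtype=float
    )
    if res.size == 0 or np.any(res <= 0):
        raise ContractViolation("resolutions must be positive")
    pool: list[PooledCommunity] = []
    cell = 0
    for t_idx in range(len(stack.fractions)):
        g = stack.graph(t_idx)
        if g.ecount() == 0:
            logger.info("threshold %d: empty graph, cells skipped", t_idx)
            cell += res.size
            continue
        for r_idx, gamma in enumerate(res):
            cell_seed = (seed * 100003 + cell) % (2**31 - 1000)  # keep int32-safe
            part = _leiden_cpm(g, float(gamma), seed=cell_seed, restarts=restarts)
            for comm in part:
                if len(comm) >= min_size:
                    pool.append(
                        PooledCommunity(
                            cell=cell,
                            threshold_index=t_idx,
                            resolution=float(gamma),
                            members=frozenset(stack.ids[i] for i in comm),
                        )
                    )
            cell += 1
    return pool


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def compute_persistence(
    pool: Sequence[PooledCommunity],
    jaccard_tau: float = 0.75,
    rho_min: int = 3,
) -> list[Community]:
    """Chain communities across consecutive sweep cells by Jaccard >= tau.

    Persistence is the chain length; each surviving chain is represented by
    its medoid member set — the one with maximal mean Jaccard to the rest of
    the chain (ties → larger set, then lexicographically smallest member
    list). The medoid is the chain's stable core; taking the largest set
    instead would propagate transiently merged variants.
    """
    by_cell: dict[int, list[PooledCommunity]] = {}
    for c in pool:
        by_cell.setdefault(c.cell, []).append(c)
    cells = sorted(by_cell)

    # chain: tail = member set at the latest cell; sets = every cell's version
    active: list[dict] = []
    finished: list[dict] = []
    prev_cell = None
    for cell in cells:
        current = sorted(by_cell[cell], key=lambda c: tuple(sorted(c.members)))
        if prev_cell is not None and cell != prev_cell + 1:
            finished.extend(active)
            active = []
        # candidate matches between active chain tails and current communities
        cands: list[tuple[float, int, int]] = []
        for ci, chain in enumerate(active):
            for ki, com in enumerate(current):
                j = jaccard(chain["tail"], com.members)
                if j >= jaccard_tau:
                    cands.append((j, ci, ki))
        cands.sort(key=lambda x: (-x[0], x[1], x[2]))
        chain_used: set[int] = set()
        comm_used: set[int] = set()
        new_active: list[dict] = []
        for j, ci, ki in cands:
            if ci in chain_used or ki in comm_used:
                continue
            chain_used.add(ci)
            comm_used.add(ki)
            chain = active[ci]
            com = current[ki]
            chain["tail"] = com.members
            chain["sets"].append(com.members)
            new_active.append(chain)
        for ci, chain in enumerate(active):
            if ci not in chain_used:
                finished.append(chain)
        for ki, com in enumerate(current):
            if ki not in comm_used:
                new_active.append(
                    {
                        "tail": com.members,
                        "sets": [com.members],
                        "origin": (com.threshold_index, com.resolution),
                    }
                )
        active = new_active
        prev_cell = cell
    finished.extend(active)

    def medoid(sets: list[frozenset]) -> frozenset:
        best = None
        best_key = None
        for s in sets:
            mean_j = sum(jaccard(s, t) for t in sets) / len(sets)
            key = (-mean_j, -len(s), tuple(sorted(s)))
            if best_key is None or key < best_key:
                best, best_key = s, key
        return best

    out = [
        Community(
            members=medoid(c["sets"]), persistence=len(c["sets"]), origin=c["origin"]
        )
        for c in finished
        if len(c["sets"]) >= rho_min
    ]
    out.sort(key=lambda c: (-c.persistence, -c.size, c.sorted_members()))
    return out


def dedupe_communities(
    communities: Sequence[Community], dedupe_tau: float = 0.9
) -> list[Community]:
    """Greedy dedupe: keep by (persistence desc, size desc, lexicographic)."""
    ordered = sorted(
        communities, key=lambda c: (-c.persistence, -c.size, c.sorted_members())
    )
    kept: list[Community] = []
    for c in ordered:
        if all(jaccard(c.members, k.members) < dedupe_tau for k in kept):
            kept.append(c)
    return kept


def containment_index(child: frozenset, parent: frozenset) -> float:
    """|child ∩ parent| / |child|."""
    if not child or not parent:
        raise ContractViolation("containment_index needs non-empty sets")
    return len(child & parent) / len(child)


def build_dag(
    communities: Sequence[Community],
    universe: Sequence[str],
    containment_threshold: float = 0.75,
) -> HierarchyDAG:
    """Assemble the containment DAG over deduplicated communities.

    Parent candidates of a community are strictly larger communities with
    containment >= threshold; only minimal candidates are kept (no shortcut
    edges to grandparents). Parentless communities attach to the root.
    """
    comms = sorted(communities, key=lambda c: (-c.size, c.sorted_members()))
    names: list[str] = []
    for i, c in enumerate(comms):
        names.append(f"C{i}")
    nodes: dict[str, DagNode] = {
        "Root": DagNode("Root", frozenset(universe), 0)
    }
    for name, c in zip(names, comms):
        nodes[name] = DagNode(name, c.members, c.persistence)
    edges: list[tuple[str, str]] = []
    for i, c in enumerate(comms):
        cand = [
            j
            for j in range(len(comms))
            if comms[j].size > c.size
            and containment_index(c.members, comms[j].members) >= containment_threshold
        ]
        # minimal parents: drop p if some other candidate q would itself sit under p
        minimal = []
        for p in cand:
            shadowed = any(
                q != p
                and comms[q].size < comms[p].size
                and containment_index(comms[q].members, comms[p].members)
                >= containment_threshold
                for q in cand
            )
            if not shadowed:
                minimal.append(p)
        if minimal:
            for p in minimal:
                edges.append((names[p], names[i]))
        else:
            edges.append(("Root", names[i]))
    dag = HierarchyDAG(nodes, edges)
    dag.validate()
    return dag


def build_hierarchy(
    emb: EmbeddingSet,
    edge_fractions: Sequence[float] = DEFAULT_EDGE_FRACTIONS,
    resolutions: Sequence[float] | None = None,
    min_size: int = 4,
    jaccard_tau: float = 0.75,
    rho_min: int = 3,
    dedupe_tau: float = 0.9,
    containment_threshold: float = 0.75,
    seed: int = 0,
) -> HierarchyDAG:
    """Full hierarchy-generation stage from a unified embedding."""
    sim = cosine_matrix(emb)
    stack = build_graph_stack(sim, edge_fractions)
    pool = detect_communities(stack, resolutions, min_size=min_size, seed=seed)
    comms = compute_persistence(pool, jaccard_tau=jaccard_tau, rho_min=rho_min)
    comms = dedupe_communities(comms, dedupe_tau=dedupe_tau)
    return build_dag(comms, sorted(emb.ids), containment_threshold)


def write_hierarchy(dag: HierarchyDAG, outdir: str | Path) -> None:
    """Write edges TSV, nodes TSV and a nested-JSON tree view of the DAG."""
    dag.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "hierarchy_edges.tsv").open("w", encoding="utf-8") as fh:
        for p, c in sorted(dag.edges):
            fh.write(f"{p}\t{c}\tcontains\n")
    with (outdir / "hierarchy_nodes.tsv").open("w", encoding="utf-8") as fh:
        for name in sorted(dag.nodes):
            node = dag.nodes[name]
            members = " ".join(sorted(node.members))
            fh.write(f"{name}\t{node.size}\t{node.persistence}\t{members}\n")

    multi_parent = {n for n in dag.nodes if len(dag.parents(n)) > 1}

    def unroll(name: str) -> dict:
        node = dag.nodes[name]
        doc: dict = {"name": name, "size": node.size, "persistence": node.persistence}
        if name in multi_parent:
            doc["duplicate"] = True
        kids = dag.children(name)
        if kids:
            doc["children"] = [unroll(k) for k in kids]
        return doc

    (outdir / "hierarchy.json").write_text(
        json.dumps(unroll(dag.root), indent=2) + "\n", encoding="utf-8"
    )


def read_hierarchy_nodes(path: str | Path) -> dict[str, DagNode]:
    nodes: dict[str, DagNode] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        name, size, persistence, members = line.split("\t")
        nodes[name] = DagNode(name, frozenset(members.split()), int(persistence))
        if nodes[name].size != int(size):
            raise CellpipeError(f"size column mismatch for node {name}")
    return nodes


def read_hierarchy(outdir: str | Path) -> HierarchyDAG:
    outdir = Path(outdir)
    nodes = read_hierarchy_nodes(outdir / "hierarchy_nodes.tsv")
    edges = []
    for line in (outdir / "hierarchy_edges.tsv").read_text(encoding="utf-8").splitlines():
        if line.strip():
            p, c, _rel = line.split("\t")
            edges.append((p, c))
    dag = HierarchyDAG(nodes, edges)
    dag.validate()
    return dag
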