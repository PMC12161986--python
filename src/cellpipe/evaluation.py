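"""Hierarchy evaluation.

Hypergeometric overlap of DAG nodes with reference assembly sets (exact
upper-tail test, Benjamini–Hochberg control) and jackknife robustness
scoring of nodes under protein dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .hierarchy import HierarchyDAG, build_hierarchy, jaccard
from .types import ContractViolation, EmbeddingSet, ReferenceSets


def hypergeom_tail(k: int, s: int, t: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, t successes, s draws).

    Exact integer summation (no asymptotics).
    """
    if not (0 <= s <= N and 0 <= t <= N):
        raise ContractViolation(f"need s,t <= N; got s={s}, t={t}, N={N}")
    if not (0 <= k <= min(s, t)):
        raise ContractViolation(f"need 0 <= k <= min(s,t); got k={k}, s={s}, t={t}")
    if k == 0:
        return 1.0
    num = sum(comb(t, i) * comb(N - t, s - i) for i in range(k, min(s, t) + 1))
    return num / comb(N, s)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-up Benjamini–Hochberg q-values, order-preserving on input index."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ContractViolation("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


@dataclass(frozen=True)
class EnrichmentRecord:
    node: str
    term_id: str
    term_name: str
    overlap: int  # k
    node_size: int  # s
    term_size: int  # t
    background: int  # N
    p_value: float
    q_value: float
    jaccard: float


@dataclass
class AnnotationResult:
    records: list[EnrichmentRecord]
    best_term: dict[str, str]  # node -> term_id or "unannotated"
    background: int


def annotate_nodes(
    dag: HierarchyDAG,
    reference: ReferenceSets,
    background: Sequence[str] | None = None,
    fdr: float = 0.05,
) -> AnnotationResult:
    """Hypergeometric enrichment of every non-root node against every term.

    Background defaults to the root's protein universe. Terms and nodes are
    restricted to the background; tests are run for all (node, term) pairs
    with non-zero overlap and BH-adjusted jointly.
    """
    if len(reference) == 0:
        raise ContractViolation("empty reference sets")
    bg = frozenset(background) if background is not None else dag.nodes[dag.root].members
    N = len(bg)
    terms = [
        (t.term_id, t.term_name, t.members & bg)
        for t in reference.terms
        if t.members & bg
    ]
    if not terms:
        raise ContractViolation("no reference member overlaps the background universe")

    raw: list[tuple[str, str, str, int, int, int, float, float]] = []
    for node in dag.non_root_nodes():
        mem = node.members & bg
        s = len(mem)
        if s == 0:
            continue
        for term_id, term_name, tmem in terms:
            k = len(mem & tmem)
            if k == 0:
                continue
            p = hypergeom_tail(k, s, len(tmem), N)
            jac = len(mem & tmem) / len(mem | tmem)
            raw.append((node.name, term_id, term_name, k, s, len(tmem), p, jac))

    qs = bh_adjust([r[6] for r in raw])
    records = [
        EnrichmentRecord(
            node=r[0],
            term_id=r[1],
            term_name=r[2],
            overlap=r[3],
            node_size=r[4],
            term_size=r[5],
            background=N,
            p_value=r[6],
            q_value=q,
            jaccard=r[7],
        )
        for r, q in zip(raw, qs)
    ]

    best: dict[str, str] = {}
    for node in dag.non_root_nodes():
        sig = sorted(
            (r for r in records if r.node == node.name and r.q_value <= fdr),
            key=lambda r: (r.q_value, -r.jaccard, r.term_id),
        )
        best[node.name] = sig[0].term_id if sig else "unannotated"
    return AnnotationResult(records, best, N)


def write_enrichment(result: AnnotationResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "enrichment.tsv").open("w", encoding="utf-8") as fh:
        fh.write(
            "node\tterm_id\tterm_name\toverlap\tnode_size\tterm_size\t"
            "background\tp_value\tq_value\tjaccard\n"
        )
        for r in sorted(result.records, key=lambda r: (r.node, r.q_value, r.term_id)):
            fh.write(
                f"{r.node}\t{r.term_id}\t{r.term_name}\t{r.overlap}\t{r.node_size}\t"
                f"{r.term_size}\t{r.background}\t{r.p_value!r}\t{r.q_value!r}\t"
                f"{r.jaccard!r}\n"
            )
    with (outdir / "node_annotations.tsv").open("w", encoding="utf-8") as fh:
        fh.write("node\tbest_term\n")
        for node, term in sorted(result.best_term.items()):
            fh.write(f"{node}\t{term}\n")


@dataclass
class RobustnessReport:
    scores: dict[str, float]  # non-root node -> mean max-Jaccard in [0, 1]
    n_resamples: int
    drop_fraction: float
    seed: int


def jackknife_robustness(
    embedding: EmbeddingSet,
    base_dag: HierarchyDAG,
    hierarchy_fn: Callable[[EmbeddingSet], HierarchyDAG] | None = None,
    n_resamples: int = 10,
    drop_fraction: float = 0.1,
    seed: int = 0,
    min_viable: int = 12,
) -> RobustnessReport:
    """Score node stability under repeated protein dropout.

    Each resample drops ``floor(drop_fraction * n)`` proteins uniformly from
    the co-embedding universe and re-runs hierarchy generation on the rest; a
    node's score is the mean over resamples of the max Jaccard between the
    node (restricted to retained proteins) and any node of the resampled DAG.
    """
    if not (0 <= drop_fraction < 1):
        raise ContractViolation("drop_fraction must be in [0, 1)")
    if hierarchy_fn is None:
        hierarchy_fn = build_hierarchy
    rng = np.random.default_rng(seed)
    n = embedding.n
    n_drop = int(drop_fraction * n)
    if n - n_drop < min_viable:
        raise ContractViolation(
            f"resample would retain {n - n_drop} < {min_viable} proteins"
        )
    node_list = base_dag.non_root_nodes()
    totals = {node.name: 0.0 for node in node_list}
    for _ in range(n_resamples):
        drop_idx = rng.choice(n, size=n_drop, replace=False)
        keep = sorted(set(range(n)) - set(drop_idx.tolist()))
        retained_ids = [embedding.ids[i] for i in keep]
        sub = embedding.subset(retained_ids)
        resampled = hierarchy_fn(sub)
        retained = frozenset(retained_ids)
        res_sets = [nd.members for nd in resampled.non_root_nodes()]
        for node in node_list:
            restricted = node.members & retained
            if not restricted:
                continue  # fully dropped: contributes 0
            best = max((jaccard(restricted, s) for s in res_sets), default=0.0)
            totals[node.name] += best
    scores = {k: v / n_resamples for k, v in totals.items()}
    return RobustnessReport(scores, n_resamples, drop_fraction, seed)


def write_robustness(report: RobustnessReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "robustness.tsv").open("w", encoding="utf-8") as fh:
        fh.write("node\tscore\n")
        for node, score in sorted(report.scores.items()):
            fh.write(f"{node}\t{score!r}\n")


def export_naming_requests(dag: HierarchyDAG, outpath: str | Path) -> None:
    """One JSON record per node for an external naming service; no network."""
    records = []
    for node in [dag.nodes[dag.root]] + dag.non_root_nodes():
        records.append(
            {
                "node": node.name,
                "members": sorted(node.members),
                "prompt_template": (
                    "Propose a concise name and a confidence score for the protein "
                    "assembly containing: {members}"
                ),
            }
        )
    Path(outpath).write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
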