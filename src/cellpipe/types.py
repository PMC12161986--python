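"""Core domain types shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

Edge = tuple[str, str]


class CellpipeError(Exception):
    """Base class for all package errors."""


class ParseError(CellpipeError):
    """A file could not be parsed; message names the offending line."""


class EmptyNetworkError(CellpipeError):
    """Filtering removed every edge of an interaction network."""


class ContractViolation(CellpipeError):
    """An operation was called outside its precondition."""


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered pair (a, b) in sorted orientation."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected, optionally score-weighted graph over protein symbols.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node, scores (when present) lie in [0, 1].
    """

    nodes: frozenset[str]
    edges: frozenset[Edge]
    scores: Mapping[Edge, float] | None = None

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ContractViolation(f"self-loop on {a!r}")
            if a > b:
                raise ContractViolation(f"edge ({a!r}, {b!r}) not canonical")
            if a not in self.nodes or b not in self.nodes:
                raise ContractViolation(f"edge endpoint missing from nodes: ({a!r}, {b!r})")
        if self.scores is not None:
            if set(self.scores) != set(self.edges):
                raise ContractViolation("score map keys do not match edge set")
            for e, s in self.scores.items():
                if not (0.0 <= s <= 1.0):
                    raise ContractViolation(f"score {s} for edge {e} outside [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> dict[str, list[str]]:
        """Adjacency map with neighbor lists sorted for determinism."""
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        for n in adj:
            adj[n].sort()
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for a, b in sorted(self.edges):
            w = 1.0 if self.scores is None else self.scores[(a, b)]
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class EmbeddingSet:
    """Ordered protein ids with one fixed-length real vector per id."""

    ids: list[str]
    vectors: np.ndarray
    modality: str = "ppi"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ContractViolation("vectors must be a 2-D matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise ContractViolation(
                f"{len(self.ids)} ids but {self.vectors.shape[0]} vector rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ContractViolation("duplicate ids in embedding")
        if not np.all(np.isfinite(self.vectors)):
            raise ContractViolation("non-finite values in embedding vectors")

    @property
    def d(self) -> int:
        return int(self.vectors.shape[1])

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.ids)}

    def subset(self, ids: Sequence[str]) -> "EmbeddingSet":
        idx = self.index()
        rows = [idx[p] for p in ids]
        return EmbeddingSet(list(ids), self.vectors[rows].copy(), self.modality)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmbeddingSet):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.modality == other.modality
            and self.vectors.shape == other.vectors.shape
            and bool(np.all(self.vectors == other.vectors))
        )


@dataclass(frozen=True)
class ReferenceTerm:
    term_id: str
    term_name: str
    members: frozenset[str]


@dataclass
class ReferenceSets:
    """Curated assembly collections (CORUM / GO-CC style term lists)."""

    terms: list[ReferenceTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.terms:
            if not t.members:
                raise ContractViolation(f"term {t.term_id!r} has no members")
            if t.term_id in seen:
                raise ContractViolation(f"duplicate term_id {t.term_id!r}")
            seen.add(t.term_id)

    def __len__(self) -> int:
        return len(self.terms)

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.members
        return frozenset(out)


@dataclass
class ImageFeatureTable:
    """Per-image feature vectors with a protein label per row."""

    image_ids: list[str]
    proteins: list[str]
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ContractViolation("features must be 2-D")
        if not (len(self.image_ids) == len(self.proteins) == self.features.shape[0]):
            raise ContractViolation("row counts of ids / proteins / features differ")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ContractViolation("duplicate image ids")

    @property
    def d(self) -> int:
        return int(self.features.shape[1])

    @property
    def n(self) -> int:
        return len(self.image_ids)


def as_sorted_members(members: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(members))
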