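"""Readers and writers for the pipeline's on-disk formats.

All files are UTF-8, tab-separated, unquoted. Embedding tables carry a
mandatory header and round-trip at full float precision (``repr`` on write,
``float`` on read).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .types import (
    EmbeddingSet,
    EmptyNetworkError,
    ImageFeatureTable,
    InteractionNetwork,
    ParseError,
    ReferenceSets,
    ReferenceTerm,
    canonical_edge,
)

_MEMBER_SPLIT = re.compile(r"[,;]")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_edge_list(
    path: str | Path,
    min_score: float | None = None,
) -> InteractionNetwork:
    """Parse a 2/3-column edge-list TSV into an :class:`InteractionNetwork`.

    Symbols are uppercased and stripped; self-loops are dropped; duplicate
    edges collapse keeping the maximum score; when a score column is present
    edges below ``min_score`` are removed. A header line is recognized by a
    non-numeric third field on the first row.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        rows.append((lineno, line.split("\t")))
    if not rows:
        raise EmptyNetworkError(f"{path}: no rows")

    ncols = len(rows[0][1])
    if ncols < 2:
        raise ParseError(f"{path}:{rows[0][0]}: expected >= 2 tab-separated columns")
    has_scores = ncols >= 3
    # Header detection: first row whose third field is non-numeric.
    if has_scores and not _is_number(rows[0][1][2].strip()):
        rows = rows[1:]

    edges: dict[tuple[str, str], float | None] = {}
    nodes: set[str] = set()
    for lineno, fields in rows:
        if len(fields) != ncols:
            raise ParseError(
                f"{path}:{lineno}: expected {ncols} columns, found {len(fields)}"
            )
        a = fields[0].strip().upper()
        b = fields[1].strip().upper()
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty gene symbol")
        if a == b:
            continue  # self-loop
        score: float | None = None
        if has_scores:
            tok = fields[2].strip()
            if not _is_number(tok):
                raise ParseError(f"{path}:{lineno}: non-numeric score {tok!r}")
            score = float(tok)
        e = canonical_edge(a, b)
        if e in edges:
            if score is not None:
                prev = edges[e]
                edges[e] = score if prev is None else max(prev, score)
        else:
            edges[e] = score

    if has_scores and min_score is not None:
        edges = {e: s for e, s in edges.items() if s is not None and s >= min_score}
    if not edges:
        raise EmptyNetworkError(f"{path}: no edges remain after filtering")

    for a, b in edges:
        nodes.add(a)
        nodes.add(b)
    scores = None
    if has_scores:
        scores = {e: float(min(max(s, 0.0), 1.0)) for e, s in edges.items() if s is not None}
    return InteractionNetwork(frozenset(nodes), frozenset(edges), scores)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            if net.scores is not None:
                fh.write(f"{a}\t{b}\t{net.scores[(a, b)]!r}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_embedding_tsv(path: str | Path, modality: str | None = None) -> EmbeddingSet:
    """Read a header-carrying embedding TSV (id column + d numeric columns)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise EmptyNetworkError(f"{path}: empty embedding file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}:1: embedding header needs an id column and >= 1 feature")
    d = len(header) - 1
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != d + 1:
            raise ParseError(f"{path}:{lineno}: expected {d + 1} columns, found {len(fields)}")
        pid = fields[0].strip()
        if pid in ids:
            raise ParseError(f"{path}:{lineno}: duplicate id {pid!r}")
        vals: list[float] = []
        for col, tok in enumerate(fields[1:], start=2):
            if not _is_number(tok.strip()):
                raise ParseError(f"{path}:{lineno}: non-numeric cell at column {col}: {tok!r}")
            vals.append(float(tok))
        ids.append(pid)
        rows.append(vals)
    if not ids:
        raise EmptyNetworkError(f"{path}: embedding file has a header but no rows")
    if modality is None:
        modality = header[0] if header[0] in {"ppi", "image", "coembedding"} else "ppi"
    return EmbeddingSet(ids, np.array(rows, dtype=float), modality)


def write_embedding_tsv(emb: EmbeddingSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        cols = "\t".join(f"v{i + 1}" for i in range(emb.d))
        fh.write(f"{emb.modality}\t{cols}\n")
        for pid, row in zip(emb.ids, emb.vectors):
            vals = "\t".join(repr(float(x)) for x in row)
            fh.write(f"{pid}\t{vals}\n")


def read_reference_sets(path: str | Path) -> ReferenceSets:
    """Parse term_id ⇥ term_name ⇥ members (comma/semicolon-separated)."""
    path = Path(path)
    terms: list[ReferenceTerm] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, found {len(fields)}")
        term_id, term_name, member_blob = (f.strip() for f in fields)
        if term_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
        members = frozenset(
            m.strip().upper() for m in _MEMBER_SPLIT.split(member_blob) if m.strip()
        )
        if not members:
            raise ParseError(f"{path}:{lineno}: term {term_id!r} has no members")
        seen.add(term_id)
        terms.append(ReferenceTerm(term_id, term_name, members))
    return ReferenceSets(terms)


def write_reference_sets(ref: ReferenceSets, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in ref.terms:
            fh.write(f"{t.term_id}\t{t.term_name}\t{','.join(sorted(t.members))}\n")


def read_protein_list(path: str | Path) -> list[str]:
    out: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        sym = line.strip().upper()
        if sym:
            out.append(sym)
    return out


def write_protein_list(proteins: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in proteins), encoding="utf-8")


def read_image_features(path: str | Path) -> ImageFeatureTable:
    """Read image_id ⇥ protein ⇥ f1..fd (header required)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise EmptyNetworkError(f"{path}: empty image-feature file")
    header = lines[0].split("\t")
    if len(header) < 3:
        raise ParseError(f"{path}:1: need image_id, protein and >= 1 feature column")
    d = len(header) - 2
    image_ids: list[str] = []
    proteins: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != d + 2:
            raise ParseError(f"{path}:{lineno}: expected {d + 2} columns, found {len(fields)}")
        image_ids.append(fields[0].strip())
        proteins.append(fields[1].strip().upper())
        try:
            rows.append([float(t) for t in fields[2:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric feature cell") from exc
    if not rows:
        raise EmptyNetworkError(f"{path}: image-feature file has a header but no rows")
    return ImageFeatureTable(image_ids, proteins, np.array(rows, dtype=float))


def write_image_features(table: ImageFeatureTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        cols = "\t".join(f"f{i + 1}" for i in range(table.d))
        fh.write(f"image_id\tprotein\t{cols}\n")
        for img, prot, row in zip(table.image_ids, table.proteins, table.features):
            vals = "\t".join(repr(float(x)) for x in row)
            fh.write(f"{img}\t{prot}\t{vals}\n")
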