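"""Image-modality embedding: aggregate per-image feature vectors per protein."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .io import write_embedding_tsv
from .provenance import register_stage
from .types import ContractViolation, EmbeddingSet, ImageFeatureTable


def aggregate_per_protein(table: ImageFeatureTable, method: str = "median") -> EmbeddingSet:
    """Collapse per-image vectors to one vector per protein (mean or median).

    A protein with a single image returns that image's vector exactly;
    aggregation is invariant to image order.
    """
    if table.n == 0:
        raise ContractViolation("empty image feature table")
    if method not in ("mean", "median"):
        raise ContractViolation(f"unknown aggregation method {method!r}")
    proteins = sorted(set(table.proteins))
    rows_by_protein: dict[str, list[int]] = {p: [] for p in proteins}
    for i, p in enumerate(table.proteins):
        rows_by_protein[p].append(i)
    agg = np.median if method == "median" else np.mean
    vectors = np.vstack(
        [agg(table.features[rows_by_protein[p]], axis=0) for p in proteins]
    )
    return EmbeddingSet(proteins, vectors, modality="image")


def l2_normalize(emb: EmbeddingSet) -> EmbeddingSet:
    """Scale every row to unit Euclidean norm; zero vectors are an error."""
    norms = np.linalg.norm(emb.vectors, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ContractViolation(
            f"zero vector(s) cannot be normalized: {', '.join(emb.ids[i] for i in zero)}"
        )
    return EmbeddingSet(list(emb.ids), emb.vectors / norms[:, None], emb.modality)


def image_embed(
    table: ImageFeatureTable,
    method: str = "median",
    outdir: str | Path | None = None,
    inputs: Sequence[str] = (),
) -> EmbeddingSet:
    emb = aggregate_per_protein(table, method=method)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_embedding_tsv(emb, outdir / "image_emb.tsv")
        (outdir / "image_embed.log").write_text(
            f"images={table.n} proteins={emb.n} dim={emb.d} method={method}\n",
            encoding="utf-8",
        )
        register_stage(outdir, "image_embedding", inputs=inputs, params={"agg": method})
    return emb
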