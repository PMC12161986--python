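"""End-to-end pipeline orchestration over numbered stage directories.

Stage layout mirrors the per-step directory convention:
``1.image_embedding/ 2.ppi_embedding/ 3.coembedding/ 4.hierarchy/
5.hierarchyeval/`` — each holding outputs, a log file and a provenance JSON
whose lineage chain validates end-to-end. A global seed fans out to
per-stage seeds through a seed splitter so resuming never shifts downstream
randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import io
from .coembedding import CoembedConfig, coembed
from .evaluation import annotate_nodes, export_naming_requests, write_enrichment
from .hierarchy import (
    build_hierarchy,
    read_hierarchy,
    write_hierarchy,
)
from .image_embedding import image_embed
from .ppi_embedding import SkipGramConfig, WalkParams, ppi_embed
from .provenance import load_stage_record, register_stage, validate_stage
from .types import CellpipeError, ContractViolation

logger = logging.getLogger(__name__)

STAGE_DIRS = {
    "image_embedding": "1.image_embedding",
    "ppi_embedding": "2.ppi_embedding",
    "coembedding": "3.coembedding",
    "hierarchy": "4.hierarchy",
    "hierarchyeval": "5.hierarchyeval",
}
STAGE_ORDER = list(STAGE_DIRS)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    outdir: str
    edge_list: str
    image_features: str
    reference: str | None = None
    min_score: float = 0.7
    seed: int = 0
    resume: bool = False
    # stage parameter blocks
    image_agg: str = "median"
    walk_params: dict[str, Any] = field(default_factory=dict)
    skipgram: dict[str, Any] = field(default_factory=dict)
    coembed: dict[str, Any] = field(default_factory=dict)
    hierarchy: dict[str, Any] = field(default_factory=dict)
    fdr: float = 0.05

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**doc)


def _stage_done(stage_dir: Path) -> bool:
    return stage_dir.is_dir() and validate_stage(stage_dir).ok


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all five stages; returns the stage-name → directory map."""
    root = Path(config.outdir)
    root.mkdir(parents=True, exist_ok=True)
    dirs = {name: root / sub for name, sub in STAGE_DIRS.items()}
    seeds = {name: stage_seed(config.seed, i) for i, name in enumerate(STAGE_ORDER)}

    # 1. image embedding
    d = dirs["image_embedding"]
    if not (config.resume and _stage_done(d)):
        table = io.read_image_features(config.image_features)
        image_embed(table, method=config.image_agg, outdir=d, inputs=[config.image_features])
    image_emb = io.read_embedding_tsv(d / "image_emb.tsv", modality="image")

    # 2. ppi embedding
    d = dirs["ppi_embedding"]
    if not (config.resume and _stage_done(d)):
        net = io.read_edge_list(config.edge_list, min_score=config.min_score)
        wp = WalkParams(seed=seeds["ppi_embedding"], **config.walk_params)
        sg = SkipGramConfig(seed=seeds["ppi_embedding"], **config.skipgram)
        ppi_embed(net, wp, sg, outdir=d, inputs=[config.edge_list])
    ppi_emb = io.read_embedding_tsv(d / "ppi_emb.tsv", modality="ppi")

    # 3. coembedding
    d = dirs["coembedding"]
    if not (config.resume and _stage_done(d)):
        cc = CoembedConfig(seed=seeds["coembedding"], **config.coembed)
        coembed(
            ppi_emb,
            image_emb,
            cc,
            outdir=d,
            inputs=[
                load_stage_record(dirs["ppi_embedding"]).stage_id,
                load_stage_record(dirs["image_embedding"]).stage_id,
            ],
        )
    unified = io.read_embedding_tsv(d / "coembedding.tsv", modality="coembedding")

    # 4. hierarchy
    d = dirs["hierarchy"]
    hier_kwargs = dict(config.hierarchy)
    if not (config.resume and _stage_done(d)):
        d.mkdir(parents=True, exist_ok=True)
        dag = build_hierarchy(unified, seed=seeds["hierarchy"], **hier_kwargs)
        write_hierarchy(dag, d)
        (d / "hierarchy.log").write_text(
            f"nodes={len(dag.nodes)} edges={len(dag.edges)}\n", encoding="utf-8"
        )
        register_stage(
            d,
            "hierarchy",
            inputs=[load_stage_record(dirs["coembedding"]).stage_id],
            params={"seed": seeds["hierarchy"], **{k: str(v) for k, v in hier_kwargs.items()}},
        )
    dag = read_hierarchy(d)

    # 5. evaluation
    d = dirs["hierarchyeval"]
    if not (config.resume and _stage_done(d)):
        d.mkdir(parents=True, exist_ok=True)
        if config.reference is not None:
            reference = io.read_reference_sets(config.reference)
            result = annotate_nodes(dag, reference, fdr=config.fdr)
            write_enrichment(result, d)
        export_naming_requests(dag, d / "naming_requests.json")
        (d / "hierarchyeval.log").write_text(
            f"nodes={len(dag.nodes) - 1} reference={config.reference}\n",
            encoding="utf-8",
        )
        register_stage(
            d,
            "hierarchyeval",
            inputs=[load_stage_record(dirs["hierarchy"]).stage_id],
            params={"fdr": config.fdr, "reference": str(config.reference)},
        )
    return {name: str(p) for name, p in dirs.items()}


@dataclass
class SubstitutionReport:
    stage_name: str
    ok: bool
    problems: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


_STAGE_SCHEMA_FILES = {
    "image_embedding": "image_emb.tsv",
    "ppi_embedding": "ppi_emb.tsv",
    "coembedding": "coembedding.tsv",
}


def substitute_stage(stage_name: str, external_dir: str | Path) -> SubstitutionReport:
    """Validate an externally produced stage directory against its schema.

    Missing provenance is a warning (external inputs are declared, not
    registered); malformed data files are itemized errors.
    """
    if stage_name not in STAGE_DIRS:
        raise ContractViolation(f"unknown stage {stage_name!r}")
    external_dir = Path(external_dir)
    report = SubstitutionReport(stage_name, ok=True)
    if not external_dir.is_dir():
        report.ok = False
        report.problems.append(f"not a directory: {external_dir}")
        return report
    if stage_name in _STAGE_SCHEMA_FILES:
        fname = _STAGE_SCHEMA_FILES[stage_name]
        path = external_dir / fname
        if not path.is_file():
            report.ok = False
            report.problems.append(f"missing required file: {fname}")
        else:
            try:
                io.read_embedding_tsv(path)
            except CellpipeError as exc:
                report.ok = False
                report.problems.append(str(exc))
    elif stage_name == "hierarchy":
        for fname in ("hierarchy_edges.tsv", "hierarchy_nodes.tsv"):
            if not (external_dir / fname).is_file():
                report.ok = False
                report.problems.append(f"missing required file: {fname}")
        if report.ok:
            try:
                read_hierarchy(external_dir)
            except (CellpipeError, ValueError) as exc:
                report.ok = False
                report.problems.append(str(exc))
    if not (external_dir / "ro-crate-metadata.json").is_file():
        report.warnings.append("no provenance JSON (external input, declared not registered)")
    return report


def example_provenance() -> dict[str, Any]:
    """Template provenance document for user-supplied input data."""
    return {
        "name": "",
        "organization": "",
        "project": "",
        "cell_line": "",
        "treatment": "",
        "gene_set": "",
        "inputs": [
            {"file": "ppi_edges.tsv", "description": "protein interaction edge list"},
            {"file": "image_features.tsv", "description": "per-image feature vectors"},
        ],
    }
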