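"""Per-stage provenance records.

Every pipeline stage owns a directory; :func:`register_stage` inventories the
directory's files with content digests into a single JSON document
(``ro-crate-metadata.json``), and :func:`validate_stage` re-checks manifest
completeness and digest match. This is a deliberately simplified lineage
record, not a full RO-Crate implementation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .types import CellpipeError

PROVENANCE_FILENAME = "ro-crate-metadata.json"


class ProvenanceError(CellpipeError):
    pass


@dataclass
class StageRecord:
    stage_name: str
    stage_id: str
    input_artifact_ids: list[str]
    parameters: dict[str, Any]
    software_version: str
    created: str
    manifest: dict[str, str]  # filename -> sha256 digest

    def to_json(self) -> dict[str, Any]:
        return {
            "stage_name": self.stage_name,
            "stage_id": self.stage_id,
            "input_artifact_ids": self.input_artifact_ids,
            "parameters": self.parameters,
            "software_version": self.software_version,
            "created": self.created,
            "manifest": self.manifest,
        }

    @classmethod
    def from_json(cls, doc: Mapping[str, Any]) -> "StageRecord":
        return cls(
            stage_name=doc["stage_name"],
            stage_id=doc["stage_id"],
            input_artifact_ids=list(doc["input_artifact_ids"]),
            parameters=dict(doc["parameters"]),
            software_version=doc["software_version"],
            created=doc["created"],
            manifest=dict(doc["manifest"]),
        )


@dataclass
class ValidationReport:
    stage_dir: str
    ok: bool
    problems: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def register_stage(
    stage_dir: str | Path,
    stage_name: str,
    inputs: Sequence[str] = (),
    params: Mapping[str, Any] | None = None,
) -> StageRecord:
    """Write a provenance JSON covering every file currently in ``stage_dir``."""
    stage_dir = Path(stage_dir)
    if not stage_dir.is_dir():
        raise ProvenanceError(f"stage directory does not exist: {stage_dir}")
    manifest: dict[str, str] = {}
    for p in sorted(stage_dir.rglob("*")):
        if p.is_file() and p.name != PROVENANCE_FILENAME:
            manifest[str(p.relative_to(stage_dir))] = _sha256(p)
    digest_of_manifest = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    record = StageRecord(
        stage_name=stage_name,
        stage_id=f"{stage_name}:{digest_of_manifest}",
        input_artifact_ids=list(inputs),
        parameters=dict(params or {}),
        software_version=__version__,
        created=datetime.now(timezone.utc).isoformat(),
        manifest=manifest,
    )
    (stage_dir / PROVENANCE_FILENAME).write_text(
        json.dumps(record.to_json(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return record


def load_stage_record(stage_dir: str | Path) -> StageRecord:
    doc_path = Path(stage_dir) / PROVENANCE_FILENAME
    if not doc_path.is_file():
        raise ProvenanceError(f"no {PROVENANCE_FILENAME} in {stage_dir}")
    return StageRecord.from_json(json.loads(doc_path.read_text(encoding="utf-8")))


def validate_stage(stage_dir: str | Path) -> ValidationReport:
    """Check that every manifest entry exists and its digest still matches."""
    stage_dir = Path(stage_dir)
    problems: list[str] = []
    try:
        record = load_stage_record(stage_dir)
    except (ProvenanceError, json.JSONDecodeError, KeyError) as exc:
        return ValidationReport(str(stage_dir), False, [str(exc)])
    for name, digest in record.manifest.items():
        path = stage_dir / name
        if not path.is_file():
            problems.append(f"missing file: {name}")
        elif _sha256(path) != digest:
            problems.append(f"digest mismatch: {name}")
    return ValidationReport(str(stage_dir), not problems, problems)
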