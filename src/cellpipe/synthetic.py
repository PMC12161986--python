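"""Synthetic multimodal inputs with a planted nested assembly structure.

Proteins partition into compartments, compartments into assemblies (and
optionally subcomplexes). The PPI modality is a stochastic block model whose
connection probability depends on the deepest shared unit of a pair; the
image modality places per-protein mean vectors at a compartment centroid plus
an orthogonal assembly offset. Every stage of the pipeline — and the
end-to-end recovery claim — is testable against the planted ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .hierarchy import HierarchyDAG, jaccard
from .types import (
    ContractViolation,
    ImageFeatureTable,
    InteractionNetwork,
    ReferenceSets,
    ReferenceTerm,
    canonical_edge,
)

MIN_PLANT_SIZE = 6


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 600
    n_compartments: int = 3
    assemblies_per_compartment: int = 8
    assembly_size_range: tuple[int, int] = (15, 35)
    with_subcomplexes: bool = False
    p_bg: float = 0.002
    p_comp: float = 0.01
    p_assy: float = 0.25
    p_sub: float = 0.6
    image_dim: int = 64
    images_per_protein: int = 3
    noise_sd: float = 0.5
    image_compartment_scale: float = 3.0
    image_assembly_scale: float = 2.0  # 0 → images carry compartment signal only

    def __post_init__(self) -> None:
        if not (0 <= self.p_bg < self.p_comp < self.p_assy < self.p_sub <= 1):
            raise ContractViolation("need 0 <= p_bg < p_comp < p_assy < p_sub <= 1")
        if self.image_dim < 2 * self.n_compartments:
            raise ContractViolation("image_dim must be >= 2 x n_compartments")


PRESETS: dict[str, SyntheticConfig] = {
    # image_dim sized to the signal axes (compartments + assemblies) plus a
    # few dead dims; per-feature z-scoring downstream amplifies dead noise
    # columns, so huge feature counts only dilute the planted signal
    "demo600": SyntheticConfig(image_compartment_scale=4.0, image_dim=32),
    "demo150": SyntheticConfig(
        n=150,
        assemblies_per_compartment=3,
        assembly_size_range=(12, 22),
        image_compartment_scale=4.0,
        image_dim=16,
    ),
    # images carry compartment signal only; PPI assembly signal kept noisy so
    # integration has headroom over either modality alone
    "complementary150": SyntheticConfig(
        n=150,
        assemblies_per_compartment=3,
        assembly_size_range=(12, 22),
        image_assembly_scale=0.0,
        p_assy=0.15,
    ),
}


@dataclass
class PlantedHierarchy:
    proteins: list[str]
    compartment_of: np.ndarray  # (n,) int
    assembly_of: np.ndarray  # (n,) int, global assembly index
    subcomplex_of: np.ndarray  # (n,) int, -1 when the protein has none
    config: SyntheticConfig

    @property
    def n(self) -> int:
        return len(self.proteins)

    def compartments(self) -> list[frozenset[str]]:
        return self._units(self.compartment_of)

    def assemblies(self) -> list[frozenset[str]]:
        return self._units(self.assembly_of)

    def subcomplexes(self) -> list[frozenset[str]]:
        labels = self.subcomplex_of
        return [
            frozenset(np.array(self.proteins)[labels == u].tolist())
            for u in sorted(set(labels.tolist()))
            if u >= 0
        ]

    def _units(self, labels: np.ndarray) -> list[frozenset[str]]:
        arr = np.array(self.proteins)
        return [
            frozenset(arr[labels == u].tolist()) for u in sorted(set(labels.tolist()))
        ]

    def validate(self) -> None:
        """Refinement invariant: deeper units never straddle shallower ones."""
        for a in sorted(set(self.assembly_of.tolist())):
            comps = set(self.compartment_of[self.assembly_of == a].tolist())
            if len(comps) != 1:
                raise ContractViolation(f"assembly {a} straddles compartments {comps}")
        for s in sorted(set(self.subcomplex_of.tolist())):
            if s < 0:
                continue
            assys = set(self.assembly_of[self.subcomplex_of == s].tolist())
            if len(assys) != 1:
                raise ContractViolation(f"subcomplex {s} straddles assemblies {assys}")
        for units in (self.compartments(), self.assemblies()):
            for u in units:
                if len(u) < MIN_PLANT_SIZE:
                    raise ContractViolation(f"planted unit below minimum size: {len(u)}")


def _draw_sizes(
    total: int, k: int, lo: int, hi: int, rng: np.random.Generator
) -> list[int]:
    if k * lo > total or k * hi < total:
        raise ContractViolation(
            f"cannot split {total} into {k} parts within [{lo}, {hi}]"
        )
    for _ in range(2000):
        sizes = rng.integers(lo, hi + 1, size=k - 1).tolist() if k > 1 else []
        last = total - sum(sizes)
        if lo <= last <= hi:
            return sizes + [last]
    base = total // k
    sizes = [base] * k
    for i in range(total - base * k):
        sizes[i] += 1
    return sizes


def sample_planted(config: SyntheticConfig, seed: int = 0) -> PlantedHierarchy:
    """Draw a planted hierarchy; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    n, C = config.n, config.n_compartments
    if n % C != 0:
        raise ContractViolation(f"n={n} not divisible by {C} compartments")
    comp_size = n // C
    proteins = [f"P{i + 1:05d}" for i in range(n)]
    compartment_of = np.repeat(np.arange(C), comp_size)
    assembly_of = np.full(n, -1, dtype=int)
    subcomplex_of = np.full(n, -1, dtype=int)
    lo, hi = config.assembly_size_range
    a_global = 0
    s_global = 0
    for c in range(C):
        members = np.where(compartment_of == c)[0]
        perm = rng.permutation(members)
        sizes = _draw_sizes(comp_size, config.assemblies_per_compartment, lo, hi, rng)
        pos = 0
        for size in sizes:
            block = perm[pos : pos + size]
            assembly_of[block] = a_global
            if config.with_subcomplexes and size >= 2 * MIN_PLANT_SIZE:
                half = size // 2
                subcomplex_of[block[:half]] = s_global
                subcomplex_of[block[half:]] = s_global + 1
                s_global += 2
            a_global += 1
            pos += size
    planted = PlantedHierarchy(proteins, compartment_of, assembly_of, subcomplex_of, config)
    planted.validate()
    return planted


def sample_ppi(
    planted: PlantedHierarchy,
    p_bg: float | None = None,
    p_comp: float | None = None,
    p_assy: float | None = None,
    p_sub: float | None = None,
    seed: int = 0,
) -> InteractionNetwork:
    """SBM-style PPI draw: pair probability set by the deepest shared unit.

    Assembly-level (and deeper) edges get scores in [0.7, 1.0); shallower
    edges get scores in [0, 0.7), so a score >= 0.7 filter retains exactly
    the planted signal.
    """
    cfg = planted.config
    p_bg = cfg.p_bg if p_bg is None else p_bg
    p_comp = cfg.p_comp if p_comp is None else p_comp
    p_assy = cfg.p_assy if p_assy is None else p_assy
    p_sub = cfg.p_sub if p_sub is None else p_sub
    if not (0 <= p_bg < p_comp < p_assy < p_sub <= 1):
        raise ContractViolation("need 0 <= p_bg < p_comp < p_assy < p_sub <= 1")
    rng = np.random.default_rng(seed)
    n = planted.n
    iu, ju = np.triu_indices(n, k=1)
    same_comp = planted.compartment_of[iu] == planted.compartment_of[ju]
    same_assy = planted.assembly_of[iu] == planted.assembly_of[ju]
    has_sub = (planted.subcomplex_of[iu] >= 0) & (planted.subcomplex_of[ju] >= 0)
    same_sub = has_sub & (planted.subcomplex_of[iu] == planted.subcomplex_of[ju])
    probs = np.where(
        same_sub, p_sub, np.where(same_assy, p_assy, np.where(same_comp, p_comp, p_bg))
    )
    hit = rng.random(probs.size) < probs
    planted_edge = same_assy  # assembly or deeper
    scores_raw = np.where(
        planted_edge, rng.uniform(0.7, 1.0, probs.size), rng.uniform(0.0, 0.7, probs.size)
    )
    names = np.array(planted.proteins)
    edges: set = set()
    scores: dict = {}
    for a, b, s in zip(names[iu[hit]], names[ju[hit]], scores_raw[hit]):
        e = canonical_edge(str(a), str(b))
        edges.add(e)
        scores[e] = float(s)
    return InteractionNetwork(frozenset(planted.proteins), frozenset(edges), scores)


def sample_image_features(
    planted: PlantedHierarchy,
    image_dim: int | None = None,
    images_per_protein: int | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> ImageFeatureTable:
    """Per-image vectors = compartment centroid + assembly offset + noise.

    Compartment centroids and assembly offsets live in disjoint coordinate
    blocks, so they are exactly orthogonal. With assembly scale 0 the images
    carry compartment signal only (the complementary-modality regime).
    """
    cfg = planted.config
    image_dim = cfg.image_dim if image_dim is None else image_dim
    images_per_protein = (
        cfg.images_per_protein if images_per_protein is None else images_per_protein
    )
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    C = cfg.n_compartments
    n_assy = int(planted.assembly_of.max()) + 1
    if image_dim < 2 * C:
        raise ContractViolation("image_dim must be >= 2 x n_compartments")
    if cfg.image_assembly_scale > 0 and image_dim < C + n_assy:
        raise ContractViolation(
            f"image_dim={image_dim} too small for {C} compartments + {n_assy} assembly axes"
        )
    rng = np.random.default_rng(seed)
    means = np.zeros((planted.n, image_dim))
    means[np.arange(planted.n), planted.compartment_of] = cfg.image_compartment_scale
    if cfg.image_assembly_scale > 0:
        means[np.arange(planted.n), C + planted.assembly_of] = cfg.image_assembly_scale
    image_ids: list[str] = []
    prot_col: list[str] = []
    rows = np.repeat(means, images_per_protein, axis=0)
    rows = rows + rng.normal(0.0, noise_sd, size=rows.shape) if noise_sd > 0 else rows
    for i, prot in enumerate(planted.proteins):
        for r in range(images_per_protein):
            image_ids.append(f"IMG{i * images_per_protein + r + 1:06d}")
            prot_col.append(prot)
    return ImageFeatureTable(image_ids, prot_col, rows)


def truth_sets(planted: PlantedHierarchy, level: str = "all") -> ReferenceSets:
    """Planted units as a reference collection (term ids COMP:/ASSY:/SUB:)."""
    terms: list[ReferenceTerm] = []
    if level in ("all", "compartment"):
        for i, m in enumerate(planted.compartments()):
            terms.append(ReferenceTerm(f"COMP:{i}", f"compartment_{i}", m))
    if level in ("all", "assembly"):
        for i, m in enumerate(planted.assemblies()):
            terms.append(ReferenceTerm(f"ASSY:{i}", f"assembly_{i}", m))
    if level in ("all", "subcomplex"):
        for i, m in enumerate(planted.subcomplexes()):
            terms.append(ReferenceTerm(f"SUB:{i}", f"subcomplex_{i}", m))
    if not terms:
        raise ContractViolation(f"unknown level {level!r}")
    return ReferenceSets(terms)


@dataclass
class RecoverySummary:
    scores: dict[str, float]  # term_id -> max Jaccard over DAG nodes
    mean: float
    fraction_recovered: float
    threshold: float


def recovery_score(
    dag: HierarchyDAG,
    truth: ReferenceSets,
    threshold: float = 0.5,
) -> RecoverySummary:
    """Max Jaccard of each planted unit against any DAG node (root included)."""
    node_sets = [n.members for n in dag.nodes.values()]
    scores = {
        t.term_id: max(jaccard(t.members, s) for s in node_sets) for t in truth.terms
    }
    vals = np.array(list(scores.values()))
    return RecoverySummary(
        scores=scores,
        mean=float(vals.mean()),
        fraction_recovered=float((vals >= threshold).mean()),
        threshold=threshold,
    )


def write_synthetic_inputs(
    outdir: str | Path, config: SyntheticConfig, seed: int = 0
) -> PlantedHierarchy:
    """Generate and write edge list, image features, protein list and truth sets."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    planted = sample_planted(config, seed=seed)
    net = sample_ppi(planted, seed=seed + 1)
    images = sample_image_features(planted, seed=seed + 2)
    io.write_edge_list(net, outdir / "ppi_edges.tsv")
    io.write_image_features(images, outdir / "image_features.tsv")
    io.write_protein_list(planted.proteins, outdir / "proteins.txt")
    io.write_reference_sets(truth_sets(planted, "all"), outdir / "truth_sets.tsv")
    doc = asdict(config)
    doc["seed"] = seed
    (outdir / "synthetic_config.json").write_text(
        json.dumps(doc, indent=2) + "\n", encoding="utf-8"
    )
    return planted
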