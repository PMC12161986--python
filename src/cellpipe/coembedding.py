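"""Self-supervised co-embedding of two modality embeddings.

A dual autoencoder with a shared latent space: each modality has a one-hidden-
layer encoder and decoder; the unified latent is the mean of the two encoder
outputs and must reconstruct both modalities. An optional triplet term pulls
together proteins sharing a pseudo-label (k-means partition of each modality)
and pushes apart proteins that do not. Implemented in plain numpy with manual
gradients and Adam so runs are bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans

from .io import write_embedding_tsv
from .provenance import register_stage
from .types import CellpipeError, ContractViolation, EmbeddingSet, ReferenceSets

logger = logging.getLogger(__name__)


class DivergenceError(CellpipeError):
    def __init__(self, trajectory: list[float]):
        super().__init__(f"training loss became non-finite at epoch {len(trajectory)}")
        self.trajectory = trajectory


@dataclass(frozen=True)
class CoembedConfig:
    latent_dim: int = 128
    hidden_dim: int = 512
    epochs: int = 250
    learning_rate: float = 1e-3
    triplet_margin: float = 0.1
    # one k for both modalities, or (k_a, k_b) to cluster each modality at its
    # own granularity; None entries default to ceil(sqrt(n))
    pseudo_label_k: int | tuple[int | None, int | None] | None = None
    alignment_weight: float = 1.0
    triplets_per_anchor: int = 1
    plateau_epochs: int = 25
    plateau_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ContractViolation("latent_dim must be >= 2")
        if self.alignment_weight < 0:
            raise ContractViolation("alignment_weight must be >= 0")
        if self.triplet_margin <= 0:
            raise ContractViolation("triplet_margin must be > 0")


@dataclass
class CoembeddingResult:
    embedding: EmbeddingSet
    loss_trajectory: list[float] = field(default_factory=list)


def align_universes(
    emb_a: EmbeddingSet, emb_b: EmbeddingSet
) -> tuple[EmbeddingSet, EmbeddingSet]:
    """Row-align both embeddings on the lexicographically sorted id intersection."""
    shared = sorted(set(emb_a.ids) & set(emb_b.ids))
    if not shared:
        raise ContractViolation(
            f"empty id intersection ({emb_a.n} vs {emb_b.n} proteins)"
        )
    return emb_a.subset(shared), emb_b.subset(shared)


def zscore_columns(x: np.ndarray) -> np.ndarray:
    """Per-feature z-score; constant columns become zero."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = x - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def _pseudo_labels(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    k = min(k, x.shape[0])
    if k < 2:
        return np.zeros(x.shape[0], dtype=int)
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    return km.fit_predict(x)


def _sample_triplets(
    labels: np.ndarray, rng: np.random.Generator, per_anchor: int
) -> np.ndarray:
    """(T, 3) anchor/positive/negative index triplets from one labeling."""
    n = labels.size
    by_label: dict[int, np.ndarray] = {
        int(l): np.where(labels == l)[0] for l in np.unique(labels)
    }
    triplets: list[tuple[int, int, int]] = []
    for i in range(n):
        same = by_label[int(labels[i])]
        if same.size < 2:
            continue
        other_mask = labels != labels[i]
        others = np.where(other_mask)[0]
        if others.size == 0:
            continue
        for _ in range(per_anchor):
            pos = i
            while pos == i:
                pos = int(same[rng.integers(same.size)])
            neg = int(others[rng.integers(others.size)])
            triplets.append((i, pos, neg))
    if not triplets:
        return np.empty((0, 3), dtype=np.int64)
    return np.asarray(triplets, dtype=np.int64)


def _init_params(d_a: int, d_b: int, h: int, z: int, rng: np.random.Generator) -> dict:
    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        s = math.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    p = {}
    for tag, d in (("a", d_a), ("b", d_b)):
        p[f"W1{tag}"] = glorot(d, h)
        p[f"b1{tag}"] = np.zeros(h)
        p[f"W2{tag}"] = glorot(h, z)
        p[f"b2{tag}"] = np.zeros(z)
        p[f"V1{tag}"] = glorot(z, h)
        p[f"c1{tag}"] = np.zeros(h)
        p[f"V2{tag}"] = glorot(h, d)
        p[f"c2{tag}"] = np.zeros(d)
    return p


def _forward(p: dict, A: np.ndarray, B: np.ndarray) -> dict:
    """Encoders → per-modality latents, L2-normalized and averaged → decoders.

    Normalizing each encoder output before fusing keeps the shared latent
    balanced between modalities regardless of their raw scales.
    """
    Ha = np.maximum(A @ p["W1a"] + p["b1a"], 0.0)
    Hb = np.maximum(B @ p["W1b"] + p["b1b"], 0.0)
    Za = Ha @ p["W2a"] + p["b2a"]
    Zb = Hb @ p["W2b"] + p["b2b"]
    na = np.maximum(np.linalg.norm(Za, axis=1, keepdims=True), 1e-12)
    nb = np.maximum(np.linalg.norm(Zb, axis=1, keepdims=True), 1e-12)
    Zan, Zbn = Za / na, Zb / nb
    Z = 0.5 * (Zan + Zbn)
    Ga = np.maximum(Z @ p["V1a"] + p["c1a"], 0.0)
    Gb = np.maximum(Z @ p["V1b"] + p["c1b"], 0.0)
    Ahat = Ga @ p["V2a"] + p["c2a"]
    Bhat = Gb @ p["V2b"] + p["c2b"]
    return dict(
        Ha=Ha, Hb=Hb, Za=Za, Zb=Zb, na=na, nb=nb, Zan=Zan, Zbn=Zbn, Z=Z,
        Ga=Ga, Gb=Gb, Ahat=Ahat, Bhat=Bhat,
    )


def fit_coembedding(
    emb_a: EmbeddingSet, emb_b: EmbeddingSet, config: CoembedConfig | None = None
) -> CoembeddingResult:
    """Train the dual autoencoder and return the unified embedding.

    Objective: MSE reconstruction of both (z-scored) modalities from the
    shared latent plus ``alignment_weight`` × triplet hinge loss on the
    latent, with triplets drawn from per-modality pseudo-labels.
    """
    config = config or CoembedConfig()
    emb_a, emb_b = align_universes(emb_a, emb_b)
    ids = list(emb_a.ids)
    n = len(ids)
    A = zscore_columns(emb_a.vectors.copy())
    B = zscore_columns(emb_b.vectors.copy())
    z, h = config.latent_dim, config.hidden_dim
    rng = np.random.default_rng(config.seed)
    p = _init_params(A.shape[1], B.shape[1], h, z, rng)

    k_default = max(2, math.ceil(math.sqrt(n)))
    pk = config.pseudo_label_k
    if pk is None:
        k_a = k_b = k_default
    elif isinstance(pk, tuple):
        k_a = pk[0] if pk[0] is not None else k_default
        k_b = pk[1] if pk[1] is not None else k_default
    else:
        k_a = k_b = int(pk)
    labels_a = _pseudo_labels(A, k_a, config.seed)
    labels_b = _pseudo_labels(B, k_b, config.seed + 1)

    adam_m = {k_: np.zeros_like(v) for k_, v in p.items()}
    adam_v = {k_: np.zeros_like(v) for k_, v in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lam, margin = config.alignment_weight, config.triplet_margin
    trajectory: list[float] = []
    t = 0
    for epoch in range(config.epochs):
        f = _forward(p, A, B)
        dAhat = 2.0 * (f["Ahat"] - A) / A.size
        dBhat = 2.0 * (f["Bhat"] - B) / B.size
        loss = float(np.mean((f["Ahat"] - A) ** 2) + np.mean((f["Bhat"] - B) ** 2))

        dZ = np.zeros_like(f["Z"])
        if lam > 0:
            trips = np.vstack(
                [
                    _sample_triplets(labels_a, rng, config.triplets_per_anchor),
                    _sample_triplets(labels_b, rng, config.triplets_per_anchor),
                ]
            )
            if trips.shape[0] > 0:
                Zm = f["Z"]
                ai, pi, ni = trips[:, 0], trips[:, 1], trips[:, 2]
                dp = Zm[ai] - Zm[pi]
                dn = Zm[ai] - Zm[ni]
                hinge = np.einsum("td,td->t", dp, dp) - np.einsum("td,td->t", dn, dn) + margin
                active = hinge > 0
                T = trips.shape[0]
                loss += lam * float(np.sum(np.maximum(hinge, 0.0))) / T
                if np.any(active):
                    coef = lam / T
                    dpa, dna = dp[active], dn[active]
                    np.add.at(dZ, ai[active], coef * 2.0 * (dpa - dna))
                    np.add.at(dZ, pi[active], -coef * 2.0 * dpa)
                    np.add.at(dZ, ni[active], coef * 2.0 * dna)

        trajectory.append(loss)
        if not np.isfinite(loss):
            raise DivergenceError(trajectory)

        grads: dict[str, np.ndarray] = {}
        for tag, X, dXhat in (("a", A, dAhat), ("b", B, dBhat)):
            G = f[f"G{tag}"]
            dG = (dXhat @ p[f"V2{tag}"].T) * (G > 0)
            grads[f"V2{tag}"] = G.T @ dXhat
            grads[f"c2{tag}"] = dXhat.sum(axis=0)
            grads[f"V1{tag}"] = f["Z"].T @ dG
            grads[f"c1{tag}"] = dG.sum(axis=0)
            dZ = dZ + dG @ p[f"V1{tag}"].T
        for tag, X in (("a", A), ("b", B)):
            # back through Z = 0.5 * Z_norm: remove the radial component
            Zn = f[f"Z{tag}n"]
            dZn = 0.5 * dZ
            dZraw = (dZn - Zn * np.sum(dZn * Zn, axis=1, keepdims=True)) / f[f"n{tag}"]
            H = f[f"H{tag}"]
            grads[f"W2{tag}"] = H.T @ dZraw
            grads[f"b2{tag}"] = dZraw.sum(axis=0)
            dH = (dZraw @ p[f"W2{tag}"].T) * (H > 0)
            grads[f"W1{tag}"] = X.T @ dH
            grads[f"b1{tag}"] = dH.sum(axis=0)

        t += 1
        for k_ in p:
            g = grads[k_]
            adam_m[k_] = beta1 * adam_m[k_] + (1 - beta1) * g
            adam_v[k_] = beta2 * adam_v[k_] + (1 - beta2) * g * g
            mhat = adam_m[k_] / (1 - beta1**t)
            vhat = adam_v[k_] / (1 - beta2**t)
            p[k_] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

        if (
            epoch >= config.plateau_epochs
            and trajectory[-config.plateau_epochs - 1] - loss
            < config.plateau_tol * max(1.0, abs(loss))
        ):
            logger.info("coembedding early stop at epoch %d", epoch + 1)
            break

    Z = _forward(p, A, B)["Z"]
    norms = np.linalg.norm(Z, axis=1)
    norms[norms == 0] = 1.0
    unified = EmbeddingSet(ids, Z / norms[:, None], modality="coembedding")
    return CoembeddingResult(unified, trajectory)


@dataclass
class PairSimilarityReport:
    decile_cocomplex_fraction: list[float]  # index 0 = highest-similarity decile
    rank_sum: float  # Mann-Whitney U, within-term vs other pairs
    auc: float  # U normalized to [0, 1]
    p_value: float
    n_within: int
    n_other: int


def evaluate_pair_similarity(
    emb: EmbeddingSet, reference: ReferenceSets
) -> PairSimilarityReport:
    """Cosine similarity of all protein pairs vs co-membership in reference terms."""
    member_universe = reference.universe()
    overlap = [p for p in emb.ids if p in member_universe]
    if len(overlap) < 2:
        raise ContractViolation(
            f"only {len(overlap)} embedding protein(s) overlap the reference"
        )
    X = emb.vectors
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    Xn = X / norms[:, None]
    S = Xn @ Xn.T
    n = emb.n
    iu, ju = np.triu_indices(n, k=1)
    sims = S[iu, ju]

    idx = emb.index()
    within = np.zeros(sims.size, dtype=bool)
    # row-major upper-triangle offsets: pair (i, j) lives at offsets[i] + j - i - 1
    offsets = np.zeros(n, dtype=np.int64)
    cnt = 0
    for i in range(n):
        offsets[i] = cnt
        cnt += n - i - 1
    for term in reference.terms:
        mem = sorted(m for m in term.members if m in idx)
        for a_i in range(len(mem)):
            for b_i in range(a_i + 1, len(mem)):
                i, j = idx[mem[a_i]], idx[mem[b_i]]
                if i > j:
                    i, j = j, i
                within[offsets[i] + (j - i - 1)] = True

    order = np.argsort(-sims, kind="stable")
    deciles: list[float] = []
    bounds = np.linspace(0, sims.size, 11).astype(int)
    for d in range(10):
        sl = order[bounds[d] : bounds[d + 1]]
        deciles.append(float(within[sl].mean()) if sl.size else float("nan"))

    w = sims[within]
    o = sims[~within]
    if w.size == 0 or o.size == 0:
        raise ContractViolation("need both within-term and non-term pairs")
    res = mannwhitneyu(w, o, alternative="greater")
    return PairSimilarityReport(
        decile_cocomplex_fraction=deciles,
        rank_sum=float(res.statistic),
        auc=float(res.statistic) / (w.size * o.size),
        p_value=float(res.pvalue),
        n_within=int(w.size),
        n_other=int(o.size),
    )


def project_2d(emb: EmbeddingSet, seed: int = 0) -> np.ndarray:
    """UMAP projection to 2 coordinates, deterministic for a fixed seed."""
    if emb.n < 10:
        raise ContractViolation(
            f"n={emb.n} < 10: too few points to project, plot the vectors directly"
        )
    import umap  # heavy import (numba), keep lazy

    reducer = umap.UMAP(
        n_components=2,
        random_state=seed,
        n_neighbors=min(15, emb.n - 1),
        n_jobs=1,
    )
    coords = reducer.fit_transform(emb.vectors)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise CellpipeError("UMAP produced non-finite coordinates")
    return coords


def coembed(
    emb_a: EmbeddingSet,
    emb_b: EmbeddingSet,
    config: CoembedConfig | None = None,
    outdir: str | Path | None = None,
    inputs: Sequence[str] = (),
    write_umap: bool = False,
) -> CoembeddingResult:
    """Fit the co-embedding and optionally write a stage directory."""
    result = fit_coembedding(emb_a, emb_b, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_embedding_tsv(result.embedding, outdir / "coembedding.tsv")
        (outdir / "coembed_loss.tsv").write_text(
            "epoch\tloss\n"
            + "".join(f"{i}\t{v!r}\n" for i, v in enumerate(result.loss_trajectory)),
            encoding="utf-8",
        )
        if write_umap and result.embedding.n >= 10:
            coords = project_2d(result.embedding, seed=(config or CoembedConfig()).seed)
            with (outdir / "umap.tsv").open("w", encoding="utf-8") as fh:
                fh.write("id\tx\ty\n")
                for pid, (x, y) in zip(result.embedding.ids, coords):
                    fh.write(f"{pid}\t{x!r}\t{y!r}\n")
        cfg = config or CoembedConfig()
        register_stage(
            outdir,
            "coembedding",
            inputs=inputs,
            params={
                "latent_dim": cfg.latent_dim,
                "hidden_dim": cfg.hidden_dim,
                "epochs": cfg.epochs,
                "learning_rate": cfg.learning_rate,
                "triplet_margin": cfg.triplet_margin,
                "alignment_weight": cfg.alignment_weight,
                "seed": cfg.seed,
            },
        )
    return result
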