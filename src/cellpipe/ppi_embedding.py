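"""Network-modality embedding.

Second-order biased random walks over the interaction network followed by
skip-gram training with negative sampling. Training is single-threaded pure
numpy and bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .io import write_embedding_tsv
from .provenance import register_stage
from .types import ContractViolation, EmbeddingSet, InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkParams:
    num_walks: int = 10
    walk_length: int = 80
    p: float = 1.0
    q: float = 1.0
    seed: int = 0
    use_edge_scores: bool = False


@dataclass
class WalkCorpus:
    walks: list[list[str]]
    params: WalkParams


@dataclass(frozen=True)
class SkipGramConfig:
    dimension: int = 128
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    batch_size: int = 256  # small batches: updates aggregate within a batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.window < 1 or self.negatives < 1:
            raise ContractViolation("dimension, window and negatives must be >= 1")


def second_order_weight(
    prev_node: str,
    cur_node: str,
    next_node: str,
    p: float,
    q: float,
    network: InteractionNetwork,
    use_edge_scores: bool = False,
) -> float:
    """node2vec bias for stepping cur→next having arrived from prev.

    weight × 1/p if next == prev, × 1 if next is adjacent to prev,
    × 1/q otherwise.
    """
    adj = network.neighbors()
    if next_node not in adj.get(cur_node, []):
        raise ContractViolation(f"{cur_node!r} and {next_node!r} are not adjacent")
    w = 1.0
    if use_edge_scores and network.scores is not None:
        a, b = (cur_node, next_node) if cur_node <= next_node else (next_node, cur_node)
        w = network.scores[(a, b)]
    if next_node == prev_node:
        return w / p
    if prev_node in adj and next_node in adj[prev_node]:
        return w
    return w / q


def generate_walks(network: InteractionNetwork, params: WalkParams) -> WalkCorpus:
    """Generate ``num_walks`` biased walks per node, deterministic per seed.

    Isolated nodes yield length-1 walks, so |walks| = num_walks × |nodes|.
    """
    if not network.nodes:
        raise ContractViolation("cannot walk an empty network")
    nodes = sorted(network.nodes)
    node_idx = {n: i for i, n in enumerate(nodes)}
    adj_lists = network.neighbors()
    neigh = [np.array([node_idx[m] for m in adj_lists[n]], dtype=np.int64) for n in nodes]
    neigh_sets = [set(a.tolist()) for a in neigh]
    if params.use_edge_scores and network.scores is not None:
        wts = []
        for n in nodes:
            row = []
            for m in adj_lists[n]:
                a, b = (n, m) if n <= m else (m, n)
                row.append(network.scores[(a, b)])
            wts.append(np.asarray(row, dtype=float))
    else:
        wts = [np.ones(len(a), dtype=float) for a in neigh]

    rng = np.random.default_rng(params.seed)
    inv_p, inv_q = 1.0 / params.p, 1.0 / params.q
    walks: list[list[str]] = []
    for _ in range(params.num_walks):
        for start in range(len(nodes)):
            walk = [start]
            while len(walk) < params.walk_length:
                cur = walk[-1]
                nbrs = neigh[cur]
                if nbrs.size == 0:
                    break
                if len(walk) == 1:
                    probs = wts[cur]
                else:
                    prev = walk[-2]
                    bias = np.where(
                        nbrs == prev,
                        inv_p,
                        np.fromiter(
                            ((1.0 if m in neigh_sets[prev] else inv_q) for m in nbrs),
                            dtype=float,
                            count=nbrs.size,
                        ),
                    )
                    probs = wts[cur] * bias
                probs = probs / probs.sum()
                walk.append(int(nbrs[rng.choice(nbrs.size, p=probs)]))
            walks.append([nodes[i] for i in walk])
    return WalkCorpus(walks, params)


def _walk_pairs(
    token_walks: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Center/context pairs with the word2vec dynamic (seeded) window."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for walk in token_walks:
        L = walk.size
        if L < 2:
            continue
        spans = rng.integers(1, window + 1, size=L)
        for i in range(L):
            lo = max(0, i - int(spans[i]))
            hi = min(L, i + int(spans[i]) + 1)
            ctx = np.concatenate([walk[lo:i], walk[i + 1 : hi]])
            centers.append(np.full(ctx.size, walk[i], dtype=np.int64))
            contexts.append(ctx)
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def train_skipgram(
    corpus: WalkCorpus,
    config: SkipGramConfig,
    vocabulary: Sequence[str] | None = None,
) -> EmbeddingSet:
    """Skip-gram with negative sampling over the walk corpus.

    ``vocabulary`` may list nodes absent from every walk (isolated nodes);
    they keep their random-init vectors and are logged.
    """
    if not corpus.walks:
        raise ContractViolation("empty walk corpus")
    vocab = sorted(vocabulary) if vocabulary is not None else sorted(
        {tok for w in corpus.walks for tok in w}
    )
    tok_idx = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)
    token_walks = [
        np.array([tok_idx[t] for t in w], dtype=np.int64) for w in corpus.walks
    ]

    counts = np.zeros(V, dtype=float)
    for w in token_walks:
        np.add.at(counts, w, 1.0)
    unseen = [vocab[i] for i in range(V) if counts[i] == 0]
    if unseen:
        logger.warning(
            "%d node(s) absent from all walks keep random-init vectors: %s",
            len(unseen),
            ", ".join(unseen[:10]),
        )
    # unigram^(3/4) negative-sampling distribution over walk tokens
    neg_probs = np.power(np.maximum(counts, 0.0), 0.75)
    if neg_probs.sum() == 0:
        neg_probs = np.ones(V)
    neg_probs = neg_probs / neg_probs.sum()

    rng = np.random.default_rng(config.seed)
    d = config.dimension
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))

    total_steps = 0
    pair_counts = []
    # Pre-draw pair sets per epoch so the lr schedule has a known horizon.
    epoch_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(config.epochs):
        c, o = _walk_pairs(token_walks, config.window, rng)
        perm = rng.permutation(c.size)
        epoch_pairs.append((c[perm], o[perm]))
        pair_counts.append(c.size)
    horizon = max(1, sum(pair_counts))

    lr0, lr_min = config.learning_rate, config.min_learning_rate
    seen = 0
    for centers, contexts in epoch_pairs:
        for s in range(0, centers.size, config.batch_size):
            c = centers[s : s + config.batch_size]
            o = contexts[s : s + config.batch_size]
            B = c.size
            if B == 0:
                continue
            negs = rng.choice(V, size=(B, config.negatives), p=neg_probs)
            lr = max(lr_min, lr0 * (1.0 - seen / horizon))

            vc = W_in[c]  # (B, d)
            vo = W_out[o]  # (B, d)
            vn = W_out[negs]  # (B, k, d)

            pos_score = expit(np.einsum("bd,bd->b", vc, vo))
            neg_score = expit(np.einsum("bd,bkd->bk", vc, vn))

            g_pos = (pos_score - 1.0)[:, None]  # d/dx of -log sigma(x)
            g_neg = neg_score[..., None]

            grad_c = g_pos * vo + np.einsum("bko,bkd->bd", g_neg, vn)
            grad_o = g_pos * vc
            grad_n = g_neg * vc[:, None, :]

            np.add.at(W_in, c, -lr * grad_c)
            np.add.at(W_out, o, -lr * grad_o)
            np.add.at(W_out, negs.reshape(-1), -lr * grad_n.reshape(-1, d))
            seen += B
            total_steps += 1

    if not np.all(np.isfinite(W_in)):
        raise ContractViolation("skip-gram training diverged to non-finite values")
    logger.info("skip-gram: %d vocab, %d batches, %d pairs", V, total_steps, horizon)
    return EmbeddingSet(list(vocab), W_in, modality="ppi")


def ppi_embed(
    network: InteractionNetwork,
    walk_params: WalkParams | None = None,
    sg_config: SkipGramConfig | None = None,
    outdir: str | Path | None = None,
    inputs: Sequence[str] = (),
) -> EmbeddingSet:
    """Walks + skip-gram composition; optionally writes a stage directory."""
    walk_params = walk_params or WalkParams()
    sg_config = sg_config or SkipGramConfig()
    corpus = generate_walks(network, walk_params)
    emb = train_skipgram(corpus, sg_config, vocabulary=sorted(network.nodes))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_embedding_tsv(emb, outdir / "ppi_emb.tsv")
        (outdir / "ppi_embed.log").write_text(
            f"nodes={network.n_nodes} edges={network.n_edges} "
            f"walks={len(corpus.walks)} dim={sg_config.dimension}\n",
            encoding="utf-8",
        )
        register_stage(
            outdir,
            "ppi_embedding",
            inputs=inputs,
            params={
                "num_walks": walk_params.num_walks,
                "walk_length": walk_params.walk_length,
                "p": walk_params.p,
                "q": walk_params.q,
                "walk_seed": walk_params.seed,
                "dimension": sg_config.dimension,
                "window": sg_config.window,
                "negatives": sg_config.negatives,
                "epochs": sg_config.epochs,
                "sg_seed": sg_config.seed,
            },
        )
    return emb


def exact_transition_matrix(network: InteractionNetwork) -> tuple[list[str], np.ndarray]:
    """First-order (p=q=1, unweighted) walk transition matrix, for oracles."""
    nodes = sorted(network.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    T = np.zeros((len(nodes), len(nodes)))
    adj = network.neighbors()
    for n in nodes:
        nbrs = adj[n]
        for m in nbrs:
            T[idx[n], idx[m]] = 1.0 / len(nbrs)
    return nodes, T
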