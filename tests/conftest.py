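import numpy as np
import pytest

from cellpipe.image_embedding import aggregate_per_protein
from cellpipe.ppi_embedding import (
    SkipGramConfig,
    WalkParams,
    generate_walks,
    train_skipgram,
)
from cellpipe.synthetic import (
    PRESETS,
    sample_image_features,
    sample_planted,
    sample_ppi,
)
from cellpipe.types import InteractionNetwork


def filter_network(net: InteractionNetwork, min_score: float = 0.7) -> InteractionNetwork:
    kept = {e for e, s in net.scores.items() if s >= min_score}
    return InteractionNetwork(
        net.nodes, frozenset(kept), {e: net.scores[e] for e in kept}
    )


def small_chain(
    seed: int,
    preset: str = "demo150",
    coembed_epochs: int = 300,
    pseudo_label_k=(None, 4),
):
    """Synthetic inputs → modality embeddings → unified embedding (desk scale)."""
    from cellpipe.coembedding import CoembedConfig, fit_coembedding

    cfg = PRESETS[preset]
    planted = sample_planted(cfg, seed=seed)
    net = filter_network(sample_ppi(planted, seed=seed + 1))
    corpus = generate_walks(net, WalkParams(num_walks=8, walk_length=40, seed=seed + 2))
    ppi_emb = train_skipgram(
        corpus,
        SkipGramConfig(dimension=32, epochs=4, seed=seed + 3),
        vocabulary=sorted(net.nodes),
    )
    img_emb = aggregate_per_protein(sample_image_features(planted, seed=seed + 4))
    result = fit_coembedding(
        ppi_emb,
        img_emb,
        # coarse pseudo-labels on the image side (compartment scale), default
        # (assembly scale) on the network side
        CoembedConfig(
            latent_dim=64,
            hidden_dim=256,
            epochs=coembed_epochs,
            pseudo_label_k=pseudo_label_k,
            seed=seed + 5,
        ),
    )
    return planted, net, ppi_emb, img_emb, result


@pytest.fixture(scope="session")
def demo150_chain():
    return small_chain(seed=1)


@pytest.fixture(scope="session")
def demo150_dag(demo150_chain):
    from cellpipe.hierarchy import build_hierarchy

    _, _, _, _, result = demo150_chain
    return build_hierarchy(result.embedding, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
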