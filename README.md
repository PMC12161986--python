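# cellpipe

Multimodal protein embedding, self-supervised co-embedding, and multi-scale
assembly-hierarchy construction — an end-to-end pipeline that turns a
protein–protein interaction network and per-image protein feature vectors
into a hierarchical map of protein assemblies, with enrichment evaluation,
jackknife robustness scoring, and per-stage provenance records.

## Pipeline stages

1. **Image embedding** — aggregate per-image feature vectors (one row per
   image, stand-ins for classifier penultimate-layer features) into one
   vector per protein (median by default).
2. **PPI embedding** — second-order biased random walks over the interaction
   network plus skip-gram with negative sampling (pure numpy, seeded,
   bit-deterministic).
3. **Co-embedding** — a dual autoencoder with a shared latent space: each
   modality is encoded, the L2-normalized encoder outputs are averaged, and
   both modalities are reconstructed from the shared latent; a triplet term
   over per-modality k-means pseudo-labels aligns the space.
4. **Hierarchy generation** — cosine similarities → a nested stack of
   threshold graphs over an edge-density ladder → CPM Leiden partitioning at
   every (threshold, resolution) sweep cell → persistence filtering of
   communities re-identified across consecutive cells → containment DAG.
5. **Evaluation** — exact hypergeometric enrichment of DAG nodes against
   reference assembly sets (CORUM/GO-CC-style) with Benjamini–Hochberg
   control, plus jackknife robustness under protein dropout.

Each stage writes a directory containing its outputs, a log file, and a
`ro-crate-metadata.json` provenance document (inputs, parameters, software
version, output manifest with SHA-256 digests). `validate_stage` re-checks
manifests at any time, and the stage records chain into a full lineage.

A synthetic generator (`cellpipe.synthetic`) plants a nested
compartment → assembly ground truth shared across both modalities, so every
stage — and end-to-end recovery — is testable without any downloads.

## CLI

One `cellpipe` group plus per-stage aliases (`ppi-embed`, `image-embed`,
`coembed`, `generate-hierarchy`, `hierarchy-eval`):

```bash
# generate synthetic inputs with a planted hierarchy (600 proteins,
# 3 compartments x 200, assembly edge scores >= 0.7)
cellpipe synth ./inputs --preset demo600 --seed 1

# full pipeline: five numbered stage directories under ./out
cellpipe run ./out --edge_list inputs/ppi_edges.tsv \
    --image_features inputs/image_features.tsv \
    --reference inputs/truth_sets.tsv --seed 1

# stages can also be run separately
ppi-embed ./out/2.ppi_embedding --inputdir ./inputs --dimensions 128 --seed 1
image-embed ./out/1.image_embedding --inputdir ./inputs --agg median
coembed ./out/3.coembedding --embeddings ./out/2.ppi_embedding ./out/1.image_embedding
generate-hierarchy ./out/4.hierarchy --coembedding_dirs ./out/3.coembedding
hierarchy-eval ./out/5.hierarchyeval --hierarchy_dir ./out/4.hierarchy \
    --reference inputs/truth_sets.tsv

# provenance utilities
cellpipe validate-stage ./out/2.ppi_embedding
cellpipe substitute-stage coembedding ./my_external_coembedding
cellpipe run . --example_provenance   # print a provenance template
```

`cellpipe run --resume` skips stages whose directories still validate and
rebuilds the rest; the global seed fans out to per-stage seeds through a
seed splitter, so resuming never shifts downstream randomness.

## Acceptance

The acceptance criteria are property-based and implemented in
`tests/test_acceptance.py` (exhaustive CPM and hypergeometric oracles,
planted-structure recovery, co-embedding gain, FDR control, robustness
monotonicity, determinism + provenance). The report generator

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a fast end-to-end sanity check and writes the (empty — no numeric
targets are defined for this build) target report.

## Layout

```
src/cellpipe/
  types.py            core domain types (network, embeddings, references)
  io.py               TSV readers/writers, full-precision round trips
  provenance.py       stage registration + manifest/digest validation
  ppi_embedding.py    biased walks + numpy skip-gram
  image_embedding.py  per-protein aggregation
  coembedding.py      dual autoencoder, pair-similarity evaluation, UMAP
  hierarchy.py        similarity stack, CPM sweep, persistence, DAG
  evaluation.py       hypergeometric enrichment, BH, jackknife robustness
  synthetic.py        planted-hierarchy generator + recovery metrics
  pipeline.py         stage orchestration, resume, external substitution
  cli.py              click CLI
```
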