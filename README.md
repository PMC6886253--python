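# ppimm

Multimodal protein representation learning for protein–protein
interaction (PPI) prediction and protein family classification.

The pipeline combines two unsupervised modalities per protein and two
supervised heads:

1. **Sequence descriptors** — variable-length amino-acid sequences are
   encoded into fixed 468-dim vectors: amino-acid composition (AAC, 20),
   grouped AAC (GAAC, 5), conjoint triad (CT, 343) and
   quasi-sequence-order (QSO, 100 = 2 distance matrices × (20 + 30 lags)).
2. **Stacked autoencoder (SAE)** — a symmetric 256-128-64-128-256
   autoencoder trained by SGD on MSE compresses each 468-dim descriptor
   to a 64-dim deep feature.
3. **Metapath CBOW embeddings** — bounded uniform random walks (length
   10, 4 walks per node) over the PPI graph are used as a corpus for a
   CBOW model (window 1, 128 dims) that learns topological node vectors;
   cosine nearest-neighbour queries are supported.
4. **Late fusion + supervised heads** — the 128-dim topological vector
   and 64-dim deep sequence feature are concatenated into a 192-dim
   representation feeding (a) a twin-branch binary interaction
   classifier trained on binary cross entropy, and (b) a three-layer
   softmax DNN (dropout 0.5) for multi-family classification trained on
   categorical cross entropy.

Balanced datasets are built by sampling negative pairs whose proteins
share no subcellular location, with an 80/20 shuffled train/test split;
evaluation covers precision/accuracy/specificity/recall, rank-based
AUC-ROC, micro/macro-F1 and a stratified 5-fold CV driver. A synthetic
fixture generator (random sequences with per-family composition bias +
planted-partition graphs with block-aligned location/family labels)
exercises everything offline.

All neural components (CBOW, SAE, both heads) are implemented directly
in numpy with seeded, reproducible minibatch SGD.

## CLI

Every stage is a subcommand of `ppimm` (see `ppimm --help`):

```bash
ppimm fixtures --out fixture/ --seed 1            # synthetic bundle
ppimm encode --fasta fixture/proteins.fasta --out features.tsv
ppimm walks --edges fixture/edges.tsv --out walks.txt --length 10 --fanout 4 --seed 1
ppimm embed --walks walks.txt --out emb.txt --dim 128 --window 1 --epochs 10 --seed 1
ppimm sae-train --features features.tsv --out sae.json --epochs 50 --seed 1
ppimm sae-encode --model sae.json --features features.tsv --out latent.tsv
ppimm make-dataset --positives fixture/positive_pairs.tsv \
    --locations fixture/locations.tsv --out-train train.tsv --out-test test.tsv --seed 1
ppimm train-ppi / predict-ppi / train-family / predict-family / evaluate ...
```

The whole pipeline (encode → walks → embed → SAE → fuse → train →
evaluate, with a manifest of artifact hashes) runs as:

```bash
ppimm run --fasta fixture/proteins.fasta --positives fixture/positive_pairs.tsv \
    --locations fixture/locations.tsv --families fixture/families.tsv \
    --config config.yaml --seed 1 --out artifacts/
```

`config.yaml` may override any default (batch size 64, SGD lr 0.01, SAE
epochs 50, CBOW epochs 10, DNN epochs 200, dropout 0.5, QSO w=0.1 /
nlag=30, split 0.8, family min-count 15, ...). Precedence: CLI flag >
config file > default. Per-stage seeds are derived from the master seed.

## Layout

```
src/ppimm/
  seq_features.py   descriptor encoders + FASTA/feature-table IO
  distances.py      QSO residue-distance matrices
  ppi_graph.py      edge-list graph, metapath walks, context pairs
  cbow.py           CBOW embedder + cosine nearest neighbours
  sae.py            stacked autoencoder
  fusion.py         late fusion, PPI head, family head, family filter
  dataset.py        location-aware negatives, train/test split
  evaluation.py     metrics, AUC, F1, stratified k-fold CV
  fixtures.py       synthetic sequence/graph/label generators
  pipeline.py       end-to-end orchestration + manifest
  cli.py            click CLI (`ppimm`)
```
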