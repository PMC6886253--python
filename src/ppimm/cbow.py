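"""CBOW node embeddings over metapath corpora.

The model predicts a walk's center node from the average of its context
node vectors and is trained by SGD on the negative log-likelihood of the
softmax-parameterized conditional. Two estimators are available:

* ``full`` -- exact softmax over the vocabulary (tractable for the graph
  sizes handled here; also the mode used for determinism/loss tests);
* ``neg`` -- negative sampling with ``k`` noise nodes drawn from the
  unigram^0.75 distribution (default, standard CBOW practice).

Implemented directly in numpy with batched updates; runs are bitwise
reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ppi_graph import context_pairs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CbowConfig:
    dim: int = 128
    window: int = 1
    epochs: int = 10
    learning_rate: float = 0.025
    seed: int = 0
    softmax_mode: str = "neg"  # "full" | "neg"
    negatives: int = 5
    batch_size: int = 256

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("dim, window and epochs must all be >= 1")
        if self.softmax_mode not in ("full", "neg"):
            raise ValueError(f"unknown softmax_mode {self.softmax_mode!r}")


@dataclass
class EmbeddingMatrix:
    """Node-ID -> row lookup over a |V| x dim vector matrix."""

    vocabulary: dict[str, int]
    vectors: np.ndarray
    loss_history: list[float] | None = None

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.vectors[self.vocabulary[node_id]]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.vocabulary

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def get(self, node_id: str, cold_start: str = "zero") -> np.ndarray:
        """Vector for ``node_id``; unseen nodes get zeros (or the mean)."""
        if node_id in self.vocabulary:
            return self.vectors[self.vocabulary[node_id]]
        logger.info("cold-start node %s: substituting %s vector", node_id, cold_start)
        if cold_start == "mean":
            return self.vectors.mean(axis=0)
        return np.zeros(self.dim)


def _batches(n: int, size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, size):
        yield order[lo: lo + size]


def train_cbow(paths: list[list[str]], cfg: CbowConfig | None = None) -> EmbeddingMatrix:
    """Learn node vectors from walk corpus ``paths``.

    Raises on an empty corpus or a single-node vocabulary (no context
    exists to predict from).
    """
    cfg = cfg or CbowConfig()
    pairs = context_pairs(paths, cfg.window)
    if not pairs:
        raise ValueError("empty training corpus: need at least one path of length >= 2")
    vocab: dict[str, int] = {}
    for path in paths:
        for node in path:
            vocab.setdefault(node, len(vocab))
    if len(vocab) < 2:
        raise ValueError("vocabulary has a single node; no context exists")

    v, d = len(vocab), cfg.dim
    rng = np.random.default_rng(cfg.seed)
    # unit-scale input vectors avoid the vanishing cold start of the
    # classic +/-0.5/dim init at the small step counts used here
    w_in = rng.normal(0.0, 1.0 / np.sqrt(d), size=(v, d))
    w_out = np.zeros((v, d))

    centers = np.array([vocab[c] for c, _ in pairs])
    max_ctx = max(len(ctx) for _, ctx in pairs)
    ctx_idx = np.zeros((len(pairs), max_ctx), dtype=np.int64)
    ctx_mask = np.zeros((len(pairs), max_ctx))
    for i, (_, ctx) in enumerate(pairs):
        ctx_idx[i, : len(ctx)] = [vocab[x] for x in ctx]
        ctx_mask[i, : len(ctx)] = 1.0
    ctx_count = ctx_mask.sum(axis=1, keepdims=True)

    counts = np.bincount(
        np.concatenate([centers, ctx_idx[ctx_mask.astype(bool)]]), minlength=v
    ).astype(float)
    noise = counts**0.75
    noise /= noise.sum()

    n_steps = cfg.epochs * max(1, int(np.ceil(len(pairs) / cfg.batch_size)))
    step = 0
    history: list[float] = []
    for _ in range(cfg.epochs):
        epoch_loss = 0.0
        epoch_n = 0
        for batch in _batches(len(pairs), cfg.batch_size, rng):
            lr = cfg.learning_rate * max(1e-4, 1.0 - step / n_steps)
            step += 1
            b = len(batch)
            ci = ctx_idx[batch]
            cm = ctx_mask[batch][:, :, None]
            h = (w_in[ci] * cm).sum(axis=1) / ctx_count[batch]  # B x d
            tgt = centers[batch]
            if cfg.softmax_mode == "full":
                logits = h @ w_out.T  # B x V
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                epoch_loss -= np.log(np.maximum(p[np.arange(b), tgt], 1e-300)).sum()
                epoch_n += b
                # batch-sum gradient: learning_rate is the per-sample step,
                # as in the reference word2vec implementation
                dlogits = p
                dlogits[np.arange(b), tgt] -= 1.0
                dh = dlogits @ w_out
                w_out -= lr * (dlogits.T @ h)
            else:
                neg = rng.choice(v, size=(b, cfg.negatives), p=noise)
                rows = np.concatenate([tgt[:, None], neg], axis=1)  # B x (1+k)
                sign = np.full((b, 1 + cfg.negatives), -1.0)
                sign[:, 0] = 1.0
                scores = np.einsum("bkd,bd->bk", w_out[rows], h)
                sig = 1.0 / (1.0 + np.exp(-sign * scores))
                epoch_loss -= np.log(np.maximum(sig, 1e-300)).sum()
                epoch_n += b
                g = sign * (sig - 1.0)  # d(loss)/d(score), per-sample step
                dh = np.einsum("bk,bkd->bd", g, w_out[rows])
                dw = g[:, :, None] * h[:, None, :]
                np.add.at(w_out, rows, -lr * dw)
            # distribute dh back over this batch's context slots
            upd = (dh[:, None, :] * cm) / ctx_count[batch][:, :, None]
            np.add.at(w_in, ci, -lr * upd)
        history.append(epoch_loss / max(1, epoch_n))
    logger.info("CBOW trained: |V|=%d, dim=%d, final loss %.4f", v, d, history[-1])
    return EmbeddingMatrix(vocab, w_in, history)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def most_similar(emb: EmbeddingMatrix, query_id: str, k: int = 10) -> list[tuple[str, float]]:
    """Top-k nodes by cosine similarity to the query, descending.

    Ties are broken lexicographically by node ID; the query itself is
    excluded. k larger than |V|-1 is clipped.
    """
    if query_id not in emb.vocabulary:
        raise KeyError(f"unknown node {query_id!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    q = emb[query_id]
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(emb.vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = emb.vectors @ q / np.where(norms * qn == 0, np.inf, norms * qn)
    ranked = sorted(
        (
            (node, float(sims[i]))
            for node, i in emb.vocabulary.items()
            if node != query_id
        ),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]


def write_embeddings(path, emb: EmbeddingMatrix) -> None:
    """word2vec text format: header "V dim", then "id v1 ... vdim" lines."""
    with open(path, "w") as fh:
        fh.write(f"{len(emb.vocabulary)} {emb.dim}\n")
        for node, i in emb.vocabulary.items():
            fh.write(node + " " + " ".join(repr(float(x)) for x in emb.vectors[i]) + "\n")


def read_embeddings(path) -> EmbeddingMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        v, d = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.empty((v, d))
        for line in fh:
            parts = line.split()
            vocab[parts[0]] = len(vocab)
            vectors[vocab[parts[0]]] = [float(x) for x in parts[1:]]
    if len(vocab) != v:
        raise ValueError(f"{path}: header promised {v} rows, found {len(vocab)}")
    return EmbeddingMatrix(vocab, vectors)
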