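"""Late fusion and the two supervised heads.

``fuse`` concatenates the per-protein topological embedding (128-dim) and
the deep sequence feature (64-dim) into a 192-dim vector, layout
``[topo | seq]`` (recorded on the model checkpoints so they are
self-describing).

The interaction head is a twin-branch network: each protein's fused
vector passes through its own branch, the branch outputs are concatenated
into one 64-unit fully connected layer and a single sigmoid output,
trained by SGD on binary cross entropy. The family head is a three-layer
softmax DNN (default 128-64-C) with dropout 0.5, trained on categorical
cross entropy. Both are plain numpy SGD implementations.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-7  # probability clipping inside the cross-entropy losses


class NotTrainedError(RuntimeError):
    """Prediction was requested from an untrained model."""


@dataclass(frozen=True)
class FusedFeature:
    protein_id: str
    values: np.ndarray
    topo_dim: int = 128

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PairExample:
    m: str
    n: str
    label: int

    def __post_init__(self) -> None:
        if self.m == self.n:
            raise ValueError(f"self-pair {self.m!r}")
        if self.label not in (0, 1):
            raise ValueError(f"pair label must be 0/1, got {self.label!r}")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.m, self.n))


@dataclass(frozen=True)
class FamilyExample:
    protein_id: str
    family: str


def fuse(topo: np.ndarray, seq: np.ndarray, protein_id: str = "",
         topo_missing: bool = False) -> FusedFeature:
    """Concatenate [topological | deep-sequence] vectors.

    ``topo_missing`` marks a cold-start node whose topological block was
    zero-substituted; it is logged but the layout is unchanged.
    """
    topo = np.asarray(topo, dtype=float)
    seq = np.asarray(seq, dtype=float)
    if topo.ndim != 1 or seq.ndim != 1:
        raise ValueError("fuse expects two 1-D vectors")
    if topo_missing:
        logger.info("protein %s: fused with zero topological block", protein_id)
    return FusedFeature(protein_id, np.concatenate([topo, seq]), topo_dim=len(topo))


def binary_cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean BCE with y_hat clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def categorical_cross_entropy(y_onehot: np.ndarray, p: np.ndarray) -> float:
    """Mean categorical CE over rows, probabilities clipped."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0)
    return float(-np.mean(np.sum(np.asarray(y_onehot, dtype=float) * np.log(p), axis=1)))


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class PpiHeadConfig:
    branch_hidden: tuple[int, ...] = (64,)
    merge_hidden: int = 64
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 0.01
    seed: int = 0
    symmetrize: bool = True  # augment each pair with its swap
    standardize: bool = True  # z-score inputs on training stats


@dataclass
class PpiModel:
    config: PpiHeadConfig
    input_dim: int
    params: dict[str, np.ndarray]
    layout: str = "topo|seq"
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if "mu" in self.params:
            return (x - self.params["mu"]) / self.params["sd"]
        return x

    def _forward(self, xm: np.ndarray, xn: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        hm = _relu(xm @ p["wm0"] + p["bm0"])
        hn = _relu(xn @ p["wn0"] + p["bn0"])
        h = np.concatenate([hm, hn], axis=1)
        g = _relu(h @ p["wf"] + p["bf"])
        z = g @ p["wo"] + p["bo"]
        prob = 1.0 / (1.0 + np.exp(-z[:, 0]))
        return {"hm": hm, "hn": hn, "h": h, "g": g, "prob": prob}

    def predict_proba(self, m_feat: np.ndarray, n_feat: np.ndarray) -> np.ndarray:
        """Interaction probabilities for rows of (m_feat, n_feat)."""
        if not self.trained:
            raise NotTrainedError("PPI head has not been trained")
        xm = np.atleast_2d(np.asarray(m_feat, dtype=float))
        xn = np.atleast_2d(np.asarray(n_feat, dtype=float))
        if xm.shape[1] != self.input_dim or xn.shape[1] != self.input_dim:
            raise ValueError(f"expected feature width {self.input_dim}")
        xm, xn = self._standardize(xm), self._standardize(xn)
        prob = self._forward(xm, xn)["prob"]
        if self.config.symmetrize:
            prob = 0.5 * (prob + self._forward(xn, xm)["prob"])
        return prob


def _pair_matrix(pairs, features):
    missing = [pid for p in pairs for pid in (p.m, p.n) if pid not in features]
    if missing:
        raise KeyError(f"pairs reference proteins without features: {sorted(set(missing))[:5]}")
    xm = np.stack([np.asarray(features[p.m].values, dtype=float) for p in pairs])
    xn = np.stack([np.asarray(features[p.n].values, dtype=float) for p in pairs])
    y = np.array([p.label for p in pairs], dtype=float)
    return xm, xn, y


def train_ppi_classifier(
    pairs: list[PairExample],
    features: dict[str, FusedFeature],
    cfg: PpiHeadConfig | None = None,
) -> PpiModel:
    """Fit the twin-branch interaction head by SGD on binary cross entropy."""
    cfg = cfg or PpiHeadConfig()
    if len({p.label for p in pairs}) < 2:
        raise ValueError("training set must contain both interaction classes")
    xm, xn, y = _pair_matrix(pairs, features)
    if cfg.symmetrize:
        xm, xn = np.concatenate([xm, xn]), np.concatenate([xn, xm])
        y = np.concatenate([y, y])
    d = xm.shape[1]
    if cfg.standardize:
        stacked = np.concatenate([xm, xn])
        mu = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        sd[sd == 0] = 1.0
        xm, xn = (xm - mu) / sd, (xn - mu) / sd
    rng = np.random.default_rng(cfg.seed)
    (bh,) = cfg.branch_hidden  # single branch hidden layer at default depth
    mh = cfg.merge_hidden

    def init(fan_in, fan_out):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))

    params = {
        "wm0": init(d, bh), "bm0": np.zeros(bh),
        "wn0": init(d, bh), "bn0": np.zeros(bh),
        "wf": init(2 * bh, mh), "bf": np.zeros(mh),
        "wo": init(mh, 1), "bo": np.zeros(1),
    }
    if cfg.standardize:
        params["mu"], params["sd"] = mu, sd
    model = PpiModel(cfg, d, params)
    n = len(y)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo: lo + cfg.batch_size]
            bxm, bxn, by = xm[idx], xn[idx], y[idx]
            f = model._forward(bxm, bxn)
            prob = np.clip(f["prob"], _EPS, 1.0 - _EPS)
            epoch_loss += binary_cross_entropy(by, prob) * len(idx)
            dz = (prob - by)[:, None] / len(idx)  # dBCE/dz for sigmoid output
            gwo = f["g"].T @ dz
            gbo = dz.sum(axis=0)
            dg = dz @ params["wo"].T * (f["g"] > 0)
            gwf = f["h"].T @ dg
            gbf = dg.sum(axis=0)
            dh = dg @ params["wf"].T
            dhm, dhn = dh[:, :bh] * (f["hm"] > 0), dh[:, bh:] * (f["hn"] > 0)
            lr = cfg.learning_rate
            params["wm0"] -= lr * (bxm.T @ dhm)
            params["bm0"] -= lr * dhm.sum(axis=0)
            params["wn0"] -= lr * (bxn.T @ dhn)
            params["bn0"] -= lr * dhn.sum(axis=0)
            params["wf"] -= lr * gwf
            params["bf"] -= lr * gbf
            params["wo"] -= lr * gwo
            params["bo"] -= lr * gbo
        model.loss_history.append(epoch_loss / n)
    model.trained = True
    return model


def predict_interaction(
    model: PpiModel, m_feat: np.ndarray, n_feat: np.ndarray,
    threshold: float = 0.5,
) -> tuple[float, int]:
    """(probability, hard label at ``threshold``) for one protein pair."""
    prob = float(model.predict_proba(m_feat, n_feat)[0])
    return prob, int(prob >= threshold)


@dataclass(frozen=True)
class FamilyHeadConfig:
    hidden: tuple[int, int] = (128, 64)
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 0.01
    dropout: float = 0.5
    seed: int = 0
    standardize: bool = True  # z-score inputs on training stats


@dataclass
class FamilyModel:
    config: FamilyHeadConfig
    input_dim: int
    classes: tuple[str, ...]
    params: dict[str, np.ndarray]
    layout: str = "topo|seq"
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if "mu" in self.params:
            return (x - self.params["mu"]) / self.params["sd"]
        return x

    def _forward(self, x, rng=None):
        p = self.params
        h1 = _relu(x @ p["w1"] + p["b1"])
        h2_in = h1
        masks = {}
        if rng is not None and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            masks["m1"] = (rng.random(h1.shape) < keep) / keep
            h2_in = h1 * masks["m1"]
        h2 = _relu(h2_in @ p["w2"] + p["b2"])
        h3_in = h2
        if rng is not None and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            masks["m2"] = (rng.random(h2.shape) < keep) / keep
            h3_in = h2 * masks["m2"]
        probs = _softmax(h3_in @ p["w3"] + p["b3"])
        return {"h1": h1, "h1d": h2_in, "h2": h2, "h2d": h3_in, "probs": probs,
                "masks": masks}

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise NotTrainedError("family head has not been trained")
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected feature width {self.input_dim}")
        return self._forward(self._standardize(x))["probs"]

    def predict(self, x: np.ndarray) -> list[str]:
        probs = self.predict_proba(x)
        return [self.classes[i] for i in probs.argmax(axis=1)]


def train_family_classifier(
    examples: list[FamilyExample],
    features: dict[str, FusedFeature],
    cfg: FamilyHeadConfig | None = None,
) -> FamilyModel:
    """Fit the multi-family softmax DNN by SGD on categorical cross entropy."""
    cfg = cfg or FamilyHeadConfig()
    counts = Counter(e.family for e in examples)
    if len(counts) < 2:
        raise ValueError("need at least 2 family classes")
    singletons = [f for f, c in counts.items() if c < 2]
    if singletons:
        raise ValueError(
            f"families with a single example cannot be trained/stratified: "
            f"{sorted(singletons)}; filter them out first (filter_families)"
        )
    classes = tuple(sorted(counts))
    cls_idx = {c: i for i, c in enumerate(classes)}
    x = np.stack([np.asarray(features[e.protein_id].values, dtype=float) for e in examples])
    y = np.array([cls_idx[e.family] for e in examples])
    n, d = x.shape
    if cfg.standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    c = len(classes)
    rng = np.random.default_rng(cfg.seed)
    h1, h2 = cfg.hidden

    def init(fan_in, fan_out):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))

    params = {
        "w1": init(d, h1), "b1": np.zeros(h1),
        "w2": init(h1, h2), "b2": np.zeros(h2),
        "w3": init(h2, c), "b3": np.zeros(c),
    }
    if cfg.standardize:
        params["mu"], params["sd"] = mu, sd
    model = FamilyModel(cfg, d, classes, params)
    onehot = np.eye(c)[y]
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo: lo + cfg.batch_size]
            bx, byoh = x[idx], onehot[idx]
            f = model._forward(bx, rng=rng)
            epoch_loss += categorical_cross_entropy(byoh, f["probs"]) * len(idx)
            dz3 = (f["probs"] - byoh) / len(idx)
            gw3 = f["h2d"].T @ dz3
            gb3 = dz3.sum(axis=0)
            dh2 = dz3 @ params["w3"].T
            if f["masks"]:
                dh2 = dh2 * f["masks"]["m2"]
            dh2 = dh2 * (f["h2"] > 0)
            gw2 = f["h1d"].T @ dh2
            gb2 = dh2.sum(axis=0)
            dh1 = dh2 @ params["w2"].T
            if f["masks"]:
                dh1 = dh1 * f["masks"]["m1"]
            dh1 = dh1 * (f["h1"] > 0)
            lr = cfg.learning_rate
            params["w3"] -= lr * gw3
            params["b3"] -= lr * gb3
            params["w2"] -= lr * gw2
            params["b2"] -= lr * gb2
            params["w1"] -= lr * (bx.T @ dh1)
            params["b1"] -= lr * dh1.sum(axis=0)
        model.loss_history.append(epoch_loss / n)
    model.trained = True
    return model


def filter_families(
    examples: list[FamilyExample], min_count: int = 15
) -> tuple[list[FamilyExample], tuple[str, ...]]:
    """Keep only families with strictly more than ``min_count`` examples."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = Counter(e.family for e in examples)
    kept = {f for f, n in counts.items() if n > min_count}
    filtered = [e for e in examples if e.family in kept]
    logger.info("family filter >%d: kept %d/%d families (%d/%d examples)",
                min_count, len(kept), len(counts), len(filtered), len(examples))
    return filtered, tuple(sorted(kept))


# ---------------------------------------------------------------------------
# Checkpoints and the pair/family/prediction TSV dialects.
# ---------------------------------------------------------------------------

def _save_params(path, kind, meta, params):
    payload = {"kind": kind, **meta, "params": {k: v.tolist() for k, v in params.items()}}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def save_ppi_model(path, model: PpiModel) -> None:
    meta = {
        "config": model.config.__dict__ | {"branch_hidden": list(model.config.branch_hidden)},
        "input_dim": model.input_dim, "layout": model.layout,
        "loss_history": model.loss_history,
    }
    _save_params(path, "ppi", meta, model.params)


def load_ppi_model(path) -> PpiModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload["kind"] != "ppi":
        raise ValueError(f"{path}: not a PPI model checkpoint")
    cfg_d = dict(payload["config"])
    cfg_d["branch_hidden"] = tuple(cfg_d["branch_hidden"])
    model = PpiModel(
        PpiHeadConfig(**cfg_d), payload["input_dim"],
        {k: np.array(v) for k, v in payload["params"].items()},
        layout=payload["layout"], trained=True,
        loss_history=payload["loss_history"],
    )
    return model


def save_family_model(path, model: FamilyModel) -> None:
    meta = {
        "config": model.config.__dict__ | {"hidden": list(model.config.hidden)},
        "input_dim": model.input_dim, "layout": model.layout,
        "classes": list(model.classes), "loss_history": model.loss_history,
    }
    _save_params(path, "family", meta, model.params)


def load_family_model(path) -> FamilyModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload["kind"] != "family":
        raise ValueError(f"{path}: not a family model checkpoint")
    cfg_d = dict(payload["config"])
    cfg_d["hidden"] = tuple(cfg_d["hidden"])
    return FamilyModel(
        FamilyHeadConfig(**cfg_d), payload["input_dim"], tuple(payload["classes"]),
        {k: np.array(v) for k, v in payload["params"].items()},
        layout=payload["layout"], trained=True,
        loss_history=payload["loss_history"],
    )


def read_pairs(path) -> list[PairExample]:
    """TSV ``id_m  id_n  label``; '#' comment lines skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m, n, label = line.split("\t")
            out.append(PairExample(m, n, int(label)))
    return out


def write_pairs(path, pairs: list[PairExample]) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.m}\t{p.n}\t{p.label}\n")


def read_families(path) -> list[FamilyExample]:
    """TSV ``id  family``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, fam = line.split("\t")
            out.append(FamilyExample(pid, fam))
    return out


def write_families(path, examples: list[FamilyExample]) -> None:
    with open(path, "w") as fh:
        for e in examples:
            fh.write(f"{e.protein_id}\t{e.family}\n")


def write_predictions(path, rows: list[tuple[str, str, float]]) -> None:
    """TSV ``id_m  id_n  probability``."""
    with open(path, "w") as fh:
        for m, n, prob in rows:
            fh.write(f"{m}\t{n}\t{prob!r}\n")
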