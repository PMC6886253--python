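"""End-to-end pipeline: encode -> walks -> embed -> SAE -> fuse -> heads -> metrics.

``PipelineConfig`` carries every tunable with its published default
(batch 64, SGD lr 0.01, SAE 256-128-64-128-256 for 50 epochs, CBOW
window 1 / dim 128 / 10 epochs, walk fanout 4 / length 10, family DNN
200 epochs with dropout 0.5, QSO w=0.1 / nlag=30, 80/20 split, family
min-count 15). Stage seeds are derived deterministically from one master
seed so each stage is independently reproducible.

Walk generation consumes only training-split positive edges; test pairs
stay held out. Proteins that only appear in test pairs are fused with a
zero topological block (cold start, logged).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import cbow as cbow_mod
from . import fusion as fusion_mod
from . import sae as sae_mod
from .dataset import LocationTable, generate_negatives, split_dataset, verify_negatives
from .evaluation import ConfusionCounts, auc_roc, binary_metrics, f1_scores
from .ppi_graph import MetapathConfig, PPINetwork, generate_metapaths, load_edge_list, write_walks
from .seq_features import (
    EncoderConfigs,
    QsoConfig,
    encode_all,
    read_fasta,
    write_feature_table,
)

logger = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())]).generate_state(1)[0]
    )


@dataclass
class PipelineConfig:
    batch_size: int = 64
    learning_rate: float = 0.01
    sae_layers: tuple[int, ...] = (256, 128, 64, 128, 256)
    optimizer: str = "sgd"
    window: int = 1
    embedding_dim: int = 128
    neighbor_size: int = 4
    walk_length: int = 10
    cbow_epochs: int = 10
    cbow_learning_rate: float = 0.025
    cbow_mode: str = "full"
    sae_epochs: int = 50
    ppi_epochs: int = 200
    dnn_epochs: int = 200
    dropout: float = 0.5
    qso_weight: float = 0.1
    qso_nlag: int = 30
    split_ratio: float = 0.8
    family_min_count: int = 15
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "sae_layers" in d:
            d["sae_layers"] = tuple(d["sae_layers"])
        cfg = cls(**d)
        for key, value in d.items():
            default = cls.__dataclass_fields__[key].default
            if value != default:
                logger.info("config override: %s=%r (default %r)", key, value, default)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sae_layers"] = list(self.sae_layers)
        return d


@dataclass
class PipelineInputs:
    fasta: str | Path
    edges: str | Path | None = None
    positives: str | Path | None = None  # pre-built positive pair TSV
    locations: str | Path | None = None
    families: str | Path | None = None


@dataclass
class PipelineResult:
    out_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs, out_dir) -> PipelineResult:
    """Execute every stage in order, writing all intermediates + a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out)
    art = result.artifacts
    stage = "setup"
    try:
        # ---- sequence features -------------------------------------------
        stage = "encode"
        records = read_fasta(inputs.fasta)
        enc_cfg = EncoderConfigs(qso=QsoConfig(weight=config.qso_weight, nlag=config.qso_nlag))
        vectors = [encode_all(r, enc_cfg) for r in records]
        art["features"] = out / "features.tsv"
        write_feature_table(art["features"], [r.id for r in records], vectors)
        feat = {r.id: v.values for r, v in zip(records, vectors)}

        # ---- positive pairs ----------------------------------------------
        stage = "pairs"
        if inputs.positives is not None:
            positives = fusion_mod.read_pairs(inputs.positives)
        elif inputs.edges is not None:
            net_all, stats = load_edge_list(inputs.edges)
            logger.info("edge list: %s", stats)
            positives = [
                fusion_mod.PairExample(a, b, 1)
                for a, b in sorted(tuple(sorted(e)) for e in net_all.edges)
            ]
        else:
            raise ValueError("need either edges or positives input")

        pairs = positives
        if inputs.locations is not None:
            locs = LocationTable.read(inputs.locations)
            negatives = generate_negatives(
                positives, locs, seed=stage_seed(config.seed, "negatives")
            )
            verify_negatives(negatives, positives, locs)
            pairs = positives + negatives
        train_pairs, test_pairs = split_dataset(
            pairs, config.split_ratio, seed=stage_seed(config.seed, "split")
        )
        art["train_pairs"] = out / "train_pairs.tsv"
        art["test_pairs"] = out / "test_pairs.tsv"
        fusion_mod.write_pairs(art["train_pairs"], train_pairs)
        fusion_mod.write_pairs(art["test_pairs"], test_pairs)

        # ---- walks over training-split positive edges --------------------
        stage = "walks"
        train_net = PPINetwork.from_pairs(
            (p.m, p.n) for p in train_pairs if p.label == 1
        )
        walks = generate_metapaths(
            train_net,
            MetapathConfig(
                length=config.walk_length,
                neighbor_size=config.neighbor_size,
                seed=stage_seed(config.seed, "walks"),
            ),
        )
        art["walks"] = out / "walks.txt"
        write_walks(art["walks"], walks)

        # ---- CBOW embeddings ---------------------------------------------
        stage = "embed"
        emb = cbow_mod.train_cbow(
            walks,
            cbow_mod.CbowConfig(
                dim=config.embedding_dim,
                window=config.window,
                epochs=config.cbow_epochs,
                learning_rate=config.cbow_learning_rate,
                softmax_mode=config.cbow_mode,
                seed=stage_seed(config.seed, "cbow"),
            ),
        )
        art["embeddings"] = out / "embeddings.txt"
        cbow_mod.write_embeddings(art["embeddings"], emb)

        # ---- SAE deep sequence features ----------------------------------
        stage = "sae"
        ids = [r.id for r in records]
        x = np.stack([feat[p] for p in ids])
        sae_model = sae_mod.train_sae(
            x,
            sae_mod.SaeConfig(
                layer_sizes=config.sae_layers,
                epochs=config.sae_epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                seed=stage_seed(config.seed, "sae"),
            ),
        )
        art["sae_model"] = out / "sae_model.json"
        sae_mod.save_sae(art["sae_model"], sae_model)
        art["sae_history"] = out / "sae_history.csv"
        with open(art["sae_history"], "w") as fh:
            fh.write("epoch,train_mse,val_mse\n")
            for i, tr in enumerate(sae_model.history["train"]):
                val = sae_model.history["val"][i] if sae_model.history["val"] else ""
                fh.write(f"{i},{tr!r},{val!r}\n")
        latents = sae_model.encode(x)

        # ---- late fusion --------------------------------------------------
        stage = "fuse"
        fused: dict[str, fusion_mod.FusedFeature] = {}
        for i, pid in enumerate(ids):
            topo = emb.get(pid, cold_start="zero")
            fused[pid] = fusion_mod.fuse(
                topo, latents[i], protein_id=pid, topo_missing=pid not in emb
            )
        art["fused"] = out / "fused.tsv"
        with open(art["fused"], "w") as fh:
            dim = config.embedding_dim + config.sae_layers[len(config.sae_layers) // 2]
            fh.write("id\t" + "\t".join(f"f{i}" for i in range(dim)) + "\n")
            for pid in ids:
                fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in fused[pid].values) + "\n")

        # ---- interaction head --------------------------------------------
        stage = "train-ppi"
        ppi_model = fusion_mod.train_ppi_classifier(
            train_pairs,
            fused,
            fusion_mod.PpiHeadConfig(
                epochs=config.ppi_epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                seed=stage_seed(config.seed, "ppi-head"),
            ),
        )
        art["ppi_model"] = out / "ppi_model.json"
        fusion_mod.save_ppi_model(art["ppi_model"], ppi_model)

        stage = "evaluate-ppi"
        xm = np.stack([fused[p.m].values for p in test_pairs])
        xn = np.stack([fused[p.n].values for p in test_pairs])
        y = np.array([p.label for p in test_pairs])
        scores = ppi_model.predict_proba(xm, xn)
        art["ppi_predictions"] = out / "ppi_predictions.tsv"
        fusion_mod.write_predictions(
            art["ppi_predictions"],
            [(p.m, p.n, float(s)) for p, s in zip(test_pairs, scores)],
        )
        report = binary_metrics(ConfusionCounts.from_predictions(y, scores >= 0.5))
        report.auc_roc = auc_roc(y, scores)
        result.metrics["ppi"] = json.loads(report.to_json())
        art["ppi_metrics"] = out / "ppi_metrics.json"
        report.to_json(art["ppi_metrics"])

        # ---- family head --------------------------------------------------
        if inputs.families is not None:
            stage = "train-family"
            fam_examples = fusion_mod.read_families(inputs.families)
            fam_examples = [e for e in fam_examples if e.protein_id in fused]
            kept, retained = fusion_mod.filter_families(fam_examples, config.family_min_count)
            fam_train, fam_test = split_dataset(
                kept, config.split_ratio, seed=stage_seed(config.seed, "family-split")
            )
            fam_model = fusion_mod.train_family_classifier(
                fam_train,
                fused,
                fusion_mod.FamilyHeadConfig(
                    epochs=config.dnn_epochs,
                    batch_size=config.batch_size,
                    learning_rate=config.learning_rate,
                    dropout=config.dropout,
                    seed=stage_seed(config.seed, "family-head"),
                ),
            )
            art["family_model"] = out / "family_model.json"
            fusion_mod.save_family_model(art["family_model"], fam_model)

            stage = "evaluate-family"
            xt = np.stack([fused[e.protein_id].values for e in fam_test])
            y_true = [e.family for e in fam_test]
            y_pred = fam_model.predict(xt)
            result.metrics["family"] = {
                "micro_f1": f1_scores(y_true, y_pred, "micro"),
                "macro_f1": f1_scores(y_true, y_pred, "macro"),
                "retained_families": len(retained),
            }
            art["family_metrics"] = out / "family_metrics.json"
            with open(art["family_metrics"], "w") as fh:
                json.dump(result.metrics["family"], fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- manifest ---------------------------------------------------------
    resolved = out / "config.json"
    with open(resolved, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    art["config"] = resolved
    result.manifest = {
        "config": config.to_dict(),
        "hashes": {name: _sha256(path) for name, path in sorted(art.items())},
        "metrics": result.metrics,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    art["manifest"] = out / "manifest.json"
    return result
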