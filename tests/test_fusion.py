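import math

import numpy as np
import pytest

from ppimm.evaluation import auc_roc
from ppimm.fusion import (
    FamilyExample,
    FamilyHeadConfig,
    FamilyModel,
    FusedFeature,
    NotTrainedError,
    PairExample,
    PpiHeadConfig,
    PpiModel,
    binary_cross_entropy,
    categorical_cross_entropy,
    filter_families,
    fuse,
    load_family_model,
    load_ppi_model,
    predict_interaction,
    read_families,
    read_pairs,
    save_family_model,
    save_ppi_model,
    train_family_classifier,
    train_ppi_classifier,
    write_families,
    write_pairs,
)


def blob_pair_fixture(rng, n_pairs=600, dim=24):
    """Two Gaussian blobs; same-blob pairs interact, cross-blob pairs do not."""
    centers = {0: np.full(dim, 2.0), 1: np.full(dim, -2.0)}
    features, pairs = {}, []
    counter = 0

    def new_protein(blob):
        nonlocal counter
        pid = f"p{counter}"
        counter += 1
        features[pid] = FusedFeature(pid, centers[blob] + rng.normal(size=dim))
        return pid

    for i in range(n_pairs):
        if i % 2 == 0:
            blob = int(rng.integers(2))
            pairs.append(PairExample(new_protein(blob), new_protein(blob), 1))
        else:
            pairs.append(PairExample(new_protein(0), new_protein(1), 0))
    return pairs, features


class TestFuse:
    def test_width_192(self, rng):
        f = fuse(rng.normal(size=128), rng.normal(size=64))
        assert len(f) == 192

    def test_zero_vectors(self):
        f = fuse(np.zeros(128), np.zeros(64))
        assert (f.values == 0).all() and len(f) == 192

    def test_block_recovery(self, rng):
        topo, seq = rng.normal(size=128), rng.normal(size=64)
        f = fuse(topo, seq)
        np.testing.assert_array_equal(f.values[:128], topo)
        np.testing.assert_array_equal(f.values[128:], seq)

    def test_width_conservation_arbitrary_dims(self, rng):
        for dt, ds in [(5, 3), (1, 1), (200, 17)]:
            f = fuse(rng.normal(size=dt), rng.normal(size=ds))
            assert len(f) == dt + ds and f.topo_dim == dt

    def test_shape_error(self, rng):
        with pytest.raises(ValueError):
            fuse(rng.normal(size=(2, 4)), rng.normal(size=3))


class TestLosses:
    def test_bce_of_half_is_ln2(self):
        y = np.array([0, 1, 0, 1])
        assert abs(binary_cross_entropy(y, np.full(4, 0.5)) - math.log(2)) < 1e-12

    def test_bce_hand_computed_three_examples(self):
        y = [1, 0, 1]
        p = [0.9, 0.2, 0.6]
        expected = -(math.log(0.9) + math.log(0.8) + math.log(0.6)) / 3
        assert abs(binary_cross_entropy(y, p) - expected) < 1e-10

    def test_cce_one_hot_correct_is_zero(self):
        onehot = np.eye(3)
        assert categorical_cross_entropy(onehot, onehot) == 0.0

    def test_cce_hand_computed_three_examples(self):
        y = np.eye(3)
        p = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.25, 0.25, 0.5]])
        expected = -(math.log(0.7) + math.log(0.8) + math.log(0.5)) / 3
        assert abs(categorical_cross_entropy(y, p) - expected) < 1e-10


class TestPairExample:
    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            PairExample("a", "a", 1)

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            PairExample("a", "b", 2)


class TestPpiHead:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(5)
        pairs, features = blob_pair_fixture(rng)
        # verify separability with a linear baseline before asserting on the net
        from sklearn.linear_model import LogisticRegression

        x = np.stack(
            [np.concatenate([features[p.m].values, features[p.n].values]) for p in pairs]
        )
        y = [p.label for p in pairs]
        assert LogisticRegression(max_iter=1000).fit(x, y).score(x, y) > 0.95
        train, test = pairs[:480], pairs[480:]
        model = train_ppi_classifier(
            train, features, PpiHeadConfig(epochs=80, seed=0)
        )
        return model, test, features

    def test_holdout_accuracy(self, separable):
        model, test, features = separable
        xm = np.stack([features[p.m].values for p in test])
        xn = np.stack([features[p.n].values for p in test])
        y = np.array([p.label for p in test])
        acc = ((model.predict_proba(xm, xn) >= 0.5) == y).mean()
        assert acc > 0.95

    def test_holdout_auc(self, separable):
        model, test, features = separable
        xm = np.stack([features[p.m].values for p in test])
        xn = np.stack([features[p.n].values for p in test])
        y = np.array([p.label for p in test])
        assert auc_roc(y, model.predict_proba(xm, xn)) > 0.95

    def test_probability_range_and_determinism(self, separable, rng):
        model, _, _ = separable
        a, b = rng.normal(size=24), rng.normal(size=24)
        prob, label = predict_interaction(model, a, b)
        assert 0.0 <= prob <= 1.0 and label in (0, 1)
        assert prob == predict_interaction(model, a, b)[0]

    def test_swap_symmetry(self, separable, rng):
        model, _, _ = separable
        a, b = rng.normal(size=24), rng.normal(size=24)
        assert abs(
            predict_interaction(model, a, b)[0] - predict_interaction(model, b, a)[0]
        ) < 1e-12

    def test_single_class_rejected(self, rng):
        pairs, features = blob_pair_fixture(rng, 10)
        only_pos = [p for p in pairs if p.label == 1]
        with pytest.raises(ValueError):
            train_ppi_classifier(only_pos, features)

    def test_untrained_predict_rejected(self):
        model = PpiModel(PpiHeadConfig(), 4, {})
        with pytest.raises(NotTrainedError):
            model.predict_proba(np.zeros((1, 4)), np.zeros((1, 4)))

    def test_missing_feature_rejected(self, rng):
        pairs, features = blob_pair_fixture(rng, 4)
        features.pop(pairs[0].m)
        with pytest.raises(KeyError):
            train_ppi_classifier(pairs, features)

    def test_overfits_memorization_fixture(self, rng):
        pairs, features = blob_pair_fixture(rng, 50, dim=8)
        # scramble labels so only memorization can fit
        pairs = [
            PairExample(p.m, p.n, int(rng.integers(2)))
            for p in pairs
        ]
        if len({p.label for p in pairs}) < 2:
            pairs[0] = PairExample(pairs[0].m, pairs[0].n, 1 - pairs[0].label)
        model = train_ppi_classifier(
            pairs, features, PpiHeadConfig(epochs=600, learning_rate=0.05,
                                           symmetrize=False, seed=1)
        )
        xm = np.stack([features[p.m].values for p in pairs])
        xn = np.stack([features[p.n].values for p in pairs])
        y = np.array([p.label for p in pairs])
        acc = ((model._forward((xm - model.params["mu"]) / model.params["sd"],
                               (xn - model.params["mu"]) / model.params["sd"])["prob"] >= 0.5) == y).mean()
        assert acc >= 0.98


class TestFamilyHead:
    @pytest.fixture(scope="class")
    def blobs(self):
        rng = np.random.default_rng(2)
        dim = 16
        features, examples = {}, []
        for c in range(5):
            center = np.zeros(dim)
            center[3 * c: 3 * c + 3] = 4.0
            for i in range(200):
                pid = f"c{c}_{i}"
                features[pid] = FusedFeature(pid, center + rng.normal(size=dim))
                examples.append(FamilyExample(pid, f"FAM{c}"))
        rng.shuffle(examples)
        return examples, features

    def test_softmax_rows_sum_to_one(self, blobs):
        examples, features = blobs
        model = train_family_classifier(
            examples[:100], features, FamilyHeadConfig(epochs=5, seed=0)
        )
        probs = model.predict_proba(np.stack([features[e.protein_id].values for e in examples[:20]]))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_holdout_micro_f1(self, blobs):
        from ppimm.evaluation import f1_scores

        examples, features = blobs
        train, test = examples[:800], examples[800:]
        model = train_family_classifier(train, features, FamilyHeadConfig(epochs=60, seed=0))
        preds = model.predict(np.stack([features[e.protein_id].values for e in test]))
        assert f1_scores([e.family for e in test], preds, "micro") > 0.9

    def test_overfits_memorization_fixture(self, rng):
        dim = 8
        features = {f"p{i}": FusedFeature(f"p{i}", rng.normal(size=dim)) for i in range(50)}
        examples = [
            FamilyExample(f"p{i}", f"F{i % 2}") for i in range(50)
        ]
        model = train_family_classifier(
            examples, features,
            FamilyHeadConfig(epochs=800, learning_rate=0.05, dropout=0.0, seed=0),
        )
        preds = model.predict(np.stack([features[e.protein_id].values for e in examples]))
        acc = np.mean([p == e.family for p, e in zip(preds, examples)])
        assert acc >= 0.98

    def test_single_class_rejected(self, rng):
        features = {f"p{i}": FusedFeature(f"p{i}", rng.normal(size=4)) for i in range(4)}
        with pytest.raises(ValueError):
            train_family_classifier(
                [FamilyExample(f"p{i}", "F0") for i in range(4)], features
            )

    def test_singleton_family_rejected(self, rng):
        features = {f"p{i}": FusedFeature(f"p{i}", rng.normal(size=4)) for i in range(5)}
        examples = [FamilyExample(f"p{i}", "F0") for i in range(4)]
        examples.append(FamilyExample("p4", "F1"))
        with pytest.raises(ValueError, match="single example"):
            train_family_classifier(examples, features)

    def test_untrained_predict_rejected(self):
        model = FamilyModel(FamilyHeadConfig(), 4, ("a", "b"), {})
        with pytest.raises(NotTrainedError):
            model.predict(np.zeros((1, 4)))


class TestFilterFamilies:
    def make(self, sizes):
        out = []
        for f, size in enumerate(sizes):
            out.extend(FamilyExample(f"p{f}_{i}", f"F{f}") for i in range(size))
        return out

    def test_strict_threshold(self):
        examples = self.make([16, 15, 3])
        kept, families = filter_families(examples, 15)
        assert families == ("F0",)
        assert len(kept) == 16

    def test_zero_min_count_keeps_all(self):
        examples = self.make([2, 1])
        kept, families = filter_families(examples, 0)
        assert kept == examples
        assert set(families) == {"F0", "F1"}

    def test_count_conservation(self):
        examples = self.make([20, 18, 5, 16])
        kept, families = filter_families(examples, 15)
        sizes = {f: sum(e.family == f for e in examples) for f in families}
        assert len(kept) == sum(sizes.values()) == 20 + 18 + 16


class TestCheckpoints:
    def test_ppi_roundtrip(self, tmp_path, rng):
        pairs, features = blob_pair_fixture(rng, 40, dim=6)
        model = train_ppi_classifier(pairs, features, PpiHeadConfig(epochs=5, seed=0))
        path = tmp_path / "ppi.json"
        save_ppi_model(path, model)
        loaded = load_ppi_model(path)
        a, b = rng.normal(size=6), rng.normal(size=6)
        assert loaded.layout == "topo|seq"
        assert predict_interaction(loaded, a, b) == predict_interaction(model, a, b)

    def test_family_roundtrip(self, tmp_path, rng):
        features = {f"p{i}": FusedFeature(f"p{i}", rng.normal(size=6)) for i in range(20)}
        examples = [FamilyExample(f"p{i}", f"F{i % 2}") for i in range(20)]
        model = train_family_classifier(examples, features, FamilyHeadConfig(epochs=5, seed=0))
        path = tmp_path / "fam.json"
        save_family_model(path, model)
        loaded = load_family_model(path)
        x = rng.normal(size=(3, 6))
        np.testing.assert_array_equal(loaded.predict_proba(x), model.predict_proba(x))
        assert loaded.classes == model.classes


class TestTsvDialects:
    def test_pairs_roundtrip(self, tmp_path):
        pairs = [PairExample("a", "b", 1), PairExample("c", "d", 0)]
        path = tmp_path / "pairs.tsv"
        write_pairs(path, pairs)
        assert read_pairs(path) == pairs

    def test_families_roundtrip(self, tmp_path):
        examples = [FamilyExample("a", "F0"), FamilyExample("b", "F1")]
        path = tmp_path / "fam.tsv"
        write_families(path, examples)
        assert read_families(path) == examples
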