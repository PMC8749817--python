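"""Classifier: stratified split, head architecture, training protocol."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from manoflow import classifier
from manoflow.classifier import (
    ConfigurationError,
    DatasetSplit,
    ModelConfig,
    build_classifier,
    stratified_split,
    train,
)

SMALL_SHAPE = (63, 63, 3)


def small_config(**kw):
    """Config with a reduced input raster so unit tests stay fast."""
    kw.setdefault("input_shape", SMALL_SHAPE)
    kw.setdefault("epochs", 5)
    return ModelConfig(**kw)


def constant_tensor(value, shape=SMALL_SHAPE):
    return np.full(shape, value, dtype=np.float32)


class TestStratifiedSplit:
    def test_reproduces_printed_cohort_counts(self):
        """A 939-high / 140-normal cohort splits 657/98, 140/21, 142/21."""
        labels = ["high"] * 939 + ["normal"] * 140
        split = stratified_split(list(range(len(labels))), labels, seed=0)

        def counts(part):
            return (
                sum(1 for _, l in part if l == "high"),
                sum(1 for _, l in part if l == "normal"),
            )

        assert counts(split.train) == (657, 98)
        assert counts(split.test) == (140, 21)
        assert counts(split.validation) == (142, 21)

    def test_floor_rule_on_ten_items(self):
        split = stratified_split(list(range(10)), ["a"] * 10, seed=1)
        assert (len(split.train), len(split.test), len(split.validation)) == (7, 1, 2)

    def test_same_seed_identical_membership(self):
        labels = ["x"] * 17 + ["y"] * 9
        items = list(range(26))
        s1 = stratified_split(items, labels, seed=5)
        s2 = stratified_split(items, labels, seed=5)
        assert s1.train == s2.train and s1.validation == s2.validation

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n_a=st.integers(1, 1000), n_b=st.integers(1, 1000), seed=st.integers(0, 1000)
    )
    def test_partition_invariants(self, n_a, n_b, seed):
        """Parts are disjoint, exhaustive, and follow per-class floor counts."""
        labels = ["a"] * n_a + ["b"] * n_b
        items = list(range(n_a + n_b))
        split = stratified_split(items, labels, seed=seed)
        seen = [i for part in (split.train, split.test, split.validation) for i, _ in part]
        assert sorted(seen) == items  # exhaustive and pairwise disjoint
        for cls, n in (("a", n_a), ("b", n_b)):
            n_train = sum(1 for _, l in split.train if l == cls)
            n_test = sum(1 for _, l in split.test if l == cls)
            assert n_train == int(np.floor(0.70 * n))
            assert n_test == int(np.floor(0.15 * n))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            stratified_split([1, 2], ["a"], seed=0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            stratified_split([], [], seed=0)


class TestBuildClassifier:
    def test_head_has_exactly_two_output_units(self):
        model = build_classifier(small_config())
        assert model.W.shape[1] == 2 and model.b.shape == (2,)

    def test_seeded_init_is_reproducible(self):
        m1 = build_classifier(small_config(seed=4))
        m2 = build_classifier(small_config(seed=4))
        assert np.array_equal(m1.W, m2.W)
        assert np.array_equal(m1.backbone.kernels[0], m2.backbone.kernels[0])

    def test_forward_pass_is_a_probability_pair(self):
        model = build_classifier(small_config(seed=2))
        probs = model.predict_proba(constant_tensor(0.3))
        assert probs.shape == (2,)
        assert probs.min() >= 0 and probs.sum() == pytest.approx(1.0)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(backbone="resnet50")


def separable_split(n_per_class=16, seed=0):
    """Trivially separable fixture: constant-color images per class."""
    rng = np.random.default_rng(seed)
    items, labels = [], []
    for value, label in ((-0.8, "dark"), (0.8, "bright")):
        for _ in range(n_per_class):
            items.append(constant_tensor(value + rng.normal(0, 0.02)))
            labels.append(label)
    return stratified_split(items, labels, seed=seed)


class TestTrain:
    def test_separable_classes_reach_perfect_validation_accuracy(self):
        cfg = small_config(epochs=5, seed=0)
        split = separable_split()
        model, history = train(build_classifier(cfg), split, cfg)
        preds = model.predict(np.stack([t for t, _ in split.validation]))
        truth = [l for _, l in split.validation]
        assert preds == truth
        assert len(history) <= 5

    def test_one_epoch_on_32_items_is_one_optimizer_step(self):
        cfg = small_config(epochs=1, seed=0)
        rng = np.random.default_rng(1)
        pairs = [
            (constant_tensor(rng.uniform(-1, 1)), lbl)
            for lbl in ("a", "b")
            for _ in range(16)
        ]
        split = DatasetSplit(train=pairs, test=pairs[:4], validation=[])
        model, _ = train(build_classifier(cfg), split, cfg)
        assert model.n_optimizer_steps == 1

    def test_fixed_seed_identical_final_metrics(self):
        cfg = small_config(epochs=3, seed=9)
        runs = []
        for _ in range(2):
            split = separable_split(seed=3)
            model, history = train(build_classifier(cfg), split, cfg)
            runs.append((model.W.copy(), history[-1]["test_loss"]))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_validation_partition_never_read(self):
        class Poison(list):
            def __iter__(self):
                raise AssertionError("validation read during training")

            def __len__(self):
                raise AssertionError("validation read during training")

        cfg = small_config(epochs=2, seed=0)
        split = separable_split()
        split.validation = Poison(split.validation)
        train(build_classifier(cfg), split, cfg)  # must not touch validation

    def test_empty_split_part_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            train(build_classifier(cfg), DatasetSplit([], [], []), cfg)


class TestPredict:
    def _trained(self):
        cfg = small_config(epochs=2, seed=0)
        split = separable_split()
        model, _ = train(build_classifier(cfg), split, cfg)
        return model

    def test_tie_breaks_to_first_class(self):
        model = self._trained()
        model.W[:] = 0.0
        model.b[:] = 0.0
        assert model.predict(constant_tensor(0.5)) == model.classes_[0]

    def test_batch_of_n_gives_n_labels(self):
        model = self._trained()
        batch = np.stack([constant_tensor(v) for v in (-0.8, 0.8, 0.0)])
        labels = model.predict(batch)
        assert len(labels) == 3
        assert set(labels) <= set(model.classes_)

    def test_wrong_input_shape_rejected(self):
        model = self._trained()
        with pytest.raises(ValueError):
            model.predict(np.zeros((10, 10, 3), dtype=np.float32))

    def test_save_load_roundtrip(self, tmp_path):
        model = self._trained()
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = classifier.TransferClassifier.load(path, model.config)
        x = constant_tensor(0.8)
        assert loaded.predict(x) == model.predict(x)
        assert np.allclose(loaded.predict_proba(x), model.predict_proba(x))
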