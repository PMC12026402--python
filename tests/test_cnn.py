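"""CNN split arithmetic, training contracts and invariances."""

from __future__ import annotations

import numpy as np
import pytest

from mkflow.cnn import (
    CLASS_ORDER,
    CnnModel,
    CnnModelSpec,
    NEGATIVE,
    POSITIVE,
    SplitSpec,
    TruthSet,
    crop_event,
    predict,
    realized_split_fractions,
    split_truth_set,
    synthetic_truth_set,
    train_cnn,
)
from mkflow.event_model import DEFAULT_PANEL
from mkflow.synthgen import render_event


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


class TestSplit:
    def test_exact_divisibility_100_events(self):
        crops = np.zeros((100, 2, 8, 8), np.float32)
        labels = np.array([POSITIVE] * 50 + [NEGATIVE] * 50, object)
        ts = TruthSet(crops, labels)
        train, val, test = split_truth_set(ts, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (80, 10, 10)
        for part in (train, val, test):
            assert (part.labels == POSITIVE).sum() == (part.labels == NEGATIVE).sum()

    def test_partitions_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        crops = rng.random((97, 2, 8, 8)).astype(np.float32)
        labels = np.array([POSITIVE] * 41 + [NEGATIVE] * 56, object)
        ts = TruthSet(crops, labels)
        parts = split_truth_set(ts, SplitSpec(seed=3))
        assert sum(len(p) for p in parts) == 97
        seen = np.concatenate([p.crops.reshape(len(p), -1) for p in parts])
        assert len(np.unique(seen, axis=0)) == len(
            np.unique(crops.reshape(97, -1), axis=0)
        )

    def test_same_seed_reproduces_partition(self):
        crops = np.random.default_rng(1).random((60, 2, 8, 8)).astype(np.float32)
        labels = np.array([POSITIVE] * 30 + [NEGATIVE] * 30, object)
        ts = TruthSet(crops, labels)
        a = split_truth_set(ts, SplitSpec(seed=9))
        b = split_truth_set(ts, SplitSpec(seed=9))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.crops, pb.crops)

    def test_realized_fractions_of_610_92_92(self):
        assert realized_split_fractions((610, 92, 92)) == (76.8, 11.6, 11.6)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(ratios=(0.8, 0.1, 0.2))

    def test_small_class_rejected(self):
        crops = np.zeros((15, 2, 8, 8), np.float32)
        labels = np.array([POSITIVE] * 9 + [NEGATIVE] * 6, object)
        with pytest.raises(ValueError, match="< 10"):
            split_truth_set(TruthSet(crops, labels))


# ---------------------------------------------------------------------------
# Crops
# ---------------------------------------------------------------------------


def test_crop_shape_and_normalization():
    rng = np.random.default_rng(0)
    ev = render_event("mk", rng)
    crop = crop_event(ev, DEFAULT_PANEL)
    assert crop.shape == (2, 64, 64)
    assert crop.min() >= 0.0 and crop.max() <= 1.0
    assert crop.max() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _separable_truth_set(n_per_class=24, size=32, seed=0) -> TruthSet:
    """Blank-vs-ring crops: trivially separable."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.sqrt((yy - size / 2) ** 2 + (xx - size / 2) ** 2)
    ring = ((r > size * 0.3) & (r < size * 0.42)).astype(np.float32)
    crops, labels = [], []
    for i in range(2 * n_per_class):
        noise = rng.random((2, size, size)).astype(np.float32) * 0.05
        crop = noise
        if i < n_per_class:
            crop = crop + np.stack([ring * 0.2, ring])
            labels.append(POSITIVE)
        else:
            labels.append(NEGATIVE)
        crops.append(np.clip(crop, 0, 1))
    return TruthSet(np.stack(crops), np.array(labels, object))


_FAST_SPEC = CnnModelSpec(
    input_size=32, max_epochs=25, min_epochs=4, patience=3, learning_rate=1e-2, seed=0
)


class TestTraining:
    def test_separable_limit_reaches_perfect_validation(self):
        ts = _separable_truth_set()
        train, val, _ = split_truth_set(ts, SplitSpec(ratios=(0.6, 0.2, 0.2), seed=0))
        model, hist = train_cnn(train, val, _FAST_SPEC)
        assert hist["val_acc"].iloc[-1] == 1.0

    def test_training_is_deterministic_given_seed(self):
        ts = _separable_truth_set(n_per_class=16)
        train, val, _ = split_truth_set(ts, SplitSpec(ratios=(0.6, 0.2, 0.2), seed=0))
        spec = CnnModelSpec(input_size=32, max_epochs=3, min_epochs=3, seed=5)
        m1, h1 = train_cnn(train, val, spec)
        m2, h2 = train_cnn(train, val, spec)
        assert m1.checksum() == m2.checksum()
        assert h1.equals(h2)

    def test_single_class_training_rejected(self):
        ts = _separable_truth_set(n_per_class=12)
        pos = ts.subset(np.flatnonzero(ts.labels == POSITIVE))
        with pytest.raises(ValueError, match="both classes"):
            train_cnn(pos, pos, _FAST_SPEC)

    def test_model_archive_round_trip(self, tmp_path):
        ts = _separable_truth_set(n_per_class=12)
        train, val, _ = split_truth_set(ts, SplitSpec(ratios=(0.6, 0.2, 0.2), seed=0))
        model, _ = train_cnn(train, val, _FAST_SPEC)
        model.save(tmp_path / "m.npz")
        back = CnnModel.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            back.predict_proba(ts.crops), model.predict_proba(ts.crops)
        )
        assert back.checksum() == model.checksum()


@pytest.fixture(scope="module")
def fitted():
    ts = _separable_truth_set()
    train, val, test = split_truth_set(ts, SplitSpec(ratios=(0.6, 0.2, 0.2), seed=0))
    model, _ = train_cnn(train, val, _FAST_SPEC)
    return model, test


class TestPredict:
    def test_probabilities_sum_to_one(self, fitted):
        model, test = fitted
        proba = model.predict_proba(test.crops)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_prediction_invariant_to_event_order(self, fitted):
        model, test = fitted
        perm = np.random.default_rng(0).permutation(len(test))
        a = predict(model, test.crops)
        b = predict(model, test.crops[perm])
        assert list(a["label"].iloc[perm]) == list(b["label"])

    def test_wrong_channel_count_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError, match="crops must be"):
            model.predict_proba(np.zeros((3, 1, 32, 32), np.float32))


# ---------------------------------------------------------------------------
# Invariances on a medium synthetic benchmark
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def medium_benchmark():
    ts = synthetic_truth_set(n_pos=120, n_neg=110, seed=2)
    train, val, test = split_truth_set(ts, SplitSpec(seed=2))
    spec = CnnModelSpec(max_epochs=15, min_epochs=8, patience=3, seed=2)
    model, hist = train_cnn(train, val, spec)
    return model, spec, train, val, test


def test_rotated_test_set_accuracy_within_three_points(medium_benchmark):
    """Flip/rotation augmentation ⇒ orientation-invariant predictions."""
    model, _, _, _, test = medium_benchmark
    base = (model.predict_proba(test.crops).argmax(1) == test.y).mean()
    rotated = np.rot90(test.crops, 1, axes=(2, 3)).copy()
    rot = (model.predict_proba(rotated).argmax(1) == test.y).mean()
    assert abs(base - rot) <= 0.03


def test_class_prior_reweighting_changes_little(medium_benchmark):
    model, spec, train, val, test = medium_benchmark
    base = (model.predict_proba(test.crops).argmax(1) == test.y).mean()
    from dataclasses import replace

    wmodel, _ = train_cnn(train, val, replace(spec, class_weighted=True))
    weighted = (wmodel.predict_proba(test.crops).argmax(1) == test.y).mean()
    assert abs(base - weighted) < 0.05


def test_truthset_label_validation():
    with pytest.raises(ValueError, match="unknown labels"):
        TruthSet(np.zeros((2, 2, 8, 8)), np.array(["a", "b"], object))
    with pytest.raises(ValueError, match="2 channels"):
        TruthSet(np.zeros((2, 3, 8, 8)), np.array([POSITIVE, NEGATIVE], object))
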