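"""Slice classifier: forward contract, loss, schedule, early stop, training."""

import numpy as np
import pytest

from adslice.augment import AugmentConfig
from adslice.model import (
    ClassifierConfig,
    SliceClassifier,
    SliceSample,
    SubjectSlices,
    TrainConfig,
    TrainingState,
    batch_loss,
    early_stop_check,
    forward,
    lr_schedule_step,
    train_fold,
)

TINY = ClassifierConfig(feature_dim=32, input_px=16, channels=(4, 8), n_slices=10)


def _subject(rng, sid, label, n_slices=10, px=16, shift=0.2):
    imgs = np.clip(
        rng.normal(0.3 + shift * label, 0.05, (n_slices, px, px)), 0, 1
    ).astype(np.float32)
    return SubjectSlices(sid, imgs, 70.0 + rng.normal(0, 5), int(rng.random() < 0.5), label)


# ---------------------------------------------------------------------------
# forward contract
# ---------------------------------------------------------------------------

def test_default_concatenated_vector_has_1027_entries():
    assert ClassifierConfig().concat_dim == 1024 + 3 == 1027


def test_softmax_outputs_normalized(rng):
    clf = SliceClassifier(TINY, rng=rng)
    x = rng.random((8, 3, 16, 16)).astype(np.float32)
    meta = clf.scale_metadata(np.full(8, 70.0), np.zeros(8), np.arange(8))
    probs = clf.forward_batch(x, meta)
    assert probs.shape == (8, 2)
    assert np.all(probs >= 0)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_metadata_reaches_the_head(rng):
    """Changing only the age must change the predicted probability."""
    clf = SliceClassifier(TINY, rng=rng)
    img = rng.random((16, 16)).astype(np.float32)
    a = forward(SliceSample(img, age_years=60.0, sex_code=0, slice_number=3, label=0), clf)
    b = forward(SliceSample(img, age_years=90.0, sex_code=0, slice_number=3, label=0), clf)
    assert a != b


def test_forward_has_no_hidden_state(rng):
    clf = SliceClassifier(TINY, rng=rng)
    s = SliceSample(rng.random((16, 16)).astype(np.float32), 70.0, 1, 2, 1)
    assert forward(s, clf) == forward(s, clf)


def test_slice_sample_invariants(rng):
    img = rng.random((3, 16, 16)).astype(np.float32)
    with pytest.raises(ValueError):
        SliceSample(img, 70.0, 0, 0, 0)  # channels not identical replicas
    with pytest.raises(ValueError):
        SliceSample(rng.random((16, 16)), 70.0, 2, 0, 0)


def test_inception_backbone_not_provided():
    with pytest.raises(NotImplementedError):
        SliceClassifier(ClassifierConfig(backbone_name="inception_v4"))


def test_backbones_share_feature_contract(rng):
    """Feature length follows config, keeping head and ensembling agnostic."""
    for fd in (32, 64):
        cc = ClassifierConfig(feature_dim=fd, input_px=16, channels=(4, 8))
        clf = SliceClassifier(cc, rng=np.random.default_rng(0))
        x = rng.random((4, 3, 16, 16)).astype(np.float32)
        feat = clf.backbone.forward(x)
        assert feat.shape == (4, fd)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_batch_loss_closed_forms():
    assert batch_loss([0.5, 0.5, 0.5], [1, 0, 1]) == pytest.approx(np.log(2), abs=1e-9)
    assert batch_loss([0.9, 0.2], [1, 0]) == pytest.approx(
        -(np.log(0.9) + np.log(0.8)) / 2, abs=1e-9
    )
    assert batch_loss([0.9, 0.2], [1, 0]) == pytest.approx(0.164252, abs=1e-6)
    assert batch_loss([1.0, 0.0], [1, 0]) <= 2e-6  # clamped perfect prediction


def test_batch_loss_validation():
    with pytest.raises(ValueError):
        batch_loss([0.5, 0.5], [1])
    with pytest.raises(ValueError):
        batch_loss([], [])


def test_batch_loss_matches_elementwise_oracle(rng):
    """Agreement with an independently coded elementwise sum, 100 batches."""
    eps = 1e-7
    for _ in range(100):
        n = rng.integers(1, 40)
        p = rng.random(n)
        y = rng.integers(0, 2, n)
        pc = np.minimum(np.maximum(p, eps), 1 - eps)
        oracle = -sum(
            yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for pi, yi in zip(pc, y)
        ) / n
        assert batch_loss(p, y) == pytest.approx(oracle, abs=1e-9)


def test_gradients_match_finite_differences(rng):
    """Analytic backprop equals central finite differences in float64."""
    cc = ClassifierConfig(feature_dim=16, input_px=16, channels=(3, 5))
    clf = SliceClassifier(cc, rng=np.random.default_rng(2), dtype=np.float64)
    x = rng.random((6, 3, 16, 16))
    meta = rng.random((6, 3))
    y = rng.integers(0, 2, 6)
    import copy

    state0 = copy.deepcopy(clf.backbone.state)
    probs, cache = clf.forward_batch(x, meta, want_cache=True, train=True)
    grads = clf.backward_batch(probs, y, cache)

    def loss_at():
        for k, v in state0.items():
            clf.backbone.state[k] = v.copy()
        return batch_loss(clf.forward_batch(x, meta, train=True)[:, 1], y)

    check = np.random.default_rng(3)
    for name in ("conv1_w", "conv2_w", "fc_w", "head_w", "head_b"):
        w = clf.params[name]
        for _ in range(3):
            idx = tuple(check.integers(0, s) for s in w.shape)
            eps, orig = 1e-6, w[idx]
            w[idx] = orig + eps
            lp = loss_at()
            w[idx] = orig - eps
            lm = loss_at()
            w[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def _state(losses, lr=0.001, decays=0):
    s = TrainingState(lr=lr, decays_applied=decays)
    for v in losses:
        s.val_loss_history.append(v)
        lr_schedule_step(s, TrainConfig())
    return s


def test_lr_unchanged_while_loss_decreases():
    s = _state([1.0, 0.9, 0.8, 0.7, 0.6])
    assert s.lr == 0.001
    assert s.decays_applied == 0


def test_lr_decays_by_factor_ten_on_plateau():
    s = _state([1.0, 1.0, 1.0, 1.0])
    assert s.lr == pytest.approx(0.0001)
    assert s.decays_applied == 1


def test_lr_decay_capped_at_three():
    s = _state([1.0] * 30)
    assert s.decays_applied == 3
    assert s.lr == pytest.approx(0.001 * 0.1**3)


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------

def _acc_state(accs):
    s = TrainingState(lr=0.001)
    s.val_accuracy_history = list(accs)
    return s


def test_early_stop_false_while_improving():
    accs = [0.5 + 0.01 * i for i in range(10)]
    assert not early_stop_check(_acc_state(accs), TrainConfig())


def test_early_stop_true_on_constant_accuracy():
    assert early_stop_check(_acc_state([0.8] * 6), TrainConfig())
    assert early_stop_check(_acc_state([0.8] * 12), TrainConfig())


def test_early_stop_boundary_equality_stops():
    """Rising by exactly the threshold over the window is not 'more than'."""
    delta = TrainConfig().early_stop_delta
    accs = [0.5 + delta / 5.0 * i for i in range(15)]  # MA gain = delta exactly
    assert early_stop_check(_acc_state(accs), TrainConfig())


def test_early_stop_needs_enough_history():
    assert not early_stop_check(_acc_state([0.5] * 5), TrainConfig())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_train_fold_learns_separable_classes():
    rng = np.random.default_rng(0)
    train = [_subject(rng, f"T{i}", i % 2) for i in range(24)]
    val = [_subject(rng, f"V{i}", i % 2) for i in range(8)]
    fm = train_fold(
        train,
        val,
        TINY,
        TrainConfig(max_epochs=20, base_lr=0.003),
        aug_config=None,
        rng=np.random.default_rng(1),
    )
    assert max(fm.history["val_accuracy"]) == 1.0
    assert fm.history["epochs_run"] <= 20


def test_train_fold_deterministic():
    rng = np.random.default_rng(0)
    train = [_subject(rng, f"T{i}", i % 2) for i in range(12)]
    val = [_subject(rng, f"V{i}", i % 2) for i in range(4)]
    runs = []
    for _ in range(2):
        fm = train_fold(
            train,
            val,
            TINY,
            TrainConfig(max_epochs=4, base_lr=0.003, min_epochs=4),
            aug_config=AugmentConfig(),
            rng=np.random.default_rng(7),
        )
        runs.append(fm)
    assert runs[0].history["train_loss"] == runs[1].history["train_loss"]
    for k in runs[0].classifier.params:
        assert np.array_equal(runs[0].classifier.params[k], runs[1].classifier.params[k])


def test_weight_decay_changes_final_norms():
    rng = np.random.default_rng(0)
    train = [_subject(rng, f"T{i}", i % 2) for i in range(12)]
    val = [_subject(rng, f"V{i}", i % 2) for i in range(4)]
    norms = []
    for wd in (0.0, 5e-5):
        fm = train_fold(
            train,
            val,
            TINY,
            TrainConfig(max_epochs=6, base_lr=0.003, weight_decay=wd, min_epochs=6),
            aug_config=None,
            rng=np.random.default_rng(3),
        )
        norms.append(
            float(np.linalg.norm(fm.classifier.params["fc_w"]))
        )
    assert norms[0] != norms[1]


def test_train_fold_rejects_overlapping_subjects(rng):
    subj = _subject(rng, "X", 1)
    with pytest.raises(ValueError):
        train_fold([subj], [subj], TINY, TrainConfig())
    with pytest.raises(ValueError):
        train_fold([], [subj], TINY, TrainConfig())
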