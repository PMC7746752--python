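"""Slice classifier and training recipe.

One coronal slice at a time: a convolutional backbone maps the 3-channel
(triplicated greyscale) slice to a fixed-length feature vector, three
metadata values are appended — subject age, sex, and the index of the slice
within the extracted range — and a fully connected head plus softmax yields
the AD probability.  With the reference configuration the concatenated
vector has 1024 + 3 = 1027 entries.

Training follows a fixed recipe: mini-batch SGD with Nesterov momentum,
batch size 64, weight decay 5e-5, base learning rate 1e-3 decayed by 0.1
(at most three times) when the validation loss plateaus, and early stopping
when the 5-epoch moving average of subject-level validation accuracy stops
improving by more than 5e-4.  Augmentation is applied to training slices
only.  The weights returned are those of the best-validation-accuracy epoch.

Metadata scaling: age/100, sex in {0,1}, slice_number/n_slices — keeps the
metadata on the same order of magnitude as the backbone features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .augment import AugmentConfig, augment_slice
from .nets import TinyCNNBackbone

__all__ = [
    "SliceSample",
    "SubjectSlices",
    "ClassifierConfig",
    "TrainConfig",
    "TrainingState",
    "SliceClassifier",
    "FoldModel",
    "batch_loss",
    "forward",
    "lr_schedule_step",
    "early_stop_check",
    "train_fold",
    "prepare_subject",
]

LOSS_EPS = 1e-7


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

@dataclass
class SliceSample:
    """One slice plus its metadata; image replicated to 3 identical channels."""

    image: np.ndarray  # (3, px, px), values in [0, 1]
    age_years: float
    sex_code: int
    slice_number: int
    label: int  # 0 = CN, 1 = AD

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim == 2:
            self.image = np.repeat(self.image[None], 3, axis=0)
        if self.image.shape[0] != 3:
            raise ValueError("image must have 3 channels")
        if not np.allclose(self.image[0], self.image[1]) or not np.allclose(
            self.image[0], self.image[2]
        ):
            raise ValueError("the 3 channels must be identical replicas")
        if self.sex_code not in (0, 1):
            raise ValueError("sex_code must be 0 or 1")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (CN) or 1 (AD)")


@dataclass
class SubjectSlices:
    """All extracted slices of one subject, resized to the classifier input."""

    subject_id: str
    images: np.ndarray  # (n_slices, px, px) in [0, 1]
    age_years: float
    sex_code: int
    label: int


def prepare_subject(stack, subject, input_px: int) -> SubjectSlices:
    """Resize a SliceStack to the classifier input size.

    ``subject`` needs ``subject_id``, ``age_years``, ``sex`` and ``label``
    attributes (a phantom subject qualifies).
    """
    arr = stack.to_array().astype(np.float32)
    if arr.shape[1:] != (input_px, input_px):
        arr = np.stack(
            [
                resize(s, (input_px, input_px), order=1, anti_aliasing=True)
                for s in arr
            ]
        ).astype(np.float32)
        arr = np.clip(arr, 0.0, 1.0)
    return SubjectSlices(
        subject_id=subject.subject_id,
        images=arr,
        age_years=float(subject.age_years),
        sex_code=int(subject.sex),
        label=int(subject.label),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    backbone_name: str = "tiny_cnn"
    feature_dim: int = 1024
    metadata_dim: int = 3
    input_px: int = 32
    channels: tuple[int, int] = (16, 32)
    n_slices: int = 30  # used to scale the slice-number metadata value

    def __post_init__(self) -> None:
        if self.backbone_name not in ("tiny_cnn", "inception_v4"):
            raise ValueError("backbone_name must be 'tiny_cnn' or 'inception_v4'")
        if self.metadata_dim != 3:
            raise ValueError("the classifier head expects exactly 3 metadata values")

    @property
    def concat_dim(self) -> int:
        return self.feature_dim + self.metadata_dim


@dataclass
class TrainConfig:
    batch_size: int = 64
    base_lr: float = 0.001
    weight_decay: float = 5e-5
    momentum: float = 0.9  # Nesterov
    lr_decay_factor: float = 0.1
    max_lr_decays: int = 3
    lr_plateau_patience: int = 3
    lr_plateau_rel_tol: float = 1e-4
    early_stop_delta: float = 5e-4
    early_stop_window_epochs: int = 5
    min_epochs: int = 0  # epochs before the early-stop rule is consulted
    max_epochs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_lr <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("rates, batch size and epoch budget must be positive")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must lie in (0, 1)")


@dataclass
class TrainingState:
    """Mutable optimization state: weights, histories, schedule counters."""

    lr: float
    decays_applied: int = 0
    epoch: int = 0
    train_loss_history: list = field(default_factory=list)
    val_loss_history: list = field(default_factory=list)
    val_accuracy_history: list = field(default_factory=list)
    best_val_loss: float = np.inf
    epochs_since_loss_improve: int = 0


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class SliceClassifier:
    """Backbone + metadata concatenation + FC head + softmax."""

    def __init__(
        self,
        config: ClassifierConfig,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if config.backbone_name == "inception_v4":
            raise NotImplementedError(
                "the inception_v4 backbone is not provided; use 'tiny_cnn' "
                "(same feature-vector contract)"
            )
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.backbone = TinyCNNBackbone(
            input_px=config.input_px,
            feature_dim=config.feature_dim,
            channels=config.channels,
            rng=rng,
            dtype=dtype,
        )
        d = config.concat_dim
        self.params = dict(self.backbone.params)
        self.params["head_w"] = (
            rng.standard_normal((d, 2)) * np.sqrt(1.0 / d)
        ).astype(dtype)
        self.params["head_b"] = np.zeros(2, dtype=dtype)
        self.backbone.params = self.params  # shared storage

    # -- metadata ---------------------------------------------------------
    def scale_metadata(self, age_years, sex_code, slice_number) -> np.ndarray:
        meta = np.stack(
            [
                np.asarray(age_years, dtype=np.float32) / 100.0,
                np.asarray(sex_code, dtype=np.float32),
                np.asarray(slice_number, dtype=np.float32) / self.config.n_slices,
            ],
            axis=-1,
        )
        if not np.all(np.isfinite(meta)):
            raise ValueError("metadata must be finite")
        return meta

    # -- forward ----------------------------------------------------------
    def forward_batch(
        self, images: np.ndarray, meta: np.ndarray, want_cache=False, train=False
    ):
        """images (N,3,px,px), meta (N,3) -> softmax probabilities (N,2).

        ``train=True`` uses batch statistics in the backbone's normalization
        layers and updates their running averages; inference uses the stored
        running statistics, so repeated forward passes are side-effect free.
        """
        if images.shape[1:] != (3, self.config.input_px, self.config.input_px):
            raise ValueError(
                f"image batch shape {images.shape[1:]} does not match backbone "
                f"input (3, {self.config.input_px}, {self.config.input_px})"
            )
        out = self.backbone.forward(images, want_cache=want_cache, train=train)
        feat, cache = out if want_cache else (out, None)
        concat = np.concatenate([feat, meta.astype(feat.dtype)], axis=1)
        logits = concat @ self.params["head_w"] + self.params["head_b"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if want_cache:
            return probs, (cache, concat)
        return probs

    def backward_batch(self, probs, labels, cache_all) -> dict:
        """Gradients of the batch cross-entropy w.r.t. all parameters."""
        cache, concat = cache_all
        n = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        grads = {
            "head_w": concat.T @ dlogits,
            "head_b": dlogits.sum(axis=0),
        }
        dconcat = dlogits @ self.params["head_w"].T
        dfeat = dconcat[:, : self.config.feature_dim]
        grads.update(self.backbone.backward(dfeat, cache))
        return grads

    def recalibrate_bn(
        self, images, age, sex, slice_no, batch: int = 256, max_slices: int = 512
    ) -> None:
        """Recompute the backbone's normalization statistics in one clean pass.

        After an epoch of augmented mini-batches the exponential running
        statistics lag the current weights, which shifts inference-mode
        probabilities by a global bias.  A pass over (a deterministic, evenly
        spaced sample of) the un-augmented training slices replaces them with
        population moments so validation and test predictions are stable;
        each slice contributes every spatial position to the convolutional
        statistics, so a few hundred slices estimate them tightly.
        """
        if images.shape[0] > max_slices:
            idx = np.linspace(0, images.shape[0] - 1, max_slices).astype(int)
            images, age = images[idx], age[idx]
            sex, slice_no = sex[idx], slice_no[idx]
        self.backbone.start_bn_recalibration()
        n = images.shape[0]
        for i in range(0, n, batch):
            x = np.repeat(images[i : i + batch][:, None], 3, axis=1)
            meta = self.scale_metadata(
                age[i : i + batch], sex[i : i + batch], slice_no[i : i + batch]
            )
            self.forward_batch(x, meta, train=True)
        self.backbone.finish_bn_recalibration()

    def predict_slices(self, subject: SubjectSlices, batch: int = 64) -> np.ndarray:
        """Per-slice AD probabilities for one subject."""
        n = subject.images.shape[0]
        imgs = np.repeat(subject.images[:, None], 3, axis=1)
        meta = self.scale_metadata(
            np.full(n, subject.age_years),
            np.full(n, subject.sex_code),
            np.arange(n),
        )
        probs = []
        for i in range(0, n, batch):
            probs.append(self.forward_batch(imgs[i : i + batch], meta[i : i + batch])[:, 1])
        return np.concatenate(probs)

    def predict_subject_prob(self, subject: SubjectSlices) -> float:
        """Slice-averaged AD probability — the subject-level prediction."""
        return float(self.predict_slices(subject).mean())

    def snapshot(self) -> dict:
        snap = {k: v.copy() for k, v in self.params.items()}
        snap["__state__"] = {k: v.copy() for k, v in self.backbone.state.items()}
        return snap

    def load_snapshot(self, snap: dict) -> None:
        for k in self.params:
            self.params[k][...] = snap[k]
        for k in self.backbone.state:
            self.backbone.state[k][...] = snap["__state__"][k]


def forward(sample: SliceSample, classifier: SliceClassifier) -> float:
    """AD probability for a single slice sample."""
    meta = classifier.scale_metadata(
        [sample.age_years], [sample.sex_code], [sample.slice_number]
    )
    probs = classifier.forward_batch(sample.image[None], meta)
    return float(probs[0, 1])


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def batch_loss(probabilities, labels) -> float:
    """Mean binary cross-entropy of predicted AD probabilities over a batch.

    J = -(1/N) sum_n [ y_n log p_n + (1 - y_n) log(1 - p_n) ], with the
    probabilities clamped to [eps, 1 - eps], eps = 1e-7.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if p.size == 0:
        raise ValueError("batch must contain at least one sample")
    p = np.clip(p, LOSS_EPS, 1.0 - LOSS_EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


# ---------------------------------------------------------------------------
# schedule and stopping
# ---------------------------------------------------------------------------

def lr_schedule_step(state: TrainingState, config: TrainConfig) -> float:
    """Decay the LR by the configured factor when validation loss plateaus.

    A plateau is `lr_plateau_patience` consecutive epochs without the
    validation loss improving by more than `lr_plateau_rel_tol` (relative).
    At most `max_lr_decays` decays are ever applied.
    """
    if not state.val_loss_history:
        raise ValueError("need at least one validation-loss entry")
    current = state.val_loss_history[-1]
    if current < state.best_val_loss * (1.0 - config.lr_plateau_rel_tol):
        state.best_val_loss = current
        state.epochs_since_loss_improve = 0
    else:
        state.epochs_since_loss_improve += 1
    if (
        state.epochs_since_loss_improve >= config.lr_plateau_patience
        and state.decays_applied < config.max_lr_decays
    ):
        state.lr *= config.lr_decay_factor
        state.decays_applied += 1
        state.epochs_since_loss_improve = 0
    return state.lr


def early_stop_check(state: TrainingState, config: TrainConfig) -> bool:
    """True when the moving average of validation accuracy has stalled.

    Compares the window-sized moving average of the accuracy history with
    its value one window earlier; training stops unless the improvement
    exceeds ``early_stop_delta`` strictly.
    """
    acc = state.val_accuracy_history
    w = config.early_stop_window_epochs
    if len(acc) < w + 1:
        return False
    ma_now = float(np.mean(acc[-w:]))
    ma_prev = float(np.mean(acc[max(0, len(acc) - 2 * w) : len(acc) - w]))
    return (ma_now - ma_prev) <= config.early_stop_delta


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class _NesterovSGD:
    def __init__(self, params: dict, lr: float, momentum: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        mu, wd = self.momentum, self.weight_decay
        for k, w in self.params.items():
            g = grads[k].astype(w.dtype) + wd * w
            v = self.velocity[k]
            v *= mu
            v += g
            w -= self.lr * (g + mu * v)  # Nesterov look-ahead form


# ---------------------------------------------------------------------------
# fold training
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """One trained slice classifier (one cross-validation fold)."""

    classifier: SliceClassifier
    history: dict
    best_epoch: int
    val_subject_ids: list
    fold_index: int = -1


def _flatten_subjects(subjects: list[SubjectSlices]):
    images, age, sex, slice_no, label = [], [], [], [], []
    for s in subjects:
        n = s.images.shape[0]
        images.append(s.images)
        age.append(np.full(n, s.age_years, dtype=np.float32))
        sex.append(np.full(n, s.sex_code, dtype=np.float32))
        slice_no.append(np.arange(n, dtype=np.float32))
        label.append(np.full(n, s.label, dtype=np.int64))
    return (
        np.concatenate(images),
        np.concatenate(age),
        np.concatenate(sex),
        np.concatenate(slice_no),
        np.concatenate(label),
    )


def _subject_eval(classifier, subjects, batch: int = 256):
    """Subject-level probabilities plus slice-level validation loss.

    Slices of all subjects are scored in shared batches; per-subject
    averages are recovered from the flat probability vector afterwards.
    """
    images, age, sex, slice_no, slice_labels = _flatten_subjects(subjects)
    counts = [s.images.shape[0] for s in subjects]
    flat = []
    for i in range(0, images.shape[0], batch):
        x = np.repeat(images[i : i + batch][:, None], 3, axis=1)
        meta = classifier.scale_metadata(
            age[i : i + batch], sex[i : i + batch], slice_no[i : i + batch]
        )
        flat.append(classifier.forward_batch(x, meta)[:, 1])
    flat = np.concatenate(flat)
    bounds = np.cumsum([0] + counts)
    probs = np.array(
        [flat[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    )
    labels = np.array([s.label for s in subjects])
    acc = float(((probs >= 0.5).astype(int) == labels).mean())
    loss = batch_loss(flat, slice_labels)
    return probs, labels, acc, loss


def train_fold(
    train_subjects: list[SubjectSlices],
    val_subjects: list[SubjectSlices],
    cconfig: ClassifierConfig,
    tconfig: TrainConfig,
    aug_config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FoldModel:
    """Train one slice classifier on disjoint train/validation subject sets.

    Shuffled mini-batches with on-the-fly augmentation (training slices
    only), Nesterov-momentum SGD with weight decay, plateau LR decay, early
    stopping on the subject-level validation accuracy moving average.
    Returns the best-validation-accuracy weights plus the full histories.
    """
    if not train_subjects or not val_subjects:
        raise ValueError("train and validation sets must both be non-empty")
    train_ids = {s.subject_id for s in train_subjects}
    if train_ids & {s.subject_id for s in val_subjects}:
        raise ValueError("train and validation subject sets must be disjoint")

    rng = rng or np.random.default_rng(tconfig.seed)
    classifier = SliceClassifier(cconfig, rng=rng)
    optimizer = _NesterovSGD(
        classifier.params, tconfig.base_lr, tconfig.momentum, tconfig.weight_decay
    )
    state = TrainingState(lr=tconfig.base_lr)

    images, age, sex, slice_no, labels = _flatten_subjects(train_subjects)
    n = images.shape[0]

    best_acc = -1.0
    best_epoch = -1
    best_snap = classifier.snapshot()

    for epoch in range(1, tconfig.max_epochs + 1):
        state.epoch = epoch
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, tconfig.batch_size):
            idx = perm[start : start + tconfig.batch_size]
            batch_imgs = images[idx]
            if aug_config is not None:
                batch_imgs = np.stack(
                    [augment_slice(im, aug_config, rng) for im in batch_imgs]
                )
            x = np.repeat(batch_imgs[:, None], 3, axis=1)
            meta = classifier.scale_metadata(age[idx], sex[idx], slice_no[idx])
            y = labels[idx]
            probs, cache = classifier.forward_batch(x, meta, want_cache=True, train=True)
            losses.append(batch_loss(probs[:, 1], y))
            grads = classifier.backward_batch(probs, y, cache)
            optimizer.lr = state.lr
            optimizer.step(grads)

        classifier.recalibrate_bn(images, age, sex, slice_no)
        _, _, val_acc, val_loss = _subject_eval(classifier, val_subjects)
        state.train_loss_history.append(float(np.mean(losses)))
        state.val_loss_history.append(val_loss)
        state.val_accuracy_history.append(val_acc)

        if val_acc > best_acc:
            best_acc = val_acc
            best_epoch = epoch
            best_snap = classifier.snapshot()

        lr_schedule_step(state, tconfig)
        if epoch >= tconfig.min_epochs and early_stop_check(state, tconfig):
            break

    classifier.load_snapshot(best_snap)
    return FoldModel(
        classifier=classifier,
        history={
            "train_loss": state.train_loss_history,
            "val_loss": state.val_loss_history,
            "val_accuracy": state.val_accuracy_history,
            "epochs_run": state.epoch,
            "lr_decays": state.decays_applied,
        },
        best_epoch=best_epoch,
        val_subject_ids=sorted({s.subject_id for s in val_subjects}),
    )
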