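"""Residual-attention embedding network and its training regime.

The network maps a 4-channel input stack (original image + IMF2/3/4) to a
compact 32-dimensional embedding and per-class logits:

* stem: 7x7 convolution, stride 2, then 3x3 max-pool, stride 2;
* three attention stages of bottleneck width (64, 128, 256), each an entry
  bottleneck residual unit followed by one attention mask block
  (bottom-up/top-down mask, sigmoid gating, residual combination);
* a plain residual stage of bottleneck width 512 repeated 3 times;
* a reduction head: 3x3 convolution with 32 filters (same padding),
  2x2 max-pool, global average pooling -> the 32-d retrieval embedding;
* a fully connected softmax classifier on top of the embedding.

Training minimises the joint supervision signal

    Loss = softmax cross-entropy + lambda * center loss,

where the center loss (1/2) * mean_i ||x_i - c_{y_i}||^2 pulls each
embedding toward its learned class center, promoting intra-class
compactness and inter-class dispersion of the retrieval features.  The
centers follow their own moving-average update rather than the Adam step.

The ``full`` preset takes 256x256 inputs; the ``reduced`` preset keeps the
topology and the 32-d embedding but scales widths by 1/4 and takes 64x64
inputs, so the whole pipeline trains in minutes on one CPU core.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (
    AttentionBlock,
    Bottleneck,
    Conv2d,
    ConvBNRelu,
    Linear,
    Module,
)
from .nn.optim import Adam

logger = logging.getLogger(__name__)

EMBEDDING_DIM = 32


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural hyperparameters of the embedding network.

    ``preset='full'`` is the full-scale configuration (256x256 input,
    stem width 64, attention bottleneck widths (64, 128, 256), residual
    stage width 512 x 3); ``preset='reduced'`` divides all widths by 4 and
    takes 64x64 inputs.  Both emit 32-d embeddings.
    """

    preset: str = "reduced"
    input_size: int = 64
    in_channels: int = 4
    stem_width: int = 16
    stage_widths: tuple[int, int, int] = (16, 32, 64)
    residual_width: int = 128
    residual_repeats: int = 3
    embedding_dim: int = EMBEDDING_DIM
    trunk_depth: int = 57  # reported backbone depth; metadata only

    @classmethod
    def full(cls) -> "ArchitectureSpec":
        return cls(
            preset="full",
            input_size=256,
            stem_width=64,
            stage_widths=(64, 128, 256),
            residual_width=512,
        )

    @classmethod
    def reduced(cls) -> "ArchitectureSpec":
        return cls()

    @classmethod
    def from_preset(cls, preset: str) -> "ArchitectureSpec":
        if preset == "full":
            return cls.full()
        if preset == "reduced":
            return cls.reduced()
        raise ValueError(f"unknown preset {preset!r}; expected 'full' or 'reduced'")

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "input_size": self.input_size,
            "in_channels": self.in_channels,
            "stem_width": self.stem_width,
            "stage_widths": list(self.stage_widths),
            "residual_width": self.residual_width,
            "residual_repeats": self.residual_repeats,
            "embedding_dim": self.embedding_dim,
        }


@dataclass
class LossState:
    """Class centers and weighting of the joint supervision signal."""

    centers: np.ndarray  # (n_classes, embedding_dim)
    lambda_: float = 0.002
    alpha: float = 0.5  # center moving-average update rate

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("class centers must be finite")

    @classmethod
    def init(cls, n_classes: int, embedding_dim: int = EMBEDDING_DIM,
             lambda_: float = 0.002, alpha: float = 0.5) -> "LossState":
        return cls(centers=np.zeros((n_classes, embedding_dim)), lambda_=lambda_, alpha=alpha)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation regime (Adam, early stopping on validation accuracy)."""

    epochs: int = 500
    batch_size: int = 16
    learning_rate: float = 1e-4
    early_stopping_patience: int = 20
    validation_fraction: float = 0.15
    augment_shift: bool = True
    augment_flip: bool = True
    augment_rotate: bool = False
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if not 0 < self.early_stopping_patience < self.epochs:
            raise ValueError("patience must be positive and smaller than epochs")


class EmbeddingNetwork(Module):
    """The attention-CNN mapping input stacks to (32-d embedding, logits)."""

    def __init__(self, spec: ArchitectureSpec, n_classes: int, rng,
                 dropout_rate: float = 0.5, dtype=np.float32):
        super().__init__()
        if n_classes < 2:
            raise ValueError("the classifier needs at least 2 classes")
        if spec.input_size % 64 != 0:
            raise ValueError(
                f"input size {spec.input_size} is incompatible with the "
                "stage strides (must be a multiple of 64)"
            )
        self.spec = spec
        self.n_classes = n_classes
        self.dropout_rate = dropout_rate
        self._rng = rng
        self.stem = ConvBNRelu(spec.in_channels, spec.stem_width, 7, rng, stride=2, pad=3, dtype=dtype)
        cin = spec.stem_width
        stages = []
        for width, stride in zip(spec.stage_widths, (1, 2, 2)):
            entry = Bottleneck(cin, width, rng, stride=stride, dtype=dtype)
            cin = width * Bottleneck.expansion
            stages.append(entry)
            stages.append(AttentionBlock(cin, width, rng, dtype=dtype))
        self.stages = stages
        residual = [Bottleneck(cin, spec.residual_width, rng, stride=2, dtype=dtype)]
        cin = spec.residual_width * Bottleneck.expansion
        for _ in range(spec.residual_repeats - 1):
            residual.append(Bottleneck(cin, spec.residual_width, rng, dtype=dtype))
        self.residual = residual
        self.reduction = ConvBNRelu(cin, spec.embedding_dim, 3, rng, stride=1, pad=1, dtype=dtype)
        self.fc = Linear(spec.embedding_dim, n_classes, rng, dtype=dtype)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        sizes = []
        h = self.stem(x)
        sizes.append(h.data.shape[2])
        h = ag.maxpool2d(h, 3, 2, pad=1)
        sizes.append(h.data.shape[2])
        for block in self.stages:
            h = block(h)
            sizes.append(h.data.shape[2])
        for block in self.residual:
            h = block(h)
        sizes.append(h.data.shape[2])
        h = self.reduction(h)
        sizes.append(h.data.shape[2])
        h = ag.maxpool2d(h, 2, 2)
        sizes.append(h.data.shape[2])
        embedding = ag.global_avg_pool(h)
        sizes.append(1)
        self.stage_sizes_ = sizes
        dropped = ag.dropout(embedding, self.dropout_rate, self._rng, self.training)
        logits = self.fc(dropped)
        return embedding, logits


def build_network(spec: ArchitectureSpec, n_classes: int, seed: int = 0,
                  dropout_rate: float = 0.5, dtype=np.float32) -> EmbeddingNetwork:
    """Construct the embedding network with seeded He initialisation."""
    rng = np.random.default_rng(seed)
    return EmbeddingNetwork(spec, n_classes, rng, dropout_rate=dropout_rate, dtype=dtype)


def joint_loss(logits: Tensor, embeddings: Tensor, labels, state: LossState) -> Tensor:
    """Softmax cross-entropy plus lambda times the batch-averaged center loss."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= state.centers.shape[0]:
        raise ValueError("label out of range of the configured class centers")
    ce = ag.softmax_cross_entropy(logits, labels)
    if state.lambda_ == 0.0:
        return ce
    cl = ag.center_loss(embeddings, state.centers.astype(embeddings.data.dtype), labels)
    return ag.add(ce, ag.scale(cl, state.lambda_))


def update_centers(embeddings, labels, state: LossState) -> LossState:
    """Moving-average center update: c <- c - alpha * sum(c - x_i) / (1 + n_c).

    Only classes present in the batch move; the damping by ``1 + n_c``
    keeps centers stable when a class dominates a batch.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    centers = state.centers.copy()
    for cls in np.unique(labels):
        mask = labels == cls
        count = int(mask.sum())
        delta = (centers[cls] - emb[mask]).sum(axis=0) / (1.0 + count)
        centers[cls] = centers[cls] - state.alpha * delta
    return replace(state, centers=centers)


def _augment_batch(batch: np.ndarray, config: TrainConfig, rng) -> np.ndarray:
    """Light augmentation on NCHW batches: integer shifts and horizontal flips."""
    out = batch
    if config.augment_flip:
        flip = rng.random(len(out)) < 0.5
        if flip.any():
            out = out.copy()
            out[flip] = out[flip, :, :, ::-1]
    if config.augment_shift:
        shifted = np.empty_like(out)
        for i, img in enumerate(out):
            dr, dc = rng.integers(-2, 3, size=2)
            shifted[i] = np.roll(img, (dr, dc), axis=(1, 2))
        out = shifted
    if config.augment_rotate:
        from scipy.ndimage import rotate

        out = out.copy() if out is batch else out
        for i in range(len(out)):
            if rng.random() < 0.5:
                angle = rng.uniform(-10.0, 10.0)
                out[i] = rotate(out[i], angle, axes=(1, 2), reshape=False, order=1, mode="nearest")
    return out


def _to_nchw(stacks: np.ndarray, dtype=np.float32) -> np.ndarray:
    arr = np.asarray(stacks, dtype=dtype)
    if arr.ndim != 4:
        raise ValueError(f"expected (n, H, W, C) stacks, got shape {arr.shape}")
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def _forward_in_batches(model: EmbeddingNetwork, x_nchw: np.ndarray, batch_size: int = 32):
    embeddings, logits = [], []
    for start in range(0, len(x_nchw), batch_size):
        emb, logit = model.forward(Tensor(x_nchw[start : start + batch_size]))
        embeddings.append(emb.data)
        logits.append(logit.data)
    return np.concatenate(embeddings), np.concatenate(logits)


def train(model: EmbeddingNetwork, dataset, config: TrainConfig, state: LossState):
    """Train under the joint loss with early stopping on validation accuracy.

    ``dataset`` is ``(stacks, labels)`` with stacks of shape (n, H, W, 4);
    a stratified validation split of ``config.validation_fraction`` is held
    out internally.  Returns ``(model, history, state)`` with the model
    restored to its best-validation-accuracy weights; ``history`` records
    per-epoch train/validation loss and accuracy.
    """
    stacks, labels = dataset
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")
    x = _to_nchw(stacks)
    idx_train, idx_val = train_test_split(
        np.arange(len(labels)),
        test_size=config.validation_fraction,
        stratify=labels,
        random_state=config.seed,
    )
    x_train, y_train = x[idx_train], labels[idx_train]
    x_val, y_val = x[idx_val], labels[idx_val]

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_loss": [], "train_accuracy": [], "val_loss": [], "val_accuracy": []}
    best_val_acc = -np.inf
    best_state = None
    best_centers = state.centers.copy()
    epochs_since_best = 0

    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(x_train))
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            take = order[start : start + config.batch_size]
            xb = _augment_batch(x_train[take], config, rng)
            yb = y_train[take]
            emb, logits = model.forward(Tensor(xb))
            loss = joint_loss(logits, emb, yb, state)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            state = update_centers(emb.data, yb, state)
            epoch_loss += float(loss.data) * len(take)
            epoch_correct += int((logits.data.argmax(axis=1) == yb).sum())
        history["train_loss"].append(epoch_loss / len(order))
        history["train_accuracy"].append(epoch_correct / len(order))

        model.eval()
        val_emb, val_logits = _forward_in_batches(model, x_val)
        val_pred = val_logits.argmax(axis=1)
        val_acc = float((val_pred == y_val).mean())
        val_ce = ag.softmax_cross_entropy(Tensor(val_logits), y_val)
        val_cl = 0.5 * float(
            np.mean(np.sum((val_emb - state.centers[y_val]) ** 2, axis=1))
        )
        history["val_loss"].append(float(val_ce.data) + state.lambda_ * val_cl)
        history["val_accuracy"].append(val_acc)

        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            best_centers = state.centers.copy()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.early_stopping_patience:
                logger.info(
                    "early stopping at epoch %d (best val accuracy %.3f)",
                    epoch + 1, best_val_acc,
                )
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
        state = replace(state, centers=best_centers)
    model.eval()
    return model, history, state


def extract_embeddings(model: EmbeddingNetwork, stacks) -> np.ndarray:
    """Deterministic 32-d embeddings (inference mode) in input order."""
    model.eval()
    x = _to_nchw(stacks)
    expected = model.spec.input_size
    if x.shape[2] != expected or x.shape[3] != expected or x.shape[1] != model.spec.in_channels:
        raise ValueError(
            f"stacks of shape {x.shape[1:]} do not match the model input "
            f"({model.spec.in_channels}, {expected}, {expected})"
        )
    emb, _ = _forward_in_batches(model, x)
    return emb


def save_checkpoint(model: EmbeddingNetwork, path, *, state: LossState | None = None,
                    train_config: TrainConfig | None = None, manifest_hash: str | None = None):
    """Persist weights as .npz with a JSON sidecar of hyperparameters."""
    import pathlib

    path = pathlib.Path(path)
    arrays = model.state_arrays()
    if state is not None:
        arrays["__centers__"] = state.centers
    np.savez_compressed(path, **arrays)
    sidecar = {
        "architecture": model.spec.to_dict(),
        "n_classes": model.n_classes,
        "dropout_rate": model.dropout_rate,
        "loss": None if state is None else {"lambda": state.lambda_, "alpha": state.alpha},
        "train_config": None if train_config is None else train_config.__dict__,
        "manifest_hash": manifest_hash,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path) -> tuple[EmbeddingNetwork, LossState | None]:
    import pathlib

    path = pathlib.Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    arch = sidecar["architecture"]
    spec = ArchitectureSpec(
        preset=arch["preset"],
        input_size=arch["input_size"],
        in_channels=arch["in_channels"],
        stem_width=arch["stem_width"],
        stage_widths=tuple(arch["stage_widths"]),
        residual_width=arch["residual_width"],
        residual_repeats=arch["residual_repeats"],
        embedding_dim=arch["embedding_dim"],
    )
    model = build_network(spec, sidecar["n_classes"], dropout_rate=sidecar["dropout_rate"])
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    arrays = {k: data[k] for k in data.files if k != "__centers__"}
    model.load_state_arrays(arrays)
    model.eval()
    state = None
    if "__centers__" in data.files and sidecar.get("loss"):
        state = LossState(
            centers=data["__centers__"],
            lambda_=sidecar["loss"]["lambda"],
            alpha=sidecar["loss"]["alpha"],
        )
    return model, state


class AttentionEmbeddingClassifier(BaseEstimator, ClassifierMixin, TransformerMixin):
    """scikit-learn estimator facade over the embedding network.

    ``fit(X, y)`` trains on 4-channel stacks of shape (n, H, W, 4);
    ``predict`` returns softmax-argmax classes, ``transform`` the 32-d
    retrieval embeddings.
    """

    def __init__(self, preset: str = "reduced", lambda_center: float = 0.002,
                 center_update_rate: float = 0.5, epochs: int = 500,
                 batch_size: int = 16, learning_rate: float = 1e-4,
                 early_stopping_patience: int = 20, dropout_rate: float = 0.5,
                 augment_shift: bool = True, augment_flip: bool = True,
                 augment_rotate: bool = False, validation_fraction: float = 0.15,
                 seed: int = 0):
        self.preset = preset
        self.lambda_center = lambda_center
        self.center_update_rate = center_update_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.early_stopping_patience = early_stopping_patience
        self.dropout_rate = dropout_rate
        self.augment_shift = augment_shift
        self.augment_flip = augment_flip
        self.augment_rotate = augment_rotate
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            early_stopping_patience=self.early_stopping_patience,
            validation_fraction=self.validation_fraction,
            augment_shift=self.augment_shift,
            augment_flip=self.augment_flip,
            augment_rotate=self.augment_rotate,
            dropout_rate=self.dropout_rate,
            seed=self.seed,
        )

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, encoded = np.unique(y, return_inverse=True)
        spec = ArchitectureSpec.from_preset(self.preset)
        model = build_network(
            spec, len(self.classes_), seed=self.seed, dropout_rate=self.dropout_rate
        )
        state = LossState.init(
            len(self.classes_), spec.embedding_dim,
            lambda_=self.lambda_center, alpha=self.center_update_rate,
        )
        model, history, state = train(model, (X, encoded), self._train_config(), state)
        self.model_ = model
        self.history_ = history
        self.loss_state_ = state
        self.n_features_in_ = int(np.prod(np.asarray(X).shape[1:]))
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        self.model_.eval()
        _, logits = _forward_in_batches(self.model_, _to_nchw(X))
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return ag.softmax_probs(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return extract_embeddings(self.model_, X)
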