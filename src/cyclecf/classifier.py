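"""The binary softmax CNN that the counterfactual generator explains.

An AlexNet-style network — five convolutional stages followed by three
fully connected stages ending in a two-unit softmax — trained with SGD +
momentum against a mean-squared-error loss on one-hot targets, with L2
regularization on all weights.  The exact layer widths are this package's
own compact stand-in for the canonical topology; the explanation machinery
only requires *some* binary classifier exposing the softmax pair
``C2(img) = (p_X, p_Y)``.

Class order is fixed everywhere as (X, Y) = (normal, opacity); one-hot
targets are (1, 0) for X and (0, 1) for Y, the same convention as the
counterfactual target vectors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, fbeta_score

from . import nn
from .data import CorpusPartitions
from .exceptions import (ConfigurationError, DivergenceError, ParameterError,
                         ShapeError)
from .images import Label, LabeledImage

__all__ = [
    "ClassProbability", "ClassifierConfig", "ClassifierMetrics",
    "AlexNetSmall", "build_classifier", "train_classifier",
    "predict_probabilities", "evaluate_classifier",
    "save_classifier", "load_classifier",
]


@dataclass(frozen=True)
class ClassProbability:
    """The classifier's softmax pair ``(p_X, p_Y)``."""

    p_x: float
    p_y: float

    def __post_init__(self):
        if self.p_x < 0 or self.p_y < 0 or abs(self.p_x + self.p_y - 1.0) > 1e-6:
            raise ParameterError(
                f"({self.p_x}, {self.p_y}) is not a probability pair")

    @property
    def predicted_label(self) -> Label:
        # tie p_X == p_Y resolves to X: deterministic, conservative to normal
        return Label.CLASS_Y if self.p_y > self.p_x else Label.CLASS_X

    def as_array(self) -> np.ndarray:
        return np.array([self.p_x, self.p_y], dtype=np.float32)


@dataclass(frozen=True)
class ClassifierConfig:
    """Training configuration. Defaults follow the full-scale recipe
    (SGD, lr 1e-4, momentum 0.9, batch 32, MSE, 1000 epochs); toy runs
    override ``epochs`` and ``learning_rate``."""

    optimizer: str = "sgd"
    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 1000
    loss: str = "mse"
    l2_weight: float = 1e-4
    input_size: int = 512

    def __post_init__(self):
        if self.learning_rate < 0 or self.momentum < 0 or self.l2_weight < 0:
            raise ParameterError("rates must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ParameterError("batch_size and epochs must be >= 1")
        if self.optimizer != "sgd" or self.loss != "mse":
            raise ParameterError("supported: optimizer='sgd', loss='mse'")


@dataclass(frozen=True)
class ClassifierMetrics:
    accuracy: float
    f1: float
    f2: float
    confusion: np.ndarray   # rows true (X, Y), cols predicted (X, Y)

    def to_json(self) -> str:
        return json.dumps({"accuracy": self.accuracy, "f1": self.f1,
                           "f2": self.f2,
                           "confusion": self.confusion.tolist()})


class AlexNetSmall(nn.Module):
    """Five conv stages + three FC stages + 2-unit softmax, single channel.

    Spatial downsampling is /16 (one stride-2 conv, three 2x2 pools), so
    ``input_size`` must be a multiple of 16 and at least 32.  Doubling the
    input size changes only the first fully connected stage's fan-in.
    """

    WIDTHS = (32, 64, 96, 96, 64)

    def __init__(self, input_size: int, rng: np.random.Generator):
        super().__init__()
        if input_size % 16 or input_size < 32:
            raise ConfigurationError(
                f"input_size must be a multiple of 16 and >= 32, got {input_size}")
        self.input_size = input_size
        w = self.WIDTHS
        self.conv1 = nn.Conv2d(1, w[0], 5, stride=2, padding=2, rng=rng)
        self.conv2 = nn.Conv2d(w[0], w[1], 5, padding=2, rng=rng)
        self.conv3 = nn.Conv2d(w[1], w[2], 3, padding=1, rng=rng)
        self.conv4 = nn.Conv2d(w[2], w[3], 3, padding=1, rng=rng)
        self.conv5 = nn.Conv2d(w[3], w[4], 3, padding=1, rng=rng)
        feat = w[4] * (input_size // 16) ** 2
        self.fc1 = nn.Linear(feat, 256, rng=rng)
        self.fc2 = nn.Linear(256, 64, rng=rng)
        self.fc3 = nn.Linear(64, 2, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """Input: (N, 1, S, S) in [0, 1]. Output: softmax probabilities (N, 2)."""
        if x.ndim != 4 or x.shape[2] != self.input_size or x.shape[3] != self.input_size:
            raise ShapeError(
                f"expected (N, 1, {self.input_size}, {self.input_size}), "
                f"got {x.shape}")
        h = self.conv1(x).relu().max_pool2d()
        h = self.conv2(h).relu().max_pool2d()
        h = self.conv3(h).relu()
        h = self.conv4(h).relu()
        h = self.conv5(h).relu().max_pool2d()
        h = h.reshape(x.shape[0], -1)
        h = self.fc1(h).relu()
        h = self.fc2(h).relu()
        logits = self.fc3(h)
        # softmax is shift-invariant; subtracting the detached row-max is exact
        z = logits - logits.data.max(axis=1, keepdims=True)
        e = z.exp()
        return e / e.sum(axis=1, keepdims=True)


def build_classifier(config: ClassifierConfig, seed: int = 0) -> AlexNetSmall:
    """Deterministically build the network from config and seed."""
    return AlexNetSmall(config.input_size, np.random.default_rng(seed))


def _as_batch(images, input_size: int) -> np.ndarray:
    """Stack LabeledImages / 2-D arrays into an (N, 1, S, S) float32 batch."""
    arrs = []
    for im in images:
        px = im.pixels if isinstance(im, LabeledImage) else np.asarray(im)
        if px.shape != (input_size, input_size):
            raise ShapeError(f"image shape {px.shape} != ({input_size}, {input_size})")
        arrs.append(px)
    return np.stack(arrs).astype(np.float32)[:, None, :, :]


def _one_hot(labels: list[Label]) -> np.ndarray:
    out = np.zeros((len(labels), 2), dtype=np.float32)
    for i, lab in enumerate(labels):
        out[i, lab.index] = 1.0
    return out


def train_classifier(classifier: AlexNetSmall, partitions: CorpusPartitions,
                     config: ClassifierConfig, seed: int = 0,
                     ) -> dict[str, list[float]]:
    """Train by SGD with momentum on MSE against one-hot targets.

    Returns the per-epoch loss history ``{"train_loss": [...],
    "val_loss": [...]}`` (one entry per epoch each).
    """
    if not partitions.train or not partitions.validation:
        raise ParameterError("train and validation partitions must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    opt = nn.SGD(classifier.parameters(), lr=config.learning_rate,
                 momentum=config.momentum, weight_decay=2.0 * config.l2_weight)
    train = list(partitions.train)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        rng.shuffle(train)
        losses = []
        for start in range(0, len(train), config.batch_size):
            batch = train[start:start + config.batch_size]
            x = nn.Tensor(_as_batch(batch, config.input_size))
            target = _one_hot([im.label for im in batch])
            probs = classifier(x)
            loss = ((probs - target) ** 2).mean()
            if not np.isfinite(loss.item()):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        val_probs = _predict_batched(classifier, partitions.validation)
        val_target = _one_hot([im.label for im in partitions.validation])
        history["val_loss"].append(float(np.mean((val_probs - val_target) ** 2)))
    return history


def _predict_batched(classifier: AlexNetSmall, images, batch: int = 64) -> np.ndarray:
    out = []
    for start in range(0, len(images), batch):
        x = nn.Tensor(_as_batch(images[start:start + batch], classifier.input_size))
        out.append(classifier(x).data)
    return np.concatenate(out, axis=0)


def predict_probabilities(classifier: AlexNetSmall, image
                          ) -> ClassProbability | list[ClassProbability]:
    """Softmax probabilities for one image (LabeledImage or 2-D array) or a
    list/3-D stack of them. Deterministic forward pass."""
    if isinstance(image, LabeledImage):
        single = True
    elif isinstance(image, (list, tuple)):
        single = False
    else:
        single = np.asarray(image).ndim == 2
    images = [image] if single else list(image)
    probs = _predict_batched(classifier, images)
    result = [ClassProbability(float(p[0]), float(p[1])) for p in probs]
    return result[0] if single else result


def evaluate_classifier(classifier: AlexNetSmall, test: list[LabeledImage]
                        ) -> ClassifierMetrics:
    """Accuracy, F1 and F2 (class Y = positive) from hard-label predictions."""
    if not test:
        raise ParameterError("test set is empty")
    probs = _predict_batched(classifier, test)
    # tie-break to X: predict Y only when p_Y strictly exceeds p_X
    pred = (probs[:, 1] > probs[:, 0]).astype(int)
    true = np.array([im.label.index for im in test])
    cm = confusion_matrix(true, pred, labels=[0, 1])
    acc = float((pred == true).mean())
    f1 = float(fbeta_score(true, pred, beta=1, pos_label=1, zero_division=0))
    f2 = float(fbeta_score(true, pred, beta=2, pos_label=1, zero_division=0))
    return ClassifierMetrics(accuracy=acc, f1=f1, f2=f2, confusion=cm)


def save_classifier(classifier: AlexNetSmall, config: ClassifierConfig,
                    path: str | Path) -> Path:
    """Checkpoint: parameter blob (npz) + config echo (json sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **classifier.state_dict())
    path.with_suffix(".json").write_text(json.dumps(asdict(config)))
    return path


def load_classifier(path: str | Path) -> tuple[AlexNetSmall, ClassifierConfig]:
    path = Path(path)
    config = ClassifierConfig(**json.loads(path.with_suffix(".json").read_text()))
    clf = build_classifier(config)
    with np.load(path) as blob:
        clf.load_state_dict({k: blob[k] for k in blob.files})
    return clf, config
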