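"""Eight-stage hierarchical image classifier (NumPy surrogate).

The surrogate mirrors the stage taxonomy of a classic deep convolutional
classifier: five convolutional stages (with 2x2 max pooling after stages 1,
2 and 5), two fully-connected ReLU stages, and a softmax output stage.  It
is deliberately small — the downstream representational analyses only need
*a* trained hierarchy with per-stage activations and exact input gradients,
not a large-scale network.

A real pretrained AlexNet can be plugged in through :class:`FeatureExtractor`
(see :func:`load_alexnet_adapter`); nothing in the pipeline or tests depends
on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Conv2D, Dense, Flatten, MaxPool2, ReLU, softmax

STAGE_NAMES = ("L1", "L2", "L3", "L4", "L5", "L6", "L7", "L8")
#: stages followed by 2x2 max pooling (mirrors pooling placement at 1, 2, 5)
POOLED_STAGES = frozenset({"L1", "L2", "L5"})


class TrainingError(RuntimeError):
    """Surrogate failed to reach the required held-out accuracy."""


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class StageSpec:
    name: str
    kind: str  # conv+relu+pool | conv+relu | fully-connected+relu | softmax-output
    width: int


@dataclass
class ActivationStack:
    """Flattened activations of all 8 stages plus output probabilities."""

    per_stage: dict[str, np.ndarray]
    probabilities: np.ndarray
    top1: int

    def __post_init__(self):
        missing = [s for s in STAGE_NAMES if s not in self.per_stage]
        if missing:
            raise DataError(f"activation stack missing stages {missing}")


@dataclass
class SurrogateConfig:
    image_size: int = 32
    n_channels: int = 3
    n_classes: int = 40
    conv_channels: tuple[int, ...] = (8, 16, 16, 16, 16)
    fc_widths: tuple[int, ...] = (64, 64)
    kernel: int = 3

    def __post_init__(self):
        if self.image_size % 8:
            raise ConfigurationError("image_size must be divisible by 8 (three 2x2 pools)")
        if len(self.conv_channels) != 5 or len(self.fc_widths) != 2:
            raise ConfigurationError("surrogate needs 5 conv widths and 2 fc widths")


class SurrogateModel:
    """Trainable 8-stage classifier over images in [0, 255], shape (H, W, C)."""

    def __init__(self, config: SurrogateConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        cc = c.conv_channels
        s_after_pool3 = c.image_size // 8
        flat_dim = cc[4] * s_after_pool3 * s_after_pool3
        self._stages: list[tuple[str, list]] = [
            ("L1", [Conv2D(c.n_channels, cc[0], c.kernel, rng), ReLU(), MaxPool2()]),
            ("L2", [Conv2D(cc[0], cc[1], c.kernel, rng), ReLU(), MaxPool2()]),
            ("L3", [Conv2D(cc[1], cc[2], c.kernel, rng), ReLU()]),
            ("L4", [Conv2D(cc[2], cc[3], c.kernel, rng), ReLU()]),
            ("L5", [Conv2D(cc[3], cc[4], c.kernel, rng), ReLU(), MaxPool2()]),
            ("L6", [Flatten(), Dense(flat_dim, c.fc_widths[0], rng), ReLU()]),
            ("L7", [Dense(c.fc_widths[0], c.fc_widths[1], rng), ReLU()]),
            ("L8", [Dense(c.fc_widths[1], c.n_classes, rng)]),
        ]
        self.val_accuracy_: float | None = None

    # -- low-level batch passes -------------------------------------------

    def _layers(self):
        for _, layers in self._stages:
            yield from layers

    def _forward_batch(self, images: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """images (N, H, W, C) in [0, 255] -> (logits, flattened stage activations)."""
        if images.ndim != 4 or images.shape[1:] != self.input_shape:
            raise DataError(
                f"expected images of shape (N,)+{self.input_shape}, got {images.shape}"
            )
        x = (np.asarray(images, dtype=np.float64) / 255.0 - 0.5).transpose(0, 3, 1, 2)
        acts: dict[str, np.ndarray] = {}
        for name, layers in self._stages:
            for layer in layers:
                x = layer.forward(x)
            acts[name] = x.reshape(x.shape[0], -1).copy()
        return x, acts  # x are the L8 logits

    def _backward_batch(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop from L8 logits to pixel space (0-255 scale), (N, H, W, C)."""
        d = dlogits
        for _, layers in reversed(self._stages):
            for layer in reversed(layers):
                d = layer.backward(d)
        return d.transpose(0, 2, 3, 1) / 255.0

    @property
    def input_shape(self) -> tuple[int, int, int]:
        c = self.config
        return (c.image_size, c.image_size, c.n_channels)

    @property
    def stage_specs(self) -> list[StageSpec]:
        kinds = {
            "L1": "conv+relu+pool", "L2": "conv+relu+pool", "L3": "conv+relu",
            "L4": "conv+relu", "L5": "conv+relu+pool", "L6": "fully-connected+relu",
            "L7": "fully-connected+relu", "L8": "softmax-output",
        }
        widths = list(self.config.conv_channels) + list(self.config.fc_widths) + [
            self.config.n_classes
        ]
        return [StageSpec(n, kinds[n], w) for n, w in zip(STAGE_NAMES, widths)]

    # -- public inference API ---------------------------------------------

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        logits, _ = self._forward_batch(images)
        return softmax(logits)

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            for k, v in layer.params.items():
                out[f"{i}:{k}"] = v
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Parameters to ``<path>`` (.npz) with a JSON sidecar of stage specs."""
        path = Path(path)
        np.savez(path, **self.parameters())
        sidecar = {
            "config": {
                "image_size": self.config.image_size,
                "n_channels": self.config.n_channels,
                "n_classes": self.config.n_classes,
                "conv_channels": list(self.config.conv_channels),
                "fc_widths": list(self.config.fc_widths),
                "kernel": self.config.kernel,
            },
            "stages": [vars(s) for s in self.stage_specs],
            "val_accuracy": self.val_accuracy_,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        cfg["fc_widths"] = tuple(cfg["fc_widths"])
        model = cls(SurrogateConfig(**cfg))
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz") if not path.exists() else path
        with np.load(path if path.exists() else path.with_suffix(".npz")) as data:
            params = dict(data)
        for i, layer in enumerate(model._layers()):
            for k in layer.params:
                layer.params[k] = params[f"{i}:{k}"]
        model.val_accuracy_ = meta.get("val_accuracy")
        return model


def forward_with_activations(model: SurrogateModel, image: np.ndarray) -> ActivationStack:
    """Run one image through the classifier, returning all 8 stage vectors.

    The L8 entry holds the softmax probabilities (not the raw logits), so the
    recorded stack is exactly what downstream representational analyses use.
    """
    logits, acts = model._forward_batch(np.asarray(image)[None])
    probs = softmax(logits)[0]
    acts = {k: v[0] for k, v in acts.items()}
    acts["L8"] = probs.copy()
    return ActivationStack(per_stage=acts, probabilities=probs, top1=int(np.argmax(probs)))


def input_gradient(
    model: SurrogateModel, image: np.ndarray, class_id: int, *, of: str = "prob"
) -> np.ndarray:
    """Gradient of the class score with respect to pixels (0-255 scale).

    ``of='prob'`` differentiates the softmax probability P_c (the default,
    matching the adversarial-noise objective); ``of='logprob'`` differentiates
    log P_c.
    """
    if not 0 <= class_id < model.config.n_classes:
        raise ConfigurationError(f"class_id {class_id} outside [0, {model.config.n_classes})")
    logits, _ = model._forward_batch(np.asarray(image, dtype=np.float64)[None])
    p = softmax(logits)
    onehot = np.zeros_like(p)
    onehot[0, class_id] = 1.0
    if of == "prob":
        dlogits = p[0, class_id] * (onehot - p)
    elif of == "logprob":
        dlogits = onehot - p
    else:
        raise ConfigurationError(f"unknown gradient target {of!r}")
    return model._backward_batch(dlogits)[0]


def train_surrogate(
    stimuli: np.ndarray,
    labels: np.ndarray,
    epochs: int = 30,
    seed: int = 0,
    *,
    config: SurrogateConfig | None = None,
    learning_rate: float = 2e-3,
    betas: tuple[float, float] = (0.9, 0.999),
    batch_size: int = 32,
    val_fraction: float = 0.25,
    accuracy_threshold: float | None = 0.95,
) -> SurrogateModel:
    """Train the 8-stage surrogate with minibatch Adam, seeded.

    A stratified ``val_fraction`` of the stimuli is held out; if the final
    held-out accuracy falls below ``accuracy_threshold`` a
    :class:`TrainingError` with diagnostics is raised (pass ``None`` to skip
    the check, e.g. for tiny smoke runs).
    """
    stimuli = np.asarray(stimuli, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ConfigurationError("need at least 2 classes to train a classifier")
    counts = np.bincount(labels, minlength=classes.max() + 1)[classes]
    if accuracy_threshold is not None and counts.min() < 20:
        raise ConfigurationError(
            f"need >= 20 images per class (got min {counts.min()}); "
            "pass accuracy_threshold=None for smoke runs"
        )
    if config is None:
        h, w, c = stimuli.shape[1:]
        config = SurrogateConfig(image_size=h, n_channels=c, n_classes=int(classes.max()) + 1)
    model = SurrogateModel(config, seed=seed)
    rng = np.random.default_rng(seed + 1)

    # stratified holdout
    val_idx = []
    for cl in classes:
        idx = np.flatnonzero(labels == cl)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * idx.size))) if val_fraction > 0 else 0
        val_idx.extend(idx[:n_val])
    val_idx = np.array(sorted(val_idx), dtype=int)
    train_idx = np.setdiff1d(np.arange(labels.size), val_idx)

    x_tr, y_tr = stimuli[train_idx], labels[train_idx]
    b1, b2 = betas
    eps = 1e-8
    moments = {
        id(l): {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in l.params.items()}
        for l in model._layers()
    }
    n = x_tr.shape[0]
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            logits, _ = model._forward_batch(x_tr[batch])
            probs = softmax(logits)
            onehot = np.zeros_like(probs)
            onehot[np.arange(batch.size), y_tr[batch]] = 1.0
            model._backward_batch((probs - onehot) / batch.size)
            step += 1
            for layer in model._layers():
                for k, g in layer.grads.items():
                    m1, m2 = moments[id(layer)][k]
                    m1 *= b1
                    m1 += (1 - b1) * g
                    m2 *= b2
                    m2 += (1 - b2) * g * g
                    mhat = m1 / (1 - b1**step)
                    vhat = m2 / (1 - b2**step)
                    layer.params[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)

    if val_idx.size:
        val_probs = model.predict_proba(stimuli[val_idx])
        acc = float(np.mean(val_probs.argmax(axis=1) == labels[val_idx]))
    else:
        acc = float("nan")
    model.val_accuracy_ = acc
    if accuracy_threshold is not None and not acc >= accuracy_threshold:
        tr_probs = model.predict_proba(x_tr)
        tr_acc = float(np.mean(tr_probs.argmax(axis=1) == y_tr))
        raise TrainingError(
            f"held-out accuracy {acc:.3f} < {accuracy_threshold} "
            f"(train accuracy {tr_acc:.3f}, {epochs} epochs, lr={learning_rate}, "
            f"{classes.size} classes, {n} training images)"
        )
    return model


class FeatureExtractor:
    """Contract for plugging a real pretrained network into the pipeline.

    Implementations map an image to an :class:`ActivationStack` with the same
    8-stage taxonomy the surrogate exposes.  Loaded lazily; never required.
    """

    input_shape: tuple[int, int, int]

    def forward_with_activations(self, image: np.ndarray) -> ActivationStack:
        raise NotImplementedError

    def input_gradient(self, image: np.ndarray, class_id: int) -> np.ndarray:
        raise NotImplementedError


def load_alexnet_adapter():  # pragma: no cover - optional heavy dependency
    """Return a :class:`FeatureExtractor` backed by torchvision's AlexNet.

    Requires the optional ``torch`` extra; images are resized to 227x227 as
    the pretrained network expects.
    """
    try:
        from ._alexnet_adapter import AlexNetAdapter
    except ImportError as exc:
        raise ImportError(
            "the real-AlexNet adapter needs the optional 'torch' extra"
        ) from exc
    return AlexNetAdapter()
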