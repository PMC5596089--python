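"""The 8-weight-layer crop classifier: four 3x3 conv stages (32, 64, 128,
256 kernels, each ReLU + 2x2 max-pool) feeding four fully connected stages
(256, 128, 64, 4) with 0.5 dropout between the last two, ending in a 4-way
softmax over {background, cup, bottle, can}.

Input size is configurable (the reference scale is 3x200x200; tests run
3x32x32); each spatial side must survive four halvings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam, Conv2D, Dense, Dropout, Flatten, Layer, MaxPool2x2, ReLU,
    cross_entropy_grad, softmax,
)

__all__ = ["CnnSpec", "Cnn", "build", "train", "predict", "CLASSES"]

CLASSES = ("background", "cup", "bottle", "can")


@dataclass(frozen=True)
class CnnSpec:
    input_shape: tuple[int, int, int] = (3, 200, 200)   # C, H, W
    conv_channels: tuple[int, ...] = (32, 64, 128, 256)
    kernel: int = 3
    fc_sizes: tuple[int, ...] = (256, 128, 64, 4)
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if self.fc_sizes[-1] != len(CLASSES):
            raise ValueError(f"final layer width must be {len(CLASSES)}")


@dataclass
class Cnn:
    spec: CnnSpec
    layers: list[Layer]
    rng: np.random.Generator

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def stages(self) -> list[str]:
        """Machine-checkable architecture listing."""
        return [layer.describe() for layer in self.layers]

    def parameter_counts(self) -> list[tuple[str, int]]:
        return [(layer.describe(), layer.n_params) for layer in self.layers if layer.params]

    @property
    def n_params(self) -> int:
        return sum(n for _, n in self.parameter_counts())


def build(spec: CnnSpec = CnnSpec(), seed: int = 0) -> Cnn:
    """Assemble the network; raises if any pooling stage would collapse the
    feature map."""
    rng = np.random.default_rng(seed)
    c, h, w = spec.input_shape
    layers: list[Layer] = []
    for stage, out_c in enumerate(spec.conv_channels, start=1):
        layers.append(Conv2D(c, out_c, spec.kernel, rng))
        layers.append(ReLU())
        if h // 2 < 1 or w // 2 < 1:
            raise ValueError(
                f"input {spec.input_shape[1]}x{spec.input_shape[2]} too small: "
                f"pool stage {stage} would reduce a {h}x{w} map below 1x1"
            )
        layers.append(MaxPool2x2())
        c, h, w = out_c, h // 2, w // 2
    layers.append(Flatten())
    n_in = c * h * w
    for i, n_out in enumerate(spec.fc_sizes):
        if i == len(spec.fc_sizes) - 1:
            layers.append(Dropout(spec.dropout_p, rng))
        layers.append(Dense(n_in, n_out, rng))
        if i < len(spec.fc_sizes) - 1:
            layers.append(ReLU())
        n_in = n_out
    return Cnn(spec=spec, layers=layers, rng=rng)


def _to_nchw(images: np.ndarray, spec: CnnSpec) -> np.ndarray:
    """Accept a stack of H x W x C images (or a single one) and reorder."""
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[None]
    if x.shape[3] != spec.input_shape[0]:
        raise ValueError(
            f"expected {spec.input_shape[0]} channels, got {x.shape[3]}"
        )
    if x.shape[1:3] != spec.input_shape[1:]:
        raise ValueError(
            f"expected {spec.input_shape[1]}x{spec.input_shape[2]} crops, "
            f"got {x.shape[1]}x{x.shape[2]} (resize first)"
        )
    return x.transpose(0, 3, 1, 2)


def train(
    model: Cnn,
    dataset,
    epochs: int = 5,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> dict:
    """Cross-entropy training with Adam.  Deterministic under ``seed``.

    ``dataset`` is a :class:`~mindreach.recognizer.data.CropDataset`; the
    accuracy trace holds per-epoch training (and, if present, validation)
    accuracy.
    """
    x_tr, y_tr = dataset.split_arrays("train")
    if len(y_tr) == 0:
        raise ValueError("empty training split")
    present = set(np.unique(y_tr).tolist())
    missing = [CLASSES[i] for i in range(len(CLASSES)) if i not in present]
    if missing:
        raise ValueError(f"training split is missing classes: {missing}")
    x_va, y_va = dataset.split_arrays("val")

    x_tr = _to_nchw(x_tr, model.spec)
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.layers, lr=lr)
    trace: dict = {"loss": [], "train_accuracy": [], "val_accuracy": []}
    for _ in range(epochs):
        order = rng.permutation(len(y_tr))
        losses = []
        for start in range(0, len(order), batch_size):
            batch = order[start:start + batch_size]
            logits = model.forward(x_tr[batch], train=True)
            loss, grad = cross_entropy_grad(logits, y_tr[batch])
            model.backward(grad)
            optimizer.step()
            losses.append(loss)
        trace["loss"].append(float(np.mean(losses)))
        trace["train_accuracy"].append(_accuracy(model, x_tr, y_tr))
        if len(y_va):
            trace["val_accuracy"].append(
                _accuracy(model, _to_nchw(x_va, model.spec), y_va)
            )
    return trace


def _accuracy(model: Cnn, x: np.ndarray, y: np.ndarray) -> float:
    preds = []
    for start in range(0, len(y), 64):
        logits = model.forward(x[start:start + 64], train=False)
        preds.append(np.argmax(logits, axis=1))
    return float(np.mean(np.concatenate(preds) == y))


def predict(model: Cnn, crop: np.ndarray) -> np.ndarray:
    """4-class probability vector for one H x W x 3 crop (dropout off)."""
    x = _to_nchw(crop, model.spec)
    return softmax(model.forward(x, train=False))[0]
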