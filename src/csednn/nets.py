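"""3D CNN architectures for depression diagnosis and HAM-D regression.

Classification network (one per seed ROI): an average-pooling layer, three
convolution layers (32/64/128 filters, kernels 3/3/2) with a max-pool and a
batch-norm after each of the first two, a flatten, and four fully connected
layers (500/500/500/2) with a softmax head.

Regression network: same convolutional front end but all three kernels are
3, batch-norm is applied *before* each max-pool (kernel 3), and the head is
seven fully connected layers (1028/1028/1028/512/512/512/1) ending in a
linear unit.

Every layer except the head is followed by ReLU.  Convolutions are
unpadded, stride 1.  Both builders accept reduced input sizes, filter
counts and FC widths without altering the layer order, so desk-scale tests
exercise the same code path as the full 91x109x91 configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import (
    Adam,
    AvgPool3d,
    BatchNorm3d,
    Conv3d,
    Dense,
    Flatten,
    Layer,
    MaxPool3d,
    ReLU,
    Sequential,
    cross_entropy_with_logits,
    mse_loss,
    softmax,
)

__all__ = [
    "ClassifierSpec",
    "RegressorSpec",
    "TrainConfig",
    "ShapeError",
    "architecture_summary",
    "build_classifier",
    "build_regressor",
    "predict_proba",
    "train",
    "save_model",
    "load_model",
    "small_classifier_spec",
    "small_regressor_spec",
]


class ShapeError(ValueError):
    """Input dimensions cannot survive the pooling/convolution reductions."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Diagnosis/severity classification network configuration."""

    input_shape: tuple[int, int, int] = (91, 109, 91)
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    conv_kernels: tuple[int, int, int] = (3, 3, 2)
    avgpool_kernel: int = 2
    maxpool_kernels: tuple[int, int] = (2, 2)
    fc_widths: tuple[int, ...] = (500, 500, 500, 2)


@dataclass(frozen=True)
class RegressorSpec:
    """HAM-D regression network configuration (linear head)."""

    input_shape: tuple[int, int, int] = (91, 109, 91)
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    conv_kernels: tuple[int, int, int] = (3, 3, 3)
    avgpool_kernel: int = 2
    maxpool_kernels: tuple[int, int] = (3, 3)
    fc_widths: tuple[int, ...] = (1028, 1028, 1028, 512, 512, 512, 1)


def _layer_plan(spec: ClassifierSpec | RegressorSpec) -> list[tuple[str, dict]]:
    """The ordered layer list for a spec (classification: batch-norm after
    max-pool; regression: batch-norm before max-pool)."""
    f1, f2, f3 = spec.conv_filters
    k1, k2, k3 = spec.conv_kernels
    m1, m2 = spec.maxpool_kernels
    regression = isinstance(spec, RegressorSpec)
    plan: list[tuple[str, dict]] = [("avgpool", {"kernel": spec.avgpool_kernel})]
    plan.append(("conv", {"in": 1, "out": f1, "kernel": k1}))
    if regression:
        plan += [("batchnorm", {"channels": f1}), ("maxpool", {"kernel": m1})]
    else:
        plan += [("maxpool", {"kernel": m1}), ("batchnorm", {"channels": f1})]
    plan.append(("conv", {"in": f1, "out": f2, "kernel": k2}))
    if regression:
        plan += [("batchnorm", {"channels": f2}), ("maxpool", {"kernel": m2})]
    else:
        plan += [("maxpool", {"kernel": m2}), ("batchnorm", {"channels": f2})]
    plan.append(("conv", {"in": f2, "out": f3, "kernel": k3}))
    plan.append(("flatten", {}))
    for width in spec.fc_widths:
        plan.append(("fc", {"width": width}))
    return plan


def architecture_summary(
    spec: ClassifierSpec | RegressorSpec,
) -> list[dict]:
    """Walk the layer plan symbolically, computing every output shape.

    Raises :class:`ShapeError` naming the first layer whose output would
    underflow.  Useful for auditing the architecture without allocating
    weights.
    """
    plan = _layer_plan(spec)
    shape = tuple(spec.input_shape)
    channels = 1
    flat: int | None = None
    rows = []
    for idx, (kind, info) in enumerate(plan):
        name = f"{kind}{idx}"
        if kind in ("avgpool", "maxpool"):
            k = info["kernel"]
            new = tuple(s // k for s in shape)
            if min(new) < 1:
                raise ShapeError(
                    f"layer {name} (kernel {k}) reduces shape {shape} below 1"
                )
            shape = new
            out = (channels, *shape)
        elif kind == "conv":
            k = info["kernel"]
            new = tuple(s - k + 1 for s in shape)
            if min(new) < 1:
                raise ShapeError(
                    f"layer {name} (kernel {k}) reduces shape {shape} below 1"
                )
            shape = new
            channels = info["out"]
            out = (channels, *shape)
        elif kind == "batchnorm":
            out = (channels, *shape)
        elif kind == "flatten":
            flat = channels * int(np.prod(shape))
            out = (flat,)
        elif kind == "fc":
            flat = info["width"]
            out = (flat,)
        rows.append({"layer": kind, "detail": dict(info), "output": out})
    return rows


def _build(spec: ClassifierSpec | RegressorSpec, seed: int) -> Sequential:
    summary = architecture_summary(spec)  # validates shapes first
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    flat_dim = None
    n_fc = len(spec.fc_widths)
    fc_seen = 0
    for row in summary:
        kind, info = row["layer"], row["detail"]
        if kind == "avgpool":
            layers.append(AvgPool3d(info["kernel"]))
        elif kind == "maxpool":
            layers.append(MaxPool3d(info["kernel"]))
        elif kind == "batchnorm":
            layers.append(BatchNorm3d(info["channels"]))
        elif kind == "conv":
            layers.append(Conv3d(info["in"], info["out"], info["kernel"], rng))
            layers.append(ReLU())
        elif kind == "flatten":
            layers.append(Flatten())
            flat_dim = row["output"][0]
        elif kind == "fc":
            layers.append(Dense(flat_dim, info["width"], rng))
            flat_dim = info["width"]
            fc_seen += 1
            if fc_seen < n_fc:
                layers.append(ReLU())
    return Sequential(layers)


def build_classifier(spec: ClassifierSpec = ClassifierSpec(), seed: int = 0) -> Sequential:
    """Trainable map from one CSE volume to 2-class logits (softmax head is
    applied by :func:`predict_proba` / the training loss)."""
    return _build(spec, seed)


def build_regressor(spec: RegressorSpec = RegressorSpec(), seed: int = 0) -> Sequential:
    """Trainable map from one CSE volume to a single real HAM-D estimate."""
    return _build(spec, seed)


def predict_proba(model: Sequential, x: np.ndarray) -> np.ndarray:
    """Class probabilities (rows sum to 1) in evaluation mode."""
    return softmax(model.forward(np.asarray(x, dtype=np.float32), train=False))


@dataclass
class TrainConfig:
    """Training protocol: Adam, fixed epoch cap, early stopping on
    validation loss with best-epoch weight restoration."""

    loss: str = "categorical_crossentropy"  # or "mse"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    patience: int = 60
    min_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("categorical_crossentropy", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.patience >= self.epochs:
            raise ValueError("patience must be smaller than the epoch cap")


def _loss_fn(cfg: TrainConfig):
    return cross_entropy_with_logits if cfg.loss == "categorical_crossentropy" else mse_loss


def _eval_loss(model: Sequential, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> float:
    out = model.forward(x, train=False)
    return _loss_fn(cfg)(out, y)[0]


def train(
    model: Sequential,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    cfg: TrainConfig,
) -> dict:
    """Mini-batch training with early stopping.

    Stops at the epoch cap or when validation loss has not improved by
    ``min_delta`` for ``patience`` consecutive epochs; the weights of the
    best-validation epoch are restored.  Returns a history dict with
    per-epoch train/val loss and the stopping epoch.
    """
    train_x = np.asarray(train_x, dtype=np.float32)
    val_x = np.asarray(val_x, dtype=np.float32)
    train_y = np.asarray(train_y, dtype=np.float32)
    val_y = np.asarray(val_y, dtype=np.float32)
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    loss_fn = _loss_fn(cfg)
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    wait = 0
    history: dict = {"train_loss": [], "val_loss": []}
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_x))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            out = model.forward(train_x[idx], train=True)
            loss, grad = loss_fn(out, train_y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss} at epoch {epoch}"
                )
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        val_loss = _eval_loss(model, val_x, val_y, cfg)
        history["train_loss"].append(epoch_loss / len(train_x))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    history["epochs_run"] = len(history["val_loss"])
    return history


def history_to_tsv(history: dict, path: str | Path) -> None:
    """Export per-epoch training curves as TSV (epoch, train_loss, val_loss)."""
    lines = ["epoch\ttrain_loss\tval_loss"]
    for e, (tr, va) in enumerate(
        zip(history["train_loss"], history["val_loss"]), start=1
    ):
        lines.append(f"{e}\t{tr:.8g}\t{va:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_model(model: Sequential, spec, path: str | Path) -> None:
    """Checkpoint: spec as JSON sidecar, state arrays as .npz."""
    path = Path(path)
    arrays = {f"a{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"kind": type(spec).__name__, "spec": asdict(spec)}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_model(path: str | Path, seed: int = 0) -> tuple[Sequential, object]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_cls = {"ClassifierSpec": ClassifierSpec, "RegressorSpec": RegressorSpec}[
        meta["kind"]
    ]
    raw = meta["spec"]
    spec = spec_cls(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.items()
        }
    )
    model = _build(spec, seed)
    data = np.load(path.with_suffix(".npz"))
    model.set_weights([data[f"a{i}"] for i in range(len(data.files))])
    return model, spec


def small_classifier_spec(
    input_shape: tuple[int, int, int] = (16, 20, 16),
    conv_filters: tuple[int, int, int] = (4, 8, 8),
    fc_widths: tuple[int, ...] = (32, 32, 32, 2),
) -> ClassifierSpec:
    """Desk-scale classifier: same layer order as the full network, sized
    for a toy atlas grid on one CPU (the avgpool slot uses kernel 1 so the
    stack survives the small grid)."""
    return ClassifierSpec(
        input_shape=input_shape,
        conv_filters=conv_filters,
        conv_kernels=(3, 3, 2),
        avgpool_kernel=1,
        maxpool_kernels=(2, 2),
        fc_widths=fc_widths,
    )


def small_regressor_spec(
    input_shape: tuple[int, int, int] = (16, 20, 16),
    conv_filters: tuple[int, int, int] = (4, 8, 8),
    fc_widths: tuple[int, ...] = (64, 64, 64, 32, 32, 32, 1),
) -> RegressorSpec:
    """Desk-scale regressor mirroring the full architecture's layer order."""
    return RegressorSpec(
        input_shape=input_shape,
        conv_filters=conv_filters,
        conv_kernels=(3, 3, 2),
        avgpool_kernel=1,
        maxpool_kernels=(2, 2),
        fc_widths=fc_widths,
    )
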