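"""The counting network: a compact inception-style fully convolutional model.

The network maps a zero-padded grayscale frame to a redundant count map of
the same spatial size.  Its architecture follows the Count-Ception family:
a small stem convolution, a chain of inception blocks (parallel 1x1 / 3x3
convolutions, concatenated), a 1x1 "chokepoint" that narrows the channel
dimension, two large same-padded convolutions that widen the receptive
field up to the count kernel k, and a final 1x1 chokepoint down to one
output channel.  Every convolution uses same padding so spatial size is
preserved end to end — a requirement of the sum / k^2 count rule — and the
composed nominal receptive field must be at least k, otherwise an output
unit cannot see the whole window it is asked to count.

Batch normalization follows every convolution except the final output
layer, all activations are ReLU, weights are Glorot-uniform, and training
uses Adam on a mean-absolute-error pixel loss (mean-squared-error is
available as an option).  The raw network output is unconstrained; negative
values are clipped to zero when a map is turned into a count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    ConvUnit,
    InceptionBlock,
    clipped_l2_loss_grad,
    l1_loss_grad,
    l2_loss_grad,
)
from .count_targets import CountMap, CountMapSpec, make_count_target, pad_image
from .image_io import PointAnnotations, RasterImage, luma_grayscale


class ConfigurationError(ValueError):
    """Model architecture incompatible with the requested count kernel."""


def default_large_kernels(
    kernel_size: int, stem_kernel: int = 3, n_inception_blocks: int = 5
) -> tuple[int, int]:
    """Pick the two large conv kernels so the nominal receptive field >= k.

    The stem contributes ``stem_kernel`` and each inception block 2 (its
    3x3 branch); the remainder is split evenly between the two large
    convolutions, rounded up to keep their kernels odd.
    """
    extra = kernel_size - stem_kernel - 2 * n_inception_blocks
    if extra <= 0:
        return 1, 1
    half = (extra + 1) // 2
    half += half % 2  # kernel = half+1 must be odd
    return half + 1, half + 1


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of the counting network.

    ``inception_channels`` is the per-branch width of each inception block
    (each block outputs twice that, from the concatenated 1x1 and 3x3
    branches).
    """

    kernel_size: int = 65
    n_inception_blocks: int = 5
    stem_kernel: int = 3
    stem_channels: int = 64
    inception_channels: int = 16
    chokepoint_channels: int = 16
    large_kernels: tuple[int, int] = (27, 27)
    large_channels: tuple[int, int] = (32, 16)
    batch_norm: bool = True
    bn_running_stats: bool = True

    def __post_init__(self) -> None:
        if self.n_inception_blocks < 1:
            raise ValueError("need at least one inception block")
        for ksz in (self.stem_kernel, *self.large_kernels):
            if ksz < 1 or ksz % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and positive, got {ksz}")

    @property
    def receptive_field(self) -> int:
        """Nominal receptive field of the composed network (1x1 convs add 0)."""
        return (
            self.stem_kernel
            + 2 * self.n_inception_blocks  # 3x3 branch of each block
            + (self.large_kernels[0] - 1)
            + (self.large_kernels[1] - 1)
        )

    @classmethod
    def reference(cls, kernel_size: int = 65) -> "ModelSpec":
        """Full-width instantiation for production-scale frames."""
        return cls(
            kernel_size=kernel_size,
            large_kernels=default_large_kernels(kernel_size),
        )

    @classmethod
    def compact(cls, kernel_size: int = 33) -> "ModelSpec":
        """Narrow instantiation used for small frames and the test suite."""
        return cls(
            kernel_size=kernel_size,
            stem_channels=8,
            inception_channels=4,
            chokepoint_channels=4,
            large_kernels=default_large_kernels(kernel_size),
            large_channels=(8, 8),
        )

    def describe(self) -> str:
        """Human-readable architecture report."""
        lines = [
            f"stem: {self.stem_kernel}x{self.stem_kernel} conv, {self.stem_channels} ch",
        ]
        ch = self.stem_channels
        for i in range(self.n_inception_blocks):
            lines.append(
                f"inception block {i + 1}: 1x1/{self.inception_channels} + "
                f"3x3/{self.inception_channels} -> {2 * self.inception_channels} ch"
            )
            ch = 2 * self.inception_channels
        lines.append(f"chokepoint 1: 1x1 conv, {ch} -> {self.chokepoint_channels} ch")
        for i, (ksz, c) in enumerate(zip(self.large_kernels, self.large_channels)):
            lines.append(f"large conv {i + 1}: {ksz}x{ksz}, {c} ch")
        lines.append("chokepoint 2: 1x1 conv -> 1 ch (count map)")
        lines.append(f"nominal receptive field: {self.receptive_field}")
        return "\n".join(lines)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: Adam, learning rate 1e-3, batch size 1 by default."""

    learning_rate: float = 1e-3
    batch_size: int = 1
    epochs: int = 400
    seed: int = 0
    augment: bool = True
    validation_fraction: float = 0.2
    loss: str = "mae"  # or "mse" / "clipped_mse"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.loss not in ("mae", "mse", "clipped_mse"):
            raise ValueError("loss must be 'mae', 'mse' or 'clipped_mse'")


@dataclass
class TrainResult:
    """Per-epoch losses and the best-validation weight snapshot."""

    best_weights: list[np.ndarray]
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int  # 1-based; 0 when no epoch was run


class FCNN:
    """The assembled network.  Input: float32 (1, H, W) in [0, 1]."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        if spec.receptive_field < spec.kernel_size:
            raise ConfigurationError(
                f"receptive field {spec.receptive_field} is smaller than the "
                f"count kernel {spec.kernel_size}; an output unit cannot see "
                "its whole counting window"
            )
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        bn = spec.batch_norm
        rs = spec.bn_running_stats
        layers: list = [
            ConvUnit(1, spec.stem_channels, spec.stem_kernel, rng, bn, bn_running_stats=rs)
        ]
        ch = spec.stem_channels
        for _ in range(spec.n_inception_blocks):
            block = InceptionBlock(ch, spec.inception_channels, rng, bn, bn_running_stats=rs)
            layers.append(block)
            ch = block.out_channels
        layers.append(ConvUnit(ch, spec.chokepoint_channels, 1, rng, bn, bn_running_stats=rs))
        ch = spec.chokepoint_channels
        for ksz, c in zip(spec.large_kernels, spec.large_channels):
            layers.append(ConvUnit(ch, c, ksz, rng, bn, bn_running_stats=rs))
            ch = c
        layers.append(ConvUnit(ch, 1, 1, rng, batch_norm=False, activation=False))
        self.layers = layers

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            d_out = layer.backward(d_out)
        return d_out

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out += layer.parameters()
        return out

    # -- state handling -----------------------------------------------------
    def _state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        arrays = [p for p, _ in self.parameters()]
        for layer in self.layers:
            units = layer.__dict__.get("branch1"), layer.__dict__.get("branch3")
            for unit in (layer, *units):
                bnorm = getattr(unit, "bn", None)
                if bnorm is not None:
                    arrays += [bnorm.running_mean, bnorm.running_var]
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self._state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self._state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state does not match this architecture")
        for a, s in zip(arrays, state):
            a[...] = s

    def set_norm_frozen(self, frozen: bool = True) -> None:
        """Freeze (or unfreeze) all normalization statistics.

        While frozen, training forward passes normalize by the stored
        running statistics — the exact inference-time function — and the
        statistics stop updating.  Used for calibration fine-tuning after
        the main training phase.
        """
        for layer in self.layers:
            units = (layer, layer.__dict__.get("branch1"), layer.__dict__.get("branch3"))
            for unit in units:
                bnorm = getattr(unit, "bn", None) if unit is not None else None
                if bnorm is not None:
                    bnorm.frozen = frozen

    # -- inference ----------------------------------------------------------
    def predict_map(self, padded: RasterImage) -> np.ndarray:
        """Raw (unclipped) count-map output for a padded grayscale image."""
        if padded.channels != 1:
            raise ValueError(
                "the counting model takes single-channel images; convert "
                "RGB frames to grayscale first"
            )
        x = (padded.pixels.astype(np.float32) / 255.0)[None, :, :]
        return self.forward(x, train=False)[0]


def build_model(spec: ModelSpec, seed: int = 0) -> FCNN:
    """Construct the network with Glorot-uniform weights from ``seed``."""
    return FCNN(spec, seed=seed)


def predict_count_map(model: FCNN, img: RasterImage, spec: CountMapSpec) -> CountMap:
    """Predict the redundant count map of one padded quadrant or frame.

    Negative raw outputs are clipped to zero, so the map feeds directly
    into count inference.
    """
    if spec.kernel_size != model.spec.kernel_size:
        raise ValueError(
            f"count spec k={spec.kernel_size} does not match the model "
            f"(trained for k={model.spec.kernel_size})"
        )
    raw = model.predict_map(img)
    return CountMap(values=np.clip(raw, 0.0, None), spec=spec, kind="prediction")


def _prepare_pair(
    img: RasterImage, ann: PointAnnotations, spec: CountMapSpec
) -> tuple[np.ndarray, np.ndarray]:
    gray = luma_grayscale(img)
    padded = pad_image(gray, spec.pad)
    x = (padded.pixels.astype(np.float32) / 255.0)[None, :, :]
    t = make_count_target(ann, spec).values.astype(np.float32)[None, :, :]
    return x, t


def train(
    model: FCNN,
    train_set: list[tuple[RasterImage, PointAnnotations]],
    cfg: TrainConfig,
    spec: CountMapSpec,
    val_set: list[tuple[RasterImage, PointAnnotations]] | None = None,
) -> TrainResult:
    """Train the network on (image, annotations) pairs.

    Pairs are unpadded frames or quadrants with frame-local annotations;
    padding, grayscale conversion and target construction happen here.  If
    ``val_set`` is not given, ``cfg.validation_fraction`` of the training
    pairs is split off (seeded shuffle) for validation.  With
    ``cfg.augment`` the three right-angle rotations of every training pair
    are added.  The model is left holding the weights of the epoch with
    the lowest validation loss (first occurrence on ties), and those
    weights are also returned in the result.
    """
    from .count_targets import rotate_with_annotations  # local: avoid heavy import order

    if not train_set:
        raise ValueError("training set must not be empty")
    rng = np.random.default_rng(cfg.seed)

    pairs = list(train_set)
    if val_set is None:
        idx = rng.permutation(len(pairs))
        n_val = int(round(cfg.validation_fraction * len(pairs)))
        val_pairs = [pairs[i] for i in idx[:n_val]]
        tr_pairs = [pairs[i] for i in idx[n_val:]]
    else:
        tr_pairs, val_pairs = pairs, list(val_set)

    if cfg.augment:
        augmented = []
        for img, ann in tr_pairs:
            augmented.append((img, ann))
            for angle in (90, 180, 270):
                augmented.append(rotate_with_annotations(img, ann, angle))
        tr_pairs = augmented

    tr_data = [_prepare_pair(img, ann, spec) for img, ann in tr_pairs]
    val_data = [_prepare_pair(img, ann, spec) for img, ann in val_pairs]

    loss_fn = {
        "mae": l1_loss_grad,
        "mse": l2_loss_grad,
        "clipped_mse": clipped_l2_loss_grad,
    }[cfg.loss]
    params = model.parameters()
    opt = Adam(params, learning_rate=cfg.learning_rate)

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_loss = np.inf
    best_state = model.get_state()
    best_epoch = 0

    grad_acc = [np.zeros_like(p) for p, _ in params] if cfg.batch_size > 1 else None

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(tr_data))
        epoch_losses = []
        pending = 0
        for j, i in enumerate(order):
            x, t = tr_data[i]
            pred = model.forward(x, train=True)
            loss, d_pred = loss_fn(pred, t)
            epoch_losses.append(loss)
            model.backward(d_pred)
            if cfg.batch_size == 1:
                opt.step(params)
            else:
                for acc, (_, g) in zip(grad_acc, params):
                    acc += g
                pending += 1
                if pending == cfg.batch_size or j == len(order) - 1:
                    stepped = [(p, acc / pending) for (p, _), acc in zip(params, grad_acc)]
                    opt.step(stepped)
                    for acc in grad_acc:
                        acc[...] = 0.0
                    pending = 0
        train_loss = float(np.mean(epoch_losses))
        if val_data:
            val_loss = float(
                np.mean(
                    [loss_fn(model.forward(x, train=False), t)[0] for x, t in val_data]
                )
            )
        else:
            val_loss = train_loss
        train_losses.append(train_loss)
        val_losses.append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            best_epoch = epoch + 1

    model.set_state(best_state)
    return TrainResult(
        best_weights=best_state,
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=best_epoch,
    )


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(
    model: FCNN, count_spec: CountMapSpec, path: str | Path, model_id: str = "fcnn"
) -> None:
    """Serialize weights plus both specs into one ``.npz`` checkpoint.

    Embedding the count-map spec means inference can never silently run
    with a mismatched kernel size.
    """
    meta = {
        "model_id": model_id,
        "seed": model.seed,
        "model_spec": asdict(model.spec),
        "count_spec": {"kernel_size": count_spec.kernel_size},
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model._state_arrays())}
    np.savez(Path(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[FCNN, CountMapSpec, str]:
    """Rebuild a model (+ its count spec and id) from a checkpoint file."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        ms = meta["model_spec"]
        ms["large_kernels"] = tuple(ms["large_kernels"])
        ms["large_channels"] = tuple(ms["large_channels"])
        spec = ModelSpec(**ms)
        model = FCNN(spec, seed=meta.get("seed", 0))
        n = len(model._state_arrays())
        state = [data[f"arr_{i}"] for i in range(n)]
        model.set_state(state)
    return model, CountMapSpec(**meta["count_spec"]), meta.get("model_id", "fcnn")
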