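"""The gated-inception classifier with a spatial-pyramid-pooling head.

Architecture (defaults): five gated-inception convolution stages with four
interleaved stride-2 max pools, a mean-pooling pyramid head (levels 1, 2, 4
-> 7 features per channel), and three fully connected layers with batch
normalization and dropout. Every activation is a LeakyReLU with divisor
100. The final convolution stage emits 384 channels, so the head hands
384 x 7 = 2688 features to the classifier regardless of input length.

Block structure:

* Inception-A: four gated-conv branches with kernel sizes 1, 3, 5, 7.
* Inception-B: branches 1x1, 1x1->3, 1x1->5, and pool3->1x1.
* Inception-C: branches 1x1, 1x1->3, 1x1->3->3, and pool3->1x1.

Each branch contributes ``branch_width`` channels, so a block's output has
4 x branch_width channels. The default widths (8, 12, 24, 64, 96) and FC
widths (836, 376) give exactly 3,077,382 trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np

from ..errors import BatchError, ModelConfigError
from .layers import (
    BatchNorm1d,
    Dropout,
    GatedConv1d,
    InceptionBlock,
    Layer,
    LeakyReLU,
    Linear,
    MaxPool1d,
    MaxPoolSame3,
    Sequential,
    SpatialPyramidPool,
)
from .losses import softmax


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    ``branch_widths`` holds the per-branch channel count of the five
    inception stages (each stage outputs 4x its width); ``fc_widths`` the
    two hidden fully-connected widths. ``bn_parameter`` is the running-
    statistics momentum of the batch-normalization layers.
    """

    in_channels: int = 4
    inception_a_kernel_sizes: Tuple[int, ...] = (1, 3, 5, 7)
    branch_widths: Tuple[int, int, int, int, int] = (8, 12, 24, 64, 96)
    fc_widths: Tuple[int, int] = (836, 376)
    n_classes: int = 2
    spp_levels: Tuple[int, ...] = (1, 2, 4)
    leaky_divisor: float = 100.0
    dropout_rate: float = 0.3
    bn_parameter: float = 0.5
    min_input_len: int = 200
    max_input_len: int = 800
    init_seed: int = 0

    # architecture constants (documented, not meant to vary)
    n_conv_blocks: int = 5
    n_max_pools: int = 4
    n_fc_layers: int = 3

    def __post_init__(self) -> None:
        if not self.spp_levels or list(self.spp_levels) != sorted(
            set(self.spp_levels)
        ) or self.spp_levels[0] != 1:
            raise ModelConfigError(
                "spp_levels must be strictly increasing and include 1"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ModelConfigError("dropout_rate must be in [0, 1)")
        if self.leaky_divisor <= 0:
            raise ModelConfigError("leaky_divisor must be positive")
        if len(self.branch_widths) != self.n_conv_blocks:
            raise ModelConfigError(
                f"branch_widths must have {self.n_conv_blocks} entries"
            )
        if self.min_input_len < 2 ** self.n_max_pools * max(self.spp_levels):
            raise ModelConfigError(
                "min_input_len too short to survive the pooling stack"
            )

    @property
    def final_conv_channels(self) -> int:
        return 4 * self.branch_widths[-1]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for key in ("inception_a_kernel_sizes", "branch_widths", "fc_widths",
                    "spp_levels"):
            d[key] = tuple(d[key])
        return cls(**d)


def _branch(rng, *convs) -> Sequential:
    return Sequential(*convs)


def _inception_a(in_ch: int, width: int, kernels, rng) -> InceptionBlock:
    return InceptionBlock(
        *[GatedConv1d(in_ch, width, k, rng) for k in kernels]
    )


def _inception_b(in_ch: int, width: int, rng) -> InceptionBlock:
    return InceptionBlock(
        GatedConv1d(in_ch, width, 1, rng),
        Sequential(GatedConv1d(in_ch, width, 1, rng),
                   GatedConv1d(width, width, 3, rng)),
        Sequential(GatedConv1d(in_ch, width, 1, rng),
                   GatedConv1d(width, width, 5, rng)),
        Sequential(MaxPoolSame3(), GatedConv1d(in_ch, width, 1, rng)),
    )


def _inception_c(in_ch: int, width: int, rng) -> InceptionBlock:
    return InceptionBlock(
        GatedConv1d(in_ch, width, 1, rng),
        Sequential(GatedConv1d(in_ch, width, 1, rng),
                   GatedConv1d(width, width, 3, rng)),
        Sequential(GatedConv1d(in_ch, width, 1, rng),
                   GatedConv1d(width, width, 3, rng),
                   GatedConv1d(width, width, 3, rng)),
        Sequential(MaxPoolSame3(), GatedConv1d(in_ch, width, 1, rng)),
    )


class Model(Sequential):
    """Full classifier network; forward yields logits of shape (N, 2)."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.init_seed)
        b1, b2, b3, b4, b5 = config.branch_widths
        act = lambda: LeakyReLU(config.leaky_divisor)  # noqa: E731
        drop = lambda: Dropout(config.dropout_rate)  # noqa: E731
        c_in = config.in_channels
        stages = [
            _inception_a(c_in, b1, config.inception_a_kernel_sizes, rng),
            act(), MaxPool1d(),
            _inception_a(4 * b1, b2, config.inception_a_kernel_sizes, rng),
            act(), MaxPool1d(),
            _inception_b(4 * b2, b3, rng),
            act(), MaxPool1d(),
            _inception_b(4 * b3, b4, rng),
            act(), MaxPool1d(),
            _inception_c(4 * b4, b5, rng),
            act(),
            SpatialPyramidPool(config.spp_levels),
        ]
        spp_out = config.final_conv_channels * sum(config.spp_levels)
        f1, f2 = config.fc_widths
        head = [
            Linear(spp_out, f1, rng),
            BatchNorm1d(f1, momentum=config.bn_parameter),
            act(), drop(),
            Linear(f1, f2, rng),
            BatchNorm1d(f2, momentum=config.bn_parameter),
            act(), drop(),
            Linear(f2, config.n_classes, rng),
        ]
        super().__init__(*stages, *head)
        self.config = config

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of equal-length one-hot inputs.

        Accepts (N, L, 4) one-hot matrices or (N, 4, L) channel-first
        arrays; evaluation mode, deterministic.
        """
        x = _to_channel_first(batch, self.config)
        return softmax(self.forward(x, train=False))


def _to_channel_first(batch: np.ndarray, config: ModelConfig) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim == 2:  # single (L, 4) matrix
        batch = batch[None]
    if batch.ndim != 3:
        raise BatchError(f"expected a 3-d batch, got shape {batch.shape}")
    if batch.shape[2] == 4 and batch.shape[1] != 4:
        batch = np.ascontiguousarray(batch.transpose(0, 2, 1))
    if batch.shape[1] != config.in_channels:
        raise BatchError(f"batch shape {batch.shape} has no base axis of 4")
    length = batch.shape[2]
    if not config.min_input_len <= length <= config.max_input_len:
        raise BatchError(
            f"input length {length} outside supported range "
            f"[{config.min_input_len}, {config.max_input_len}]"
        )
    return batch


def build_model(config: Optional[ModelConfig] = None) -> Model:
    """Build the network; default configuration reproduces the reference
    architecture (3,077,382 trainable parameters)."""
    return Model(config or ModelConfig())


def count_parameters(model: Layer) -> int:
    """Total size of all trainable weight/bias arrays, including gate
    convolutions and batch-norm scale/shift."""
    total = 0
    stack = [model]
    while stack:
        layer = stack.pop()
        if layer.trainable:
            total += sum(p.size for p in layer.params)
        stack.extend(layer.children())
    return total


def predict(model: Model, batch) -> np.ndarray:
    """Probability pairs for a batch of equal-length one-hot matrices.

    A list of matrices is accepted; all must share one length (the
    parallel-compute contract) or :class:`BatchError` is raised.
    """
    if isinstance(batch, (list, tuple)):
        lengths = {np.asarray(m).shape[0] for m in batch}
        if len(lengths) != 1:
            raise BatchError(
                f"mixed fragment lengths in one batch: {sorted(lengths)}"
            )
        batch = np.stack([np.asarray(m, dtype=np.float32) for m in batch])
    return model.predict_proba(batch)


def save_checkpoint(path, model: Model, extra: Optional[dict] = None) -> None:
    """Single-file checkpoint: config JSON + weights + BN running stats."""
    arrays = {f"param/{k}": v for k, v in model.named_parameters()}
    arrays.update({f"buffer/{k}": v for k, v in model.buffers()})
    arrays["config"] = np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8
    )
    if extra:
        arrays["extra"] = np.frombuffer(json.dumps(extra).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as data:
        config = ModelConfig.from_json(bytes(data["config"]).decode())
        model = Model(config)
        params = dict(model.named_parameters())
        buffers = dict(model.buffers())
        for key in data.files:
            if key.startswith("param/"):
                params[key[6:]][...] = data[key]
            elif key.startswith("buffer/"):
                buffers[key[7:]][...] = data[key]
    return model
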