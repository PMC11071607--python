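"""Dual-branch encoder/decoder segmentation network.

One shared residual convolutional encoder feeds two architecturally
identical decoders with independent parameters: a *strong* decoder trained
on trusted labels and a *weak* decoder trained on inaccurate labels. After
self-supervised warm-up the encoder is frozen and only the decoders are
fine-tuned, so the encoder doubles as a fixed feature extractor — the
transfer-learning step the refinement pipeline relies on.

The network is deliberately small and configuration-driven: ``width`` and
``depth`` scale it from desk-test size (width 8, depth 2) upward without
changing code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .nn import Tensor, add, conv2d, instance_norm, relu, softmax_channels, upsample2x
from .nn.tensor import concat_channels, no_grad, smooth3

__all__ = ["DualBranchModel", "build_model", "freeze_encoder", "parameter_checksum"]


class _ConvLayer:
    """Convolution + bias with He-normal initialization."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, dtype: np.dtype) -> None:
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(
            rng.normal(0.0, std, size=(k, k, cin, cout)).astype(dtype),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class _NormConv:
    """Convolution followed by instance norm; ReLU applied by the caller."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, dtype: np.dtype) -> None:
        self.conv = _ConvLayer(cin, cout, k, stride, pad, rng, dtype)
        self.gamma = Tensor(np.ones(cout, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(self.conv(x), self.gamma, self.beta)

    def params(self) -> list[Tensor]:
        return self.conv.params() + [self.gamma, self.beta]


class _ResBlock:
    """Residual block of two normalized convolutions: relu(x + NC(relu(NC(x))))."""

    def __init__(self, ch: int, rng: np.random.Generator, dtype: np.dtype) -> None:
        self.c1 = _NormConv(ch, ch, 3, 1, 1, rng, dtype)
        self.c2 = _NormConv(ch, ch, 3, 1, 1, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(add(x, self.c2(relu(self.c1(x)))))

    def params(self) -> list[Tensor]:
        return self.c1.params() + self.c2.params()


class _Encoder:
    def __init__(self, channels: int, width: int, depth: int,
                 rng: np.random.Generator, dtype: np.dtype) -> None:
        self.stem = _NormConv(channels, width, 3, 1, 1, rng, dtype)
        self.stages: list[tuple[_ResBlock, _NormConv]] = []
        ch = width
        for _ in range(depth):
            self.stages.append(
                (_ResBlock(ch, rng, dtype), _NormConv(ch, 2 * ch, 3, 2, 1, rng, dtype))
            )
            ch *= 2
        self.bottleneck = _ResBlock(ch, rng, dtype)
        self.out_channels = ch

    def __call__(self, x: Tensor) -> Tensor:
        return self.features(x)[0]

    def features(self, x: Tensor) -> tuple[Tensor, tuple[Tensor, ...]]:
        """Bottleneck features plus the pre-downsampling activation of each
        stage (highest resolution first), for optional skip connections."""
        h = relu(self.stem(x))
        skips: list[Tensor] = []
        for block, down in self.stages:
            h = block(h)
            skips.append(h)
            h = relu(down(h))
        return self.bottleneck(h), tuple(skips)

    def params(self) -> list[Tensor]:
        out = self.stem.params()
        for block, down in self.stages:
            out += block.params() + down.params()
        return out + self.bottleneck.params()


class _Decoder:
    """Mirror-image upsampling path. By default it has no skip connections,
    so every feature the decoder sees passes through the (freezable)
    encoder bottleneck; with ``skips=True`` each upsampling stage also
    concatenates the matching-resolution encoder activation."""

    def __init__(self, width: int, depth: int, classes: int,
                 rng: np.random.Generator, dtype: np.dtype,
                 skips: bool = False) -> None:
        self.skips = skips
        self.ups: list[_NormConv] = []
        ch = width * 2**depth
        for _ in range(depth):
            cin = ch + (ch // 2 if skips else 0)
            self.ups.append(_NormConv(cin, ch // 2, 3, 1, 1, rng, dtype))
            ch //= 2
        self.refine = _NormConv(ch, ch, 3, 1, 1, rng, dtype)
        self.head = _ConvLayer(ch, classes, 1, 1, 0, rng, dtype)

    def __call__(self, feat: Tensor, skips: tuple[Tensor, ...] = ()) -> Tensor:
        if self.skips and len(skips) != len(self.ups):
            raise ValueError("decoder built with skips requires one encoder "
                             "activation per upsampling stage")
        h = feat
        for level, up in enumerate(self.ups):
            # nearest 2x + [1/4,1/2,1/4] smoothing = bilinear upsampling;
            # avoids the half-pixel boundary bias of raw nearest-neighbour
            h = smooth3(upsample2x(h))
            if self.skips:
                h = concat_channels(h, skips[len(skips) - 1 - level])
            h = relu(up(h))
        h = relu(self.refine(h))
        return self.head(h)  # logits

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for up in self.ups:
            out += up.params()
        return out + self.refine.params() + self.head.params()


@dataclass
class DualBranchModel:
    """Shared encoder + strong/weak decoders (identical architectures)."""

    encoder: _Encoder
    strong_decoder: _Decoder
    weak_decoder: _Decoder
    config: dict = field(default_factory=dict)
    frozen_encoder: bool = False

    @property
    def dtype(self) -> np.dtype:
        return self.encoder.stem.conv.w.data.dtype

    # -- parameter access -------------------------------------------------
    def encoder_parameters(self) -> list[Tensor]:
        return self.encoder.params()

    def decoder_parameters(self) -> list[Tensor]:
        return self.strong_decoder.params() + self.weak_decoder.params()

    def parameters(self) -> list[Tensor]:
        return self.encoder_parameters() + self.decoder_parameters()

    # -- inference ---------------------------------------------------------
    def encode(self, x: Tensor) -> tuple[Tensor, tuple[Tensor, ...]]:
        """Encoder features for an (N, H, W, 1) input tensor: bottleneck
        plus the skip activations (empty tuple when skips are disabled)."""
        if self.config.get("skips"):
            return self.encoder.features(x)
        return self.encoder(x), ()

    def _check_size(self, h: int, w: int) -> None:
        div = 2 ** self.config["depth"]
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2^depth = {div}"
            )

    def forward_batch(self, images: np.ndarray, track: bool = True) -> tuple[Tensor, Tensor]:
        """Run a (N, H, W) image batch; returns (strong, weak) probability
        tensors in channel-last (N, H, W, C) layout. ``track=False`` skips
        graph construction for pure inference."""
        images = np.asarray(images)
        if images.ndim == 2:
            images = images[None]
        n, h, w = images.shape
        self._check_size(h, w)
        x = Tensor(images[..., None].astype(self.dtype))
        if not track:
            with no_grad():
                feat, skips = self.encode(x)
                return (
                    softmax_channels(self.strong_decoder(feat, skips)),
                    softmax_channels(self.weak_decoder(feat, skips)),
                )
        if self.frozen_encoder:
            # no gradient can reach the encoder, so detach its outputs and
            # skip building the (expensive) encoder backward graph
            with no_grad():
                feat, skips = self.encode(x)
            feat = Tensor(feat.data)
            skips = tuple(Tensor(s.data) for s in skips)
        else:
            feat, skips = self.encode(x)
        strong = softmax_channels(self.strong_decoder(feat, skips))
        weak = softmax_channels(self.weak_decoder(feat, skips))
        return strong, weak

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Single 2-D image -> two (H, W, C) probability maps."""
        strong, weak = self.forward_batch(np.asarray(image)[None], track=False)
        return strong.data[0], weak.data[0]

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i:04d}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, config=json.dumps(self.config | {"frozen": self.frozen_encoder}),
                 **arrays)

    @classmethod
    def load(cls, path) -> "DualBranchModel":
        with np.load(path, allow_pickle=False) as archive:
            cfg = json.loads(str(archive["config"]))
            frozen = cfg.pop("frozen", False)
            model = build_model(**cfg)
            for i, p in enumerate(model.parameters()):
                stored = archive[f"p{i:04d}"]
                if stored.shape != p.data.shape:
                    raise ValueError("checkpoint does not match model configuration")
                p.data = stored
        if frozen:
            freeze_encoder(model)
        return model


def build_model(
    channels: int = 1,
    classes: int = 4,
    width: int = 8,
    depth: int = 2,
    seed: int = 0,
    dtype: str = "float32",
    skips: bool = False,
) -> DualBranchModel:
    """Build and seed-initialize a dual-branch model.

    Both decoders are constructed from the same hyperparameters, so their
    layer shapes match element-wise; their parameters are drawn
    independently from the seeded stream. ``skips`` enables encoder-to-
    decoder skip connections (off by default so the decoders see only the
    frozen bottleneck during fine-tuning).
    """
    if classes < 2:
        raise ValueError(f"classes must be >= 2, got {classes}")
    if depth < 2:
        raise ValueError(f"depth must be >= 2, got {depth}")
    if width < 4:
        raise ValueError(f"width must be >= 4, got {width}")
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    np_dtype = np.dtype(dtype)
    rng = np.random.default_rng(seed)
    encoder = _Encoder(channels, width, depth, rng, np_dtype)
    strong = _Decoder(width, depth, classes, rng, np_dtype, skips=skips)
    weak = _Decoder(width, depth, classes, rng, np_dtype, skips=skips)
    config = dict(channels=channels, classes=classes, width=width, depth=depth,
                  seed=seed, dtype=dtype, skips=skips)
    return DualBranchModel(encoder, strong, weak, config=config)


def freeze_encoder(model: DualBranchModel) -> DualBranchModel:
    """Mark every encoder parameter as non-trainable (in place).

    No parameter value changes at freeze time; afterwards no optimizer step
    can alter the encoder, byte for byte.
    """
    for p in model.encoder_parameters():
        p.requires_grad = False
    model.frozen_encoder = True
    return model


def parameter_checksum(params: Iterable[Tensor] | DualBranchModel) -> str:
    """Deterministic SHA-256 digest of parameter bytes (order-sensitive)."""
    if isinstance(params, DualBranchModel):
        params = params.parameters()
    digest = hashlib.sha256()
    for p in params:
        digest.update(str(p.data.shape).encode())
        digest.update(np.ascontiguousarray(p.data).tobytes())
    return digest.hexdigest()
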