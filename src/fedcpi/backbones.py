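"""Large (frozen) and small (trainable) image feature extractors.

The framework pairs a frozen, generic "foundation-model" encoder with a
trainable lightweight residual CNN.  Here the large extractor is a frozen,
seed-pinned random convolutional encoder: it plays the same structural role —
stable, generic, never updated — and any callable mapping an image batch to a
fixed-dimension embedding (e.g. a pretrained ViT) can be plugged in behind the
same contract without touching the rest of the framework.

Both extractors consume (n, s, s) grayscale batches in [0, 1] and emit an
:class:`EmbeddingBatch` of per-image vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, layer_norm, no_grad

__all__ = ["EmbeddingBatch", "ExtractorConfig", "LargeEncoder", "SmallResNet",
           "extract_large", "extract_small"]


@dataclass
class EmbeddingBatch:
    vectors: np.ndarray            # (n, d)
    source: str                    # "large" | "small"

    def __post_init__(self):
        if not np.isfinite(self.vectors).all():
            raise ValueError("embeddings must be finite")


@dataclass(frozen=True)
class ExtractorConfig:
    source: str
    dim: int
    width_mult: float = 0.25
    freeze: bool = False
    init_seed: int = 0

    def __post_init__(self):
        if self.source == "large" and not self.freeze:
            raise ValueError("the large extractor must be frozen")


def _check_batch(images: np.ndarray) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("expected a (n, s, s) batch of square grayscale images")
    return (arr - 0.5)[:, None, :, :]   # center intensities


def _gap(x: Tensor) -> Tensor:
    # global average pool (n, c, h, w) -> (n, c)
    n, c, h, w = x.shape
    return x.reshape(n, c, h * w).mean(axis=2)


_layer_norm = layer_norm   # pooled channels are standardized per sample


class LargeEncoder(Module):
    """Frozen random convolutional encoder standing in for a vision
    foundation model.  Never trained; deterministic given ``seed``."""

    trainable = False

    def __init__(self, dim: int = 768, seed: int = 0, widths=(16, 32, 64)):
        rng = np.random.default_rng(seed)
        c = 1
        self.convs = []
        for w in widths:
            self.convs.append(Conv2d(c, w, k=3, stride=2, pad=1, rng=rng))
            c = w
        self.head = Linear(c, dim, rng)
        self.dim = dim
        for p in self.named_parameters().values():
            p.requires_grad = False

    def forward(self, images: np.ndarray) -> Tensor:
        x = Tensor(_check_batch(images))
        for conv in self.convs:
            x = conv(x).relu()
        return self.head(_layer_norm(_gap(x)))


class _ResBlock(Module):
    def __init__(self, c_in: int, c_out: int, stride: int, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.proj = (Conv2d(c_in, c_out, 1, stride, 0, rng)
                     if (c_in != c_out or stride != 1) else None)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class SmallResNet(Module):
    """Width-reduced residual CNN (ResNet-style topology), trainable."""

    def __init__(self, dim: int = 512, width_mult: float = 0.25, seed: int = 0):
        rng = np.random.default_rng(seed)
        base = max(int(round(64 * width_mult)), 4)
        self.stem = Conv2d(1, base, 3, 1, 1, rng)
        self.block1 = _ResBlock(base, base, 1, rng)
        self.block2 = _ResBlock(base, 2 * base, 2, rng)
        self.block3 = _ResBlock(2 * base, 4 * base, 2, rng)
        self.head = Linear(4 * base, dim, rng)
        self.dim = dim

    def forward(self, images: np.ndarray) -> Tensor:
        x = Tensor(_check_batch(images))
        x = self.stem(x).relu()
        x = self.block3(self.block2(self.block1(x)))
        return self.head(_layer_norm(_gap(x)))


def extract_large(encoder: LargeEncoder, images: np.ndarray) -> EmbeddingBatch:
    with no_grad():
        return EmbeddingBatch(encoder.forward(images).data.copy(), "large")


def extract_small(encoder: SmallResNet, images: np.ndarray) -> EmbeddingBatch:
    with no_grad():
        return EmbeddingBatch(encoder.forward(images).data.copy(), "small")
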