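"""Weight-sharing residual encoder with a projection head.

A single-channel 2D slice is mapped through a residual convolutional
backbone, globally average-pooled into a 1024-dimensional feature vector,
projected to 128 dimensions by the projection head and L2-normalized onto
the unit hypersphere. The "twin" channels of the contrastive architecture
share one parameter set: both inputs pass through the same network, so
weight sharing holds by construction and an image's embedding cannot
depend on the channel it entered.

Global average pooling makes the network resolution-agnostic: 64x64
phantom slices and 113x113 clinical slices both fit the input contract.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .phantom import LabeledImage

_BACKBONES = ("small", "standard")


class EncoderConfigError(ValueError):
    """Raised for an invalid encoder configuration."""


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and initialization settings.

    ``backbone_depth`` selects the residual backbone: "small" (4 residual
    blocks, for desk-scale CPU training) or "standard" (an 18-layer-class
    residual network). ``feature_dim`` is the pooled feature width (1024)
    and ``projection_dim`` the embedding width (128). The projection head
    has one linear layer by default (``projection_layers=1``, no bias, no
    trailing ReLU — a trailing ReLU would zero half the hypersphere); a
    two-layer linear-ReLU-linear head is available with
    ``projection_layers=2``.
    """

    backbone_depth: str = "small"
    feature_dim: int = 1024
    projection_dim: int = 128
    projection_layers: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.backbone_depth not in _BACKBONES:
            raise EncoderConfigError(
                f"unknown backbone_depth {self.backbone_depth!r}; choose from {_BACKBONES}"
            )
        if self.feature_dim <= 0 or self.projection_dim <= 0:
            raise EncoderConfigError("feature_dim and projection_dim must be positive")
        if self.projection_layers not in (1, 2):
            raise EncoderConfigError("projection_layers must be 1 or 2")


def _build_backbone(config: EncoderConfig, rng: np.random.Generator) -> list:
    """Backbone layer list ending in a feature_dim-channel map + GAP."""
    if config.backbone_depth == "small":
        widths = (16, 32, 64)
        blocks_per_stage = (1, 1, 2)
    else:  # standard: 18-layer-class
        widths = (64, 128, 256, 512)
        blocks_per_stage = (2, 2, 2, 2)
    layers: list = [nn.Conv2d(1, widths[0], k=3, stride=2, pad=1, rng=rng), nn.ReLU()]
    for i, (w, nb) in enumerate(zip(widths, blocks_per_stage)):
        if i > 0:
            layers += [nn.Conv2d(widths[i - 1], w, k=3, stride=2, pad=1, rng=rng),
                       nn.ReLU()]
        layers += [nn.ResidualBlock(w, rng=rng) for _ in range(nb)]
    # 1x1 channel expansion so the average-pooled feature has feature_dim entries
    layers += [nn.Conv2d(widths[-1], config.feature_dim, k=1, stride=1, pad=0, rng=rng),
               nn.GlobalAvgPool()]
    return layers


class Encoder:
    """Residual backbone + projection head with one shared parameter set."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEC0DE]))
        self.backbone = _build_backbone(config, rng)
        if config.projection_layers == 1:
            self.head: list = [
                nn.Linear(config.feature_dim, config.projection_dim, bias=False, rng=rng)
            ]
        else:
            self.head = [
                nn.Linear(config.feature_dim, config.feature_dim, bias=True, rng=rng),
                nn.ReLU(),
                nn.Linear(config.feature_dim, config.projection_dim, bias=False, rng=rng),
            ]
        self.normalize = nn.L2Normalize()

    # -- parameter access -------------------------------------------------
    def parameters(self) -> list[nn.Param]:
        params: list[nn.Param] = []
        for layer in self.backbone + self.head:
            params += layer.parameters()
        return params

    def fingerprint(self) -> str:
        """Digest of all weights; ties a baseline panel to a checkpoint."""
        h = hashlib.sha256()
        h.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()

    # -- forward passes ----------------------------------------------------
    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pooled feature vectors, shape (B, feature_dim)."""
        for layer in self.backbone:
            x = layer.forward(x, train)
        return x

    def project(self, features: np.ndarray, train: bool = False) -> np.ndarray:
        """Projection head + unit-hypersphere normalization."""
        features = np.asarray(features, dtype=np.float64)
        squeeze = features.ndim == 1
        x = features[None, :] if squeeze else features
        if not np.all(np.isfinite(x)):
            raise ValueError("features must be finite")
        for layer in self.head:
            x = layer.forward(x, train)
        z = self.normalize.forward(x, train)
        return z[0] if squeeze else z

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.project(self.features(x, train), train)

    def backward(self, dz: np.ndarray) -> None:
        """Reverse pass from embedding gradients; accumulates param grads."""
        d = self.normalize.backward(dz)
        for layer in reversed(self.head):
            d = layer.backward(d)
        for layer in reversed(self.backbone):
            d = layer.backward(d)

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights + config; reload with :meth:`Encoder.load`."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        buf = io.BytesIO()
        np.savez(buf, config=json.dumps(asdict(self.config)), **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "Encoder":
        with np.load(Path(path), allow_pickle=False) as data:
            config = EncoderConfig(**json.loads(str(data["config"])))
            enc = cls(config)
            for i, p in enumerate(enc.parameters()):
                p.value[...] = data[f"p{i}"]
        return enc


def build_encoder(config: EncoderConfig | None = None) -> Encoder:
    """Construct a seeded encoder; same config (incl. seed) -> same weights."""
    return Encoder(config or EncoderConfig())


def _stack_pixels(images: Sequence[LabeledImage]) -> np.ndarray:
    arrs = []
    for im in images:
        im.validate()
        arrs.append(np.asarray(im.pixels, dtype=np.float64))
    return np.stack(arrs)[:, None, :, :]


def embed_batch(encoder: Encoder, images: Sequence[LabeledImage],
                chunk_size: int = 64) -> np.ndarray:
    """Embed images in inference mode; rows are unit-norm 128-vectors.

    Embeddings are independent of batch composition and order: the network
    has no batch-coupled statistics, so each row depends only on its own
    image and the weights.
    """
    if len(images) == 0:
        raise ValueError("cannot embed an empty image collection")
    out = []
    for start in range(0, len(images), chunk_size):
        x = _stack_pixels(images[start : start + chunk_size])
        out.append(encoder.forward(x, train=False))
    return np.vstack(out)
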