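"""3D ResNet-50 query/key encoders, projection head, classifier head.

The encoder is a 3D adaptation of ResNet-50 whose 7x7x7 stem is
replaced by a 3x3x3 convolution with stride 1 and padding 1, followed
by a stride-2 pooling. Four bottleneck stages (1x1x1 -> 3x3x3 -> 1x1x1
convolutions, expansion 4) downsample with stride 2 at stages 2-4;
global average pooling yields the feature vector. The projection head
is a two-layer MLP whose output (default dimension 128) is L2
normalized. ``reduced()`` gives a desk-scale spec used throughout the
tests.
"""

from __future__ import annotations

import dataclasses
from typing import List

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import (Conv3d, Linear, MaxPool3d2, Module, Sequential,
                        make_norm)

EXPANSION = 4


@dataclasses.dataclass
class EncoderSpec:
    """Architecture description shared by the query and key networks."""

    in_channels: int = 1
    stage_blocks: List[int] = dataclasses.field(default_factory=lambda: [3, 4, 6, 3])
    base_width: int = 64
    projection_dim: int = 128
    norm: str = "batch"

    def __post_init__(self):
        if len(self.stage_blocks) != 4:
            raise ValueError("stage_blocks must list 4 stage depths")
        if self.projection_dim < 2:
            raise ValueError("projection_dim must be >= 2")
        if self.base_width < 1 or any(b < 1 for b in self.stage_blocks):
            raise ValueError("widths and stage depths must be >= 1")

    @property
    def feature_dim(self) -> int:
        return self.base_width * 8 * EXPANSION

    @classmethod
    def reduced(cls, projection_dim: int = 16, norm: str = "batch") -> "EncoderSpec":
        """Desk-scale spec for tests: narrow, one block per stage."""
        return cls(stage_blocks=[1, 1, 1, 1], base_width=8,
                   projection_dim=projection_dim, norm=norm)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderSpec":
        return cls(**d)


class Bottleneck(Module):
    def __init__(self, in_ch: int, planes: int, stride: int, norm: str,
                 *, rng: np.random.Generator):
        super().__init__()
        out_ch = planes * EXPANSION
        self.conv1 = Conv3d(in_ch, planes, 1, rng=rng)
        self.n1 = make_norm(norm, planes)
        self.conv2 = Conv3d(planes, planes, 3, stride=stride, padding=1, rng=rng)
        self.n2 = make_norm(norm, planes)
        self.conv3 = Conv3d(planes, out_ch, 1, rng=rng)
        self.n3 = make_norm(norm, out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = Sequential(
                Conv3d(in_ch, out_ch, 1, stride=stride, rng=rng),
                make_norm(norm, out_ch))

    def forward(self, x: Tensor) -> Tensor:
        out = ad.relu(self.n1(self.conv1(x)))
        out = ad.relu(self.n2(self.conv2(out)))
        out = self.n3(self.conv3(out))
        skip = self.downsample(x) if self.downsample is not None else x
        return ad.relu(out + skip)


class Encoder3d(Module):
    """Stem + four bottleneck stages + global average pooling."""

    def __init__(self, spec: EncoderSpec, *, rng: np.random.Generator):
        super().__init__()
        w = spec.base_width
        self.stem_conv = Conv3d(spec.in_channels, w, 3, stride=1, padding=1, rng=rng)
        self.stem_norm = make_norm(spec.norm, w)
        self.pool = MaxPool3d2()
        in_ch = w
        stages = []
        for i, depth in enumerate(spec.stage_blocks):
            planes = w * 2 ** i
            blocks = []
            for b in range(depth):
                stride = 2 if (i > 0 and b == 0) else 1
                blocks.append(Bottleneck(in_ch, planes, stride, spec.norm, rng=rng))
                in_ch = planes * EXPANSION
            stages.append(Sequential(*blocks))
        self.stages = Sequential(*stages)
        self.out_dim = in_ch

    def forward(self, x: Tensor) -> Tensor:
        h = self.pool(ad.relu(self.stem_norm(self.stem_conv(x))))
        h = self.stages(h)
        return h.mean(axis=(2, 3, 4))          # (B, feature_dim)


class ProjectionHead(Module):
    """Two-layer MLP; hidden width equals the encoder feature width."""

    def __init__(self, in_dim: int, out_dim: int, *, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_dim, in_dim, rng=rng)
        self.fc2 = Linear(in_dim, out_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ad.relu(self.fc1(x)))


class SMoCoNetwork(Module):
    """Encoder + projection head; outputs unit-norm embeddings."""

    def __init__(self, spec: EncoderSpec, *, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.encoder = Encoder3d(spec, rng=rng)
        self.proj = ProjectionHead(self.encoder.out_dim, spec.projection_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return ad.l2_normalize(self.proj(self.encoder(x)), axis=-1)


class Classifier(Module):
    """Encoder + single affine layer; softmax over classes at predict time."""

    def __init__(self, spec: EncoderSpec, n_classes: int = 2,
                 *, rng: np.random.Generator):
        super().__init__()
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.spec = spec
        self.n_classes = n_classes
        self.encoder = Encoder3d(spec, rng=rng)
        self.fc = Linear(self.encoder.out_dim, n_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(self.encoder(x))        # logits

    def predict_proba(self, volumes: np.ndarray) -> np.ndarray:
        """Softmax class probabilities in evaluation mode."""
        was_training = self.training
        self.eval()
        with ad.no_grad():
            probs = ad.softmax(self.forward(_as_batch(volumes)), axis=-1).data
        self.train(was_training)
        return probs


@dataclasses.dataclass
class NetworkPair:
    """Query network (gradient-trained) and its momentum key copy."""

    query: SMoCoNetwork
    key: SMoCoNetwork
    spec: EncoderSpec


def _as_batch(volumes: np.ndarray) -> Tensor:
    v = np.asarray(volumes, dtype=np.float32)
    if v.ndim == 3:
        v = v[None]
    if v.ndim == 4:
        v = v[:, None]                         # add channel axis
    return Tensor(v)


def build_networks(spec: EncoderSpec, seed: int = 0) -> NetworkPair:
    """Initialize the query network from ``seed`` and the key network as
    an exact copy; the key is only ever updated by EMA, never gradient."""
    rng = np.random.default_rng(seed)
    query = SMoCoNetwork(spec, rng=rng)
    key = SMoCoNetwork(spec, rng=np.random.default_rng(0))
    key.load_state_dict(query.state_dict())
    return NetworkPair(query=query, key=key, spec=spec)


def forward_embed(network: SMoCoNetwork, volumes: np.ndarray) -> np.ndarray:
    """Unit-norm embeddings of a batch of cubic volumes, evaluation mode."""
    was_training = network.training
    network.eval()
    with ad.no_grad():
        z = network(_as_batch(volumes)).data
    network.train(was_training)
    return z


def to_classifier(network: SMoCoNetwork, n_classes: int = 2,
                  seed: int = 0) -> Classifier:
    """Swap the projection head for a fresh single-layer softmax
    classifier; encoder weights are carried over unchanged."""
    clf = Classifier(network.spec, n_classes, rng=np.random.default_rng(seed))
    clf.encoder.load_state_dict(network.encoder.state_dict())
    return clf


def count_parameters(module: Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))
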