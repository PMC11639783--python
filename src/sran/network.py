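"""Embedding generator, Siamese triplet wrapper, distances and triplet loss.

The embedding generator maps a preprocessed radiograph (H x W x 3, values in
[0, 1]) to a fixed-length identity embedding (default 256-d) through:

    backbone feature map -> SRAB 1 -> SRAB 2 -> attention block
    -> reverse attention block -> flatten -> dense (Softplus) -> dense

Two backbones are provided: a 50-layer bottleneck residual network
(``resnet50``) and a 4-convolution ``tiny`` backbone for CPU-scale
experiments.  The Siamese triplet wrapper runs anchor/positive/negative
batches through the *same* generator object (weight sharing by construction)
and exposes the anchor-positive / anchor-negative Euclidean distances that
feed the triplet hinge loss  L = max(0, D_AP - D_AN + margin).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .attention import (
    BlockParams,
    attention_block_forward_t,
    reverse_attention_forward_t,
    srab_forward_t,
)
from .layers import Adam, BatchNorm2d, Conv2D, Dense, Layer

_BACKBONE_ALIASES = {
    "resnet50": "resnet50",
    "deep-residual-50": "resnet50",
    "tiny": "tiny",
    "tiny-test": "tiny",
}


@dataclass
class NetworkConfig:
    """Architecture hyperparameters for the embedding generator."""

    input_height: int = 200
    input_width: int = 200
    input_channels: int = 3
    backbone: str = "resnet50"
    backbone_pretrained: bool = False
    srab_filters: tuple[int, int] = (512, 256)
    reverse_filters: int = 128
    head_hidden_units: int = 512
    embedding_dim: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in _BACKBONE_ALIASES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; expected one of "
                f"{sorted(set(_BACKBONE_ALIASES))}"
            )
        self.backbone = _BACKBONE_ALIASES[self.backbone]
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        for v in (self.input_height, self.input_width, self.input_channels,
                  *self.srab_filters, self.reverse_filters,
                  self.head_hidden_units):
            if v < 1:
                raise ValueError("all dimensions must be positive")
        minimum = 32 if self.backbone == "resnet50" else 16
        if self.input_height < minimum or self.input_width < minimum:
            raise ValueError(
                f"input {self.input_height}x{self.input_width} below the "
                f"{self.backbone} backbone minimum of {minimum}"
            )
        if self.backbone_pretrained:
            raise ValueError(
                "no pretrained backbone weights are bundled; build with "
                "backbone_pretrained=False (seeded He initialization)"
            )

    @classmethod
    def tiny(cls, size=64, embedding_dim=64, seed=0):
        """A CPU-scale configuration used by tests and the benchmark."""
        return cls(
            input_height=size, input_width=size, backbone="tiny",
            srab_filters=(48, 48), reverse_filters=32,
            head_hidden_units=128, embedding_dim=embedding_dim, seed=seed,
        )


class _BottleneckBlock(Layer):
    expansion = 4

    def __init__(self, c_in, filters, stride, rng):
        c_out = filters * self.expansion
        self.conv1 = Conv2D(c_in, filters, kernel=1, rng=rng)
        self.bn1 = BatchNorm2d(filters)
        self.conv2 = Conv2D(filters, filters, kernel=3, stride=stride, rng=rng)
        self.bn2 = BatchNorm2d(filters)
        self.conv3 = Conv2D(filters, c_out, kernel=1, rng=rng)
        self.bn3 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2D(c_in, c_out, kernel=1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None
            self.proj_bn = None

    def __call__(self, x, training=False):
        y = T.relu(self.bn1(self.conv1(x), training))
        y = T.relu(self.bn2(self.conv2(y), training))
        y = self.bn3(self.conv3(y), training)
        short = x if self.proj is None else self.proj_bn(self.proj(x), training)
        return T.relu(T.add(y, short))


class ResNet50Backbone(Layer):
    """Bottleneck residual network, stages (3, 4, 6, 3), NHWC, output C=2048."""

    def __init__(self, c_in, rng):
        self.stem = Conv2D(c_in, 64, kernel=7, stride=2, rng=rng)
        self.stem_bn = BatchNorm2d(64)
        self.blocks = []
        c = 64
        for filters, count, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
            for i in range(count):
                self.blocks.append(_BottleneckBlock(c, filters, stride if i == 0 else 1, rng))
                c = filters * _BottleneckBlock.expansion
        self.out_channels = c

    def __call__(self, x, training=False):
        y = T.relu(self.stem_bn(self.stem(x), training))
        y = T.maxpool2d(y, pool=3, stride=2)
        for block in self.blocks:
            y = block(y, training)
        return y


class TinyBackbone(Layer):
    """Four stride-2 conv/BN/ReLU stages; output C=64 at 1/16 resolution."""

    def __init__(self, c_in, rng):
        self.convs, self.bns = [], []
        for filters in (16, 32, 64, 64):
            self.convs.append(Conv2D(c_in, filters, kernel=3, stride=2, rng=rng))
            self.bns.append(BatchNorm2d(filters))
            c_in = filters
        self.out_channels = c_in

    def __call__(self, x, training=False):
        for conv, bn in zip(self.convs, self.bns):
            x = T.relu(bn(conv(x), training))
        return x


class EmbeddingGenerator(Layer):
    """Image -> identity embedding; see module docstring for the layer order."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        if cfg.backbone == "resnet50":
            self.backbone = ResNet50Backbone(cfg.input_channels, rng)
        else:
            self.backbone = TinyBackbone(cfg.input_channels, rng)
        f1, f2 = cfg.srab_filters
        self.srab1 = BlockParams.for_srab(self.backbone.out_channels, f1, rng=rng)
        self.srab2 = BlockParams.for_srab(f1, f2, rng=rng)
        self.attention = BlockParams.for_attention(f2, rng=rng)
        self.reverse = BlockParams.for_reverse(f2, cfg.reverse_filters, rng=rng)
        feat_h = self._spatial_out(cfg.input_height)
        feat_w = self._spatial_out(cfg.input_width)
        flat = feat_h * feat_w * cfg.reverse_filters
        self.head_hidden = Dense(flat, cfg.head_hidden_units, rng=rng)
        self.head_out = Dense(cfg.head_hidden_units, cfg.embedding_dim, rng=rng)

    def _spatial_out(self, size):
        reduction = 32 if self.cfg.backbone == "resnet50" else 16
        return -(-size // reduction)

    def forward(self, x: Tensor, training=False) -> Tensor:
        y = self.backbone(x, training)
        y = srab_forward_t(y, self.srab1, training)
        y = srab_forward_t(y, self.srab2, training)
        y = attention_block_forward_t(y, self.attention)
        y = reverse_attention_forward_t(y, self.reverse, training)
        n = y.data.shape[0]
        y = T.reshape(y, (n, -1))
        y = T.softplus(self.head_hidden(y))
        return self.head_out(y)

    def embed(self, images: np.ndarray) -> np.ndarray:
        """Embeddings for one image or a batch, always in inference mode."""
        x = np.asarray(images, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[3] != self.cfg.input_channels:
            raise ValueError(
                f"expected {self.cfg.input_channels}-channel input, got {x.shape[3]}"
            )
        out = self.forward(Tensor(x), training=False).data
        return out[0] if single else out

    # -- persistence -----------------------------------------------------
    def save(self, path):
        state = {k: v for k, v in self.state_arrays().items()}
        cfg = asdict(self.cfg)
        cfg["srab_filters"] = list(cfg["srab_filters"])
        np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "EmbeddingGenerator":
        with np.load(path) as archive:
            cfg_json = bytes(archive["__config__"]).decode()
            state = {k: archive[k] for k in archive.files if k != "__config__"}
        cfg_dict = json.loads(cfg_json)
        cfg_dict["srab_filters"] = tuple(cfg_dict["srab_filters"])
        model = cls(NetworkConfig(**cfg_dict))
        model.load_state_arrays(state)
        return model


def build_embedding_generator(cfg: NetworkConfig) -> EmbeddingGenerator:
    return EmbeddingGenerator(cfg)


# -- distances and loss --------------------------------------------------
@dataclass
class DistancePair:
    d_ap: float
    d_an: float

    def __post_init__(self):
        if self.d_ap < 0 or self.d_an < 0:
            raise ValueError("distances must be nonnegative")


@dataclass
class TripletLossConfig:
    margin: float = 0.5

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")


def euclidean_distance(a, b) -> float:
    """Exact Euclidean distance between two equal-length vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def triplet_loss(d: DistancePair, cfg: TripletLossConfig = TripletLossConfig()) -> float:
    """Hinge loss max(0, d_ap - d_an + margin)."""
    return max(0.0, d.d_ap - d.d_an + cfg.margin)


def _pairwise_distance_t(ea: Tensor, eb: Tensor) -> Tensor:
    diff = T.add(ea, T.mul(eb, -1.0))
    sq = T.reduce_sum(T.mul(diff, diff), axis=1)
    # clamp keeps the sqrt gradient finite when the embeddings coincide
    return T.sqrt(T.clamp_min(sq, 1e-24))


class SiameseTripletModel:
    """Three weight-shared branches of one embedding generator."""

    def __init__(self, embedding: EmbeddingGenerator,
                 loss_cfg: TripletLossConfig = TripletLossConfig()):
        self.embedding = embedding
        self.loss_cfg = loss_cfg

    def parameters(self):
        return self.embedding.parameters()

    def distances(self, anchors, positives, negatives, training=False):
        """Per-triplet (d_ap, d_an) tensors; batches run through one branch."""
        n = anchors.data.shape[0] if isinstance(anchors, Tensor) else len(anchors)
        batch = T.concat(
            [a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64))
             for a in (anchors, positives, negatives)], axis=0)
        emb = self.embedding.forward(batch, training=training)
        ea = Tensor(emb.data[:n], parents=(emb,),
                    backward=_slice_backward(emb, 0, n))
        ep = Tensor(emb.data[n:2 * n], parents=(emb,),
                    backward=_slice_backward(emb, n, 2 * n))
        en = Tensor(emb.data[2 * n:], parents=(emb,),
                    backward=_slice_backward(emb, 2 * n, 3 * n))
        return _pairwise_distance_t(ea, ep), _pairwise_distance_t(ea, en)

    def distance_pairs(self, anchors, positives, negatives) -> list[DistancePair]:
        d_ap, d_an = self.distances(anchors, positives, negatives, training=False)
        return [DistancePair(float(p), float(q)) for p, q in zip(d_ap.data, d_an.data)]

    def loss(self, anchors, positives, negatives, training=True) -> Tensor:
        d_ap, d_an = self.distances(anchors, positives, negatives, training)
        hinge = T.relu(T.add(T.add(d_ap, T.mul(d_an, -1.0)), self.loss_cfg.margin))
        return T.reduce_mean(hinge)


def _slice_backward(src: Tensor, start, stop):
    def bw(g):
        full = np.zeros_like(src.data)
        full[start:stop] = g
        if src.grad is None:
            src.grad = full
        else:
            src.grad = src.grad + full
    return bw


def build_siamese_triplet_model(
    cfg: NetworkConfig, loss_cfg: TripletLossConfig = TripletLossConfig()
) -> SiameseTripletModel:
    return SiameseTripletModel(build_embedding_generator(cfg), loss_cfg)


# -- training ------------------------------------------------------------
@dataclass
class TrainingConfig:
    optimizer: str = "adam"
    lr: float = 1e-4
    batch_size: int = 16
    epochs: int = 10
    seed: int = 0
    image_size: int | None = None
    loss_csv: str | None = None


def train_triplet_model(model: SiameseTripletModel, triplet_stream, hp: TrainingConfig):
    """Train with triplet loss; returns (model, per-epoch mean loss history).

    ``triplet_stream`` is either a fixed list of triplets or a callable
    ``epoch -> list of triplets`` (per-epoch resampling).  Triplet image
    references (paths or arrays) are loaded through the data-module
    preprocessing and cached across epochs.
    """
    from .data import preprocess_image

    if hp.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {hp.optimizer!r}")
    size = hp.image_size or model.embedding.cfg.input_height
    cache: dict = {}

    def load(ref):
        key = ref if isinstance(ref, str) else id(ref)
        if key not in cache:
            cache[key] = preprocess_image(ref, size=size)
        return cache[key]

    rng = np.random.default_rng(hp.seed)
    opt = Adam(model.parameters(), lr=hp.lr)
    history = []
    for epoch in range(hp.epochs):
        triplets = list(triplet_stream(epoch)) if callable(triplet_stream) else list(triplet_stream)
        if not triplets:
            raise ValueError("triplet stream is empty")
        order = rng.permutation(len(triplets))
        batch_losses = []
        for start in range(0, len(order), hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xa = np.stack([load(triplets[i].anchor) for i in idx])
            xp = np.stack([load(triplets[i].positive) for i in idx])
            xn = np.stack([load(triplets[i].negative) for i in idx])
            loss = model.loss(xa, xp, xn, training=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite triplet loss at epoch {epoch}, batch "
                    f"{start // hp.batch_size}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        history.append(float(np.mean(batch_losses)))
    if hp.loss_csv:
        with open(hp.loss_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "mean_loss"])
            for i, v in enumerate(history):
                writer.writerow([i, v])
    return model, history
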