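"""Patch embedding: map each kept patch to a fixed-length feature vector.

The backbone is a small convolutional network evaluated in pure NumPy
(im2col + matmul) with fixed, seeded He-initialised weights — a
random-features extractor in the extreme-learning-machine tradition.  The
convolutional filters are never trained; all task adaptation happens in the
MIL head downstream, which keeps patch embedding deterministic, fast on a
single CPU, and free of any bag-membership state.  ``small_conv`` (default)
is four stride-2 conv/ReLU blocks with global average pooling;
``resnet_like`` adds identity skip connections inside two extra
channel-preserving blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform

from .preprocess import PatchRecord

__all__ = ["BackboneConfig", "EmbeddingBag", "Backbone", "embed_patches"]


@dataclass(frozen=True)
class BackboneConfig:
    architecture: str = "small_conv"
    embedding_dim: int = 128
    input_size: int = 112
    seed: int = 0
    #: per-channel normalization applied to [0, 1] inputs
    mean: tuple[float, float, float] = (0.7, 0.6, 0.7)
    std: tuple[float, float, float] = (0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.embedding_dim < 8:
            raise ValueError("embedding_dim must be >= 8")
        if self.architecture not in ("small_conv", "resnet_like"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class EmbeddingBag:
    """All kept-patch embeddings of one biopsy, row order = patch order."""

    biopsy_id: str
    H: np.ndarray  # (N, d)
    index: list[tuple[int, int]] = field(default_factory=list)  # (row0, col0)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.ndim != 2 or self.H.shape[0] == 0:
            raise ValueError("embedding bag must be a non-empty (N, d) matrix")
        if not np.isfinite(self.H).all():
            raise ValueError("embedding bag contains non-finite values")

    @property
    def n_instances(self) -> int:
        return self.H.shape[0]


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int]:
    """(B, H, W, C) -> (B, out*out, k*k*C) patch matrix."""
    b, h, w, c = x.shape
    out = (h - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, out, out, k, k, c),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3),
        writeable=False,
    )
    return windows.reshape(b, out * out, k * k * c), out


def _maxpool2(x: np.ndarray) -> np.ndarray:
    b, h, w, c = x.shape
    h2, w2 = h // 2 * 2, w // 2 * 2
    return x[:, :h2, :w2].reshape(b, h2 // 2, 2, w2 // 2, 2, c).max(axis=(2, 4))


class Backbone:
    """Fixed-weight convolutional feature extractor.

    Valid 3x3 convolutions with ReLU, each followed by 2x2 max pooling;
    interleaved max pooling (rather than strided convolution) propagates
    the responses of small, rare objects — neutrophil-sized dots — that
    plain average pooling would wash out.  The global readout concatenates
    the spatial mean of the first half of the last layer's channels with
    the spatial max of the second half, giving ``embedding_dim`` features
    that carry both diffuse-texture and peak-event information.
    """

    def __init__(self, config: BackboneConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 977]))
        d = config.embedding_dim
        if config.architecture == "small_conv":
            # (kernel, cin, cout, pool_after, residual_skip)
            plan = [
                (3, 3, 16, True, False),
                (3, 16, 32, True, False),
                (3, 32, 64, True, False),
                (3, 64, d, True, False),
            ]
        else:  # resnet_like: extra channel-preserving blocks with skips
            plan = [
                (3, 3, 16, True, False),
                (3, 16, 16, False, True),
                (3, 16, 32, True, False),
                (3, 32, 32, False, True),
                (3, 32, 64, True, False),
                (3, 64, d, True, False),
            ]
        self.plan = plan
        self.weights = []
        for k, cin, cout, _, _ in plan:
            fan_in = k * k * cin
            self.weights.append(rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in))

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """(B, S, S, 3) float in [0, 1] -> (B, d) embeddings."""
        cfg = self.config
        x = (batch - np.asarray(cfg.mean)) / np.asarray(cfg.std)
        for w, (k, _, _, pool, skip) in zip(self.weights, self.plan):
            src = np.pad(x, ((0, 0), (k // 2, k // 2), (k // 2, k // 2), (0, 0)))
            cols, out = _im2col(src, k, 1)
            y = np.maximum(cols @ w, 0.0).reshape(x.shape[0], out, out, -1)
            if skip:
                y = y + x
            x = _maxpool2(y) if pool else y
        half = x.shape[-1] // 2
        return np.concatenate(
            [x[..., :half].mean(axis=(1, 2)), x[..., half:].max(axis=(1, 2))], axis=1
        )


_BACKBONE_CACHE: dict[tuple, Backbone] = {}


def get_backbone(config: BackboneConfig) -> Backbone:
    key = (config.architecture, config.embedding_dim, config.input_size, config.seed)
    if key not in _BACKBONE_CACHE:
        _BACKBONE_CACHE[key] = Backbone(config)
    return _BACKBONE_CACHE[key]


def embed_patches(
    patches: list[PatchRecord],
    config: BackboneConfig | None = None,
    backbone: Backbone | None = None,
    batch_size: int = 64,
) -> EmbeddingBag:
    """Embed the kept patches of one biopsy.

    Patches are resized to ``config.input_size`` and pushed through the
    fixed backbone; output row *k* is the embedding of input patch *k*, so
    permuting the input permutes the rows identically and duplicate
    patches produce identical rows.  Raises on an empty patch list — bags
    must be non-empty downstream.
    """
    if not patches:
        raise ValueError("cannot embed an empty patch list: MIL bags must be non-empty")
    if backbone is None:
        backbone = get_backbone(config or BackboneConfig())
    cfg = backbone.config
    size = cfg.input_size
    resized = np.empty((len(patches), size, size, 3))
    for i, p in enumerate(patches):
        if p.pixels.shape[0] != p.pixels.shape[1]:
            raise ValueError("patches must be square")
        if p.pixels.shape[0] == size:
            resized[i] = p.pixels / 255.0
        else:
            resized[i] = transform.resize(
                p.pixels / 255.0, (size, size), order=1, anti_aliasing=True
            )
    rows = [
        backbone.forward(resized[i : i + batch_size])
        for i in range(0, len(patches), batch_size)
    ]
    return EmbeddingBag(
        biopsy_id=patches[0].biopsy_id,
        H=np.concatenate(rows, axis=0),
        index=[(p.row0, p.col0) for p in patches],
    )
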