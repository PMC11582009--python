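"""View descriptor generation: CNN backbone + learned GeM pooling + BN.

Each binary view image passes through a shared convolutional backbone to
give a raw feature map ``F`` of shape (C, H, W); generalized-mean (GeM)
pooling then reduces every channel to a scalar

    f_c = ( (1/|chi_c|) * sum_i x_i^{p_c} )^{1/p_c},

the power mean of the channel, which is average pooling at p_c = 1 and
tends to max pooling as p_c grows.  ``p`` is learnable (a shared scalar
by default, initialised to 3, optionally per channel).  A batch
normalization layer maps the pooled descriptors to a unified space
before fusion.

The backbone is a contract, not a fixed network: any module with
``in_channels``/``out_channels`` attributes mapping image batches to
feature-map batches qualifies.  The default here is a small seeded
two-convolution network that runs on CPU in seconds; a 50-layer residual
network (C=2048 at 224 px input) is the documented full-scale choice but
requires a deep-learning framework that is not a dependency of this
package.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor
from .nn import BatchNorm1d, Conv2d, Module

__all__ = [
    "GeMPool",
    "gem_pool",
    "TinyConvBackbone",
    "build_backbone",
    "ViewEncoder",
]

_GEM_EPS = 1e-6


def _gem(x: Tensor, p: Tensor) -> Tensor:
    """Power-mean over the spatial axes of ``x`` (B, C, H, W) -> (B, C).

    Computed as ``m * mean((x/m)^p)^(1/p)`` with ``m`` the per-channel
    max; dividing by a constant leaves the power mean unchanged, so this
    is exact while avoiding overflow for very large ``p``.
    """
    if np.any(x.data < 0):
        raise ValueError("GeM pooling requires nonnegative features")
    b, c = x.shape[0], x.shape[1]
    xc = x.clamp_min(_GEM_EPS)
    m = Tensor(xc.data.max(axis=(2, 3), keepdims=True))
    p_spatial = p.reshape(1, -1, 1, 1) if p.ndim == 1 else p
    powed = (p_spatial * (xc / m).log()).exp()
    mean_pow = powed.mean(axis=(2, 3))  # (B, C)
    p_flat = p.reshape(1, -1) if p.ndim == 1 else p
    return Tensor(m.data.reshape(b, c)) * (mean_pow.log() / p_flat).exp()


def gem_pool(feature_map: np.ndarray | Tensor, p: float | np.ndarray | Tensor) -> np.ndarray:
    """Functional GeM pooling of one feature map (C, H, W) -> (C,).

    ``p`` may be a positive scalar or a length-C vector.  Entries of the
    feature map must be nonnegative (post-activation maps).
    """
    arr = feature_map.data if isinstance(feature_map, Tensor) else np.asarray(feature_map, float)
    if arr.ndim != 3:
        raise ValueError(f"expected (C, H, W) feature map, got shape {arr.shape}")
    pv = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=float)
    if np.any(pv <= 0):
        raise ValueError("GeM exponent p must be > 0")
    out = _gem(Tensor(arr[None]), Tensor(pv.reshape(-1) if pv.ndim else pv))
    return out.data[0]


class GeMPool(Module):
    """Learned GeM pooling layer; ``p`` clamped positive during training."""

    def __init__(self, channels: int, p_init: float = 3.0, per_channel: bool = False):
        super().__init__()
        if p_init <= 0:
            raise ValueError("p_init must be > 0")
        shape = (channels,) if per_channel else ()
        self.p = Parameter(np.full(shape, float(p_init)))

    def forward(self, x: Tensor) -> Tensor:
        return _gem(x, self.p.clamp_min(1e-2))


class TinyConvBackbone(Module):
    """Two strided 3x3 convolutions with ReLU; desk-scale default backbone.

    Output feature maps are nonnegative (post-ReLU), as GeM requires.
    """

    def __init__(self, rng: np.random.Generator, in_channels: int = 1,
                 channels: tuple[int, int] = (8, 16)):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = channels[1]
        self.conv1 = Conv2d(in_channels, channels[0], 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(channels[0], channels[1], 3, rng, stride=2, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


def build_backbone(name: str, rng: np.random.Generator, **kwargs) -> Module:
    """Instantiate a backbone by name.

    ``"tiny"`` is the built-in two-convolution network.  ``"resnet50"``
    (the full-scale configuration, C=2048) needs an external deep
    learning framework and raises a clear error when unavailable.
    """
    if name == "tiny":
        return TinyConvBackbone(rng, **kwargs)
    if name == "resnet50":
        raise ImportError(
            "the resnet50 backbone requires torch/torchvision, which are not "
            "installed; use backbone='tiny' or plug in a custom module"
        )
    raise ValueError(f"unknown backbone {name!r}")


class ViewEncoder(Module):
    """Shared-weight encoding of a stack of views to descriptors.

    Input: float array (B, N, H, W) of binary views.  Output: the raw
    feature maps ``F`` as a Tensor of shape (B*N, C, h, w) and the
    normalized pooled descriptors ``X`` of shape (B, N, C).
    """

    def __init__(self, backbone: Module, p_init: float = 3.0, per_channel: bool = False):
        super().__init__()
        self.backbone = backbone
        self.gem = GeMPool(backbone.out_channels, p_init=p_init, per_channel=per_channel)
        self.bn = BatchNorm1d(backbone.out_channels)

    def forward(self, views: np.ndarray) -> tuple[Tensor, Tensor]:
        views = np.asarray(views, dtype=np.float64)
        if views.ndim != 4:
            raise ValueError(f"expected (B, N, H, W) views, got shape {views.shape}")
        b, n, h, w = views.shape
        imgs = views.reshape(b * n, 1, h, w)
        if self.backbone.in_channels == 3:
            imgs = np.repeat(imgs, 3, axis=1)  # replicate for RGB backbones
        elif self.backbone.in_channels != 1:
            raise ValueError("backbone must ingest 1- or 3-channel images")
        fmap = self.backbone(Tensor(imgs))
        pooled = self.gem(fmap)          # (B*N, C)
        x = self.bn(pooled)
        return fmap, x.reshape(b, n, self.backbone.out_channels)
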