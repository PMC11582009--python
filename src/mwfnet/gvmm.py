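"""Gated View Measurement Module: per-view discriminability scores.

A view's weight in the fusion should reflect how much discriminative
morphology it actually shows.  Because neuron drawings are sparse, the
score is computed only from salient feature regions: the raw feature map
is min-max normalised to [0, 1], entries below a threshold ``T1`` are
zeroed by a binary mask (boundary values equal to ``T1`` are kept),

    F'_ij = F_ij * M_ij,   M_ij = 1 iff F_ij >= T1,

and a small scoring head maps the masked map to a scalar ``s``.  The
discriminability score is then

    d = sigmoid(log(|s| + eps)),

where the absolute value and logarithm keep the sigmoid input out of its
saturated regime, so ``d`` lies strictly inside (0, 1).

Two head wirings are provided.  ``"conv"`` follows the module's textual
description: a 1x1 convolution halving the channel count, flatten, batch
normalization, and a fully connected layer to one output.  ``"pooled"``
averages the masked map over space first and applies a single C -> 1
fully connected layer; at C = 2048 this variant costs ~2e-3 M parameters
(the published parameter budget for the module) whereas the conv head
costs ~2 M.  The conv head is the default.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import BatchNorm1d, Conv2d, Linear, Module

__all__ = ["mask_salient", "normalize_feature_map", "GVMM", "score_view", "measure_views"]

# defines d at s = 0 while perturbing d(1) = 0.5 by < 1e-12
_LOG_EPS = 1e-12
_NORM_EPS = 1e-12


def normalize_feature_map(fmap: np.ndarray, mode: str = "per_view") -> np.ndarray:
    """Min-max normalise a (C, H, W) feature map to [0, 1].

    ``per_view`` uses one min/max over the whole map; ``per_channel``
    normalises each channel independently.
    """
    fmap = np.asarray(fmap, dtype=float)
    if mode == "per_view":
        lo, hi = fmap.min(), fmap.max()
        return (fmap - lo) / (hi - lo + _NORM_EPS)
    if mode == "per_channel":
        lo = fmap.min(axis=(-2, -1), keepdims=True)
        hi = fmap.max(axis=(-2, -1), keepdims=True)
        return (fmap - lo) / (hi - lo + _NORM_EPS)
    raise ValueError(f"unknown normalization mode {mode!r}")


def mask_salient(fmap: np.ndarray, t1: float) -> np.ndarray:
    """Zero entries of a normalised feature map strictly below ``t1``.

    Entries exactly equal to ``t1`` are kept.  Idempotent for fixed t1.
    """
    if not (0.0 <= t1 <= 1.0):
        raise ValueError(f"T1 must be in [0, 1], got {t1}")
    fmap = np.asarray(fmap, dtype=float)
    return fmap * (fmap >= t1)


class GVMM(Module):
    """Scores every view of a batch from its salient feature regions.

    Input feature maps have shape (B*N, C, H, W); output is a Tensor of
    shape (B, N) of scores in (0, 1).  The same head weights are applied
    to every view.
    """

    def __init__(self, channels: int, spatial: tuple[int, int],
                 rng: np.random.Generator, t1: float = 0.9,
                 norm: str = "per_view", head: str = "conv"):
        super().__init__()
        if not (0.0 <= t1 <= 1.0):
            raise ValueError(f"T1 must be in [0, 1], got {t1}")
        self.t1 = t1
        self.norm = norm
        self.head_kind = head
        h, w = spatial
        if head == "conv":
            half = max(channels // 2, 1)
            self.reduce = Conv2d(channels, half, 1, rng)
            self.head_bn = BatchNorm1d(half * h * w)
            self.fc = Linear(half * h * w, 1, rng)
        elif head == "pooled":
            self.fc = Linear(channels, 1, rng)
        else:
            raise ValueError(f"unknown GVMM head {head!r}")

    def _normalize_and_mask(self, fmap: Tensor) -> Tensor:
        data = fmap.data
        if self.norm == "per_view":
            lo = data.min(axis=(1, 2, 3), keepdims=True)
            hi = data.max(axis=(1, 2, 3), keepdims=True)
        elif self.norm == "per_channel":
            lo = data.min(axis=(2, 3), keepdims=True)
            hi = data.max(axis=(2, 3), keepdims=True)
        else:
            raise ValueError(f"unknown normalization mode {self.norm!r}")
        scale = 1.0 / (hi - lo + _NORM_EPS)
        normed = (fmap - Tensor(lo)) * Tensor(scale)
        mask = (normed.data >= self.t1).astype(np.float64)
        return normed * Tensor(mask)

    def _head(self, masked: Tensor) -> Tensor:
        if self.head_kind == "conv":
            z = self.reduce(masked)
            z = z.reshape(z.shape[0], -1)
            z = self.head_bn(z)
            return self.fc(z)  # (B*N, 1)
        pooled = masked.mean(axis=(2, 3))
        return self.fc(pooled)

    def forward(self, fmap: Tensor, batch: int, n_views: int) -> Tensor:
        masked = self._normalize_and_mask(fmap)
        s = self._head(masked)
        d = ((s.abs() + _LOG_EPS).log()).sigmoid()
        return d.reshape(batch, n_views)


def score_view(masked: np.ndarray, head: GVMM) -> float:
    """Discriminability of one masked (C, H, W) map under a GVMM head."""
    t = Tensor(np.asarray(masked, dtype=float)[None])
    s = head._head(t)
    return float(((s.abs() + _LOG_EPS).log()).sigmoid().data.ravel()[0])


def measure_views(fmaps: np.ndarray, t1: float, head: GVMM) -> np.ndarray:
    """Scores for N feature maps (N, C, H, W), each strictly in (0, 1)."""
    fmaps = np.asarray(fmaps, dtype=float)
    head.t1 = t1
    out = head(Tensor(fmaps), batch=1, n_views=fmaps.shape[0])
    return out.data[0]
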