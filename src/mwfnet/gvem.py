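"""Gated View Enhancement Module: similarity-gated view descriptor mixing.

Rotational views of the same neuron frequently look alike, so naive
fusion keeps redundant information.  GVEM measures the pairwise
similarity of the N view descriptors, suppresses pairs that are too
similar and amplifies dissimilar ones, then re-mixes transformed
descriptors:

1. three transform layers L1, L2, L3 (a 1x1 convolution over the
   descriptor channels, i.e. a linear map C -> C, plus normalization)
   project descriptors into a common space;
2. the similarity matrix A is the row softmax of the pairwise dot
   products:  a_ij = exp(L1(x_i) . L2(x_j)) / sum_j exp(...);
3. a threshold T2 splits A into complementary binary masks
   M1 = [A >= T2] (redundant pairs; boundary values go to M1) and
   M2 = [A < T2];
4. the gated matrix takes exp(-a_ij) on M1 entries and exp(a_ij) on M2
   entries and is renormalised with a row softmax to give A';
5. the enhanced descriptors are X' = A' @ L3(X).

Since exp(a) > exp(-a) for a > 0, below-threshold (dissimilar) entries
always receive more mass than equally-similar above-threshold ones.  A
``literal_eq6`` flag switches step 4 to the alternative algebraic
reading ``exp(-A) * M1 + exp(A * M2)``, in which masked-off entries
contribute exp(0) = 1 to the other branch.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import BatchNorm1d, Linear, Module, softmax

__all__ = [
    "TransformLayer",
    "pairwise_similarity",
    "gate_masks",
    "modify_similarity",
    "enhance",
    "GVEM",
]


class TransformLayer(Module):
    """1x1 convolution over descriptor channels (C -> C) + normalization."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.linear = Linear(channels, channels, rng)
        self.bn = BatchNorm1d(channels)

    def forward(self, x: Tensor) -> Tensor:
        flat = x.reshape(-1, x.shape[-1])
        out = self.bn(self.linear(flat))
        return out.reshape(x.shape)


def pairwise_similarity(x: np.ndarray, l1=None, l2=None) -> np.ndarray:
    """Row-stochastic similarity matrix of N descriptors (N, C).

    ``l1``/``l2`` are optional callables mapping (N, C) -> (N, C); when
    omitted the identity is used.  Unscaled dot products feed a row
    softmax, so each row sums to one.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("pairwise_similarity expects (N>=2, C) descriptors")
    y1 = _apply(l1, x)
    y2 = _apply(l2, x)
    logits = y1 @ y2.T
    return _row_softmax(logits)


def _apply(layer, x: np.ndarray) -> np.ndarray:
    if layer is None:
        return x
    if isinstance(layer, Module):
        out = layer(Tensor(x))
        return out.data
    return np.asarray(layer(x), dtype=float)


def _row_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gate_masks(a: np.ndarray, t2: float) -> tuple[np.ndarray, np.ndarray]:
    """Complementary binary masks M1 = [A >= T2], M2 = [A < T2]."""
    if not (0.0 <= t2 <= 1.0):
        raise ValueError(f"T2 must be in [0, 1], got {t2}")
    a = np.asarray(a, dtype=float)
    m1 = (a >= t2).astype(float)
    return m1, 1.0 - m1


def modify_similarity(a: np.ndarray, masks: tuple[np.ndarray, np.ndarray],
                      literal_eq6: bool = False) -> np.ndarray:
    """Gate and renormalise a similarity matrix; rows sum to one."""
    a = np.asarray(a, dtype=float)
    m1, m2 = masks
    if not np.allclose(m1 + m2, 1.0):
        raise ValueError("masks must form an exact partition")
    if literal_eq6:
        b = np.exp(-a) * m1 + np.exp(a * m2)
    else:
        b = np.exp(-a) * m1 + np.exp(a) * m2
    return _row_softmax(b)


def enhance(x: np.ndarray, a_mod: np.ndarray, l3=None) -> np.ndarray:
    """Enhanced descriptors X' = A' @ L3(X)."""
    x = np.asarray(x, dtype=float)
    a_mod = np.asarray(a_mod, dtype=float)
    y = _apply(l3, x)
    if a_mod.shape != (x.shape[0], x.shape[0]):
        raise ValueError(
            f"A' must be ({x.shape[0]}, {x.shape[0]}), got {a_mod.shape}"
        )
    return a_mod @ y


class GVEM(Module):
    """Batched gated view enhancement on descriptors (B, N, C)."""

    def __init__(self, channels: int, rng: np.random.Generator, t2: float = 0.8,
                 literal_eq6: bool = False):
        super().__init__()
        if not (0.0 <= t2 <= 1.0):
            raise ValueError(f"T2 must be in [0, 1], got {t2}")
        self.t2 = t2
        self.literal_eq6 = literal_eq6
        self.l1 = TransformLayer(channels, rng)
        self.l2 = TransformLayer(channels, rng)
        self.l3 = TransformLayer(channels, rng)

    def similarity(self, x: Tensor) -> Tensor:
        logits = self.l1(x) @ self.l2(x).swapaxes(-1, -2)  # (B, N, N)
        return softmax(logits, axis=-1)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (X', A') for descriptors x of shape (B, N, C)."""
        a = self.similarity(x)
        m1 = (a.data >= self.t2).astype(np.float64)
        m2 = 1.0 - m1
        if self.literal_eq6:
            b = (-a).exp() * Tensor(m1) + (a * Tensor(m2)).exp()
        else:
            b = (-a).exp() * Tensor(m1) + a.exp() * Tensor(m2)
        a_mod = softmax(b, axis=-1)
        x_enh = a_mod @ self.l3(x)
        return x_enh, a_mod
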