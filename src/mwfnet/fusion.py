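"""Weighted-view fusion and classification.

The instance-level descriptor of a neuron is the discriminability-
weighted sum of its enhanced view descriptors,

    X_t = D @ X'        (1 x N times N x C),

optionally with a residual connection from the mean of the raw pooled
view descriptors followed by batch normalization ("residual batch
normalization").  A classifier of two 200-unit fully connected layers
(one ReLU between them) and a softmax output layer predicts the neuron
type.  Manual view-weight vectors can be injected in place of the
learned scores for ablation studies.

:class:`MWFNet` assembles the full network: shared-backbone view
encoding with GeM pooling, the measurement (GVMM) and enhancement
(GVEM) gates — each independently toggleable — and this fusion head.
With both gates disabled the model reduces to the plain baseline that
averages view descriptors.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .encoder import ViewEncoder, build_backbone
from .gvem import GVEM
from .gvmm import GVMM
from .nn import BatchNorm1d, Linear, Module, softmax

__all__ = ["fuse", "classify", "ClassifierHead", "MWFNet"]


def fuse(d: np.ndarray, x_enh: np.ndarray, residual: np.ndarray | None = None) -> np.ndarray:
    """Instance descriptor ``X_t = D @ X'`` for one neuron.

    ``d``: (N,) view weights; ``x_enh``: (N, C) enhanced descriptors;
    ``residual``: optional (N, C) raw descriptors whose mean is added.
    """
    d = np.asarray(d, dtype=float)
    x_enh = np.asarray(x_enh, dtype=float)
    if d.ndim != 1 or x_enh.ndim != 2 or d.shape[0] != x_enh.shape[0]:
        raise ValueError(
            f"shape mismatch: D {d.shape} vs X' {x_enh.shape} (need (N,) and (N, C))"
        )
    out = d @ x_enh
    if residual is not None:
        out = out + np.asarray(residual, dtype=float).mean(axis=0)
    return out


class ClassifierHead(Module):
    """Two 200-unit FC layers with one ReLU, then a softmax output layer."""

    def __init__(self, in_features: int, n_classes: int, rng: np.random.Generator,
                 hidden: int = 200):
        super().__init__()
        self.fc1 = Linear(in_features, hidden, rng)
        self.fc2 = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Returns logits; apply softmax for probabilities."""
        return self.out(self.fc2(self.fc1(x).relu()))


def classify(x_t: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Class probability vector for one instance descriptor."""
    logits = head(Tensor(np.asarray(x_t, dtype=float)[None]))
    return softmax(logits, axis=-1).data[0]


class MWFNet(Module):
    """Multi-gate weighted fusion network over rotational neuron views.

    Parameters mirror the method's hyper-parameters: ``t1`` is the
    salience threshold of the measurement gate, ``t2`` the similarity
    threshold of the enhancement gate, ``p_init`` the GeM exponent
    initialisation.  ``gvmm``/``gvem`` toggle the gates (both off is the
    ablation baseline), ``manual_weights`` replaces the learned view
    weights with a fixed vector.
    """

    def __init__(self, n_views: int, image_size: int, n_classes: int,
                 rng: np.random.Generator, backbone: str = "tiny",
                 backbone_kwargs: dict | None = None,
                 p_init: float = 3.0, gem_per_channel: bool = False,
                 gvmm: bool = True, t1: float = 0.9,
                 gvmm_norm: str = "per_view", gvmm_head: str = "conv",
                 gvem: bool = True, t2: float = 0.8, literal_eq6: bool = False,
                 residual: bool = True, fusion_bn: bool = True,
                 manual_weights: np.ndarray | None = None,
                 classifier_hidden: int = 200):
        super().__init__()
        self.n_views = n_views
        self.n_classes = n_classes
        net = build_backbone(backbone, rng, **(backbone_kwargs or {}))
        self.encoder = ViewEncoder(net, p_init=p_init, per_channel=gem_per_channel)
        c = net.out_channels
        # one dry pass fixes the feature-map spatial size for the GVMM head
        probe = net(Tensor(np.zeros((1, net.in_channels, image_size, image_size))))
        spatial = probe.shape[2], probe.shape[3]
        self.gvmm = (
            GVMM(c, spatial, rng, t1=t1, norm=gvmm_norm, head=gvmm_head)
            if gvmm else None
        )
        self.gvem = GVEM(c, rng, t2=t2, literal_eq6=literal_eq6) if gvem else None
        self.residual = residual
        self.fusion_bn = BatchNorm1d(c) if fusion_bn else None
        self.manual_weights = (
            None if manual_weights is None
            else np.asarray(manual_weights, dtype=float)
        )
        if self.manual_weights is not None and self.manual_weights.shape != (n_views,):
            raise ValueError(
                f"manual_weights must have shape ({n_views},), "
                f"got {self.manual_weights.shape}"
            )
        self.classifier = ClassifierHead(c, n_classes, rng, hidden=classifier_hidden)

    def forward_full(self, views: np.ndarray) -> dict:
        """Full forward pass; returns all intermediates keyed by name."""
        views = np.asarray(views, dtype=np.float64)
        b, n = views.shape[0], views.shape[1]
        if n != self.n_views:
            raise ValueError(f"model expects {self.n_views} views, got {n}")
        fmap, x = self.encoder(views)            # (B*N, C, h, w), (B, N, C)

        if self.manual_weights is not None:
            d = Tensor(np.tile(self.manual_weights, (b, 1)))
        elif self.gvmm is not None:
            d = self.gvmm(fmap, batch=b, n_views=n)
        else:
            d = Tensor(np.ones((b, n)))

        if self.gvem is not None:
            x_enh, a_mod = self.gvem(x)
        else:
            x_enh, a_mod = x, Tensor(np.tile(np.eye(n), (b, 1, 1)))

        fused = (d.reshape(b, 1, n) @ x_enh).reshape(b, -1)   # (B, C)
        if self.residual:
            fused = fused + x.mean(axis=1)
        if self.fusion_bn is not None:
            fused = self.fusion_bn(fused)
        logits = self.classifier(fused)
        return {
            "feature_maps": fmap, "descriptors": x, "scores": d,
            "similarity": a_mod, "enhanced": x_enh, "instance": fused,
            "logits": logits,
        }

    def forward(self, views: np.ndarray) -> Tensor:
        return self.forward_full(views)["logits"]

    def predict_proba(self, views: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities, deterministic at fixed weights."""
        was_training = self.training
        self.eval()
        try:
            probs = softmax(self.forward(views), axis=-1).data
        finally:
            self.train(was_training)
        return probs
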