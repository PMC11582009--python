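"""scikit-learn style estimators wrapping the multi-view pipeline.

:class:`ViewProjector` is a transformer turning SWC morphologies (or
paths to them) into stacked binary view arrays, and
:class:`MWFNetClassifier` is a classifier over those views (it also
accepts raw morphologies and projects internally).  Both follow the
scikit-learn contract — ``get_params``/``set_params``, ``fit`` returning
``self``, fitted attributes with trailing underscores — so they compose
with pipelines and model selection::

    from sklearn.pipeline import make_pipeline
    clf = make_pipeline(ViewProjector(image_size=64),
                        MWFNetClassifier(epochs=20, random_state=0))
    clf.fit(morphologies, labels)
"""

from __future__ import annotations

import os

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .pipeline import ExperimentConfig, _predict_in_batches, project_dataset, train
from .projection import ProjectionConfig
from .swc import NeuronMorphology, read_swc

__all__ = ["ViewProjector", "MWFNetClassifier"]


def _as_morphologies(X) -> list[NeuronMorphology]:
    out = []
    for item in X:
        if isinstance(item, NeuronMorphology):
            out.append(item)
        elif isinstance(item, (str, os.PathLike)):
            out.append(read_swc(item))
        else:
            raise TypeError(
                f"expected NeuronMorphology or SWC path, got {type(item).__name__}"
            )
    return out


class ViewProjector(TransformerMixin, BaseEstimator):
    """Transform SWC morphologies into (n, N, H, W) binary view stacks."""

    def __init__(self, phi_deg: float = 45.0, image_size: int = 224,
                 margin_frac: float = 0.05, line_thickness_px: int = 1,
                 cache_dir: str | None = None):
        self.phi_deg = phi_deg
        self.image_size = image_size
        self.margin_frac = margin_frac
        self.line_thickness_px = line_thickness_px
        self.cache_dir = cache_dir

    def fit(self, X=None, y=None) -> "ViewProjector":
        self.n_views_ = ProjectionConfig(self.phi_deg, self.image_size).n_views
        return self

    def transform(self, X) -> np.ndarray:
        cfg = ProjectionConfig(
            phi_deg=self.phi_deg, image_size=self.image_size,
            margin_frac=self.margin_frac,
            line_thickness_px=self.line_thickness_px,
        )
        return project_dataset(_as_morphologies(X), cfg, cache_dir=self.cache_dir)


class MWFNetClassifier(ClassifierMixin, BaseEstimator):
    """Multi-gate weighted-fusion neuron-type classifier.

    ``X`` passed to :meth:`fit` may be a pre-projected float array of
    shape (n, N, H, W), or a sequence of morphologies / SWC paths which
    are then projected with the estimator's own projection settings.

    Parameters follow the method's hyper-parameters; see
    :class:`~mwfnet.pipeline.ExperimentConfig`.  ``gvmm`` and ``gvem``
    toggle the measurement and enhancement gates (both ``False`` gives
    the ablation baseline); ``manual_weights`` fixes the view weights.
    """

    def __init__(self, phi_deg: float = 45.0, image_size: int = 224,
                 backbone: str = "tiny", backbone_kwargs: dict | None = None,
                 p_init: float = 3.0, gem_per_channel: bool = False,
                 gvmm: bool = True, t1: float = 0.9,
                 gvmm_norm: str = "per_view", gvmm_head: str = "conv",
                 gvem: bool = True, t2: float = 0.8, literal_eq6: bool = False,
                 residual: bool = True, fusion_bn: bool = True,
                 manual_weights=None, lr: float = 0.001, batch_size: int = 16,
                 epochs: int = 50, random_state: int = 0):
        self.phi_deg = phi_deg
        self.image_size = image_size
        self.backbone = backbone
        self.backbone_kwargs = backbone_kwargs
        self.p_init = p_init
        self.gem_per_channel = gem_per_channel
        self.gvmm = gvmm
        self.t1 = t1
        self.gvmm_norm = gvmm_norm
        self.gvmm_head = gvmm_head
        self.gvem = gvem
        self.t2 = t2
        self.literal_eq6 = literal_eq6
        self.residual = residual
        self.fusion_bn = fusion_bn
        self.manual_weights = manual_weights
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _config(self) -> ExperimentConfig:
        return ExperimentConfig(
            phi_deg=self.phi_deg, image_size=self.image_size,
            backbone=self.backbone,
            backbone_kwargs=dict(self.backbone_kwargs or {}),
            p_init=self.p_init, gem_per_channel=self.gem_per_channel,
            gvmm=self.gvmm, t1=self.t1, gvmm_norm=self.gvmm_norm,
            gvmm_head=self.gvmm_head, gvem=self.gvem, t2=self.t2,
            literal_eq6=self.literal_eq6, residual=self.residual,
            fusion_bn=self.fusion_bn,
            manual_weights=None if self.manual_weights is None
            else tuple(self.manual_weights),
            lr=self.lr, batch_size=self.batch_size, epochs=self.epochs,
            seed=self.random_state,
        )

    def _views(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 4:
            return X.astype(np.float64)
        cfg = self._config().projection()
        return project_dataset(_as_morphologies(X), cfg)

    def fit(self, X, y) -> "MWFNetClassifier":
        views = self._views(X)
        y = np.asarray(y)
        if len(views) != len(y):
            raise ValueError("X and y lengths differ")
        config = self._config()
        ckpt = train(config, views, y)
        self.classes_ = np.asarray(ckpt["classes"])
        self.model_ = ckpt["model"]
        self.loss_log_ = ckpt["loss_log"]
        self.config_ = config
        self.n_views_ = config.n_views
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("this MWFNetClassifier instance is not fitted yet")
        return _predict_in_batches(self.model_, self._views(X))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]
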