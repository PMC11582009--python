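"""End-to-end harness: projection caching, training, stratified k-fold
cross-validation, evaluation and ablation grids.

The defaults mirror the method's published settings (phi = 45 deg and
eight views, 224 px images, GeM p initialised to 3, T1 = 0.9, T2 = 0.8,
Adam at learning rate 0.001, batch size 16, 10 folds).  Desk-scale runs
on synthetic data override the image size and use the tiny backbone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import nn
from .fusion import MWFNet
from .metrics import EvaluationReport, evaluate_predictions
from .projection import ProjectionConfig, project_views
from .swc import NeuronMorphology
from .synthetic import SyntheticDataset

logger = logging.getLogger("mwfnet")

__all__ = [
    "ExperimentConfig",
    "kfold_split",
    "project_dataset",
    "train",
    "evaluate",
    "cross_validate",
    "ablation_run",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one experiment; defaults follow the published setup."""

    phi_deg: float = 45.0
    image_size: int = 224
    margin_frac: float = 0.05
    backbone: str = "tiny"  # "resnet50" documented but needs torch
    backbone_kwargs: dict = field(default_factory=dict)
    p_init: float = 3.0
    gem_per_channel: bool = False
    gvmm: bool = True
    t1: float = 0.9
    gvmm_norm: str = "per_view"
    gvmm_head: str = "conv"
    gvem: bool = True
    t2: float = 0.8
    literal_eq6: bool = False
    residual: bool = True
    fusion_bn: bool = True
    manual_weights: tuple | None = None
    lr: float = 0.001
    batch_size: int = 16
    epochs: int = 50
    folds: int = 10
    seed: int = 0

    @property
    def n_views(self) -> int:
        return int(np.floor(360.0 / self.phi_deg))

    def projection(self) -> ProjectionConfig:
        return ProjectionConfig(
            phi_deg=self.phi_deg, image_size=self.image_size,
            margin_frac=self.margin_frac,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def build_model(self, n_classes: int, rng: np.random.Generator) -> MWFNet:
        return MWFNet(
            n_views=self.n_views, image_size=self.image_size,
            n_classes=n_classes, rng=rng, backbone=self.backbone,
            backbone_kwargs=dict(self.backbone_kwargs), p_init=self.p_init,
            gem_per_channel=self.gem_per_channel, gvmm=self.gvmm, t1=self.t1,
            gvmm_norm=self.gvmm_norm, gvmm_head=self.gvmm_head,
            gvem=self.gvem, t2=self.t2, literal_eq6=self.literal_eq6,
            residual=self.residual, fusion_bn=self.fusion_bn,
            manual_weights=self.manual_weights,
        )


def kfold_split(labels: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train, test) index pairs; disjoint, exhaustive.

    Falls back to plain k-fold with a warning if some class has fewer
    samples than folds (degenerate stratification).
    """
    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(labels) < folds:
        raise ValueError("need at least as many samples as folds")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        warnings.warn(
            "a class has fewer samples than folds; using unstratified splits",
            stacklevel=2,
        )
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(labels)]
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(labels)), labels)]


def _morphology_hash(m: NeuronMorphology) -> str:
    h = hashlib.sha256()
    for n in m.nodes:
        h.update(f"{n.node_id},{n.type_code},{n.x!r},{n.y!r},{n.z!r},{n.parent_id}".encode())
    return h.hexdigest()[:20]


def project_dataset(morphologies: list[NeuronMorphology], cfg: ProjectionConfig,
                    cache_dir: str | Path | None = None) -> np.ndarray:
    """Project every morphology; returns float views (n, N, H, W).

    With ``cache_dir`` set, each projection is cached on disk keyed by
    the SWC node table hash and the projection settings.
    """
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    key_suffix = f"{cfg.phi_deg}_{cfg.image_size}_{cfg.margin_frac}_{cfg.line_thickness_px}"
    out = []
    for m in morphologies:
        path = cache / f"{_morphology_hash(m)}_{key_suffix}.npz" if cache else None
        if path is not None and path.exists():
            out.append(np.load(path)["views"])
            continue
        arr = project_views(m, cfg).as_array()
        if path is not None:
            np.savez_compressed(path, views=arr)
        out.append(arr)
    return np.stack(out)


def _encode_labels(labels: np.ndarray) -> tuple[np.ndarray, list]:
    classes = sorted(set(np.asarray(labels).tolist()))
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[l] for l in labels]), classes


def train(config: ExperimentConfig, views: np.ndarray, labels: np.ndarray) -> dict:
    """Train an MWFNet on projected views; returns a checkpoint dict.

    The checkpoint holds the model, its weights, the label vocabulary,
    the config hash and the per-epoch loss log.  Training aborts with a
    diagnostic if the loss becomes non-finite.
    """
    y, classes = _encode_labels(labels)
    rng = np.random.default_rng(config.seed)
    model = config.build_model(len(classes), rng)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    n = len(views)
    log = []
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # BN needs >= 2 samples
            logits = model(views[idx])
            loss = nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        log.append(total / n)
        logger.info("epoch %d loss %.4f", epoch, log[-1])
    model.eval()
    return {
        "model": model,
        "state": model.state_dict(),
        "classes": classes,
        "config": config,
        "config_hash": config.config_hash(),
        "loss_log": log,
    }


def evaluate(checkpoint: dict, views: np.ndarray, labels: np.ndarray) -> EvaluationReport:
    """Evaluate a trained checkpoint on a held-out set."""
    if len(views) == 0:
        raise ValueError("cannot evaluate an empty test set")
    model: MWFNet = checkpoint["model"]
    classes = checkpoint["classes"]
    unknown = set(np.asarray(labels).tolist()) - set(classes)
    if unknown:
        raise ValueError(f"labels absent from training: {sorted(unknown)}")
    probs = _predict_in_batches(model, views)
    pred = [classes[i] for i in probs.argmax(axis=1)]
    return evaluate_predictions(np.asarray(labels), np.asarray(pred), labels=classes)


def _predict_in_batches(model: MWFNet, views: np.ndarray, batch: int = 32) -> np.ndarray:
    chunks = [
        model.predict_proba(views[i:i + batch]) for i in range(0, len(views), batch)
    ]
    return np.concatenate(chunks)


def cross_validate(config: ExperimentConfig, views: np.ndarray,
                   labels: np.ndarray) -> EvaluationReport:
    """Stratified k-fold CV; the summary pools fold confusion matrices.

    The returned report's accuracy is the mean of the per-fold
    accuracies (each sample is tested exactly once, and folds are equal
    sized up to one sample, so this matches the pooled accuracy).
    """
    labels = np.asarray(labels)
    splits = kfold_split(labels, config.folds, config.seed)
    fold_reports = []
    for k, (tr, te) in enumerate(splits):
        ckpt = train(config, views[tr], labels[tr])
        rep = evaluate(ckpt, views[te], labels[te])
        logger.info("fold %d accuracy %.3f", k, rep.accuracy)
        fold_reports.append(rep)
    cm = sum(r.confusion for r in fold_reports)
    pooled = evaluate_predictions(
        *_confusion_to_pairs(cm, fold_reports[0].labels), labels=fold_reports[0].labels
    )
    pooled.per_fold = fold_reports
    pooled.accuracy = float(np.mean([r.accuracy for r in fold_reports]))
    return pooled


def _confusion_to_pairs(cm: np.ndarray, labels: list) -> tuple[np.ndarray, np.ndarray]:
    y_true, y_pred = [], []
    for i, lab_t in enumerate(labels):
        for j, lab_p in enumerate(labels):
            y_true.extend([lab_t] * cm[i, j])
            y_pred.extend([lab_p] * cm[i, j])
    return np.asarray(y_true), np.asarray(y_pred)


def count_model_parameters(config: ExperimentConfig, n_classes: int) -> int:
    """Trainable parameter count of the configured model."""
    model = config.build_model(n_classes, np.random.default_rng(0))
    return nn.count_parameters(model)


def ablation_run(base: ExperimentConfig, views: np.ndarray, labels: np.ndarray,
                 grid: list[dict]) -> list[dict]:
    """Run a config grid; one row (report + parameter count) per cell."""
    rows = []
    n_classes = len(set(np.asarray(labels).tolist()))
    for overrides in grid:
        cfg = replace(base, **overrides)
        rep = cross_validate(cfg, views, labels)
        rows.append(
            {
                **overrides,
                "accuracy": rep.accuracy,
                "macro_f1": rep.macro_f1,
                "n_parameters": count_model_parameters(cfg, n_classes),
                "report": rep,
            }
        )
    return rows


def save_checkpoint(checkpoint: dict, path: str | Path) -> None:
    """Persist weights + config hash as an .npz archive."""
    meta = {
        "classes": json.dumps([str(c) for c in checkpoint["classes"]]),
        "config": json.dumps(asdict(checkpoint["config"]), default=str),
        "config_hash": checkpoint["config_hash"],
    }
    arrays = {f"param::{k}": v for k, v in checkpoint["state"].items()}
    np.savez(path, **arrays, **{k: np.array(v) for k, v in meta.items()})


def load_checkpoint(path: str | Path) -> dict:
    """Load a checkpoint saved by :func:`save_checkpoint`."""
    data = np.load(path, allow_pickle=False)
    classes = json.loads(str(data["classes"]))
    cfg_dict = json.loads(str(data["config"]))
    cfg_dict["backbone_kwargs"] = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in cfg_dict.get("backbone_kwargs", {}).items()
    }
    if cfg_dict.get("manual_weights") is not None:
        cfg_dict["manual_weights"] = tuple(cfg_dict["manual_weights"])
    config = ExperimentConfig(**cfg_dict)
    state = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    model = config.build_model(len(classes), np.random.default_rng(0))
    model.load_state_dict(state)
    model.eval()
    return {
        "model": model, "state": state, "classes": classes,
        "config": config, "config_hash": str(data["config_hash"]),
        "loss_log": [],
    }
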