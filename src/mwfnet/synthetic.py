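"""Synthetic labeled SWC neuron trees with class-dependent branching.

The generator grows stochastic arbors from a soma root: each stem
elongates in fixed-length jittered steps whose direction is the previous
direction blended with a class-specific trunk bias plus isotropic noise;
at the end of a branch it bifurcates with probability ``branch_prob``
(up to ``max_depth`` branch orders) at a configurable mean split angle.
Classes therefore differ in branch counts, tip counts and total cable
length — enough signal that the full projection-classification pipeline
is testable at desk scale without downloading curated reconstructions.

This is deliberately not a biophysical simulator: no soma geometry,
tapering diameters, tortuosity statistics or boutons — a green test on
these trees establishes that the pipeline learns branching-statistic
differences, not that it matches repository-grade data.

Two presets ship: ``separable-3`` (three visually distinct classes) and
``confusable-2`` (two nearly identical classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .swc import NeuronMorphology, SwcNode, write_swc

__all__ = ["MorphClassSpec", "SyntheticDataset", "grow_neuron", "make_dataset", "PRESETS"]


@dataclass(frozen=True)
class MorphClassSpec:
    """Growth statistics of one synthetic morphology class."""

    class_name: str
    branch_prob: float = 0.5
    segment_length_mean: float = 20.0  # µm per elongation step
    segment_length_sd: float = 4.0
    max_depth: int = 4
    trunk_bias: tuple[float, float, float] = (0.0, 1.0, 0.0)
    apical_trunk: bool = False
    n_stems: int = 3
    steps_per_branch: int = 5
    split_angle_deg: float = 40.0
    direction_noise: float = 0.25
    bias_strength: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")
        if self.max_depth < 1 or self.n_stems < 1 or self.steps_per_branch < 1:
            raise ValueError("max_depth, n_stems and steps_per_branch must be >= 1")


@dataclass
class SyntheticDataset:
    """Labeled synthetic morphologies plus their provenance manifest."""

    morphologies: list[NeuronMorphology]
    manifest: pd.DataFrame  # columns: path, label, seed

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["label"].to_numpy()


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 1.0, 0.0])


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = rng.standard_normal(3)
    p = r - np.dot(r, v) * v
    return _unit(p)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    # Rodrigues rotation of v about a unit axis
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1.0 - np.cos(angle))
    )


def grow_neuron(spec: MorphClassSpec, seed: int) -> NeuronMorphology:
    """Grow one valid SWC tree; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    bias = _unit(np.asarray(spec.trunk_bias, dtype=float))
    nodes = [SwcNode(1, 1, 0.0, 0.0, 0.0, 2.0, -1)]
    next_id = 2

    def step_direction(prev: np.ndarray) -> np.ndarray:
        noise = rng.standard_normal(3) * spec.direction_noise
        return _unit(prev + spec.bias_strength * bias + noise)

    def grow_branch(parent_id: int, pos: np.ndarray, direction: np.ndarray,
                    depth: int, type_code: int) -> None:
        nonlocal next_id
        for _ in range(spec.steps_per_branch):
            direction = step_direction(direction)
            length = max(
                rng.normal(spec.segment_length_mean, spec.segment_length_sd), 0.5
            )
            pos = pos + direction * length
            nodes.append(
                SwcNode(next_id, type_code, float(pos[0]), float(pos[1]),
                        float(pos[2]), 0.5, parent_id)
            )
            parent_id = next_id
            next_id += 1
        if depth < spec.max_depth and rng.random() < spec.branch_prob:
            axis = _perpendicular(direction, rng)
            half = np.deg2rad(spec.split_angle_deg) / 2.0
            for sign in (+1.0, -1.0):
                child_dir = _unit(_rotate_about(direction, axis, sign * half))
                grow_branch(parent_id, pos, child_dir, depth + 1, type_code)

    for stem in range(spec.n_stems):
        tcode = 4 if (spec.apical_trunk and stem == 0) else 3
        direction = _unit(rng.standard_normal(3) + 1.5 * bias)
        grow_branch(1, np.zeros(3), direction, depth=0, type_code=tcode)

    m = NeuronMorphology(nodes, label=spec.class_name)
    return m


def make_dataset(specs: list[MorphClassSpec], per_class: int, seed: int,
                 out_dir: str | Path | None = None) -> SyntheticDataset:
    """Balanced labeled dataset; optionally written as SWC files + manifest.

    Per-sample seeds are spawned deterministically from ``seed`` and the
    (class, index) pair and recorded in the manifest, so any sample can
    be regenerated in isolation.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    if len(specs) < 1:
        raise ValueError("at least one class spec is required")
    morphologies, rows = [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for ci, spec in enumerate(specs):
        for i in range(per_class):
            sample_seed = int(
                np.random.SeedSequence([seed, ci, i]).generate_state(1)[0] & 0x7FFFFFFF
            )
            m = grow_neuron(spec, sample_seed)
            path = ""
            if out is not None:
                path = str(out / f"{spec.class_name}_{i:04d}.swc")
                write_swc(m, path)
                m.source_path = path
            morphologies.append(m)
            rows.append({"path": path, "label": spec.class_name, "seed": sample_seed})
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return SyntheticDataset(morphologies=morphologies, manifest=manifest)


PRESETS: dict[str, list[MorphClassSpec]] = {
    # three classes whose branch counts / cable lengths are well separated:
    # a depth-1 stump on branch count alone distinguishes them
    "separable-3": [
        MorphClassSpec("sparse", branch_prob=0.15, max_depth=3, n_stems=2,
                       segment_length_mean=25.0, trunk_bias=(0.0, 1.0, 0.0),
                       apical_trunk=True),
        MorphClassSpec("bushy", branch_prob=0.6, max_depth=4, n_stems=4,
                       segment_length_mean=18.0, trunk_bias=(0.3, 0.8, 0.0)),
        MorphClassSpec("dense", branch_prob=0.95, max_depth=5, n_stems=5,
                       segment_length_mean=12.0, trunk_bias=(0.0, 0.3, 0.5),
                       direction_noise=0.45),
    ],
    # two near-identical classes for hard-negative smoke tests
    "confusable-2": [
        MorphClassSpec("twin_a", branch_prob=0.50, max_depth=4, n_stems=3),
        MorphClassSpec("twin_b", branch_prob=0.55, max_depth=4, n_stems=3),
    ],
}
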