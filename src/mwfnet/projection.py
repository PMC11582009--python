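"""PCA alignment and rotational 2D binary-view projection of neurons.

A 3D reconstruction is first aligned to a canonical frame with principal
component analysis (largest-variance axis to x, second to y, third to z,
centroid at the origin) so that similarly shaped neurons yield similar
view images regardless of their original orientation.  The aligned
neuron is then rotated by an angle theta about the y-axis followed by
the same angle about the z-axis, and orthographically projected onto the
x-y plane.  Sweeping theta over [0, 360) in steps of ``phi_deg`` yields
``N = floor(360 / phi_deg)`` binary view images; both the nodes and the
child-parent segments are rasterised so arbor connectivity is preserved.

Rotations are right-handed, active, applied to column vectors; the
composite is ``R_z(theta) @ R_y(theta)`` (y-rotation first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as _bresenham_line

from .swc import NeuronMorphology

__all__ = [
    "ProjectionConfig",
    "ViewImage",
    "ViewStack",
    "pca_align",
    "rotate_then_project",
    "rasterize",
    "project_views",
    "save_views",
]

_SKEW_TOL = 1e-9


@dataclass(frozen=True)
class ProjectionConfig:
    """Settings for rotational multi-view projection.

    ``phi_deg`` is the rotation increment in degrees; the number of views
    is ``floor(360 / phi_deg)``.  Images are square ``image_size`` pixel
    binary rasters with an empty border of ``margin_frac`` of the image
    on each side; lines are drawn ``line_thickness_px`` pixels wide.
    """

    phi_deg: float = 45.0
    image_size: int = 224
    margin_frac: float = 0.05
    line_thickness_px: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_deg < 360.0):
            raise ValueError(f"phi_deg must be in (0, 360), got {self.phi_deg}")
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        if not (0.0 <= self.margin_frac < 0.5):
            raise ValueError(f"margin_frac must be in [0, 0.5), got {self.margin_frac}")
        if self.line_thickness_px < 1:
            raise ValueError("line_thickness_px must be >= 1")

    @property
    def n_views(self) -> int:
        return int(np.floor(360.0 / self.phi_deg))


@dataclass
class ViewImage:
    """A single binary projection: ``pixels`` in {0, 1}, shape (H, W)."""

    pixels: np.ndarray
    theta_deg: float
    order_index: int


@dataclass
class ViewStack:
    """The ordered views of one morphology, theta_k = k * phi."""

    views: list[ViewImage]
    source: NeuronMorphology | None = None

    def __len__(self) -> int:
        return len(self.views)

    def as_array(self) -> np.ndarray:
        """Views stacked to an ``(N, H, W)`` float array."""
        return np.stack([v.pixels.astype(np.float64) for v in self.views])


def _principal_axes(xyz: np.ndarray) -> np.ndarray:
    """Columns are the covariance eigenvectors, descending eigenvalue.

    Sign convention: each axis is oriented so the coordinate skewness
    along it is >= 0; for (near-)symmetric clouds the largest-magnitude
    loading is forced positive, giving a deterministic canonical frame.
    eigh returns an orthonormal basis even for repeated/zero eigenvalues,
    which completes degenerate (colinear/coplanar) clouds.
    """
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered / max(len(xyz), 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    for k in range(3):
        t = centered @ axes[:, k]
        skew = float(np.mean(t**3))
        if abs(skew) < _SKEW_TOL:
            lead = int(np.argmax(np.abs(axes[:, k])))
            if axes[lead, k] < 0:
                axes[:, k] = -axes[:, k]
        elif skew < 0:
            axes[:, k] = -axes[:, k]
    return axes


def pca_align(m: NeuronMorphology) -> NeuronMorphology:
    """Rotate a morphology into its canonical PCA frame, centroid at origin."""
    xyz = m.coordinates()
    if len(xyz) == 1:
        return m.with_coordinates(np.zeros((1, 3)))
    axes = _principal_axes(xyz)
    centered = xyz - xyz.mean(axis=0)
    return m.with_coordinates(centered @ axes)


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """Composite view rotation ``R_z(theta) @ R_y(theta)`` (y first)."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    ry = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rz @ ry


def rotate_then_project(m: NeuronMorphology, theta_deg: float) -> NeuronMorphology:
    """Apply the composite view rotation; z is retained for provenance.

    The subsequent orthographic projection uses only (x, y).
    """
    r = rotation_matrix(theta_deg)
    return m.with_coordinates(m.coordinates() @ r.T)


def rasterize(m: NeuronMorphology, cfg: ProjectionConfig) -> ViewImage:
    """Render the (x, y) projection of a morphology as a binary image.

    The projected arbor is min-max scaled isotropically (aspect ratio
    preserved) to fit the image with the configured margin and centred.
    Every node is plotted and every child-parent segment is drawn as a
    Bresenham pixel path, so connectivity survives projection.  A single
    point renders as one foreground blob at the image centre.
    """
    xy = m.coordinates()[:, :2]
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates cannot be rasterised")
    size = cfg.image_size
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    extent = float(max(hi[0] - lo[0], hi[1] - lo[1]))
    avail = (1.0 - 2.0 * cfg.margin_frac) * (size - 1)
    scale = avail / extent if extent > 0 else 0.0
    mid = (lo + hi) / 2.0
    center = (size - 1) / 2.0
    cols = np.clip(np.rint(center + (xy[:, 0] - mid[0]) * scale), 0, size - 1).astype(int)
    rows = np.clip(np.rint(center - (xy[:, 1] - mid[1]) * scale), 0, size - 1).astype(int)

    img = np.zeros((size, size), dtype=np.uint8)
    img[rows, cols] = 1
    for child, parent in m.segments():
        rr, cc = _bresenham_line(rows[child], cols[child], rows[parent], cols[parent])
        img[rr, cc] = 1
    if cfg.line_thickness_px > 1:
        img = ndimage.binary_dilation(
            img, iterations=cfg.line_thickness_px - 1
        ).astype(np.uint8)
    return ViewImage(pixels=img, theta_deg=0.0, order_index=0)


def project_views(m: NeuronMorphology, cfg: ProjectionConfig | None = None) -> ViewStack:
    """PCA-align once, then rotate and rasterise N rotational views.

    View k is taken at theta = k * phi_deg; view 0 is the plain x-y
    orthographic projection of the aligned morphology.
    """
    cfg = cfg or ProjectionConfig()
    aligned = pca_align(m)
    views = []
    for k in range(cfg.n_views):
        theta = k * cfg.phi_deg
        rotated = rotate_then_project(aligned, theta)
        v = rasterize(rotated, cfg)
        v.theta_deg = theta
        v.order_index = k
        views.append(v)
    return ViewStack(views=views, source=m)


def save_views(stack: ViewStack, out_dir: str | Path, stem: str) -> list[Path]:
    """Write each view as an 8-bit {0, 255} PNG; returns the paths."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for v in stack.views:
        p = out_dir / f"{stem}_view{v.order_index}_theta{int(round(v.theta_deg))}.png"
        Image.fromarray((v.pixels * 255).astype(np.uint8)).save(p)
        paths.append(p)
    return paths
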