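"""PCA alignment, view rotation and binary rasterization."""

import numpy as np
import pytest
from skimage.measure import label as cc_label

from mwfnet.projection import (
    ProjectionConfig,
    pca_align,
    project_views,
    rasterize,
    rotate_then_project,
    rotation_matrix,
)
from mwfnet.swc import NeuronMorphology, SwcNode, read_swc
from mwfnet.synthetic import MorphClassSpec, grow_neuron


def _cloud_morphology(xyz):
    nodes = [
        SwcNode(i + 1, 3 if i else 1, *map(float, p), 1.0, i if i else -1)
        for i, p in enumerate(xyz)
    ]
    return NeuronMorphology(nodes)


class TestPcaAlign:
    def test_axis_aligned_cloud_unchanged_up_to_sign(self, rng):
        # spread mostly along x, already centred
        xyz = np.zeros((40, 3))
        xyz[:, 0] = np.linspace(-10, 10, 40) ** 3 / 100  # skewed spread
        xyz[:, 1] = rng.normal(0, 0.5, 40)
        xyz[:, 2] = rng.normal(0, 0.05, 40)
        xyz -= xyz.mean(axis=0)
        out = pca_align(_cloud_morphology(xyz)).coordinates()
        assert np.allclose(np.abs(out[:, 0]), np.abs(xyz[:, 0]), atol=0.5)
        # variance ordering x >= y >= z
        v = out.var(axis=0)
        assert v[0] >= v[1] >= v[2]

    def test_rotation_invariance_of_canonical_frame(self, rng):
        # a generic skewed cloud: alignment of a rotated copy matches
        # alignment of the original (deterministic sign convention)
        xyz = rng.gamma(2.0, 1.0, size=(60, 3)) * np.array([5.0, 2.0, 0.7])
        aligned = pca_align(_cloud_morphology(xyz)).coordinates()
        # independent oracle: eigendecomposition of the 3x3 covariance
        centered = xyz - xyz.mean(axis=0)
        evals = np.linalg.eigvalsh(centered.T @ centered / len(xyz))[::-1]
        assert np.allclose(aligned.var(axis=0), evals, rtol=1e-8)
        rot = rotation_matrix(33.7)
        aligned_rot = pca_align(_cloud_morphology(xyz @ rot.T)).coordinates()
        assert np.allclose(aligned, aligned_rot, atol=1e-6)

    def test_single_node_goes_to_origin(self):
        m = read_swc("1 1 5 6 7 1 -1")
        assert np.allclose(pca_align(m).coordinates(), 0.0)

    def test_degenerate_colinear_cloud(self):
        xyz = np.outer(np.linspace(0, 9, 10) ** 2, [1.0, 1.0, 0.0])
        out = pca_align(_cloud_morphology(xyz)).coordinates()
        assert np.allclose(out[:, 1:], 0.0, atol=1e-9)  # all variance on x


class TestRotation:
    def test_theta_zero_is_identity(self):
        m = read_swc("1 1 1 2 3 1 -1\n2 3 4 5 6 1 1")
        assert np.allclose(rotate_then_project(m, 0.0).coordinates(), m.coordinates())

    def test_theta_360_periodicity(self):
        m = read_swc("1 1 1 2 3 1 -1\n2 3 4 5 6 1 1")
        assert np.allclose(
            rotate_then_project(m, 360.0).coordinates(), m.coordinates(), atol=1e-12
        )

    def test_hand_evaluated_90_degrees(self):
        # (1,0,0): R_y(90) -> (0,0,-1); R_z(90) leaves it -> (0,0,-1)
        m = read_swc("1 1 1 0 0 1 -1")
        out = rotate_then_project(m, 90.0).coordinates()[0]
        assert np.allclose(out, [0.0, 0.0, -1.0], atol=1e-12)

    def test_composite_order_y_then_z(self):
        # (0,0,1): R_y(90) -> (1,0,0); then R_z(90) -> (0,1,0)
        m = read_swc("1 1 0 0 1 1 -1")
        out = rotate_then_project(m, 90.0).coordinates()[0]
        assert np.allclose(out, [0.0, 1.0, 0.0], atol=1e-12)


class TestRasterize:
    CFG = ProjectionConfig(phi_deg=45, image_size=64, margin_frac=0.05)

    def test_single_node_renders_center_pixel(self):
        img = rasterize(read_swc("1 1 3 4 0 1 -1"), self.CFG).pixels
        assert img.sum() == 1
        r, c = np.argwhere(img)[0]
        assert abs(r - 31.5) <= 1 and abs(c - 31.5) <= 1

    def test_segment_draws_connected_bresenham_path(self):
        m = read_swc("1 1 0 0 0 1 -1\n2 3 10 10 0 1 1")
        img = rasterize(m, self.CFG).pixels
        # path length >= Chebyshev distance between projected endpoints
        pts = np.argwhere(img)
        cheb = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))
        assert img.sum() >= cheb + 1
        assert cc_label(img, connectivity=2).max() == 1  # 8-connected path

    def test_disconnected_forest_two_components(self):
        with pytest.warns(UserWarning):
            m = read_swc(
                "1 1 0 0 0 1 -1\n2 3 3 0 0 1 1\n"
                "3 1 20 20 0 1 -1\n4 3 23 20 0 1 3"
            )
        img = rasterize(m, self.CFG).pixels
        assert cc_label(img, connectivity=2).max() == 2

    def test_output_strictly_binary(self):
        m = grow_neuron(MorphClassSpec("t", branch_prob=0.8), seed=3)
        img = rasterize(m, self.CFG).pixels
        assert set(np.unique(img)) <= {0, 1}

    def test_line_thickness_dilates(self):
        m = read_swc("1 1 0 0 0 1 -1\n2 3 10 10 0 1 1")
        thin = rasterize(m, self.CFG).pixels.sum()
        thick_cfg = ProjectionConfig(45, 64, 0.05, line_thickness_px=3)
        assert rasterize(m, thick_cfg).pixels.sum() > thin


class TestProjectViews:
    @pytest.mark.parametrize("phi,n", [(45.0, 8), (90.0, 4), (120.0, 3), (100.0, 3)])
    def test_view_count_floor_360_over_phi(self, phi, n):
        m = grow_neuron(MorphClassSpec("t"), seed=1)
        stack = project_views(m, ProjectionConfig(phi_deg=phi, image_size=32))
        assert len(stack) == n
        assert [v.theta_deg for v in stack.views] == [k * phi for k in range(n)]

    @pytest.mark.parametrize("phi", [0.0, -10.0, 360.0, 400.0])
    def test_invalid_phi_rejected(self, phi):
        with pytest.raises(ValueError):
            ProjectionConfig(phi_deg=phi)

    def test_view0_is_plain_projection_of_aligned(self):
        m = grow_neuron(MorphClassSpec("t", branch_prob=0.5), seed=2)
        cfg = ProjectionConfig(phi_deg=90, image_size=48)
        stack = project_views(m, cfg)
        direct = rasterize(pca_align(m), cfg)
        assert np.array_equal(stack.views[0].pixels, direct.pixels)

    def test_views_match_manual_rotation(self):
        m = grow_neuron(MorphClassSpec("t", branch_prob=0.5), seed=2)
        cfg = ProjectionConfig(phi_deg=120, image_size=48)
        stack = project_views(m, cfg)
        aligned = pca_align(m)
        for k, view in enumerate(stack.views):
            manual = rasterize(rotate_then_project(aligned, k * 120.0), cfg)
            assert np.array_equal(view.pixels, manual.pixels)

    def test_nonempty_views_have_foreground(self, small_dataset):
        cfg = ProjectionConfig(phi_deg=90, image_size=32)
        for m in small_dataset.morphologies[:3]:
            for v in project_views(m, cfg).views:
                assert v.pixels.sum() >= 1
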