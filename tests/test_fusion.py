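"""Weighted fusion, the classifier head and the assembled network."""

import numpy as np
import pytest

from mwfnet.autograd import Tensor
from mwfnet.fusion import ClassifierHead, MWFNet, classify, fuse
from mwfnet.nn import count_parameters


class TestFuse:
    def test_one_hot_selects_single_view(self, rng):
        xp = rng.normal(size=(4, 6))
        d = np.array([0.0, 0.0, 1.0, 0.0])
        assert np.allclose(fuse(d, xp), xp[2])

    def test_all_ones_gives_column_sums(self, rng):
        xp = rng.normal(size=(3, 5))
        assert np.allclose(fuse(np.ones(3), xp), xp.sum(axis=0))

    def test_hand_weighted_product(self):
        out = fuse(np.array([0.5, 0.5]), np.array([[2.0, 0.0], [0.0, 2.0]]))
        assert np.allclose(out, [1.0, 1.0], atol=1e-12)

    def test_residual_adds_mean_of_raw(self, rng):
        xp = rng.normal(size=(3, 4))
        raw = rng.normal(size=(3, 4))
        out = fuse(np.ones(3), xp, residual=raw)
        assert np.allclose(out, xp.sum(axis=0) + raw.mean(axis=0))

    def test_linear_in_enhanced_and_scaling_in_d(self, rng):
        d = rng.uniform(size=4)
        x1, x2 = rng.normal(size=(2, 4, 5))
        assert np.allclose(fuse(d, x1 + x2), fuse(d, x1) + fuse(d, x2))
        assert np.allclose(fuse(3.0 * d, x1), 3.0 * fuse(d, x1))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fuse(np.ones(3), np.ones((4, 2)))


class TestClassify:
    def test_probabilities_valid(self, rng):
        head = ClassifierHead(8, 5, rng).eval()
        p = classify(rng.normal(size=8), head)
        assert p.shape == (5,)
        assert np.all(p >= 0) and np.isclose(p.sum(), 1.0, atol=1e-6)

    def test_zero_weight_head_uniform(self, rng):
        head = ClassifierHead(8, 4, rng).eval()
        for layer in (head.fc1, head.fc2, head.out):
            layer.weight.data[:] = 0
            layer.bias.data[:] = 0
        assert np.allclose(classify(rng.normal(size=8), head), 0.25)


def _tiny_net(seed=0, **kwargs):
    defaults = dict(
        n_views=4, image_size=32, n_classes=3,
        rng=np.random.default_rng(seed),
        backbone_kwargs={"channels": (4, 8)},
    )
    defaults.update(kwargs)
    return MWFNet(**defaults)


class TestMWFNet:
    def _views(self, rng, b=2, n=4, hw=32):
        return rng.integers(0, 2, size=(b, n, hw, hw)).astype(float)

    def test_forward_shapes_and_intermediates(self, rng):
        net = _tiny_net().eval()
        out = net.forward_full(self._views(rng))
        assert out["logits"].shape == (2, 3)
        assert out["scores"].shape == (2, 4)
        assert out["similarity"].shape == (2, 4, 4)
        assert np.all((out["scores"].data > 0) & (out["scores"].data < 1))

    def test_both_gates_off_is_baseline_path(self, rng):
        """gvmm/gvem disabled: D = 1, A' = I, X' = X."""
        net = _tiny_net(gvmm=False, gvem=False).eval()
        views = self._views(rng)
        out = net.forward_full(views)
        assert np.allclose(out["scores"].data, 1.0)
        assert np.allclose(out["similarity"].data, np.eye(4))
        assert np.allclose(out["enhanced"].data, out["descriptors"].data)

    def test_manual_weights_bypass_gvmm(self, rng):
        w = np.array([0.5, 0.3, 0.01, 0.2])
        net = _tiny_net(manual_weights=w).eval()
        out = net.forward_full(self._views(rng))
        assert np.allclose(out["scores"].data, np.tile(w, (2, 1)))

    def test_deterministic_given_seed(self, rng):
        views = self._views(rng)
        p1 = _tiny_net(seed=5).predict_proba(views)
        p2 = _tiny_net(seed=5).predict_proba(views)
        assert np.array_equal(p1, p2)

    def test_permutation_invariance_of_views(self, rng):
        """All stages treat views symmetrically, so permuting the view
        order (with fixed weights, eval mode) leaves the logits unchanged."""
        net = _tiny_net().eval()
        views = self._views(rng, b=1)
        perm = np.array([2, 0, 3, 1])
        out = net.predict_proba(views)
        out_p = net.predict_proba(views[:, perm])
        assert np.allclose(out, out_p, atol=1e-9)

    def test_wrong_view_count_rejected(self, rng):
        net = _tiny_net()
        with pytest.raises(ValueError, match="views"):
            net(self._views(rng, n=6))

    def test_gradient_reaches_every_parameter_tensor(self, rng):
        from mwfnet.nn import cross_entropy

        net = _tiny_net()
        views = rng.uniform(size=(4, 4, 32, 32)) > 0.5
        loss = cross_entropy(net(views.astype(float)), np.array([0, 1, 2, 0]))
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None, f"{name} got no gradient"
            assert np.any(p.grad != 0), f"{name} gradient identically zero"

    def test_probabilities_form_distribution(self, rng):
        net = _tiny_net().eval()
        p = net.predict_proba(self._views(rng, b=3))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)


class TestParameterBudget:
    def test_gvem_at_c2048_adds_about_12_6_million(self, rng):
        from mwfnet.gvem import GVEM

        n_params = count_parameters(GVEM(2048, rng))
        # three 1x1 (2048 -> 2048) transforms with bias + BN affine pairs
        assert n_params == 3 * (2048 * 2048 + 2048) + 3 * 2 * 2048
        assert abs(n_params / 1e6 - 12.600) < 0.01
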