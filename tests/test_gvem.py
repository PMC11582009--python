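"""Pairwise view similarity, gating and descriptor enhancement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from mwfnet.autograd import Tensor
from mwfnet.gvem import (
    GVEM,
    enhance,
    gate_masks,
    modify_similarity,
    pairwise_similarity,
)


class TestPairwiseSimilarity:
    def test_identical_views_uniform_rows(self):
        x = np.tile([1.0, 2.0, 3.0], (4, 1))
        a = pairwise_similarity(x)
        assert np.allclose(a, 0.25)

    def test_rows_sum_to_one(self, rng):
        x = rng.normal(size=(6, 8))
        a = pairwise_similarity(x)
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(a >= 0)

    def test_hand_softmax_row(self):
        # construct descriptors whose logit row 0 is [0, ln 2]
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        l2 = lambda v: v @ np.array([[0.0, 0.0], [np.log(2.0), 0.0]])
        a = pairwise_similarity(x, l1=None, l2=l2)
        assert np.allclose(a[0], [1.0 / 3.0, 2.0 / 3.0], atol=1e-9)

    def test_requires_two_views(self):
        with pytest.raises(ValueError):
            pairwise_similarity(np.ones((1, 4)))


class TestGateMasks:
    def test_boundary_goes_to_m1(self):
        a = np.array([[0.8, 0.2], [0.5, 0.5]])
        m1, m2 = gate_masks(a, 0.8)
        assert m1[0, 0] == 1 and m2[0, 0] == 0

    def test_all_below_threshold(self):
        m1, m2 = gate_masks(np.full((3, 3), 0.1), 0.8)
        assert not m1.any() and m2.all()

    @given(arrays(np.float64, (4, 4), elements=st.floats(0, 1)), st.floats(0, 1))
    def test_masks_partition(self, a, t2):
        m1, m2 = gate_masks(a, t2)
        assert np.array_equal(m1 + m2, np.ones((4, 4)))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            gate_masks(np.ones((2, 2)), -0.1)


class TestModifySimilarity:
    def test_uniform_low_similarity_row_stays_uniform(self):
        a = np.full((4, 4), 0.25)
        out = modify_similarity(a, gate_masks(a, 0.8))
        assert np.allclose(out, 0.25, atol=1e-9)

    def test_branch_values(self):
        # below threshold: b = exp(a); above: b = exp(-a)
        a = np.array([[0.9, 0.1]])
        m1, m2 = gate_masks(a, 0.8)
        # pre-softmax values b = [exp(-0.9) ~ 0.4066, exp(0.1)]; A' is the
        # row softmax of b
        b = np.array([[np.exp(-0.9), np.exp(0.1)]])
        assert np.isclose(b[0, 0], 0.4066, atol=5e-5)
        expected = np.exp(b) / np.exp(b).sum()
        out = modify_similarity(a, (m1, m2))
        assert np.allclose(out, expected, atol=1e-12)

    def test_row_stochastic(self, rng):
        a = rng.dirichlet(np.ones(5), size=5)
        out = modify_similarity(a, gate_masks(a, 0.3))
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out > 0)

    def test_gating_redistributes_toward_dissimilar(self):
        # equal raw similarity, one entry above and one below threshold:
        # the below-threshold entry must get strictly more mass
        a = np.array([[0.45, 0.45, 0.10]])
        m1 = np.array([[1.0, 0.0, 0.0]])  # pretend 0.45 >= T2 only for col 0
        out = modify_similarity(a, (m1, 1.0 - m1))
        assert out[0, 1] > out[0, 0]

    def test_literal_eq6_variant_differs(self):
        a = np.array([[0.9, 0.1]])
        masks = gate_masks(a, 0.8)
        two_branch = modify_similarity(a, masks, literal_eq6=False)
        literal = modify_similarity(a, masks, literal_eq6=True)
        assert not np.allclose(two_branch, literal)

    def test_partition_validated(self):
        with pytest.raises(ValueError):
            modify_similarity(np.ones((2, 2)) / 2, (np.ones((2, 2)), np.ones((2, 2))))


class TestEnhance:
    def test_identity_matrix_returns_l3_output(self, rng):
        x = rng.normal(size=(4, 6))
        assert np.allclose(enhance(x, np.eye(4)), x)

    def test_uniform_rows_average(self, rng):
        x = rng.normal(size=(4, 6))
        out = enhance(x, np.full((4, 4), 0.25))
        assert np.allclose(out, np.tile(x.mean(axis=0), (4, 1)))

    def test_hand_product(self):
        a = np.array([[0.75, 0.25], [0.25, 0.75]])
        l3x = np.array([[4.0, 0.0], [0.0, 4.0]])
        assert np.allclose(enhance(l3x, a), [[3.0, 1.0], [1.0, 3.0]], atol=1e-12)

    def test_linear_in_descriptors(self, rng):
        # superposition for fixed A'
        a = rng.dirichlet(np.ones(4), size=4)
        x1, x2 = rng.normal(size=(2, 4, 5))
        lhs = enhance(x1 + x2, a)
        assert np.allclose(lhs, enhance(x1, a) + enhance(x2, a), atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            enhance(np.ones((4, 3)), np.eye(3))


class TestGvemModule:
    def test_forward_matches_functional_path(self, rng):
        """Batched module output equals the naive per-instance pipeline."""
        gvem = GVEM(5, rng, t2=0.3).eval()
        x = rng.normal(size=(2, 4, 5))
        x_enh, a_mod = gvem(Tensor(x))
        for b in range(2):
            l1 = lambda v: gvem.l1(Tensor(v)).data
            l2 = lambda v: gvem.l2(Tensor(v)).data
            l3 = lambda v: gvem.l3(Tensor(v)).data
            a = pairwise_similarity(x[b], l1, l2)
            a_prime = modify_similarity(a, gate_masks(a, 0.3))
            expected = enhance(x[b], a_prime, l3)
            assert np.allclose(a_mod.data[b], a_prime, atol=1e-9)
            assert np.allclose(x_enh.data[b], expected, atol=1e-9)

    def test_module_rows_stochastic(self, rng):
        gvem = GVEM(6, rng).eval()
        _, a_mod = gvem(Tensor(rng.normal(size=(3, 8, 6))))
        assert np.allclose(a_mod.data.sum(axis=-1), 1.0, atol=1e-6)
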