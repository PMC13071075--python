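"""Multi-scale grouped convolution and attention blocks."""

import numpy as np
import pytest

from nodulenet.blocks import (
    CA,
    DSA,
    GSA,
    AttentionBlockSpec,
    MSConv,
    MSConvSpec,
    group_number,
)
from nodulenet.nn import Tensor, conv3d

from test_autograd import finite_diff_check


def brute_force_group_number(c_in: int, c_out: int) -> int:
    cap = min(c_in // 2, c_out)
    best = 1
    for g in range(1, c_out + 1):
        if g <= cap and c_out % g == 0:
            best = max(best, g)
    return best


def test_group_number_examples():
    assert group_number(64, 64) == 32
    assert group_number(32, 48) == 16
    assert group_number(3, 8) == 1
    assert group_number(2, 5) == 1


def test_group_number_matches_exhaustive_search():
    for c_in in range(1, 65):
        for c_out in range(1, 65):
            assert group_number(c_in, c_out) == brute_force_group_number(c_in, c_out)


class TestMSConv:
    def test_output_shape_and_zero_weights(self, rng):
        spec = MSConvSpec(8, 8)
        block = MSConv(spec, rng=rng)
        for p in block.parameters():
            p.data = np.zeros_like(p.data)
        x = Tensor(rng.normal(size=(1, 8, 4, 4, 4)))
        y = block(x)
        assert y.shape == (1, 8, 4, 4, 4)
        assert np.allclose(y.numpy(), 0.0)

    @pytest.mark.parametrize("c_in,c_out", [(4, 4), (8, 8), (6, 12), (16, 8)])
    def test_equals_sum_of_independent_branches(self, rng, c_in, c_out):
        """The block output equals F1 + F2 + F3 + F_res computed branch by
        branch with a plain single-branch convolution oracle."""
        spec = MSConvSpec(c_in, c_out)
        block = MSConv(spec, rng=rng)
        x = Tensor(rng.normal(size=(2, c_in, 5, 5, 5)).astype(np.float64))
        expected = np.zeros((2, c_out, 5, 5, 5))
        for br in block._branches:
            k = br.weight.shape[-1]
            expected = expected + conv3d(
                x, Tensor(br.weight.data.astype(np.float64)),
                Tensor(br.bias.data.astype(np.float64)),
                padding=(k - 1) // 2, groups=spec.groups,
            ).numpy()
        got = block(x).numpy()
        assert np.abs(got - expected).max() / np.abs(expected).max() < 1e-5

    def test_linearity_with_zero_biases(self, rng):
        block = MSConv(MSConvSpec(4, 4), rng=rng)
        for name, p in block.named_parameters():
            if name.endswith("bias"):
                p.data = np.zeros_like(p.data)
        x = rng.normal(size=(1, 4, 4, 4, 4))
        y1 = block(Tensor(3.0 * x)).numpy()
        y2 = 3.0 * block(Tensor(x)).numpy()
        assert np.allclose(y1, y2, atol=1e-5)

    def test_groups_divide_both_channel_counts(self):
        for c_in, c_out in [(4, 4), (64, 64), (32, 48), (6, 12), (16, 8)]:
            g = MSConvSpec(c_in, c_out).groups
            assert c_in % g == 0 and c_out % g == 0 and g >= 1

    def test_rejects_channel_mismatch(self, rng):
        block = MSConv(MSConvSpec(4, 4), rng=rng)
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 6, 4, 4, 4))))


class TestGSA:
    def test_shape_preserved_and_descriptors_in_unit_interval(self, rng):
        gsa = GSA(AttentionBlockSpec("GSA", 8), rng=rng)
        x = Tensor(rng.normal(size=(2, 8, 5, 6, 7)))
        assert gsa(x).shape == x.shape
        d_avg, d_max = gsa.descriptors(x)
        for d in (d_avg.numpy(), d_max.numpy()):
            assert (d > 0).all() and (d < 1).all()

    def test_zero_projections_gate_to_quarter(self, rng):
        """All-zero projection weights make every descriptor sigmoid(0)=0.5,
        so the pre-refinement reweighted map is 0.25 * x."""
        gsa = GSA(AttentionBlockSpec("GSA", 8), rng=rng)
        for name, p in gsa.named_parameters():
            if name.startswith("proj"):
                p.data = np.zeros_like(p.data)
        x = Tensor(rng.normal(size=(1, 8, 4, 4, 4)))
        assert np.allclose(gsa.reweight(x).numpy(), 0.25 * x.numpy(), atol=1e-6)

    def test_differentiable(self, rng):
        gsa = GSA(AttentionBlockSpec("GSA", 2), rng=rng)
        for p in gsa.parameters():
            p.data = p.data.astype(np.float64)
        x = Tensor(rng.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
        finite_diff_check(lambda: (gsa(x) ** 2).sum(), [x], tol=1e-3)


class TestDSA:
    def test_shape_and_sigmoid_range(self, rng):
        dsa = DSA(AttentionBlockSpec("DSA", 8), rng=rng)
        x = Tensor(rng.normal(size=(2, 8, 6, 6, 6)))
        assert dsa(x).shape == x.shape
        for m in dsa.spatial_maps(x):
            m = m.numpy()
            assert (m > 0).all() and (m < 1).all()

    def test_max_branch_peaks_at_dominant_voxel(self, rng):
        dsa = DSA(AttentionBlockSpec("DSA", 4, spatial_kernel=3), rng=rng)
        x = rng.normal(size=(1, 4, 5, 5, 5))
        x[0, 2, 3, 1, 4] = 50.0  # dominates the channel-wise max everywhere
        pooled_max = x.max(axis=1)
        assert np.unravel_index(pooled_max.argmax(), pooled_max.shape) == (0, 3, 1, 4)

    def test_spatial_kernel_must_be_odd(self):
        with pytest.raises(ValueError, match="odd"):
            AttentionBlockSpec("DSA", 8, spatial_kernel=4)

    def test_differentiable(self, rng):
        dsa = DSA(AttentionBlockSpec("DSA", 2, spatial_kernel=3), rng=rng)
        for p in dsa.parameters():
            p.data = p.data.astype(np.float64)
        x = Tensor(rng.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
        finite_diff_check(lambda: (dsa(x) ** 2).sum(), [x], tol=1e-3)


class TestCA:
    def test_shape_and_weight_range(self, rng):
        ca = CA(AttentionBlockSpec("CA", 8, reduction=4), rng=rng)
        x = Tensor(rng.normal(size=(3, 8, 4, 4, 4)))
        assert ca(x).shape == x.shape
        w = ca.channel_weights(x).numpy()
        assert w.shape == (3, 8)
        assert (w > 0).all() and (w < 1).all()

    def test_symmetric_weights_give_equal_channel_gates(self, rng):
        """Channel-constant input + tied bottleneck weights -> equal gates."""
        ca = CA(AttentionBlockSpec("CA", 4, reduction=2), rng=rng)
        ca.squeeze.weight.data = np.full_like(ca.squeeze.weight.data, 0.3)
        ca.excite.weight.data = np.full_like(ca.excite.weight.data, -0.2)
        x = Tensor(np.broadcast_to(rng.normal(size=(2, 1, 3, 3, 3)), (2, 4, 3, 3, 3)).copy())
        w = ca.channel_weights(x).numpy()
        assert np.allclose(w, w[:, :1])

    def test_differentiable(self, rng):
        ca = CA(AttentionBlockSpec("CA", 2, reduction=2), rng=rng)
        for p in ca.parameters():
            p.data = p.data.astype(np.float64)
        x = Tensor(rng.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
        finite_diff_check(lambda: (ca(x) ** 2).sum(), [x], tol=1e-3)
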