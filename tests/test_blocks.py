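"""Block contracts: shape preservation, identity-at-init, gates, gradients."""
import numpy as np
import pytest

from pestseg import tensor as T
from pestseg.blocks import (AttentiveSkip, DWConv, MSAABottleneck, MSAAConfig,
                            MSDC, MSDCConfig, MultiScaleVSSBlock, SEGate,
                            VSSBlock, VSSBlockConfig)
from pestseg.ssm import SS2DConfig


def _cfg(channels, zero_init=True):
    return VSSBlockConfig(channels=channels, expand_ratio=2, se_reduction=2,
                          ssm=SS2DConfig(state_size=2),
                          zero_init_residual=zero_init)


# the four stage sizes of a 256x256 input at C=96, scaled down spatially
STAGE_SHAPES = [(8, 8, 96), (4, 4, 192), (2, 2, 384), (2, 2, 768)]


class TestDWConv:
    def test_identity_filters_give_identity(self, rng):
        x = T.Tensor(rng.normal(size=(1, 5, 6, 3)))
        block = DWConv(3, 3, rng)
        block.depthwise.weight.data[:] = 0.0
        block.depthwise.weight.data[1, 1] = 1.0
        block.pointwise.weight.data[0, 0] = np.eye(3)
        block.pointwise.bias.data[:] = 0.0
        assert np.allclose(block(x).data, x.data)

    def test_zero_pointwise_gives_zero(self, rng):
        block = DWConv(3, 5, rng)
        block.pointwise.weight.data[:] = 0.0
        block.pointwise.bias.data[:] = 0.0
        y = block(T.Tensor(rng.normal(size=(1, 4, 4, 3))))
        assert np.allclose(y.data, 0.0)

    def test_parameter_count_formula(self, rng):
        # D*k^2 depthwise + D*D pointwise weights (+ 2D biases)
        block = DWConv(8, 3, rng)
        weights = block.depthwise.weight.size + block.pointwise.weight.size
        assert weights == 8 * 9 + 8 * 8 == 136
        total = sum(p.size for p in block.parameters())
        assert total == 136 + 8 + 8

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            DWConv(3, 4, rng)


class TestSEGate:
    def test_gate_shrinks_magnitudes(self, rng):
        gate = SEGate(6, 2, rng)
        x = rng.normal(size=(2, 5, 5, 6))
        y = gate(T.Tensor(x)).data
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)

    def test_zero_second_layer_halves_input(self, rng):
        gate = SEGate(4, 2, rng)
        gate.fc2.weight.data[:] = 0.0
        gate.fc2.bias.data[:] = 0.0
        x = rng.normal(size=(1, 3, 3, 4))
        assert np.allclose(gate(T.Tensor(x)).data, 0.5 * x)

    def test_invariant_to_pixel_shuffles_within_channels(self, rng):
        """The gate sees only channel means, so shuffling pixels inside each
        channel leaves the per-channel weights unchanged."""
        gate = SEGate(3, 1, rng)
        x = rng.normal(size=(1, 4, 4, 3))
        w_ref = gate(T.Tensor(x)).data / x
        perm = rng.permutation(16)
        xs = x.reshape(1, 16, 3)[:, perm].reshape(1, 4, 4, 3)
        w_shuf = gate(T.Tensor(xs)).data / xs
        assert np.allclose(np.sort(w_ref.reshape(-1, 3), axis=0),
                           np.sort(w_shuf.reshape(-1, 3), axis=0))


class TestIdentityAtInit:
    """Zero-initialised final projections make each block the identity."""

    @pytest.mark.parametrize("shape", STAGE_SHAPES[:2])
    def test_vss_block(self, rng, shape):
        block = VSSBlock(_cfg(shape[-1]), rng)
        x = rng.normal(size=(1,) + shape)
        assert np.abs(block(T.Tensor(x)).data - x).max() == 0.0

    @pytest.mark.parametrize("shape", STAGE_SHAPES[:2])
    def test_msvss_block(self, rng, shape):
        block = MultiScaleVSSBlock(_cfg(shape[-1]), MSDCConfig(), rng)
        x = rng.normal(size=(1,) + shape)
        assert np.abs(block(T.Tensor(x)).data - x).max() == 0.0

    @pytest.mark.parametrize("shape", STAGE_SHAPES[:2])
    def test_cavss_block(self, rng, shape):
        block = AttentiveSkip(_cfg(shape[-1]), rng)
        x = rng.normal(size=(1,) + shape)
        assert np.abs(block(T.Tensor(x)).data - x).max() == 0.0

    def test_msvss_collapses_to_projection_when_msdc_zeroed(self, rng):
        """With the multi-kernel refinement zeroed the block returns exactly
        the linear projection of the VSS output."""
        block = MultiScaleVSSBlock(_cfg(4, zero_init=False), MSDCConfig(), rng)
        block.msdc.fuse.weight.data[:] = 0.0
        block.msdc.fuse.bias.data[:] = 0.0
        x = T.Tensor(rng.normal(size=(1, 4, 4, 4)))
        expected = block.proj(block.vss(x)).data
        assert np.allclose(block(x).data, expected)


class TestMSDC:
    def test_zero_branches_give_zero(self, rng):
        block = MSDC(3, MSDCConfig(), rng, zero_init_fuse=False)
        for b in block.branches:
            b.weight.data[:] = 0.0
            b.bias.data[:] = 0.0
        block.fuse.bias.data[:] = 0.0
        y = block(T.Tensor(rng.normal(size=(1, 6, 6, 3))))
        assert np.allclose(y.data, 0.0)

    def test_constant_input_constant_output(self, rng):
        """Convolving a constant with bias-free branches gives the constant
        times the kernel sum in every interior pixel; with 'same' padding the
        interior of the output is constant at that closed-form value."""
        block = MSDC(2, MSDCConfig(kernel_sizes=(1, 3)), rng,
                     zero_init_fuse=False)
        for b in block.branches:
            b.bias.data[:] = 0.0
        block.fuse.bias.data[:] = 0.0
        c = 1.7
        x = np.full((1, 9, 9, 2), c)
        y = block(T.Tensor(x)).data
        s = sum(b.weight.data.sum(axis=(0, 1)) for b in block.branches)  # [Cin,Cout]
        expected = (c * s.sum(axis=0)) @ block.fuse.weight.data[0, 0]
        assert np.allclose(y[0, 4, 4], expected)
        assert np.allclose(y[0, 3:6, 3:6], y[0, 4, 4])

    def test_shape_preserved_with_wide_channels(self, rng):
        block = MSDC(192, MSDCConfig(), rng)
        x = T.Tensor(rng.normal(size=(1, 4, 4, 192)))
        assert block(x).shape == (1, 4, 4, 192)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            MSDCConfig(kernel_sizes=(2, 3))


class TestMSAA:
    def test_zero_gate_conv_gives_half_gate(self, rng):
        block = MSAABottleneck(3, MSAAConfig(), rng)
        block.gate_conv.weight.data[:] = 0.0
        block.gate_conv.bias.data[:] = 0.0
        x = T.Tensor(rng.normal(size=(1, 6, 6, 3)))
        p = block.proj_in(x)
        fdil = None
        for conv in block.dilated:
            y = conv(p)
            fdil = y if fdil is None else fdil + y
        expected = block.proj_out(0.5 * fdil + p).data
        assert np.allclose(block(x).data, expected)

    def test_gate_strictly_inside_unit_interval(self, rng):
        block = MSAABottleneck(4, MSAAConfig(), rng)
        x = T.Tensor(rng.normal(size=(1, 8, 8, 4)))
        p = block.proj_in(x)
        fdil = None
        for conv in block.dilated:
            y = conv(p)
            fdil = y if fdil is None else fdil + y
        from pestseg.blocks import _spatial_gate_input
        gate = T.sigmoid(block.gate_conv(_spatial_gate_input(fdil))).data
        assert np.all(gate > 0.0) and np.all(gate < 1.0)

    def test_shape_preserved_at_bottleneck_width(self, rng):
        block = MSAABottleneck(768, MSAAConfig(), rng)
        x = T.Tensor(rng.normal(size=(1, 2, 2, 768)))
        assert block(x).shape == (1, 2, 2, 768)

    def test_dilation_rates_expand_receptive_field(self, rng):
        """A dilation-5 branch reaches 5 pixels away; a unit impulse there
        must influence the centre output."""
        block = MSAABottleneck(1, MSAAConfig(dilation_rates=(5,)), rng)
        x = np.zeros((1, 11, 11, 1))
        x[0, 0, 5, 0] = 1.0   # 5 pixels above centre
        y0 = block(T.Tensor(np.zeros_like(x))).data
        y1 = block(T.Tensor(x)).data
        assert not np.allclose(y0[0, 5, 5], y1[0, 5, 5])


class TestGatesAndGradients:
    def test_cavss_gate_bounded(self, rng):
        block = AttentiveSkip(_cfg(3, zero_init=False), rng)
        v = block.vss(T.Tensor(rng.normal(size=(1, 4, 4, 3))))
        f = block.conv(block.norm(v))
        from pestseg.blocks import _spatial_gate_input
        gate = T.sigmoid(block.gate_conv(_spatial_gate_input(f))).data
        assert np.all((gate > 0) & (gate < 1))

    @pytest.mark.parametrize("factory", [
        lambda rng: VSSBlock(_cfg(3, zero_init=False), rng),
        lambda rng: MultiScaleVSSBlock(_cfg(3, zero_init=False),
                                       MSDCConfig(), rng),
        lambda rng: MSAABottleneck(3, MSAAConfig(), rng),
        lambda rng: AttentiveSkip(_cfg(3, zero_init=False), rng),
    ], ids=["vss", "msvss", "msaa", "cavss"])
    def test_every_parameter_receives_gradient(self, rng, factory):
        """Generic random init: no dead branches anywhere in the block."""
        block = factory(rng)
        x = T.Tensor(rng.normal(size=(2, 8, 8, 3)), requires_grad=True)
        y = block(x)
        (y * T.Tensor(rng.normal(size=y.shape))).sum().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            assert np.abs(p.grad).max() > 0, name
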