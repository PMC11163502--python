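"""Architecture blocks, forward contracts, and compute fingerprints."""

import numpy as np
import pytest

from nodseg.model import (ABLATION_PRESETS, ModelConfig, S3DStage, SEBlock,
                          RACMUnit, build_model, count_macs, count_parameters,
                          gmacs_table_convention, preset)
from nodseg.nn.autodiff import Tensor
from nodseg.nn.layers import Conv3d


def _rng():
    return np.random.default_rng(0)


class TestBlocks:
    def test_s3d_weight_counts(self):
        """1x3x3 then 3x1x1 at 16 channels: 2304 + 768 conv weights."""
        stage = S3DStage(16, 16, 16, _rng())
        assert stage.planar.conv.w.data.size == 16 * 16 * 9
        assert stage.axial.conv.w.data.size == 16 * 16 * 3
        full = Conv3d(16, 16, (3, 3, 3), _rng())
        assert (stage.planar.conv.w.data.size + stage.axial.conv.w.data.size) \
            == full.w.data.size * 12 // 27

    def test_s3d_preserves_shape(self):
        stage = S3DStage(4, 6, 4, _rng())
        y = stage(Tensor(np.zeros((1, 4, 11, 16, 16), np.float32)))
        assert y.shape == (1, 6, 11, 16, 16)

    def test_single_conv_param_example(self):
        conv = Conv3d(1, 16, (3, 3, 3), _rng())
        assert conv.param_count() == 1 * 16 * 27 + 16

    def test_conv_mac_example(self):
        conv = Conv3d(16, 16, (3, 3, 3), _rng())
        assert conv.macs((11, 64, 64)) == 16 * 16 * 27 * 11 * 64 * 64

    def test_se_block_recompute(self, rng):
        se = SEBlock(8, 2, _rng())
        x = rng.standard_normal((2, 8, 3, 4, 4)).astype(np.float32)
        y = se(Tensor(x)).data
        # recompute channel gates directly
        import nodseg.nn.autodiff as ad
        sq = x.mean(axis=(2, 3, 4))
        h = np.maximum(sq @ se.fc1.w.data.T + se.fc1.b.data, 0)
        wgt = 1 / (1 + np.exp(-(h @ se.fc2.w.data.T + se.fc2.b.data)))
        np.testing.assert_allclose(y, x * wgt[:, :, None, None, None], atol=1e-5)
        assert np.all((wgt > 0) & (wgt < 1))

    def test_se_channel_permutation_equivariance(self, rng):
        se = SEBlock(4, 2, _rng())
        x = rng.standard_normal((1, 4, 2, 3, 3)).astype(np.float32)
        perm = [2, 0, 3, 1]
        y = se(Tensor(x)).data
        # permuting channels of both weights and input permutes the output
        se.fc1.w.data = se.fc1.w.data[:, perm]
        se.fc2.w.data = se.fc2.w.data[perm]
        se.fc2.b.data = se.fc2.b.data[perm]
        y2 = se(Tensor(x[:, perm])).data
        np.testing.assert_allclose(y2, y[:, perm], atol=1e-6)

    def test_se_rejects_narrow_channels(self):
        with pytest.raises(ValueError):
            SEBlock(4, 16, _rng())

    def test_racm_reverse_attention_limits(self, rng):
        unit = RACMUnit(4, _rng())
        f = rng.standard_normal((1, 4, 3, 8, 8)).astype(np.float32)
        confident = np.full((1, 1, 3, 8, 8), 40.0, np.float32)
        refined, _ = unit(Tensor(f), Tensor(confident))
        np.testing.assert_allclose(refined.data, f, atol=1e-4)   # A -> 0
        doubtful = np.full((1, 1, 3, 8, 8), -40.0, np.float32)
        refined2, _ = unit(Tensor(f), Tensor(doubtful))
        conv_f = unit.conv(Tensor(f)).data
        np.testing.assert_allclose(refined2.data, f + conv_f, atol=1e-4)  # A -> 1


class TestForwardContracts:
    @pytest.mark.parametrize("number", [1, 2, 6])
    def test_output_shape_and_range(self, number, rng):
        model = build_model(preset(number, base_channels=4), seed=0)
        model.eval()
        x = rng.standard_normal((1, 1, 11, 64, 64)).astype(np.float32)
        y = model(Tensor(x)).data
        assert y.shape == (1, 1, 11, 64, 64)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_eval_forward_deterministic(self, rng):
        model = build_model(preset(6, base_channels=4), seed=1)
        model.eval()
        x = rng.standard_normal((1, 1, 11, 64, 64)).astype(np.float32)
        y1 = model(Tensor(x)).data
        y2 = model(Tensor(x)).data
        assert np.array_equal(y1, y2)

    def test_invalid_preset_and_arch(self):
        with pytest.raises(ValueError):
            preset(7)
        with pytest.raises(ValueError):
            build_model(ModelConfig(arch="unet"))


class TestFingerprints:
    def test_ablation_parameter_monotonicity(self):
        counts = [count_parameters(build_model(ABLATION_PRESETS[k]))
                  for k in (2, 3, 4, 5, 6)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_s3d_substitution_reduces_cost(self):
        """S3D at L4-L5 strictly cuts parameters and MACs vs full 3D kernels."""
        base = ABLATION_PRESETS[2]
        from dataclasses import replace
        full3d = replace(base, s3d_levels=frozenset(), s3d_hidden_factor={})
        m_s3d = build_model(replace(base, s3d_hidden_factor={}))
        m_full = build_model(full3d)
        assert count_parameters(m_s3d) < count_parameters(m_full)
        assert count_macs(m_s3d) < count_macs(m_full)

    def test_macs_scale_linearly_with_slices(self):
        # preset 2: every operation is a convolution, so MACs are
        # proportional to the slice count (SE's global pooling is not)
        model = build_model(preset(2, base_channels=4))
        m11 = count_macs(model, (1, 11, 64, 64))
        m22 = count_macs(model, (1, 22, 64, 64))
        assert m22 == 2 * m11
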