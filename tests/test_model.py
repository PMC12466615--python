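"""Model assembly: scaling rules, complexity accounting, forward shapes,
decoding, gradient flow."""

import numpy as np
import pytest

from wildasm.autograd import Tensor
from wildasm.layers import Conv, Module
from wildasm.model import (ModelConfig, build_model, complexity_report,
                           count_flops, count_parameters, decode_predictions,
                           dfl_expectation, load_checkpoint, save_checkpoint)


class TestConfig:
    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError, match="variant"):
            ModelConfig(variant="bogus")
        with pytest.raises(ValueError, match="multiple of 32"):
            ModelConfig(input_size=300)
        with pytest.raises(ValueError):
            ModelConfig(nc=0)

    def test_nano_channel_ladder(self):
        assert ModelConfig().channels == (16, 32, 64, 128, 256)
        assert ModelConfig().depths == (1, 2, 2, 1)


class TestParameterCount:
    def test_lone_conv_block(self, rng):
        """3x3 conv 3->16 with norm: 3*16*9 weights + 2 affine vectors."""
        conv = Conv(rng, 3, 16, 3)
        assert sum(p.data.size for _, p in conv.named_parameters()) == 464

    def test_two_block_toy_net_matches_hand_tally(self, rng):
        class Toy(Module):
            def __init__(self):
                super().__init__()
                self.a = Conv(rng, 3, 8, 3)
                self.b = Conv(rng, 8, 4, 1)
        # 3*8*9 + 16  +  8*4*1 + 8 = 232 + 40
        assert sum(p.data.size for _, p in Toy().named_parameters()) == 272

    def test_doubling_classes_increases_parameters(self):
        small = count_parameters(build_model(ModelConfig(nc=10)))
        big = count_parameters(build_model(ModelConfig(nc=20)))
        assert big > small

    def test_fused_vs_training_count(self):
        m = build_model(ModelConfig(nc=10))
        # folding BN removes one affine vector per conv
        assert count_parameters(m, fuse=False) - count_parameters(m) == \
            sum(c.c2 for c in m.modules() if isinstance(c, Conv))


class TestFlops:
    def test_single_conv_oracle(self):
        # 1x1 conv 1->1 on a 640 grid: 640*640 MACs -> 2*4.096e5 flops
        from wildasm.model import _conv_macs

        class FakeConv:
            c1, c2, k, s = 1, 1, 1, 1
        macs, _, _, _ = _conv_macs(FakeConv, 640, 640)
        assert 2 * macs / 1e9 == pytest.approx(0.00082, abs=1e-5)

    def test_toy_two_conv_net_hand_macs(self, rng):
        from wildasm.model import _conv_macs
        a = Conv(rng, 3, 8, 3, 2)   # on 32x32 -> out 16x16
        b = Conv(rng, 8, 4, 1, 1)
        macs_a, _, h, w = _conv_macs(a, 32, 32)
        macs_b = _conv_macs(b, h, w)[0]
        assert macs_a == 9 * 3 * 8 * 16 * 16
        assert macs_b == 8 * 4 * 16 * 16

    def test_flops_scale_with_input_size(self):
        m = build_model(ModelConfig(nc=10))
        assert count_flops(m, 320) < count_flops(m, 640)


class TestForward:
    @pytest.mark.parametrize("variant,expect", [
        ("baseline", {8: 12, 16: 6, 32: 3}),
        ("wildasm", {4: 24, 8: 12, 16: 6, 32: 3}),
    ])
    def test_grid_sizes_follow_stride_arithmetic(self, variant, expect):
        cfg = ModelConfig(variant=variant, nc=5, input_size=96, seed=0)
        model = build_model(cfg).eval()
        raw = model(np.zeros((1, 3, 96, 96), np.float32))
        assert {s: b.shape[-1] for s, (b, c) in raw.items()} == expect
        for s, (box, cls) in raw.items():
            assert box.shape[1] == 4 * cfg.reg_max
            assert cls.shape[1] == cfg.nc

    def test_wrong_spatial_size_rejected(self):
        model = build_model(ModelConfig(nc=2, input_size=96))
        with pytest.raises(ValueError, match="letterbox"):
            model(np.zeros((1, 3, 96, 95), np.float32))

    def test_deterministic_given_weights(self):
        cfg = ModelConfig(nc=2, input_size=96, seed=3)
        x = np.random.default_rng(0).random((1, 3, 96, 96)).astype(np.float32)
        a = build_model(cfg).eval()(x)
        b = build_model(cfg).eval()(x)
        for s in a:
            np.testing.assert_array_equal(a[s][0].data, b[s][0].data)

    def test_gradient_reaches_every_block(self, tiny_dataset):
        """A toy loss must propagate into every named parameter group,
        including fusion weights and attention projections."""
        from wildasm.losses import total_loss
        model = build_model(ModelConfig(variant="wildasm", nc=3,
                                        input_size=96, seed=0))
        images, targets = tiny_dataset.batch([0, 1])
        loss, _ = total_loss(model(images), targets, model)
        loss.backward()
        missing = [n for n, p in model.named_parameters() if p.grad is None]
        assert not missing
        for name in ("fuse_td4.w", "fuse_bu3.w", "mhsa.Wq", "mhsa.Wo"):
            p = dict(model.named_parameters())[name]
            assert np.any(p.grad != 0), name


class TestDecode:
    def test_uniform_distribution_decodes_to_mean_bin(self):
        logits = np.zeros((1, 64, 1, 1), np.float32)
        np.testing.assert_allclose(dfl_expectation(logits, 16), 7.5)

    def test_one_hot_limit(self):
        logits = np.full((1, 4, 16, 1, 1), -50.0, np.float32)
        logits[0, :, 3] = 50.0
        np.testing.assert_allclose(
            dfl_expectation(logits.reshape(1, 64, 1, 1), 16), 3.0, atol=1e-5)

    def test_expectation_equals_loop(self, rng):
        logits = rng.normal(size=(1, 64, 2, 2)).astype(np.float32)
        got = dfl_expectation(logits, 16)
        d = logits.reshape(4, 16, 2, 2)
        for side in range(4):
            for i in range(2):
                for j in range(2):
                    z = np.exp(d[side, :, i, j] - d[side, :, i, j].max())
                    want = float(sum(z[k] * k for k in range(16)) / z.sum())
                    assert got[0, side, i, j] == pytest.approx(want, rel=1e-5)

    def test_threshold_filters_detections(self):
        model = build_model(ModelConfig(nc=2, input_size=96)).eval()
        raw = model(np.zeros((1, 3, 96, 96), np.float32))
        strict = decode_predictions(raw, model.cfg, conf_threshold=0.999)
        loose = decode_predictions(raw, model.cfg, conf_threshold=0.0)
        assert len(strict[0]) <= len(loose[0])


class TestComplexityReportAndCheckpoint:
    def test_report_fields(self):
        rep = complexity_report(build_model(ModelConfig(nc=4)))
        assert rep.n_params > 0 and rep.gflops > 0 and rep.n_layers > 0

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = ModelConfig(variant="wildasm", nc=3, input_size=96, seed=5)
        model = build_model(cfg)
        save_checkpoint(tmp_path / "w.npz", model, {"epoch": 7})
        loaded, meta = load_checkpoint(tmp_path / "w.npz")
        assert meta == {"epoch": 7}
        x = np.random.default_rng(0).random((1, 3, 96, 96)).astype(np.float32)
        a, b = model.eval()(x), loaded.eval()(x)
        for s in a:
            np.testing.assert_array_equal(a[s][1].data, b[s][1].data)
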