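"""Residual trunks, FiLM conditioning, and the numeric engine."""

import numpy as np
import pytest

from aslnet._nn import AdamW, Conv3d, Dense, GroupNorm, MaxPool3d, softmax
from aslnet.net import (FilmParams, MlpConfig, NetConfig, build_grade_net,
                        build_os_net, film_modulate, spatial_trace)


def _directional_check(layer, x, atol=1e-2, e=1.0):
    """Analytic vs numeric directional derivative of sum(forward * dout)."""
    rng = np.random.default_rng(42)
    out = layer.forward(x)
    dout = rng.normal(size=out.shape).astype(np.float32)
    layer.forward(x)
    dx = layer.backward(dout)
    v = rng.normal(size=x.shape).astype(np.float32)
    f = lambda xx: float((layer.forward(xx) * dout).sum())
    num = (f(x + e * v) - f(x - e * v)) / (2 * e)
    assert float((dx * v).sum()) == pytest.approx(num, abs=atol * max(1, abs(num)))


class TestEngineGradients:
    @pytest.mark.parametrize("kernel,stride", [(3, 1), (3, 2), (7, 2), (1, 2)])
    def test_conv_input_gradient_exact(self, rng, kernel, stride):
        conv = Conv3d(3, 5, kernel, stride, rng)
        x = rng.normal(size=(2, 9, 10, 11, 3)).astype(np.float32)
        _directional_check(conv, x, atol=1e-3)

    def test_conv_weight_gradient(self, rng):
        conv = Conv3d(2, 3, 3, 2, rng)
        x = rng.normal(size=(2, 8, 8, 8, 2)).astype(np.float32)
        out = conv.forward(x)
        dout = rng.normal(size=out.shape).astype(np.float32)
        conv.forward(x)
        conv.backward(dout)
        g = conv.w.grad.copy()
        i = (5, 1)
        e = 1e-2
        f = lambda: float((conv.forward(x) * dout).sum())
        conv.w.value[i] += e; lp = f()
        conv.w.value[i] -= 2 * e; lm = f()
        conv.w.value[i] += e
        assert g[i] == pytest.approx((lp - lm) / (2 * e), rel=1e-3)

    def test_groupnorm_gradient(self, rng):
        gn = GroupNorm(2, 6)
        x = rng.normal(size=(2, 5, 5, 5, 6)).astype(np.float32)
        _directional_check(gn, x, atol=1e-2, e=1e-2)

    def test_maxpool_gradient(self, rng):
        pool = MaxPool3d(3, 2)
        x = rng.normal(size=(2, 9, 9, 9, 4)).astype(np.float32)
        _directional_check(pool, x, atol=1e-2, e=1e-4)

    def test_adamw_decreases_loss_on_quadratic(self):
        dense = Dense(4, 1, np.random.default_rng(0))
        opt = AdamW(dense.params(), lr=5e-2, weight_decay=0.0)
        x = np.random.default_rng(1).normal(size=(16, 4)).astype(np.float32)
        target = (x @ np.array([[1.0], [-2.0], [0.5], [3.0]], np.float32))
        losses = []
        for _ in range(200):
            pred = dense.forward(x)
            losses.append(float(((pred - target) ** 2).mean()))
            opt.zero_grad()
            dense.backward(2 * (pred - target) / len(x))
            opt.step()
        assert losses[-1] < 1e-2 * losses[0]


class TestNetConfig:
    def test_stage_widths_double(self):
        cfg = NetConfig(init_filters=8)
        assert cfg.stage_widths == (8, 16, 32, 64)

    def test_norm_groups_must_divide_widths(self):
        with pytest.raises(ValueError, match="norm_groups"):
            NetConfig(init_filters=8, norm_groups=3)

    def test_spatial_trace_of_full_resolution_input(self):
        cfg = NetConfig(input_side=70, init_filters=8, norm_groups=4)
        assert spatial_trace(cfg) == [35, 18, 18, 9, 5, 3]

    def test_stage_outputs_match_stride_arithmetic(self, rng):
        """Forward shapes through stem and stages follow ceil division."""
        cfg = NetConfig(input_side=70, init_filters=8, norm_groups=4,
                        dropout_rate=0.0)
        net = build_grade_net(cfg, seed=0).net
        x = rng.normal(size=(1, 70, 70, 70, 4)).astype(np.float32)
        h = net.trunk.forward_stem(x, False, None)
        assert h.shape[1:4] == (18, 18, 18)
        expected = [(18, 8), (9, 16), (5, 32), (3, 64)]
        for s, (side, width) in enumerate(expected):
            h = net.trunk.forward_stage(s, h, False, None)
            assert h.shape[1:] == (side, side, side, width)

    def test_untrained_output_is_valid_simplex(self, tiny_cfg, rng):
        pred = build_grade_net(tiny_cfg, seed=1)
        x = rng.normal(size=(3, 12, 12, 12, 4)).astype(np.float32)
        p = pred.predict_proba(x)
        assert p.shape == (3, 3)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p > 0)

    def test_parameter_count_scales_quadratically_with_width(self, tiny_cfg):
        def conv_params(pred):
            return sum(p.value.size for p in pred.net.trunk.params())
        from dataclasses import replace
        small = build_grade_net(tiny_cfg, seed=0)
        big = build_grade_net(replace(tiny_cfg, init_filters=8,
                                      norm_groups=2), seed=0)
        ratio = conv_params(big) / conv_params(small)
        # stem scales x2 (fixed input channels), stages x4
        assert 3.0 < ratio < 4.2


class TestBottleneck:
    def test_bottleneck_trunk_builds_and_classifies(self, rng):
        cfg = NetConfig(input_side=12, init_filters=8, norm_groups=2,
                        blocks_per_stage=(1, 1, 1, 1), n_classes=3,
                        dropout_rate=0.0, stem_kernel=3, bottleneck=True)
        pred = build_grade_net(cfg, seed=0)
        x = rng.normal(size=(2, 12, 12, 12, 4)).astype(np.float32)
        p = pred.predict_proba(x)
        assert p.shape == (2, 3)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_bottleneck_width_must_be_divisible(self):
        with pytest.raises(ValueError, match="bottleneck"):
            NetConfig(init_filters=4, norm_groups=4, bottleneck=True)


class TestClinicalVector:
    def test_encodes_to_five_features(self):
        from aslnet.net import ClinicalVector
        v = ClinicalVector(age=0.5, sex=1, eor=(1.0, 0.0, 0.0))
        arr = v.as_array()
        assert arr.shape == (5,)
        assert arr[1] == 1.0

    def test_eor_one_hot_validated(self):
        from aslnet.net import ClinicalVector
        with pytest.raises(ValueError, match="one-hot"):
            ClinicalVector(age=0.0, sex=0, eor=(0.5, 0.0, 0.0))


class TestFilm:
    def test_identity_params(self, rng):
        x = rng.normal(size=(2, 4, 4, 4, 6)).astype(np.float32)
        out = film_modulate(x, FilmParams(np.ones(6), np.zeros(6)))
        assert np.array_equal(out, x)

    def test_affine_arithmetic(self):
        x = np.full((1, 3, 3, 3, 2), 3.0, np.float32)
        out = film_modulate(x, FilmParams(np.full(2, 2.0), np.ones(2)))
        assert np.all(out == 7.0)

    def test_matches_per_voxel_loop_oracle(self, rng):
        x = rng.normal(size=(2, 3, 3, 3, 4)).astype(np.float32)
        g = rng.normal(size=(2, 4)).astype(np.float32)
        b = rng.normal(size=(2, 4)).astype(np.float32)
        out = film_modulate(x, FilmParams(g, b))
        for n in range(2):
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        for c in range(4):
                            assert out[n, i, j, k, c] == pytest.approx(
                                g[n, c] * x[n, i, j, k, c] + b[n, c], abs=1e-6)

    def test_length_mismatch_raises(self):
        x = np.zeros((1, 2, 2, 2, 4), np.float32)
        with pytest.raises(ValueError, match="length"):
            film_modulate(x, FilmParams(np.ones(3), np.zeros(3)))


class TestOsNet:
    @pytest.fixture()
    def os_cfg(self, tiny_cfg):
        from dataclasses import replace
        return replace(tiny_cfg, n_classes=2)

    def test_zero_film_reduces_to_unconditioned_trunk(self, os_cfg, rng):
        """The zero-initialised MLP head starts at the identity modulation."""
        pred = build_os_net(os_cfg, seed=3)
        x = rng.normal(size=(4, 12, 12, 12, 4)).astype(np.float32)
        clin = rng.normal(size=(4, 5)).astype(np.float32)
        conditioned = pred.net.forward(x, clin)
        net = pred.net
        h = net.trunk.forward_stem(x, False, None)
        for s in range(4):
            h = net.trunk.forward_stage(s, h, False, None)
        unconditioned = softmax(net.head.forward(h, False, None))
        assert np.array_equal(conditioned, unconditioned)

    def test_age_perturbation_changes_output(self, os_cfg, rng):
        pred = build_os_net(os_cfg, seed=3)
        # break the deliberate zero initialisation of the FiLM head
        last = pred.net.mlp[-1]
        last.w.value[...] = rng.normal(0, 0.3, last.w.value.shape)
        x = rng.normal(size=(1, 12, 12, 12, 4)).astype(np.float32)
        clin = rng.normal(size=(1, 5)).astype(np.float32)
        clin2 = clin.copy()
        clin2[0, 0] += 1.0  # age column
        p1 = pred.net.forward(x, clin)
        p2 = pred.net.forward(x, clin2)
        assert not np.allclose(p1, p2)

    def test_probabilities_sum_to_one(self, os_cfg, rng):
        pred = build_os_net(os_cfg, seed=4)
        x = rng.normal(size=(2, 12, 12, 12, 4)).astype(np.float32)
        clin = rng.normal(size=(2, 5)).astype(np.float32)
        p = pred.predict_proba(x, clin)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_clinical_enters_only_through_film(self, os_cfg):
        """Structural check: covariates touch the graph only as (gamma, beta)
        of the last three stages."""
        pred = build_os_net(os_cfg, seed=0)
        assert pred.net.conditioned_stages == (1, 2, 3)
        trunk_and_head = set(map(id, pred.net.trunk.params()
                                 + pred.net.head.params()))
        mlp = set(id(p) for layer in pred.net.mlp for p in layer.params())
        assert trunk_and_head.isdisjoint(mlp)
        with pytest.raises(ValueError, match="clinical"):
            pred.net.forward(np.zeros((1, 12, 12, 12, 4), np.float32), None)


class TestResidualBlocks:
    def test_zero_final_conv_makes_block_identity(self, rng):
        from aslnet.net import _ResBlock
        block = _ResBlock(8, 8, 1, 2, False, rng)
        final_conv = block.branch[-2]
        final_conv.w.value[...] = 0.0
        final_conv.b.value[...] = 0.0
        x = np.abs(rng.normal(size=(2, 6, 6, 6, 8))).astype(np.float32)
        out = block.forward(x)
        assert np.allclose(out, x, atol=1e-6)

    def test_forward_deterministic_in_eval_mode(self, tiny_cfg, rng):
        from dataclasses import replace
        pred = build_grade_net(replace(tiny_cfg, dropout_rate=0.4), seed=5)
        x = rng.normal(size=(2, 12, 12, 12, 4)).astype(np.float32)
        assert np.array_equal(pred.predict_proba(x), pred.predict_proba(x))


def test_predictor_save_load_round_trip(tmp_path, tiny_cfg, rng):
    pred = build_grade_net(tiny_cfg, seed=6)
    x = rng.normal(size=(2, 12, 12, 12, 4)).astype(np.float32)
    before = pred.predict_proba(x)
    from aslnet.net import Predictor
    pred.save(tmp_path / "ckpt.npz")
    loaded = Predictor.load(tmp_path / "ckpt.npz")
    assert np.array_equal(loaded.predict_proba(x), before)
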