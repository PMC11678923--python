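"""Architecture contracts: resolution/channel ladders, style-code counts,
fade-in blending, demodulation algebra, noise injection statistics."""

import numpy as np
import pytest

from volgan import autodiff as ad
from volgan.autodiff import Tensor
from volgan.networks import (LATENT_DIM, N_STAGES, N_STYLES, STYLES_PER_STAGE,
                             Critic, Encoder, MappingNetwork, ModelConfig,
                             ProGANGenerator, StageState, StyleGenerator,
                             channel_schedule, demodulated_conv, inject_noise,
                             sample_latent, stage_resolution)
from volgan.nn import pixel_norm

CFG = ModelConfig(grid=(32, 64, 64), c_gen=4, c_critic=4)


@pytest.fixture(scope="module")
def progan():
    return ProGANGenerator(CFG, np.random.default_rng(0))


@pytest.fixture(scope="module")
def stylegan():
    return StyleGenerator(CFG, np.random.default_rng(1))


@pytest.fixture(scope="module")
def critic():
    return Critic(CFG, np.random.default_rng(2))


class TestLatent:
    def test_sample_shape_and_reproducibility(self):
        a = sample_latent(3, np.random.default_rng(0))
        b = sample_latent(3, np.random.default_rng(0))
        assert a.shape == (3, LATENT_DIM)
        assert np.array_equal(a, b)

    def test_sample_mean_within_clt_bound(self):
        n = 100_000
        z = sample_latent(n, np.random.default_rng(1), dim=8)
        assert np.all(np.abs(z.mean(axis=0)) < 4.0 / np.sqrt(n))


class TestResolutionLadder:
    def test_five_growth_stages_and_32x_ratio(self, progan):
        assert len(progan.blocks) == N_STAGES == 5
        full = stage_resolution(CFG, 5)
        assert full == CFG.grid
        assert all(f // b == 32 for f, b in zip(full, CFG.base_grid))

    @pytest.mark.parametrize("stage", [1, 2, 3])
    def test_stage_output_resolution(self, progan, stage):
        z = sample_latent(1, np.random.default_rng(3))
        out = progan(z, StageState(stage))
        assert out.shape == (1, 1) + stage_resolution(CFG, stage)

    def test_channel_ladder_follows_schedule(self, progan):
        sched = channel_schedule(CFG.c_gen)
        assert sched == (32, 32, 16, 8, 4)
        for k, block in enumerate(progan.blocks):
            assert block.conv1.w.shape[0] == sched[k]

    def test_grid_must_divide_32(self):
        with pytest.raises(ValueError):
            ModelConfig(grid=(30, 64, 64))


class TestFade:
    def test_alpha_zero_equals_upsampled_previous_stage(self, progan):
        z = sample_latent(2, np.random.default_rng(4))
        lo = progan(z, StageState(2, 1.0))
        blend0 = progan(z, StageState(3, 0.0))
        assert np.allclose(blend0.data, ad.upsample2(lo).data, atol=1e-6)

    def test_alpha_one_equals_pure_new_path(self, progan):
        z = sample_latent(2, np.random.default_rng(5))
        a = progan(z, StageState(3, 1.0))
        b = progan(z, StageState(3, 1.0 - 1e-12))
        assert np.allclose(a.data, b.data, atol=1e-6)

    def test_output_continuous_in_alpha(self, progan):
        z = sample_latent(1, np.random.default_rng(6))
        outs = [progan(z, StageState(3, a)).data
                for a in (0.5, 0.5 + 1e-3)]
        assert np.abs(outs[1] - outs[0]).max() < 1e-2

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError):
            StageState(6)
        with pytest.raises(ValueError):
            StageState(3, 1.5)


class TestPixelNorm:
    def test_constant_vector_unchanged(self):
        x = Tensor(np.ones((1, 4, 2, 2, 2), dtype=np.float32))
        assert np.allclose(pixel_norm(x).data, x.data, atol=1e-4)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=(2, 8, 3, 3, 3)).astype(np.float32)
        a = pixel_norm(Tensor(x)).data
        b = pixel_norm(Tensor(10.0 * x)).data
        assert np.allclose(a, b, atol=1e-5)

    def test_unit_rms_per_voxel(self, rng):
        x = Tensor(rng.normal(size=(2, 16, 3, 3, 3)).astype(np.float32))
        out = pixel_norm(x).data
        rms = np.sqrt((out ** 2).mean(axis=1))
        assert np.allclose(rms, 1.0, atol=1e-3)


class TestMappingAndStyles:
    def test_mapping_is_deterministic_512_to_512(self, stylegan):
        z = sample_latent(2, np.random.default_rng(7))
        w1 = stylegan.mapping(Tensor(z)).data
        w2 = stylegan.mapping(Tensor(z)).data
        assert w1.shape == (2, LATENT_DIM)
        assert np.array_equal(w1, w2)

    def test_identity_initialized_mapping_is_identity(self):
        cfg = ModelConfig(grid=(32, 64, 64), c_gen=4, mapping_layers=2)
        m = MappingNetwork(cfg, np.random.default_rng(8), eq_lr=False)
        for layer in m.layers:
            layer.w.data = np.eye(LATENT_DIM, dtype=np.float32)
            layer.b.data = np.zeros(LATENT_DIM, dtype=np.float32)
        z = np.abs(sample_latent(2, np.random.default_rng(9)))  # positive: ReLU region
        assert np.allclose(m(Tensor(z)).data, z, atol=1e-6)

    def test_fifteen_styles_three_per_stage(self, stylegan):
        w = Tensor(sample_latent(1, np.random.default_rng(10)))
        styles = stylegan.synthesis.style_codes(w)
        assert len(styles) == N_STYLES == 15
        sched = channel_schedule(CFG.c_gen)
        for k in range(N_STAGES):
            for j in range(STYLES_PER_STAGE):
                conv = stylegan.synthesis.convs[k * STYLES_PER_STAGE + j]
                expected_in = sched[k - 1] if (k > 0 and j == 0) else sched[k]
                if k == 0:
                    expected_in = sched[0]
                assert styles[k * STYLES_PER_STAGE + j].shape[1] == expected_in
                assert conv.w.shape[1] == expected_in

    def test_zero_affine_weights_give_bias_style(self, stylegan):
        conv = stylegan.synthesis.convs[0]
        saved = conv.style.w.data.copy()
        try:
            conv.style.w.data = np.zeros_like(conv.style.w.data)
            w = Tensor(sample_latent(3, np.random.default_rng(11)))
            style = conv.style(w).data
            assert np.allclose(style, conv.style.b.data, atol=1e-7)
        finally:
            conv.style.w.data = saved


class TestDemodulatedConv:
    def test_positive_style_rescaling_cancels(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 4, 4, 4)).astype(np.float32))
        w = Tensor(rng.normal(size=(5, 4, 3, 3, 3)).astype(np.float32))
        s = Tensor(rng.normal(size=(2, 4)).astype(np.float32))
        a = demodulated_conv(x, w, s).data
        b = demodulated_conv(x, w, 2.5 * s).data
        assert np.allclose(a, b, atol=1e-5)

    def test_matches_modulate_demodulate_loop_oracle(self, rng):
        x = rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float64)
        w = rng.normal(size=(2, 3, 3, 3, 3)).astype(np.float64)
        s = rng.normal(size=(1, 3)).astype(np.float64)
        eps = 1e-8
        # oracle: modulate weights per input channel, demodulate per output
        wmod = w * s[0][None, :, None, None, None]
        d = 1.0 / np.sqrt((wmod ** 2).sum(axis=(1, 2, 3, 4)) + eps)
        wdem = wmod * d[:, None, None, None, None]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        expect = np.zeros((1, 2, 4, 4, 4))
        for o in range(2):
            for p in np.ndindex(4, 4, 4):
                acc = 0.0
                for i in range(3):
                    for kk in np.ndindex(3, 3, 3):
                        acc += xp[0, i, p[0] + kk[0], p[1] + kk[1], p[2] + kk[2]] \
                            * wdem[o, i, kk[0], kk[1], kk[2]]
                expect[0, o][p] = acc
        got = demodulated_conv(Tensor(x), Tensor(w), Tensor(s)).data
        assert np.allclose(got, expect, atol=1e-8)

    def test_unit_style_unit_norm_weights_is_plain_convolution(self):
        w = np.zeros((1, 1, 3, 3, 3), dtype=np.float32)
        w[0, 0, 1, 1, 1] = 1.0  # unit-norm identity kernel
        x = Tensor(np.random.default_rng(0).normal(size=(1, 1, 4, 4, 4)).astype(np.float32))
        s = Tensor(np.ones((1, 1), dtype=np.float32))
        out = demodulated_conv(x, Tensor(w), s).data
        assert np.allclose(out, x.data, atol=1e-4)


class TestNoiseInjection:
    def test_zero_scale_is_identity(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 4, 4, 4)).astype(np.float32))
        noise = rng.normal(size=(2, 1, 4, 4, 4)).astype(np.float32)
        out = inject_noise(x, Tensor(np.zeros(())), noise)
        assert np.array_equal(out.data, x.data)

    def test_all_channels_share_one_realization(self, rng):
        x = Tensor(np.zeros((1, 3, 2, 2, 2), dtype=np.float32))
        noise = rng.normal(size=(1, 1, 2, 2, 2)).astype(np.float32)
        out = inject_noise(x, Tensor(np.ones(())), noise).data
        for c in range(1, 3):
            assert np.array_equal(out[0, c], out[0, 0])

    def test_added_variance_matches_scale_squared(self):
        rng = np.random.default_rng(13)
        x = Tensor(np.zeros((1000, 1, 2, 2, 2), dtype=np.float32))
        scale = 0.7
        noise = rng.normal(size=(1000, 1, 2, 2, 2)).astype(np.float32)
        out = inject_noise(x, Tensor(np.array(scale)), noise).data
        assert np.isclose(out.var(), scale ** 2, rtol=0.15)


class TestStyleForward:
    def test_frozen_noise_is_deterministic(self, stylegan):
        w = Tensor(sample_latent(1, np.random.default_rng(14)))
        a = stylegan.forward_w(w, StageState(2), rng=None).data
        b = stylegan.forward_w(w, StageState(2), rng=None).data
        assert np.array_equal(a, b)

    def test_full_style_override_substitutes_the_other_code(self, stylegan):
        rng = np.random.default_rng(15)
        w1 = Tensor(sample_latent(1, rng))
        w2 = Tensor(sample_latent(1, rng))
        styles2 = stylegan.synthesis.style_codes(w2)
        override = {i: styles2[i] for i in range(N_STYLES)}
        mixed = stylegan.forward_w(w1, StageState(2), style_override=override).data
        plain = stylegan.forward_w(w2, StageState(2)).data
        assert np.allclose(mixed, plain, atol=1e-7)

    def test_missing_styles_rejected(self, stylegan):
        w = Tensor(sample_latent(1, np.random.default_rng(16)))
        styles = stylegan.synthesis.style_codes(w)[:10]
        with pytest.raises(ValueError):
            stylegan.synthesis(styles, StageState(2))


class TestCritic:
    def test_five_strided_layers_plus_score(self, critic):
        assert len(critic.strided) == 5
        assert critic.score.w.shape[1] == 1

    def test_accepts_generator_stage_output_shapes(self, progan, critic):
        z = sample_latent(1, np.random.default_rng(17))
        for stage in (1, 2, 3):
            out = progan(z, StageState(stage))
            score = critic(out, StageState(stage))
            assert score.shape == (1,)

    def test_wrong_resolution_rejected(self, critic):
        bad = Tensor(np.zeros((1, 1, 3, 3, 3), dtype=np.float32))
        with pytest.raises(ValueError):
            critic(bad, StageState(1))

    def test_zero_weights_give_zero_score(self):
        c = Critic(CFG, np.random.default_rng(18))
        for p in c.parameters():
            p.data = np.zeros_like(p.data)
        v = Tensor(np.random.default_rng(19).normal(
            size=(2, 1) + stage_resolution(CFG, 2)).astype(np.float32))
        assert np.allclose(c(v, StageState(2)).data, 0.0)

    def test_fade_endpoints_reproduce_pure_paths(self, critic, rng):
        v = Tensor(rng.normal(size=(1, 1) + stage_resolution(CFG, 3)).astype(np.float32))
        s_new = critic(v, StageState(3, 1.0)).data
        s_eps = critic(v, StageState(3, 1.0 - 1e-12)).data
        assert np.allclose(s_new, s_eps, atol=1e-6)


class TestEncoder:
    def test_output_is_512_dim_and_deterministic(self):
        enc = Encoder(CFG, np.random.default_rng(20), stage=2)
        v = Tensor(np.random.default_rng(21).normal(
            size=(2, 1) + stage_resolution(CFG, 2)).astype(np.float32))
        a, b = enc(v).data, enc(v).data
        assert a.shape == (2, LATENT_DIM)
        assert np.array_equal(a, b)

    def test_no_pixel_normalization_present(self):
        assert Encoder.uses_pixel_norm is False
        import inspect
        from volgan import networks
        src = inspect.getsource(networks.Encoder)
        assert "pixel_norm(" not in src  # no normalization call in the forward path

    def test_style_variant_has_two_extra_fc_layers(self):
        enc_p = Encoder(CFG, np.random.default_rng(22), variant="progan", stage=2)
        enc_s = Encoder(CFG, np.random.default_rng(22), variant="stylegan", stage=2)
        assert len(enc_p.fc_extra) == 0
        assert len(enc_s.fc_extra) == 2

    def test_wrong_shape_rejected(self):
        enc = Encoder(CFG, np.random.default_rng(23), stage=2)
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((1, 1, 4, 4, 4), dtype=np.float32)))
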