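"""Transformer GAN: embedding arithmetic, layers, losses, smoke training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vstain.tbgan import (Tensor, TbGanHyperparams, GanConfig, Generator,
                          Discriminator, PatchEmbed, MultiHeadSelfAttention,
                          FeedForward, LayerNorm, LossBreakdown,
                          compute_losses, patch_count, train, infer,
                          save_checkpoint, load_checkpoint, to_unit, from_unit)
from vstain.fixtures import SyntheticSlideSpec, generate_slide_pair, generate_patch_set


@pytest.fixture(scope="module")
def smoke_tiles():
    pair = generate_slide_pair(SyntheticSlideSpec(seed=5))
    patches = generate_patch_set(pair, 6, {}, patch_size=32, seed=2)
    return ([p.he_patch for p in patches], [p.mt_patch for p in patches])


@pytest.fixture(scope="module")
def smoke_run(smoke_tiles):
    cfg = GanConfig.from_label("O/10/3")
    hyper = TbGanHyperparams.smoke(seed=11)
    return train(cfg, *smoke_tiles, hyper, n_steps=50)


class TestTokenArithmetic:
    @pytest.mark.parametrize("side,expected", [
        (256, 1024), (512, 4096), (1024, 16384),
    ])
    def test_patch_counts(self, side, expected):
        assert patch_count(side, side, 8) == expected

    def test_single_patch(self):
        assert patch_count(8, 8, 8) == 1

    def test_attention_matrix_entries(self):
        n = patch_count(256, 256, 8)
        assert n * n == 1_048_576

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError):
            patch_count(100, 100, 8)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(1, 8), st.integers(1, 8), st.sampled_from([2, 4, 8]))
    def test_token_count_law(self, hm, wm, p):
        h, w = hm * p, wm * p
        assert patch_count(h, w, p) == (h * w) // (p * p)


class TestLayers:
    def test_zero_projection_gives_zero_tokens(self, rng):
        pe = PatchEmbed(np.random.default_rng(0), 8, 3, 16)
        pe.we.data[:] = 0.0
        x = Tensor(rng.random((1, 32, 32, 3)))
        assert np.all(pe(x).data == 0)

    def test_single_token_attention_is_value(self):
        """With N=1 the softmax weight is 1: attention output == V row."""
        r = np.random.default_rng(0)
        msa = MultiHeadSelfAttention(r, 8, 2)
        z = Tensor(r.normal(size=(1, 1, 8)))
        att = msa.attention_weights(z)
        np.testing.assert_allclose(att.data, 1.0)

    def test_identical_keys_uniform_attention(self):
        r = np.random.default_rng(1)
        msa = MultiHeadSelfAttention(r, 8, 2)
        msa.wk.data[:] = 0.0           # all keys identical -> constant logits
        z = Tensor(r.normal(size=(1, 5, 8)))
        att = msa.attention_weights(z)
        np.testing.assert_allclose(att.data, 1.0 / 5.0, atol=1e-12)

    def test_attention_rows_normalized(self, rng):
        r = np.random.default_rng(2)
        msa = MultiHeadSelfAttention(r, 16, 4)
        z = Tensor(rng.normal(size=(2, 7, 16)))
        att = msa.attention_weights(z)
        np.testing.assert_allclose(att.data.sum(-1), 1.0, atol=1e-6)

    def test_ffn_zero_weights_give_bias(self):
        r = np.random.default_rng(3)
        ffn = FeedForward(r, 4, 8)
        ffn.fc1.w.data[:] = 0.0
        ffn.fc2.w.data[:] = 0.0
        ffn.fc2.b.data[:] = [1.0, -2.0, 0.5, 0.0]
        out = ffn(Tensor(np.ones((1, 4))))
        np.testing.assert_allclose(out.data, [[1.0, -2.0, 0.5, 0.0]])

    def test_gelu_at_three(self):
        from scipy.stats import norm
        g = Tensor(np.array([3.0])).gelu()
        assert g.data[0] == pytest.approx(3.0 * norm.cdf(3.0), abs=1e-9)

    def test_layer_norm_hand_case(self):
        ln = LayerNorm(2, eps=0.0)
        out = ln(Tensor(np.array([[1.0, 3.0]])))
        np.testing.assert_allclose(out.data, [[-1.0, 1.0]], atol=1e-9)

    def test_layer_norm_constant_token_gives_beta(self):
        ln = LayerNorm(3)
        ln.beta.data[:] = [5.0, 6.0, 7.0]
        out = ln(Tensor(np.full((1, 3), 2.0)))
        np.testing.assert_allclose(out.data, [[5.0, 6.0, 7.0]], atol=1e-3)


class TestGeneratorDiscriminator:
    def test_generator_shape_and_range(self):
        hyper = TbGanHyperparams.smoke(seed=0)
        g = Generator(hyper, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).uniform(-1, 1, (1, 32, 32, 4)))
        y = g(x)
        assert y.shape == (1, 32, 32, 4)
        assert np.all(np.abs(y.data) <= 1.0)

    def test_decoder_stage_count(self):
        hyper = TbGanHyperparams.smoke(seed=0)
        g = Generator(hyper, np.random.default_rng(0))
        assert len(g.decoder.weights) == 3          # log2(8) stride-2 stages

    def test_discriminator_probabilities(self):
        hyper = TbGanHyperparams.smoke(seed=0)
        d = Discriminator(hyper, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).uniform(-1, 1, (1, 32, 32, 4)))
        p = d(x)
        assert np.all((p.data > 0) & (p.data < 1))

    def test_discriminator_per_sample_normalization(self):
        """Doubling the batch with the same image gives elementwise-equal halves."""
        hyper = TbGanHyperparams.smoke(seed=0)
        d = Discriminator(hyper, np.random.default_rng(0))
        x = np.random.default_rng(1).uniform(-1, 1, (1, 32, 32, 4))
        single = d(Tensor(x)).data
        double = d(Tensor(np.concatenate([x, x]))).data
        np.testing.assert_allclose(double[0], double[1], atol=1e-12)
        np.testing.assert_allclose(double[0], single[0], atol=1e-12)


class TestLosses:
    def test_identity_generators_zero_cycle_and_identity(self, smoke_tiles):
        hyper = TbGanHyperparams.smoke(seed=0)
        d = Discriminator(hyper, np.random.default_rng(0))

        def with_alpha(tile):
            unit = to_unit(tile)[None]
            return Tensor(np.concatenate(
                [unit, np.ones(unit.shape[:3] + (1,))], axis=-1))

        xa4 = with_alpha(smoke_tiles[0][0])
        xb4 = with_alpha(smoke_tiles[1][0])
        ident = lambda t: t
        _, bd = compute_losses(xa4, xb4, ident, ident, d, d, (10.0, 3.0))
        assert bd.cycle_A == bd.cycle_B == bd.id_A == bd.id_B == 0.0

    def test_worked_total(self):
        bd = LossBreakdown(adv_A=1.0, adv_B=1.0, cycle_A=0.5, cycle_B=0.5,
                           id_A=0.2, id_B=0.2, lambda_cycle=10.0,
                           lambda_identity=3.0)
        assert bd.total == pytest.approx(13.2, abs=1e-12)

    def test_zero_lambdas_reduce_to_adversarial(self):
        bd = LossBreakdown(adv_A=0.7, adv_B=0.3, cycle_A=9.0, cycle_B=9.0,
                           id_A=9.0, id_B=9.0, lambda_cycle=0.0,
                           lambda_identity=0.0)
        assert bd.total == pytest.approx(1.0)

    def test_logged_terms_recompose_total(self, smoke_run):
        for bd in smoke_run.loss_curve:
            recomposed = (bd.adv_A + bd.adv_B
                          + bd.lambda_cycle * (bd.cycle_A + bd.cycle_B)
                          + bd.lambda_identity * (bd.id_A + bd.id_B))
            assert recomposed == pytest.approx(bd.total, abs=1e-6)


class TestConfigs:
    @pytest.mark.parametrize("label,variant,lams", [
        ("O/10/3", "original", (10.0, 3.0)),
        ("O/3/10", "original", (3.0, 10.0)),
        ("R/10/3", "reinhard", (10.0, 3.0)),
        ("R/3/10", "reinhard", (3.0, 10.0)),
    ])
    def test_label_roundtrip(self, label, variant, lams):
        cfg = GanConfig.from_label(label)
        assert cfg.input_variant == variant
        assert cfg.lambdas == lams
        assert cfg.label == label

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            GanConfig.from_label("O/5/5")


class TestTraining:
    def test_loss_decreases_over_smoke_run(self, smoke_run):
        totals = smoke_run.generator_totals
        assert len(totals) == 50
        assert totals[-1] < totals[0]

    def test_seeded_run_bit_reproducible(self, smoke_tiles, smoke_run):
        cfg = GanConfig.from_label("O/10/3")
        again = train(cfg, *smoke_tiles, TbGanHyperparams.smoke(seed=11),
                      n_steps=50)
        assert again.generator_totals == smoke_run.generator_totals

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(GanConfig.from_label("O/10/3"), [], [],
                  TbGanHyperparams.smoke())


class TestInference:
    def test_shape_and_determinism(self, smoke_run, smoke_tiles):
        out1 = infer(smoke_run.G_B, smoke_tiles[0][0])
        out2 = infer(smoke_run.G_B, smoke_tiles[0][0])
        assert out1.shape == smoke_tiles[0][0].shape[:2] + (3,)
        np.testing.assert_array_equal(out1, out2)

    def test_unit_range_roundtrip(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        np.testing.assert_array_equal(from_unit(to_unit(img)), img)

    def test_checkpoint_roundtrip(self, smoke_run, smoke_tiles, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(smoke_run, path)
        loaded = load_checkpoint(path)
        a = infer(smoke_run.G_B, smoke_tiles[0][1])
        b = infer(loaded.G_B, smoke_tiles[0][1])
        np.testing.assert_array_equal(a, b)
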