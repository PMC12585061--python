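"""Network architecture: shape contracts, attention/fusion algebra,
gradient flow and the full-scale preset audit."""

import numpy as np
import pytest

from lungsound.model import (AcousticEmbedding, ClassFusion, ConvBlock,
                             CrossModalAttention, EncoderConfig, ModelConfig,
                             RespiratoryModel, StreamCNN, StreamConfig,
                             TemporalEmbedding, build_model,
                             temporal_align, temporal_align_matrix)
from lungsound.nn import Tensor, cross_entropy, softmax

RNG = np.random.default_rng(0)


class TestConvBlocks:
    def test_spatial_extents_halve(self):
        block = ConvBlock(1, 16, 3, np.random.default_rng(0))
        out = block(Tensor(RNG.normal(size=(2, 1, 20, 259))))
        assert out.shape == (2, 16, 10, 129)

    def test_zero_input_zero_preactivation(self):
        from lungsound.nn import Conv2d, relu
        conv = Conv2d(1, 4, 3, np.random.default_rng(1))
        conv.bias.data[:] = 0
        out = relu(conv(Tensor(np.zeros((1, 1, 8, 8)))))
        assert np.all(out.data == 0)

    def test_three_chained_blocks_on_mel_extent(self):
        stream = StreamCNN(StreamConfig(), np.random.default_rng(2))
        out = stream(Tensor(RNG.normal(size=(1, 1, 128, 259))))
        assert out.shape == (1, 64, 16, 32)

    def test_stream_flatten_lengths_match_architecture(self):
        stream = StreamCNN(StreamConfig(), np.random.default_rng(3))
        flat_mfcc, _ = stream.forward_flat(Tensor(RNG.normal(size=(1, 1, 20, 259))))
        assert flat_mfcc.shape == (1, 4096)   # 2 x 32 x 64
        flat_mel, _ = stream.forward_flat(Tensor(RNG.normal(size=(1, 1, 128, 259))))
        assert flat_mel.shape == (1, 32768)   # 16 x 32 x 64

    def test_batch_axis_preserved(self):
        stream = StreamCNN(StreamConfig(), np.random.default_rng(4))
        flat, _ = stream.forward_flat(Tensor(RNG.normal(size=(5, 1, 20, 65))))
        assert flat.shape[0] == 5


class TestAcousticEmbedding:
    def test_identity_kernel(self):
        emb = AcousticEmbedding(1, 1, np.random.default_rng(5))
        emb.kernel.data[:] = 1.0
        x = Tensor(RNG.normal(size=(1, 1, 16, 8)))
        np.testing.assert_allclose(emb(x).data, x.data, atol=1e-12)

    def test_channel_count_and_time_extent(self):
        emb = AcousticEmbedding(16, 8, np.random.default_rng(6))
        out = emb(Tensor(RNG.normal(size=(2, 1, 128, 259))))
        assert out.shape == (2, 8, 113, 259)

    def test_linearity(self):
        emb = AcousticEmbedding(4, 3, np.random.default_rng(7))
        x = RNG.normal(size=(1, 1, 16, 10))
        np.testing.assert_allclose(emb(Tensor(3.0 * x)).data,
                                   3.0 * emb(Tensor(x)).data, atol=1e-10)

    def test_oversized_kernel_rejected(self):
        emb = AcousticEmbedding(32, 2, np.random.default_rng(8))
        with pytest.raises(ValueError):
            emb(Tensor(np.zeros((1, 1, 16, 4))))


class TestTemporalEmbedding:
    def test_zero_frequency_returns_bias(self):
        emb = TemporalEmbedding(8, rng=np.random.default_rng(9))
        emb.omega.data[:] = 0.0
        out = emb(np.arange(5))
        np.testing.assert_allclose(out.data, np.tile(emb.b_t.data, (5, 1)), atol=1e-12)

    def test_periodicity(self):
        emb = TemporalEmbedding(8, rng=np.random.default_rng(10))
        emb.omega.data[:] = 0.5
        a = emb(np.array([1.0])).data
        b = emb(np.array([1.0 + 2 * np.pi / 0.5])).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_output_dimension_matches_hidden(self):
        emb = TemporalEmbedding(32, rng=np.random.default_rng(11))
        assert emb(np.arange(7)).shape == (7, 32)


class TestTemporalAlign:
    def test_identity_when_lengths_match(self):
        x = Tensor(RNG.normal(size=(2, 16, 4)))
        np.testing.assert_array_equal(temporal_align(x, 16).data, x.data)

    def test_constant_sequence_stays_constant(self):
        x = Tensor(np.full((1, 37, 3), 2.5))
        out = temporal_align(x, 16)
        np.testing.assert_allclose(out.data, 2.5, atol=1e-12)

    def test_mean_conserved(self):
        x = Tensor(RNG.normal(size=(3, 65, 8)))
        out = temporal_align(x, 16)
        np.testing.assert_allclose(out.data.mean(axis=1), x.data.mean(axis=1),
                                   atol=1e-10)

    def test_rows_of_pool_matrix_sum_to_one(self):
        p = temporal_align_matrix(65, 16)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            temporal_align_matrix(0, 4)


class TestCrossModalAttention:
    CFG = EncoderConfig(hidden=16, layers=1, heads=2, seq_len=6,
                        embed_channels=2, embed_freq_extent=4)

    def test_rows_sum_to_one(self):
        attn = CrossModalAttention(self.CFG, np.random.default_rng(12))
        ha = Tensor(RNG.normal(size=(2, 6, 16)))
        he = Tensor(RNG.normal(size=(2, 6, 16)))
        weights = attn.attention_weights(ha, he)
        np.testing.assert_allclose(weights.data.sum(axis=-1), 1.0, atol=1e-9)

    def test_identical_keys_give_uniform_attention(self):
        attn = CrossModalAttention(self.CFG, np.random.default_rng(13))
        ha = Tensor(np.tile(RNG.normal(size=(1, 1, 16)), (1, 6, 1)))
        he = Tensor(np.tile(RNG.normal(size=(1, 1, 16)), (1, 6, 1)))
        weights = attn.attention_weights(ha, he)
        np.testing.assert_allclose(weights.data, 1.0 / 6, atol=1e-9)

    def test_uniform_additive_constant_cancels_in_softmax(self):
        # the algebra that forces lambda to enter non-uniformly
        logits = RNG.normal(size=(1, 2, 6, 6))
        a = softmax(Tensor(logits), axis=-1).data
        b = softmax(Tensor(logits + 3.7), axis=-1).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_lambda_zero_matches_plain_concat_attention(self):
        attn = CrossModalAttention(self.CFG, np.random.default_rng(14))
        ha = Tensor(RNG.normal(size=(1, 6, 16)))
        he = Tensor(RNG.normal(size=(1, 6, 16)))
        base = attn.attention_weights(ha, he).data
        attn.lambda_acoustic.data[:] = 1.5
        boosted = attn.attention_weights(ha, he).data
        assert not np.allclose(base, boosted)  # lambda is not a no-op

    def test_output_dimension(self):
        attn = CrossModalAttention(self.CFG, np.random.default_rng(15))
        out = attn(Tensor(RNG.normal(size=(2, 6, 16))),
                   Tensor(RNG.normal(size=(2, 6, 16))))
        assert out.shape == (2, 6, 16)


class TestClassFusion:
    def test_alpha_on_simplex_and_final_normalized(self):
        fusion = ClassFusion(16, 5, np.random.default_rng(16))
        ha = Tensor(RNG.normal(size=(4, 16)))
        hx = Tensor(RNG.normal(size=(4, 16)))
        h_final, alpha = fusion(ha, hx)
        np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(h_final.data.mean(axis=-1), 0.0, atol=1e-4)
        np.testing.assert_allclose(h_final.data.std(axis=-1), 1.0, atol=1e-2)

    def test_gating_structure_at_alpha_extremes(self):
        # with alpha_c = 1 the class branch sees only acoustic features
        fusion = ClassFusion(4, 2, np.random.default_rng(17))
        ha = Tensor(RNG.normal(size=(1, 4)))
        zeros = Tensor(np.zeros((1, 4)))
        from lungsound.nn import concatenate
        gated = concatenate([1.0 * ha, 0.0 * zeros], axis=-1)
        contribution = (gated @ fusion.w_class[0]).data
        manual = np.concatenate([ha.data, np.zeros((1, 4))], axis=-1) @ fusion.w_class[0].data
        np.testing.assert_allclose(contribution, manual, atol=1e-12)


class TestFullModel:
    def test_tiny_forward_contracts(self):
        model = build_model("tiny", num_classes=3, seed=0)
        model.eval()
        out = model(RNG.normal(size=(2, 20, 65, 1)),
                    RNG.normal(size=(2, 20, 65, 1)),
                    RNG.normal(size=(2, 128, 65, 1)))
        assert out.logits.shape == (2, 3)
        np.testing.assert_allclose(out.class_attention.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(out.confidence >= 1 / 3 - 1e-9) and np.all(out.confidence <= 1)

    def test_argmax_invariant_to_logit_shift(self):
        model = build_model("tiny", num_classes=3, seed=1)
        model.eval()
        out = model(RNG.normal(size=(1, 20, 65, 1)),
                    RNG.normal(size=(1, 20, 65, 1)),
                    RNG.normal(size=(1, 128, 65, 1)))
        shifted = out.logits.data + 11.0
        e = np.exp(shifted - shifted.max())
        assert (e / e.sum()).argmax() == out.probabilities.argmax()

    def test_gradient_reaches_every_parameter(self):
        model = build_model("tiny", num_classes=2, seed=2)
        out = model(RNG.normal(size=(4, 20, 65, 1)),
                    RNG.normal(size=(4, 20, 65, 1)),
                    RNG.normal(size=(4, 128, 65, 1)))
        loss = cross_entropy(out.logits, np.eye(2)[[0, 1, 0, 1]])
        loss.backward()
        dead = [p.shape for p in model.parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_deterministic_forward_given_seed(self):
        outs = []
        for _ in range(2):
            model = build_model("tiny", num_classes=2, seed=7)
            model.eval()
            rng = np.random.default_rng(3)
            outs.append(model(rng.normal(size=(1, 20, 65, 1)),
                              rng.normal(size=(1, 20, 65, 1)),
                              rng.normal(size=(1, 128, 65, 1))).logits.data)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_paper_preset_full_scale_shape_audit(self):
        model = build_model("paper", num_classes=5, seed=0)
        assert model.config.encoder.hidden == 768
        assert model.config.encoder.layers == 12
        assert model.config.encoder.heads == 8
        assert model.config.encoder.head_dim == 96
        assert model.config.encoder.concat_dim == 1536
        model.eval()
        out = model(np.zeros((1, 20, 259, 1), np.float32),
                    np.zeros((1, 20, 259, 1), np.float32),
                    np.zeros((1, 128, 259, 1), np.float32))
        assert out.logits.shape == (1, 5)
        assert out.class_attention.shape == (1, 5)

    def test_state_dict_roundtrip(self):
        model = build_model("tiny", num_classes=2, seed=4)
        model.eval()
        x = (RNG.normal(size=(1, 20, 65, 1)), RNG.normal(size=(1, 20, 65, 1)),
             RNG.normal(size=(1, 128, 65, 1)))
        before = model(*x).logits.data.copy()
        state = {k: v.copy() for k, v in model.state_dict().items()}
        for p in model.parameters():
            p.data = p.data + 1.0
        model.load_state_dict(state)
        np.testing.assert_array_equal(model(*x).logits.data, before)
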