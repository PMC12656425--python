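"""Contrastive embedding: encoder, pooling, augmentation, NT-Xent, pretraining."""

import numpy as np
import pytest

from voxfuse.audio import Waveform
from voxfuse.contrastive import (
    AugmentationConfig,
    ContrastiveBatch,
    EncoderConfig,
    PretrainConfig,
    SpeechEncoder,
    augment_view,
    embed_utterance,
    encode,
    mean_pool,
    nt_xent_loss,
    pretrain_contrastive,
    project,
)
from voxfuse.errors import EmptyInputError, ValidationError
from voxfuse.synth import PhonationSpec, generate_phonation


def brute_force_nt_xent(P, pair_index, tau):
    """O((2N)^2) double-loop evaluation of the contrastive loss."""
    Z = P / np.linalg.norm(P, axis=1, keepdims=True)
    S = Z @ Z.T
    m = len(P)
    total = 0.0
    for i in range(m):
        num = np.exp(S[i, pair_index[i]] / tau)
        den = sum(np.exp(S[i, k] / tau) for k in range(m) if k != i)
        total += -np.log(num / den)
    return total / m


def phonation(seed, duration=0.4):
    w, _ = generate_phonation(
        PhonationSpec(f0=120.0 + 10 * (seed % 5), duration=duration,
                      hnr_db=25.0, seed=seed)
    )
    return w


class TestEncode:
    def test_token_dimension_follows_config(self, tiny_encoder_cfg):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        tokens = encode(phonation(0), enc)
        assert tokens.shape[1] == 32

    def test_default_hidden_dim_is_768(self):
        assert EncoderConfig().hidden_dim == 768

    def test_deterministic_in_inference_mode(self, tiny_encoder_cfg):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        w = phonation(1)
        np.testing.assert_array_equal(encode(w, enc), encode(w, enc))

    def test_token_count_scales_with_duration(self, tiny_encoder_cfg):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        t2 = encode(phonation(2, duration=1.0), enc).shape[0]
        t1 = encode(phonation(2, duration=0.5), enc).shape[0]
        assert abs(t2 - 2 * t1) <= max(2, 0.05 * t2)

    def test_too_short_input_errors(self, tiny_encoder_cfg):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        with pytest.raises(ValidationError):
            encode(Waveform(np.ones(5), 16000), enc)

    def test_adapter_protocol_accepted(self):
        adapter = lambda w: np.tile(w.samples[:4], (3, 1))
        w = Waveform(np.arange(8.0) / 8, 16000)
        assert encode(w, adapter).shape == (3, 4)


class TestMeanPool:
    def test_identical_tokens_return_that_token(self):
        tokens = np.tile([1.0, 2.0, 3.0], (5, 1))
        np.testing.assert_array_equal(mean_pool(tokens), [1.0, 2.0, 3.0])

    def test_two_token_average(self):
        np.testing.assert_array_equal(
            mean_pool(np.array([[0.0] * 4, [2.0] * 4])), [1.0] * 4
        )

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        tokens = rng.normal(size=(7, 5))
        np.testing.assert_allclose(
            mean_pool(tokens), tokens.sum(axis=0) / 7, atol=1e-9
        )

    def test_commutes_with_token_permutation(self):
        rng = np.random.default_rng(1)
        tokens = rng.normal(size=(9, 4))
        perm = rng.permutation(9)
        np.testing.assert_allclose(mean_pool(tokens), mean_pool(tokens[perm]),
                                   atol=1e-12)

    def test_empty_token_matrix_errors(self):
        with pytest.raises(EmptyInputError):
            mean_pool(np.zeros((0, 4)))


class TestProjection:
    def test_output_dimension(self, tiny_encoder_cfg):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        assert project(np.zeros(32), enc).shape == (16,)

    def test_dimension_mismatch_errors(self, tiny_encoder_cfg):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        with pytest.raises(ValidationError):
            project(np.zeros(33), enc)

    def test_deterministic_given_parameters(self, tiny_encoder_cfg):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        z = np.random.default_rng(0).normal(size=32)
        np.testing.assert_array_equal(project(z, enc), project(z, enc))


class TestAugmentation:
    def test_zero_magnitudes_are_identity(self):
        cfg = AugmentationConfig(time_mask_max=0.0, noise_snr_range=(200.0, 200.0),
                                 shift_max_frac=0.0)
        w = phonation(3)
        out = augment_view(w, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out.samples, w.samples, atol=1e-9)

    def test_noise_snr_calibration(self):
        # force the noise step on; unit-RMS input, 25 dB target
        cfg = AugmentationConfig(time_mask_max=0.0, noise_snr_range=(25.0, 25.0),
                                 shift_max_frac=0.0, apply_prob=1.0)
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 200 * np.arange(16000) / 16000) * np.sqrt(2)
        w = Waveform(x, 16000)
        out = augment_view(w, cfg, rng)
        noise_rms = np.sqrt(np.mean((out.samples - x) ** 2))
        assert abs(noise_rms - 10 ** (-25 / 20)) / 10 ** (-25 / 20) < 0.1

    def test_seed_reproducibility_and_variation(self):
        cfg = AugmentationConfig()
        w = phonation(4)
        a = augment_view(w, cfg, np.random.default_rng(7))
        b = augment_view(w, cfg, np.random.default_rng(7))
        c = augment_view(w, cfg, np.random.default_rng(8))
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_length_and_rate_preserved(self):
        cfg = AugmentationConfig(apply_prob=1.0)
        w = phonation(5)
        out = augment_view(w, cfg, np.random.default_rng(0))
        assert len(out) == len(w) and out.rate == w.rate


class TestNTXent:
    def test_single_pair_loss_is_exactly_zero(self):
        P = np.random.default_rng(0).normal(size=(2, 6))
        batch = ContrastiveBatch.from_interleaved(P)
        for tau in (0.07, 0.5, 2.0):
            assert nt_xent_loss(batch, tau) == pytest.approx(0.0, abs=1e-12)

    def test_hand_constructed_batch_matches_brute_force(self):
        # positives aligned, negatives orthogonal
        P = np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
        batch = ContrastiveBatch.from_interleaved(P)
        expected = brute_force_nt_xent(P, batch.pair_index, 0.5)
        assert nt_xent_loss(batch, 0.5) == pytest.approx(expected, abs=1e-8)

    def test_oracle_equivalence_on_random_batches(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            N = int(rng.integers(1, 9))
            P = rng.normal(size=(2 * N, int(rng.integers(3, 10))))
            batch = ContrastiveBatch.from_interleaved(P)
            tau = float(rng.uniform(0.05, 2.0))
            assert nt_xent_loss(batch, tau) == pytest.approx(
                brute_force_nt_xent(P, batch.pair_index, tau), abs=1e-8
            )

    def test_utterance_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(8, 5))
        batch = ContrastiveBatch.from_interleaved(P)
        # permute utterances (pairs move together)
        order = np.array([2, 3, 6, 7, 0, 1, 4, 5])
        permuted = ContrastiveBatch.from_interleaved(P[order])
        assert nt_xent_loss(batch, 0.3) == pytest.approx(
            nt_xent_loss(permuted, 0.3), abs=1e-9
        )

    def test_loss_decreases_as_positive_similarity_rises(self):
        # move the positive pair closer while negatives stay fixed
        losses = []
        for align in (0.0, 0.5, 0.9):
            v = np.array([1.0, 0.0])
            u = np.array([align, np.sqrt(1 - align**2)])
            P = np.stack([v, u, [0.0, -1.0], [-1.0, 0.0]])
            losses.append(nt_xent_loss(ContrastiveBatch.from_interleaved(P), 0.5))
        assert losses[0] > losses[1] > losses[2]

    def test_zero_norm_projection_rejected(self):
        P = np.array([[1.0, 0], [0, 0], [0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValidationError):
            nt_xent_loss(ContrastiveBatch.from_interleaved(P), 0.5)


@pytest.fixture(scope="module")
def corpus():
    return [phonation(i) for i in range(16)]


class TestPretraining:
    def test_loss_decreases_and_is_reproducible(self, corpus, tiny_encoder_cfg):
        cfg = PretrainConfig(epochs=3, batch_size=4)
        enc1, hist1 = pretrain_contrastive(corpus, tiny_encoder_cfg, cfg, seed=0)
        assert hist1[-1] < hist1[0]
        _, hist2 = pretrain_contrastive(corpus, tiny_encoder_cfg, cfg, seed=0)
        assert hist1 == hist2

    def test_positive_views_closer_than_negatives_after_training(
        self, corpus, tiny_encoder_cfg
    ):
        cfg = PretrainConfig(epochs=3, batch_size=4)
        enc, _ = pretrain_contrastive(corpus, tiny_encoder_cfg, cfg, seed=1)
        rng = np.random.default_rng(0)
        aug = AugmentationConfig()

        def unit(w):
            e = embed_utterance(w, enc)
            return e / np.linalg.norm(e)

        pos_sims, neg_sims = [], []
        for i in range(6):
            a = unit(augment_view(corpus[i], aug, rng))
            b = unit(augment_view(corpus[i], aug, rng))
            c = unit(augment_view(corpus[(i + 3) % len(corpus)], aug, rng))
            pos_sims.append(a @ b)
            neg_sims.append(a @ c)
        assert np.mean(pos_sims) > np.mean(neg_sims)

    def test_corpus_smaller_than_batch_rejected(self, tiny_encoder_cfg):
        with pytest.raises(ValidationError):
            pretrain_contrastive([phonation(0)], tiny_encoder_cfg,
                                 PretrainConfig(batch_size=4), seed=0)


class TestEmbedUtterance:
    def test_dimension_follows_config(self, tiny_encoder_cfg):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        assert embed_utterance(phonation(0), enc).shape == (32,)

    def test_checkpoint_roundtrip(self, tiny_encoder_cfg, tmp_path):
        enc = SpeechEncoder(tiny_encoder_cfg, seed=0)
        w = phonation(1)
        before = embed_utterance(w, enc)
        enc.save(tmp_path / "enc.npz")
        back = SpeechEncoder.load(tmp_path / "enc.npz")
        np.testing.assert_array_equal(before, embed_utterance(w, back))
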