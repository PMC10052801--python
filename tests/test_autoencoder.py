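"""SMILES autoencoder: encoding, decoding, freezing, reconstruction."""

import math

import numpy as np
import pytest

from ligandgen.nn import Adam
from ligandgen.nn.tensor import backward as backward_
from ligandgen.smiles_autoencoder import (AutoencoderConfig, FrozenDecoder,
                                          SmilesAutoencoder, encode_one_hot,
                                          reconstruction_rate,
                                          train_autoencoder)
from ligandgen.vocab import SmilesVocabulary

VOCAB = SmilesVocabulary()


class TestOneHot:
    def test_construction(self):
        m = encode_one_hot(["C", "C", "O"], VOCAB, 6)
        assert m.shape == (6, len(VOCAB))
        ids = m.argmax(axis=1).tolist()
        assert ids == [VOCAB.sos_id, VOCAB.token_id("C"), VOCAB.token_id("C"),
                       VOCAB.token_id("O"), VOCAB.eos_id, VOCAB.pad_id]

    def test_rows_sum_to_one(self):
        m = encode_one_hot(["c", "1"], VOCAB, 8)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_argmax_round_trip(self):
        tokens = VOCAB.tokenize("CCc1ccccc1Cl")
        m = encode_one_hot(tokens, VOCAB, 16)
        assert VOCAB.decode(m.argmax(axis=1).tolist()) == "CCc1ccccc1Cl"

    def test_overflow_raises(self):
        with pytest.raises(ValueError, match="too long"):
            encode_one_hot(["C"] * 10, VOCAB, 6)


@pytest.fixture(scope="module")
def tiny_ae():
    cfg = AutoencoderConfig.test_scale(seed=0, encoder_units=32,
                                       decoder_units=24, latent_dim=12)
    return SmilesAutoencoder(cfg)


class TestEncodeDecode:
    def test_initial_teacher_forced_loss_is_logV(self, tiny_ae):
        oh = np.stack([encode_one_hot(VOCAB.tokenize(s), VOCAB, 16)
                       for s in ["CCO", "c1ccccc1"]])
        loss = tiny_ae.teacher_forced_loss(oh)
        assert loss.item() == pytest.approx(math.log(len(VOCAB)), rel=0.01)

    def test_encode_deterministic_and_sized(self, tiny_ae):
        a = tiny_ae.encode("CCOC").vector
        b = tiny_ae.encode("CCOC").vector
        assert a.shape == (tiny_ae.config.latent_dim,)
        assert np.array_equal(a, b)

    def test_greedy_decode_deterministic(self, tiny_ae):
        z = np.random.default_rng(0).normal(
            size=tiny_ae.config.latent_dim).astype(np.float32)
        s1 = tiny_ae.decode(z, mode="greedy")
        s2 = tiny_ae.decode(z, mode="greedy")
        assert s1 == s2

    def test_temperature_zero_equals_greedy(self, tiny_ae):
        z = np.random.default_rng(1).normal(
            size=tiny_ae.config.latent_dim).astype(np.float32)
        assert (tiny_ae.decode(z, mode="multinomial", temperature=1e-9, seed=5)
                == tiny_ae.decode(z, mode="greedy"))

    def test_decode_emits_only_vocabulary_tokens(self, tiny_ae):
        rng = np.random.default_rng(2)
        outs = tiny_ae.decode_many(
            rng.normal(size=(8, tiny_ae.config.latent_dim)).astype(np.float32),
            mode="multinomial", seed=3)
        for s in outs:
            assert VOCAB.try_tokenize(s) is not None or s == ""
            assert len(VOCAB.try_tokenize(s) or []) <= tiny_ae.config.max_smiles_len

    def test_untokenizable_input_raises(self, tiny_ae):
        with pytest.raises(Exception):
            tiny_ae.encode("CC%10")


class TestTraining:
    def test_single_string_memorization(self):
        cfg = AutoencoderConfig.test_scale(seed=0, encoder_units=32,
                                           decoder_units=24, latent_dim=8,
                                           batch_size=2)
        ae = SmilesAutoencoder(cfg)
        oh = np.stack([encode_one_hot(VOCAB.tokenize("CCO"), VOCAB, 16)] * 2)
        params = ae.parameters()
        opt = Adam(params, lr=3e-3)
        for _ in range(150):
            loss = ae.teacher_forced_loss(oh)
            backward_(loss, params)
            opt.step()
            opt.zero_grad()
        assert reconstruction_rate(ae, ["CCO"]) == 1.0

    def test_too_few_strings_raise(self):
        with pytest.raises(ValueError):
            train_autoencoder(["CCO"], AutoencoderConfig.test_scale(), 1)

    def test_benchmark_run_reconstructs_holdout(self, trained_autoencoder):
        """The 500-molecule fixture benchmark reaches >= 90% held-out
        exact-string reconstruction at test scale."""
        assert trained_autoencoder["n_molecules"] == 500
        assert trained_autoencoder["holdout_reconstruction"] >= 0.90

    def test_benchmark_initial_loss_uniform(self, trained_autoencoder):
        assert trained_autoencoder["initial_loss"] == pytest.approx(
            math.log(len(VOCAB)), rel=0.02)

    def test_recon_history_trend(self, trained_autoencoder):
        """Reconstruction trends upward: across ten evenly spaced
        checkpoints at most one dip deeper than training noise (0.05)."""
        hist = [r for _, r in trained_autoencoder["report"]["recon_history"]]
        idx = np.linspace(0, len(hist) - 1, num=min(10, len(hist))).astype(int)
        coarse = [hist[i] for i in idx]
        dips = sum(1 for a, b in zip(coarse, coarse[1:]) if b < a - 0.05)
        assert dips <= 1
        assert coarse[-1] == max(coarse)


class TestFreeze:
    def test_freeze_checksum_stable_under_training_attempt(self, tiny_ae):
        frozen = tiny_ae.freeze_decoder()
        before = frozen.current_checksum()
        # attempt a gradient update on the full model: frozen decoder
        # parameters are excluded from the graph, so they cannot move
        oh = np.stack([encode_one_hot(VOCAB.tokenize(s), VOCAB, 16)
                       for s in ["CCO", "CCN"]])
        params = tiny_ae.parameters()
        opt = Adam(params, lr=1e-2)
        loss = tiny_ae.teacher_forced_loss(oh)
        backward_(loss, params)
        opt.step()
        assert frozen.current_checksum() == before

    def test_encoder_still_usable_after_freeze(self, tiny_ae):
        tiny_ae.freeze_decoder()
        z = tiny_ae.encode_many(["CCO", "CCN"])
        assert z.shape == (2, tiny_ae.config.latent_dim)
        assert np.isfinite(z).all()
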