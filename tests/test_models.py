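"""Encoder / decoder / classifier contracts: shapes, determinism,
conditioning, gradient correctness and checkpoint round-trips."""

import numpy as np
import pytest

from auxrad import nn
from auxrad.models import (EncoderConfig, DecoderConfig, ClassifierConfig,
                           SharedLatentModel, BiLSTMDecoder, build_encoder,
                           build_classifier, predict, prepare_images)


class TestEncoder:
    @pytest.mark.parametrize("backbone", ["small-cnn", "inception-like"])
    def test_latent_shape_contract(self, backbone):
        model = SharedLatentModel(
            EncoderConfig(input_size=64, backbone=backbone),
            ClassifierConfig(), None, seed=0)
        x = np.random.default_rng(0).random((8, 1, 64, 64), dtype=np.float32)
        z = model.encode(x)
        assert z.shape == (8, 64)

    def test_eval_mode_deterministic(self):
        model = SharedLatentModel(EncoderConfig(input_size=64),
                                  ClassifierConfig(), None, seed=1)
        x = np.random.default_rng(1).random((2, 1, 64, 64), dtype=np.float32)
        np.testing.assert_array_equal(model.encode(x), model.encode(x))

    def test_train_mode_dropout_varies(self):
        model = SharedLatentModel(EncoderConfig(input_size=64),
                                  ClassifierConfig(), None, seed=1)
        x = np.random.default_rng(1).random((2, 1, 64, 64), dtype=np.float32)
        a = model.encode(x, train=True)
        b = model.encode(x, train=True)
        assert not np.array_equal(a, b)

    def test_backprop_matches_finite_difference(self):
        cfg = EncoderConfig(input_size=64, channels=(2, 3, 4, 5),
                            dropout=0.0, dtype="float64")
        enc = build_encoder(cfg, seed=2)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 1, 64, 64))
        w = rng.standard_normal((1, 64))
        enc.forward(x)
        dx = enc.backward(w)
        eps = 1e-6
        for (i, j) in [(5, 9), (30, 40), (60, 3)]:
            xp, xm = x.copy(), x.copy()
            xp[0, 0, i, j] += eps
            xm[0, 0, i, j] -= eps
            num = ((enc.forward(xp) * w).sum()
                   - (enc.forward(xm) * w).sum()) / (2 * eps)
            assert dx[0, 0, i, j] == pytest.approx(num, rel=1e-4, abs=1e-10)

    def test_forward_nan_free_across_seeds(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            model = SharedLatentModel(
                EncoderConfig(input_size=64, channels=(2, 2, 2, 2)),
                ClassifierConfig(), None, seed=seed)
            x = rng.random((1, 1, 64, 64), dtype=np.float32)
            z = model.encode(x, train=True)
            logits = model.classify(z, train=True)
            assert np.isfinite(z).all() and np.isfinite(logits).all()

    def test_shape_mismatch_rejected(self):
        model = SharedLatentModel(EncoderConfig(input_size=64),
                                  ClassifierConfig(), None, seed=0)
        with pytest.raises(ValueError):
            model.encode(np.zeros((2, 1, 32, 32), dtype=np.float32))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(latent_dim=1)
        with pytest.raises(ValueError):
            EncoderConfig(dropout=1.0)
        with pytest.raises(ValueError):
            EncoderConfig(backbone="resnet")


@pytest.fixture(scope="module")
def decoder():
    cfg = DecoderConfig(steps=6, embed_dim=16, hidden=8, vocab_size=11,
                        dropout=0.0)
    return BiLSTMDecoder(cfg, latent_dim=4, seed=5, dtype=np.float64)


class TestDecoder:
    def test_output_rows_are_distributions(self, decoder):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((3, 4))
        ids = rng.integers(0, 11, (3, 6))
        probs = decoder.forward(z, ids)
        assert probs.shape == (3, 6, 11)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_latent_conditioning_is_live(self, decoder):
        rng = np.random.default_rng(1)
        ids = rng.integers(0, 11, (1, 6))
        p1 = decoder.forward(rng.standard_normal((1, 4)), ids)
        p2 = decoder.forward(rng.standard_normal((1, 4)), ids)
        assert not np.allclose(p1, p2)

    def test_steps_fixed_regardless_of_report_length(self):
        cfg = DecoderConfig(steps=40, embed_dim=8, hidden=4, vocab_size=5,
                            dropout=0.0)
        dec = BiLSTMDecoder(cfg, latent_dim=3, seed=0, dtype=np.float64)
        ids = np.zeros((2, 40), dtype=int)   # mostly PAD
        ids[:, :3] = 1
        assert dec.forward(np.zeros((2, 3)), ids).shape == (2, 40, 5)

    def test_teacher_length_mismatch_rejected(self, decoder):
        with pytest.raises(ValueError):
            decoder.forward(np.zeros((1, 4)), np.zeros((1, 3), dtype=int))

    def test_latent_dim_mismatch_rejected(self, decoder):
        with pytest.raises(ValueError):
            decoder.forward(np.zeros((1, 9)), np.zeros((1, 6), dtype=int))

    def test_vocab_too_small_rejected(self):
        with pytest.raises(ValueError):
            BiLSTMDecoder(DecoderConfig(steps=3, vocab_size=0), 4, 0)

    def test_glove_initialized_embeddings_are_used(self):
        cfg = DecoderConfig(steps=3, embed_dim=4, hidden=4, vocab_size=6)
        emb = np.arange(24, dtype=float).reshape(6, 4)
        dec = BiLSTMDecoder(cfg, latent_dim=2, seed=0, embeddings=emb)
        np.testing.assert_allclose(dec.params["E"], emb)
        with pytest.raises(ValueError):
            BiLSTMDecoder(cfg, latent_dim=2, seed=0,
                          embeddings=np.zeros((5, 4)))


class TestClassifier:
    def test_shape_contract(self):
        cls = build_classifier(ClassifierConfig(), 64, seed=0)
        out = cls.forward(np.zeros((8, 64), dtype=np.float32))
        assert out.shape == (8, 7)

    def test_zero_weights_give_bias_logits(self):
        cls = build_classifier(ClassifierConfig(), 64, seed=0)
        for _, layer, pname in cls.parameters():
            if pname == "W":
                layer.params[pname][:] = 0
            else:
                layer.params[pname][:] = 0.25
        out = cls.forward(np.random.default_rng(0).random((3, 64)))
        np.testing.assert_allclose(out, 0.25, atol=1e-6)

    def test_two_layer_structure(self):
        cls = build_classifier(ClassifierConfig(), 64, seed=0)
        dense = [l for l in cls.layers if l.params]
        assert len(dense) == 2


@pytest.fixture(scope="module")
def predict_model():
    return SharedLatentModel(EncoderConfig(input_size=64),
                             ClassifierConfig(), None, seed=3)


class TestPredict:

    def test_probabilities_normalized(self, predict_model):
        img = np.random.default_rng(0).random((64, 64), dtype=np.float32)
        p = predict(img, predict_model)
        assert p.shape == (7,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_logits_give_uniform_probabilities(self, predict_model):
        for _, layer, pname in predict_model.classifier.parameters():
            layer.params[pname][:] = 0
        img = np.random.default_rng(1).random((64, 64), dtype=np.float32)
        np.testing.assert_allclose(predict(img, predict_model), 1 / 7, atol=1e-6)

    def test_resize_and_rescale(self, predict_model):
        img = (np.random.default_rng(2).random((100, 90)) * 255).astype(np.uint8)
        x = prepare_images(img, predict_model.enc_cfg)
        assert x.shape == (1, 1, 64, 64)
        assert x.max() <= 1.0


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        cfg = DecoderConfig(steps=5, embed_dim=8, hidden=4, vocab_size=9)
        model = SharedLatentModel(EncoderConfig(input_size=64),
                                  ClassifierConfig(), cfg, seed=7)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = SharedLatentModel.load(path)
        img = np.random.default_rng(3).random((2, 1, 64, 64), dtype=np.float32)
        np.testing.assert_array_equal(model.predict_proba(img),
                                      back.predict_proba(img))
        assert back.dec_cfg.steps == 5
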