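"""Head architectures, the fine-tuning loop, and experiment bookkeeping."""

import numpy as np
import pytest

from medbert.evaluate import evaluate_auc
from medbert.finetune import (
    CompatibilityError,
    DegenerateLabelError,
    FinetuneConfig,
    SequenceBatch,
    attach_head,
    finetune,
)
from medbert.heads import head_logit, init_head_params
from medbert.model import MedBERT, ModelConfig
from medbert.nn import Tensor

DESK = ModelConfig(
    vocab_size=50, n_layers=1, hidden=8, n_heads=2, filter_size=16, max_len=16,
    dropout=0.0, seed=1,
)


def toy_batch(n=40, T=10, vocab=50, seed=0, signal_code=7):
    """Labels depend on the presence of one code — linearly separable."""
    rng = np.random.default_rng(seed)
    code = rng.integers(3, vocab, size=(n, T))
    mask = np.ones((n, T))
    labels = rng.integers(0, 2, size=n)
    for i in range(n):
        if labels[i]:
            code[i, rng.integers(T)] = signal_code
        else:
            code[i][code[i] == signal_code] = 3
    ser = np.tile(np.arange(1, T + 1), (n, 1))
    vis = np.ones((n, T), dtype=int)
    return SequenceBatch(
        ids=[f"t{i}" for i in range(n)], code=code, ser=ser, vis=vis,
        mask=mask.astype(float), labels=labels,
    )


class TestHeadAlgebra:
    def test_gru_roll_matches_straight_line_oracle(self):
        rng = np.random.default_rng(0)
        H, B, T = 4, 3, 5
        params = init_head_params("gru", H, rng)
        x = rng.standard_normal((B, T, H))
        mask = np.array([[1, 1, 1, 1, 1], [1, 1, 1, 0, 0], [1, 0, 0, 0, 0]], dtype=float)
        z = head_logit("gru", params, Tensor(x), mask)

        P = {k: v.data for k, v in params.items()}

        def sig(a):
            return 1 / (1 + np.exp(-a))

        expected = []
        for b in range(B):
            h = np.zeros(H)
            for t in range(T):
                if mask[b, t] == 0:
                    continue
                zt = sig(x[b, t] @ P["fw_Wz"] + h @ P["fw_Uz"] + P["fw_bz"])
                rt = sig(x[b, t] @ P["fw_Wr"] + h @ P["fw_Ur"] + P["fw_br"])
                cand = np.tanh(x[b, t] @ P["fw_Wh"] + (rt * h) @ P["fw_Uh"] + P["fw_bh"])
                h = (1 - zt) * h + zt * cand
            expected.append((h @ P["out_w"] + P["out_b"]).item())
        np.testing.assert_allclose(z.data, expected, atol=1e-10)

    def test_bigru_concatenates_two_state_widths(self):
        rng = np.random.default_rng(0)
        H = 6
        params = init_head_params("bigru", H, rng)
        assert params["out_w"].shape == (2 * H, 1)
        assert init_head_params("gru", H, rng)["out_w"].shape == (H, 1)

    def test_retain_attention_sums_to_one_over_real_positions(self):
        rng = np.random.default_rng(1)
        H, B, T = 4, 2, 6
        params = init_head_params("retain", H, rng)
        x = Tensor(rng.standard_normal((B, T, H)))
        mask = np.array([[1, 1, 1, 0, 0, 0], [1, 1, 1, 1, 1, 1]], dtype=float)
        z = head_logit("retain", params, x, mask)
        assert z.shape == (B,)
        # PAD positions cannot influence the context: perturb them
        x2 = x.data.copy()
        x2[0, 3:] += 10.0
        z2 = head_logit("retain", params, Tensor(x2), mask)
        np.testing.assert_allclose(z.data[0], z2.data[0], atol=1e-8)

    def test_unknown_head_kind_rejected(self):
        with pytest.raises(ValueError):
            init_head_params("cnn", 4, np.random.default_rng(0))


class TestAttachHead:
    def test_pretrained_vs_random_same_architecture_different_weights(self):
        ckpt = MedBERT(DESK, vocab_hash="h1")
        cfg_p = FinetuneConfig(head="gru", init="pretrained", seed=4)
        cfg_r = FinetuneConfig(head="gru", init="random", seed=4)
        pred_p = attach_head(ckpt, "gru", cfg_p)
        pred_r = attach_head(ckpt, "gru", cfg_r)
        assert set(pred_p.model.params) == set(pred_r.model.params)
        for k in pred_p.model.params:
            assert pred_p.model.params[k].shape == pred_r.model.params[k].shape
        assert pred_p.checksum() != pred_r.checksum()

    def test_pretrained_clone_never_mutates_checkpoint(self):
        ckpt = MedBERT(DESK, vocab_hash="h1")
        before = {k: p.data.copy() for k, p in ckpt.params.items()}
        cfg = FinetuneConfig(head="ffl", learning_rate=1e-2, max_epochs=2, seed=0)
        pred = attach_head(ckpt, "ffl", cfg)
        batch = toy_batch()
        finetune(pred, batch, batch, cfg)
        for k in before:
            np.testing.assert_array_equal(ckpt.params[k].data, before[k])

    def test_vocab_hash_mismatch_raises(self):
        ckpt = MedBERT(DESK, vocab_hash="h1")
        with pytest.raises(CompatibilityError):
            attach_head(ckpt, "ffl", FinetuneConfig(), vocab_hash="other")

    def test_frozen_encoder_gradients_are_zero(self):
        ckpt = MedBERT(DESK, vocab_hash="h1")
        cfg = FinetuneConfig(head="ffl", freeze_encoder=True, seed=0)
        pred = attach_head(ckpt, "ffl", cfg)
        batch = toy_batch(n=8)
        z = pred.score(batch, training=True)
        loss = (z.softplus() - z * batch.labels.astype(float)).mean()
        loss.backward()
        assert all(p.grad is None for p in pred.model.params.values())
        assert all(p.grad is not None for p in pred.head_params.values())
        assert "emb/code" not in pred.trainable_params()


class TestFinetuneLoop:
    def test_single_class_training_set_raises(self):
        batch = toy_batch()
        ones = batch.take(np.nonzero(batch.labels == 1)[0])
        cfg = FinetuneConfig(head="ffl", seed=0)
        pred = attach_head(MedBERT(DESK), "ffl", cfg)
        with pytest.raises(DegenerateLabelError):
            finetune(pred, ones, batch, cfg)

    def test_same_seed_identical_final_weights(self):
        batch = toy_batch()
        cfg = FinetuneConfig(head="gru", init="random", learning_rate=1e-2,
                             max_epochs=3, seed=9)
        sums = []
        for _ in range(2):
            pred = attach_head(MedBERT(DESK, vocab_hash=""), "gru", cfg, encoder_mode="embeddings")
            pred, hist = finetune(pred, batch, batch, cfg)
            sums.append(pred.checksum())
        assert sums[0] == sums[1]

    def test_learns_separable_toy_task_above_chance(self):
        train, valid = toy_batch(n=120, seed=1), toy_batch(n=60, seed=2)
        cfg = FinetuneConfig(head="ffl", init="random", learning_rate=3e-3,
                             max_epochs=40, patience=12, seed=0)
        pred = attach_head(MedBERT(DESK), "ffl", cfg, encoder_mode="embeddings")
        pred, hist = finetune(pred, train, valid, cfg)
        assert max(hist) > 0.85  # one-code signal is nearly separable

    def test_early_stopping_restores_best_epoch(self):
        train, valid = toy_batch(n=60, seed=3), toy_batch(n=40, seed=4)
        cfg = FinetuneConfig(head="ffl", init="random", learning_rate=1e-2,
                             max_epochs=10, patience=2, seed=0)
        pred = attach_head(MedBERT(DESK), "ffl", cfg, encoder_mode="embeddings")
        pred, hist = finetune(pred, train, valid, cfg)
        final = evaluate_auc(pred.predict_proba(valid), valid.labels)
        assert final == pytest.approx(max(hist), abs=1e-9)


class TestStaticMode:
    def test_static_lookup_is_context_independent(self):
        rng = np.random.default_rng(0)
        static = rng.standard_normal((50, 8))
        cfg = FinetuneConfig(head="gru", init="random", seed=0)
        pred = attach_head(None, "gru", cfg, encoder_mode="static", static_matrix=static)
        b = toy_batch(n=2, T=4)
        b.code[0] = [5, 5, 9, 5]
        x = pred._positions(b.trimmed(), False, None).data
        np.testing.assert_array_equal(x[0, 0], x[0, 1])
        np.testing.assert_array_equal(x[0, 0], x[0, 3])
        assert pred.trainable_params().keys() == {
            f"head/{k}" for k in pred.head_params
        }
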