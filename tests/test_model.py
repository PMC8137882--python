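"""Encoder correctness: embedding sums, an independent straight-line
attention oracle, masking invariances, head algebra and parameter counts."""

import numpy as np
import pytest

from medbert.model import (
    MedBERT,
    ModelConfig,
    count_parameters,
    parameter_shapes,
)

TINY = ModelConfig(
    vocab_size=10, n_layers=1, hidden=4, n_heads=1, filter_size=2, max_len=8,
    dropout=0.0, seed=3,
)


def batch_of(config, code, ser, vis, mask):
    return (
        np.asarray(code),
        np.asarray(ser),
        np.asarray(vis),
        np.asarray(mask, dtype=float),
    )


# ---------------------------------------------------------------------------
# straight-line reference implementation of one post-norm encoder layer
# ---------------------------------------------------------------------------

def _ln(x, g, b, eps=1e-12):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def _gelu(x):
    return 0.5 * x * (1 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x**3)))


def reference_layer(x, mask, P, prefix, n_heads):
    """Scaled dot-product attention + FFN, written independently, no batching
    tricks: explicit per-head loops."""
    B, T, H = x.shape
    dh = H // n_heads
    out_ctx = np.zeros_like(x)
    for b in range(B):
        q = x[b] @ P[f"{prefix}/attn_q_w"] + P[f"{prefix}/attn_q_b"]
        k = x[b] @ P[f"{prefix}/attn_k_w"] + P[f"{prefix}/attn_k_b"]
        v = x[b] @ P[f"{prefix}/attn_v_w"] + P[f"{prefix}/attn_v_b"]
        heads = []
        for h in range(n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            scores = q[:, sl] @ k[:, sl].T / np.sqrt(dh)
            scores = scores + (1 - mask[b])[None, :] * -1e9
            w = np.exp(scores - scores.max(-1, keepdims=True))
            w = w / w.sum(-1, keepdims=True)
            heads.append(w @ v[:, sl])
        ctx = np.concatenate(heads, axis=-1)
        out_ctx[b] = ctx @ P[f"{prefix}/attn_o_w"] + P[f"{prefix}/attn_o_b"]
    x = _ln(x + out_ctx, P[f"{prefix}/ln1_gain"], P[f"{prefix}/ln1_bias"])
    h = _gelu(x @ P[f"{prefix}/ffn_w1"] + P[f"{prefix}/ffn_b1"])
    h = h @ P[f"{prefix}/ffn_w2"] + P[f"{prefix}/ffn_b2"]
    return _ln(x + h, P[f"{prefix}/ln2_gain"], P[f"{prefix}/ln2_bias"])


class TestEmbedding:
    def test_sum_of_three_tables_single_position(self):
        model = MedBERT(TINY)
        code, ser, vis = np.array([[4]]), np.array([[2]]), np.array([[1]])
        x = model.embed_inputs(code, ser, vis)
        P = {k: p.data for k, p in model.params.items()}
        raw = P["emb/code"][4] + P["emb/serialization"][1] + P["emb/visit"][0]
        expected = _ln(raw[None, None], P["emb/ln_gain"], P["emb/ln_bias"])
        np.testing.assert_allclose(x.data, expected, atol=1e-12)

    def test_identical_index_triples_give_identical_vectors(self):
        model = MedBERT(TINY)
        code = np.array([[4, 4], [4, 5]])
        ser = np.array([[2, 2], [2, 2]])
        vis = np.array([[1, 1], [1, 1]])
        x = model.embed_inputs(code, ser, vis).data
        np.testing.assert_allclose(x[0, 0], x[0, 1])
        assert not np.allclose(x[1, 0], x[1, 1])

    def test_out_of_range_code_raises(self):
        model = MedBERT(TINY)
        with pytest.raises(ValueError):
            model.embed_inputs(np.array([[99]]), np.array([[1]]), np.array([[1]]))


class TestEncoder:
    def test_zero_layers_is_identity(self):
        cfg = ModelConfig(vocab_size=10, n_layers=0, hidden=4, n_heads=1,
                          filter_size=2, max_len=8, dropout=0.0)
        model = MedBERT(cfg)
        x = model.embed_inputs(np.array([[3, 4]]), np.array([[1, 2]]), np.array([[1, 1]]))
        out = model.encode(x, np.ones((1, 2)))
        np.testing.assert_allclose(out.hidden_states.data, x.data)

    def test_matches_straight_line_oracle(self):
        cfg = ModelConfig(vocab_size=12, n_layers=2, hidden=6, n_heads=2,
                          filter_size=5, max_len=8, dropout=0.0, seed=7)
        model = MedBERT(cfg)
        rng = np.random.default_rng(0)
        code = rng.integers(3, 12, size=(3, 4))
        mask = np.array([[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0]], dtype=float)
        ser = np.tile(np.arange(1, 5), (3, 1))
        vis = np.ones((3, 4), dtype=int)
        x = model.embed_inputs(code, ser, vis)
        out = model.encode(x, mask)
        P = {k: p.data for k, p in model.params.items()}
        ref = x.data.copy()
        for l in range(cfg.n_layers):
            ref = reference_layer(ref, mask, P, f"layer{l}", cfg.n_heads)
        # compare real positions only (PAD rows attend to garbage by design)
        for b in range(3):
            n = int(mask[b].sum())
            np.testing.assert_allclose(out.hidden_states.data[b, :n], ref[b, :n], atol=1e-5)

    def test_attention_rows_normalized_and_pad_excluded(self):
        model = MedBERT(TINY)
        code = np.array([[3, 4, 5, 0]])
        mask = np.array([[1, 1, 1, 0]], dtype=float)
        x = model.embed_inputs(code, np.array([[1, 2, 3, 0]]), np.array([[1, 1, 1, 0]]))
        out = model.encode(x, mask, collect_attention=True)
        attn = out.attention_maps[0][0, 0]  # (T, T)
        np.testing.assert_allclose(attn[:3].sum(-1), 1.0, atol=1e-5)
        np.testing.assert_allclose(attn[:3, 3], 0.0, atol=1e-9)

    def test_pad_content_cannot_leak_into_real_outputs(self):
        model = MedBERT(TINY)
        mask = np.array([[1, 1, 0, 0]], dtype=float)
        ser = np.array([[1, 2, 0, 0]])
        vis = np.array([[1, 1, 0, 0]])
        a = model.forward(np.array([[3, 4, 0, 0]]), ser, vis, mask)
        b = model.forward(np.array([[3, 4, 7, 9]]), ser, vis, mask)
        z_a = model.sequence_logit_ffl(a, mask)
        z_b = model.sequence_logit_ffl(b, mask)
        np.testing.assert_allclose(
            a.hidden_states.data[0, :2], b.hidden_states.data[0, :2], atol=1e-10
        )
        np.testing.assert_allclose(z_a.data, z_b.data, atol=1e-10)

    def test_forward_bit_reproducible_without_dropout(self):
        out = []
        for _ in range(2):
            model = MedBERT(TINY)
            o = model.forward(
                np.array([[3, 4, 5]]), np.array([[1, 2, 3]]), np.array([[1, 1, 2]]),
                np.ones((1, 3)),
            )
            out.append(o.hidden_states.data)
        assert (out[0] == out[1]).all()

    def test_mask_shape_mismatch_raises(self):
        model = MedBERT(TINY)
        x = model.embed_inputs(np.array([[3, 4]]), np.array([[1, 2]]), np.array([[1, 1]]))
        with pytest.raises(ValueError):
            model.encode(x, np.ones((1, 5)))


class TestHeads:
    def test_mlm_zero_hidden_uniform_softmax(self):
        from medbert.model import EncoderOutput
        from medbert.nn import Tensor, softmax

        model = MedBERT(TINY)
        model.params["mlm/dense_w"].data[:] = 0.0
        model.params["mlm/out_bias"].data[:] = 0.0
        out = EncoderOutput(Tensor(np.zeros((1, 2, 4))), None)
        logits = model.mlm_logits(out)
        probs = softmax(logits, axis=-1).data
        np.testing.assert_allclose(probs, 1.0 / TINY.vocab_size, atol=1e-12)
        assert logits.data.shape == (1, 2, TINY.vocab_size)

    def test_tied_projection_row_perturbation_moves_matching_column(self):
        from medbert.model import EncoderOutput
        from medbert.nn import Tensor

        model = MedBERT(TINY)
        hidden = Tensor(np.random.default_rng(1).standard_normal((1, 2, 4)))
        before = model.mlm_logits(EncoderOutput(hidden, None)).data.copy()
        # a single-element nudge: a whole-row constant shift would be invisible
        # through the zero-mean layer-normed hidden state
        model.params["emb/code"].data[7, 0] += 0.5
        after = model.mlm_logits(EncoderOutput(hidden, None)).data
        changed = np.nonzero(np.abs(after - before).sum(axis=(0, 1)) > 1e-12)[0]
        assert changed.tolist() == [7]

    def test_ffl_matches_hand_computed_chain(self):
        from medbert.model import EncoderOutput
        from medbert.nn import Tensor

        model = MedBERT(TINY)
        rng = np.random.default_rng(5)
        h = rng.standard_normal((1, 3, 4))
        mask = np.ones((1, 3))
        z = model.sequence_logit_ffl(EncoderOutput(Tensor(h), None), mask)
        P = {k: p.data for k, p in model.params.items()}
        pooled = h.sum(axis=1)
        expected = np.tanh(pooled @ P["seq/ffl_w1"] + P["seq/ffl_b1"]) @ P["seq/ffl_w2"] + P["seq/ffl_b2"]
        np.testing.assert_allclose(z.data, expected.ravel(), atol=1e-12)

    def test_ffl_pad_tail_does_not_change_score(self):
        from medbert.model import EncoderOutput
        from medbert.nn import Tensor

        model = MedBERT(TINY)
        rng = np.random.default_rng(6)
        h3 = rng.standard_normal((1, 3, 4))
        h6 = np.concatenate([h3, rng.standard_normal((1, 3, 4))], axis=1)
        z3 = model.sequence_logit_ffl(EncoderOutput(Tensor(h3), None), np.ones((1, 3)))
        mask6 = np.array([[1, 1, 1, 0, 0, 0]], dtype=float)
        z6 = model.sequence_logit_ffl(EncoderOutput(Tensor(h6), None), mask6)
        np.testing.assert_allclose(z3.data, z6.data, atol=1e-12)

    def test_all_pad_sequence_logit_raises(self):
        from medbert.model import EncoderOutput
        from medbert.nn import Tensor

        model = MedBERT(TINY)
        with pytest.raises(ValueError):
            model.sequence_logit_ffl(
                EncoderOutput(Tensor(np.zeros((1, 3, 4))), None), np.zeros((1, 3))
            )

    def test_mlm_logits_at_equals_full_logits_gather(self, prepared):
        from medbert.model import EncoderOutput
        from medbert.nn import Tensor

        model = MedBERT(TINY)
        h = Tensor(np.random.default_rng(2).standard_normal((2, 5, 4)))
        out = EncoderOutput(h, None)
        pos = np.array([1, 4])
        full = model.mlm_logits(out).data[np.arange(2), pos]
        at = model.mlm_logits_at(out, pos).data
        np.testing.assert_allclose(at, full, atol=1e-12)


class TestParameterCount:
    def test_tiny_config_formula_equals_enumeration(self):
        cfg = ModelConfig(vocab_size=10, n_layers=1, hidden=4, n_heads=1,
                          filter_size=2, max_len=8, dropout=0.0)
        assert count_parameters(cfg) == MedBERT(cfg).parameter_count()

    def test_vocab_growth_adds_row_plus_bias(self):
        base = ModelConfig(vocab_size=100, n_layers=1, hidden=4, n_heads=1,
                           filter_size=2, max_len=8)
        bigger = ModelConfig(vocab_size=150, n_layers=1, hidden=4, n_heads=1,
                             filter_size=2, max_len=8)
        # each extra code contributes one embedding row (tied head) + one bias
        assert count_parameters(bigger) - count_parameters(base) == 50 * 4 + 50

    def test_shapes_cover_all_modules(self):
        shapes = parameter_shapes(ModelConfig(vocab_size=10))
        prefixes = {k.split("/")[0] for k in shapes}
        assert prefixes == {"emb", "mlm", "seq"} | {f"layer{l}" for l in range(6)}


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = MedBERT(TINY, vocab_hash="abc123")
        model.save(tmp_path / "ckpt")
        again = MedBERT.load(tmp_path / "ckpt")
        for k in model.params:
            np.testing.assert_array_equal(model.params[k].data, again.params[k].data)
        assert again.vocab_hash == "abc123"

    def test_hash_mismatch_rejected(self, tmp_path):
        model = MedBERT(TINY, vocab_hash="abc123")
        model.save(tmp_path / "ckpt")
        with pytest.raises(ValueError):
            MedBERT.load(tmp_path / "ckpt", expect_vocab_hash="zzz")
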