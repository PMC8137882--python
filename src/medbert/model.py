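"""The Med-BERT network.

Three embedding tables — code, serialization (within-visit position) and
visit ordinal — are summed per position, layer-normalized and fed to a
bidirectional transformer encoder (post-layer-norm, GELU, the original BERT
recipe).  There are no [CLS]/[SEP] rows anywhere: visit embeddings separate
visits, and sequence-level classification pools by *summing the final-layer
vectors over all real positions* before a small feed-forward layer (FFL)
produces a scalar logit.  The masked-code head is the BERT head: dense +
GELU + layer norm, then a projection tied to the code embedding table plus
an output bias.

Published architecture: L=6 layers, hidden H=192, A=6 attention heads,
feed-forward (filter) width 64, maximum sequence length 512 — about 17
million trainable parameters at the full ICD-9+ICD-10 vocabulary.  Desk-
scale experiments in this package use a smaller configuration; the published
one is kept as the default :class:`ModelConfig`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Tensor, layer_norm, softmax, take
from .nn.optim import truncated_normal

NEG_INF = -1e9


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (symbols: L layers, H hidden, A heads)."""

    vocab_size: int
    n_layers: int = 6
    hidden: int = 192
    n_heads: int = 6
    filter_size: int = 64
    max_len: int = 512
    dropout: float = 0.1
    ffl_hidden: int | None = None  # sequence-head width; defaults to hidden
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads != 0:
            raise ValueError("hidden must be divisible by n_heads")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.hidden // self.n_heads

    @property
    def ffl_width(self) -> int:
        return self.ffl_hidden if self.ffl_hidden is not None else self.hidden


@dataclass
class EncoderOutput:
    """Final-layer hidden states and (optionally) per-layer attention maps."""

    hidden_states: Tensor                    # (B, T, H)
    attention_maps: list[np.ndarray] | None  # L arrays of (B, A, T, T)


def parameter_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    """Names and shapes of every trainable array, in a stable order."""
    V, H, F, T = config.vocab_size, config.hidden, config.filter_size, config.max_len
    shapes: dict[str, tuple[int, ...]] = {
        "emb/code": (V, H),
        "emb/serialization": (T, H),
        "emb/visit": (T, H),
        "emb/ln_gain": (H,),
        "emb/ln_bias": (H,),
    }
    for l in range(config.n_layers):
        p = f"layer{l}"
        for name in ("q", "k", "v", "o"):
            shapes[f"{p}/attn_{name}_w"] = (H, H)
            shapes[f"{p}/attn_{name}_b"] = (H,)
        shapes[f"{p}/ln1_gain"] = (H,)
        shapes[f"{p}/ln1_bias"] = (H,)
        shapes[f"{p}/ffn_w1"] = (H, F)
        shapes[f"{p}/ffn_b1"] = (F,)
        shapes[f"{p}/ffn_w2"] = (F, H)
        shapes[f"{p}/ffn_b2"] = (H,)
        shapes[f"{p}/ln2_gain"] = (H,)
        shapes[f"{p}/ln2_bias"] = (H,)
    shapes["mlm/dense_w"] = (H, H)
    shapes["mlm/dense_b"] = (H,)
    shapes["mlm/ln_gain"] = (H,)
    shapes["mlm/ln_bias"] = (H,)
    shapes["mlm/out_bias"] = (V,)  # projection itself is tied to emb/code
    W = config.ffl_width
    shapes["seq/ffl_w1"] = (H, W)
    shapes["seq/ffl_b1"] = (W,)
    shapes["seq/ffl_w2"] = (W, 1)
    shapes["seq/ffl_b2"] = (1,)
    return shapes


def count_parameters(config: ModelConfig) -> int:
    """Exact number of trainable scalars for a configuration."""
    return int(sum(int(np.prod(s)) for s in parameter_shapes(config).values()))


class MedBERT:
    """Encoder plus pretraining heads, with explicit seedable initialization."""

    def __init__(self, config: ModelConfig, vocab_hash: str = ""):
        self.config = config
        self.vocab_hash = vocab_hash
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        for name, shape in parameter_shapes(config).items():
            if name.endswith(("_gain",)):
                data = np.ones(shape)
            elif name.endswith(("_b", "_bias")):
                data = np.zeros(shape)
            else:
                data = truncated_normal(shape, rng)
            self.params[name] = Tensor(data, requires_grad=True)

    # -- utilities ------------------------------------------------------------
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def _dropout(self, x: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * keep

    # -- forward pieces -------------------------------------------------------
    def embed_inputs(
        self,
        code_ids: np.ndarray,
        serialization_ids: np.ndarray,
        visit_ids: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Sum of the three embeddings, layer-normalized, with dropout.

        Serialization and visit ids are 1-based; the tables have ``max_len``
        rows so the lookup index is ``id - 1`` clamped into range (PAD
        positions reuse row 0 — their output is never attended to or pooled).
        """
        T = self.config.max_len
        ser_idx = np.clip(serialization_ids - 1, 0, T - 1)
        vis_idx = np.clip(visit_ids - 1, 0, T - 1)
        if code_ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("code id out of vocabulary range")
        x = (
            take(self.params["emb/code"], code_ids)
            + take(self.params["emb/serialization"], ser_idx)
            + take(self.params["emb/visit"], vis_idx)
        )
        x = layer_norm(x, self.params["emb/ln_gain"], self.params["emb/ln_bias"])
        return self._dropout(x, training, rng)

    def encode(
        self,
        embedded: Tensor,
        attention_mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> EncoderOutput:
        """Run the transformer stack over embedded inputs.

        PAD positions are excluded with an additive mask on the attention
        scores; their value rows therefore never contribute to real
        positions.
        """
        B, T, H = embedded.shape
        if attention_mask.shape != (B, T):
            raise ValueError(
                f"attention mask shape {attention_mask.shape} does not match inputs {(B, T)}"
            )
        A, dh = self.config.n_heads, self.config.head_dim
        add_mask = (1.0 - attention_mask[:, None, None, :]) * NEG_INF  # (B,1,1,T)
        x = embedded
        maps: list[np.ndarray] = []
        for l in range(self.config.n_layers):
            p = f"layer{l}"

            def proj(name: str) -> Tensor:
                h = x @ self.params[f"{p}/attn_{name}_w"] + self.params[f"{p}/attn_{name}_b"]
                return h.reshape(B, T, A, dh).swapaxes(1, 2)  # (B,A,T,dh)

            q, k, v = proj("q"), proj("k"), proj("v")
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh)) + add_mask
            attn = softmax(scores, axis=-1)
            if collect_attention:
                maps.append(attn.data.copy())
            attn = self._dropout(attn, training, rng)
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, T, H)
            ctx = ctx @ self.params[f"{p}/attn_o_w"] + self.params[f"{p}/attn_o_b"]
            ctx = self._dropout(ctx, training, rng)
            x = layer_norm(x + ctx, self.params[f"{p}/ln1_gain"], self.params[f"{p}/ln1_bias"])
            h = (x @ self.params[f"{p}/ffn_w1"] + self.params[f"{p}/ffn_b1"]).gelu()
            h = h @ self.params[f"{p}/ffn_w2"] + self.params[f"{p}/ffn_b2"]
            h = self._dropout(h, training, rng)
            x = layer_norm(x + h, self.params[f"{p}/ln2_gain"], self.params[f"{p}/ln2_bias"])
        return EncoderOutput(hidden_states=x, attention_maps=maps if collect_attention else None)

    def mlm_logits(self, output: EncoderOutput) -> Tensor:
        """Per-position scores over the vocabulary, tied to the code table."""
        h = (output.hidden_states @ self.params["mlm/dense_w"] + self.params["mlm/dense_b"]).gelu()
        h = layer_norm(h, self.params["mlm/ln_gain"], self.params["mlm/ln_bias"])
        return h @ self.params["emb/code"].swapaxes(0, 1) + self.params["mlm/out_bias"]

    def mlm_logits_at(self, output: EncoderOutput, positions: np.ndarray) -> Tensor:
        """Vocabulary scores at one supervised position per sequence (B, V).

        Equivalent to gathering rows of :meth:`mlm_logits`, but avoids
        materializing the full (B, T, V) score block during training.
        """
        B = output.hidden_states.shape[0]
        h = output.hidden_states[np.arange(B), np.asarray(positions)]
        h = (h @ self.params["mlm/dense_w"] + self.params["mlm/dense_b"]).gelu()
        h = layer_norm(h, self.params["mlm/ln_gain"], self.params["mlm/ln_bias"])
        return h @ self.params["emb/code"].swapaxes(0, 1) + self.params["mlm/out_bias"]

    def sequence_logit_ffl(self, output: EncoderOutput, attention_mask: np.ndarray) -> Tensor:
        """Scalar sequence logit: sum over real positions → FFL → affine.

        Raises ``ValueError`` on an all-PAD row: there is nothing to pool.
        """
        if (attention_mask.sum(axis=-1) == 0).any():
            raise ValueError("sequence pooling is undefined for an all-PAD sequence")
        pooled = (output.hidden_states * attention_mask[:, :, None]).sum(axis=1)  # (B,H)
        h = (pooled @ self.params["seq/ffl_w1"] + self.params["seq/ffl_b1"]).tanh()
        return (h @ self.params["seq/ffl_w2"] + self.params["seq/ffl_b2"]).reshape(-1)

    def forward(
        self,
        code_ids: np.ndarray,
        serialization_ids: np.ndarray,
        visit_ids: np.ndarray,
        attention_mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> EncoderOutput:
        x = self.embed_inputs(code_ids, serialization_ids, visit_ids, training, rng)
        return self.encode(x, attention_mask, training, rng, collect_attention)

    # -- checkpointing --------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **{k: p.data for k, p in self.params.items()})
        sidecar = {"config": asdict(self.config), "vocab_hash": self.vocab_hash}
        (d / "config.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path, expect_vocab_hash: str | None = None) -> "MedBERT":
        d = Path(directory)
        sidecar = json.loads((d / "config.json").read_text())
        if expect_vocab_hash is not None and sidecar["vocab_hash"] != expect_vocab_hash:
            raise ValueError(
                "vocabulary hash mismatch: checkpoint was built for a different vocabulary"
            )
        model = cls(ModelConfig(**sidecar["config"]), sidecar["vocab_hash"])
        with np.load(d / "weights.npz") as z:
            for k in model.params:
                model.params[k].data = z[k].astype(np.float64)
        return model

    def clone(self) -> "MedBERT":
        other = MedBERT.__new__(MedBERT)
        other.config = self.config
        other.vocab_hash = self.vocab_hash
        other.params = {k: Tensor(p.data.copy(), requires_grad=True) for k, p in self.params.items()}
        return other


__all__ = [
    "ModelConfig",
    "EncoderOutput",
    "MedBERT",
    "parameter_shapes",
    "count_parameters",
    "NEG_INF",
]
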