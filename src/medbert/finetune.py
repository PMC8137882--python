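"""Fine-tuning: attach a prediction head on top of the encoder and update
all parameters jointly on a disease label.

A :class:`Predictor` couples an input representation with a head:

* ``encoder``    — the full transformer; initialized from a pretrained
  checkpoint or freshly at random (the untrained-architecture ablation).
* ``embeddings`` — the trainable multi-level embedding layer only (the
  "base model" condition for GRU/BiGRU/RETAIN).
* ``static``     — frozen context-independent code vectors (the skip-gram
  comparator); the head is the only trainable part besides nothing.

Training minimizes binary cross-entropy with AdamW, early-stopping on
validation AUC.  Deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .evaluate import evaluate_auc
from .heads import HEAD_KINDS, head_logit, init_head_params
from .model import MedBERT, ModelConfig
from .nn import Tensor
from .nn.optim import AdamW
from .tokenizer import TokenizedSequence


class DegenerateLabelError(ValueError):
    """Raised when a training split contains a single class."""


class CompatibilityError(ValueError):
    """Raised on vocabulary-hash mismatch between checkpoint and corpus."""


@dataclass(frozen=True)
class FinetuneConfig:
    head: str = "ffl"                 # ffl | gru | bigru | retain
    init: str = "pretrained"          # pretrained | random
    learning_rate: float = 1e-5       # published default; desk-scale runs override
    max_epochs: int = 20
    patience: int = 5                 # epochs without validation-AUC improvement
    batch_size: int = 32
    freeze_encoder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head not in HEAD_KINDS:
            raise ValueError(f"head must be one of {HEAD_KINDS}")
        if self.init not in ("pretrained", "random"):
            raise ValueError("init must be 'pretrained' or 'random'")


@dataclass
class SequenceBatch:
    """Stacked tokenized sequences plus labels, the unit the trainers consume."""

    ids: list[str]
    code: np.ndarray   # (N, T)
    ser: np.ndarray
    vis: np.ndarray
    mask: np.ndarray
    labels: np.ndarray  # (N,)

    @classmethod
    def from_sequences(cls, seqs: list[TokenizedSequence], labels) -> "SequenceBatch":
        return cls(
            ids=[s.patient_id for s in seqs],
            code=np.stack([s.code_ids for s in seqs]),
            ser=np.stack([s.serialization_ids for s in seqs]),
            vis=np.stack([s.visit_ids for s in seqs]),
            mask=np.stack([s.attention_mask for s in seqs]).astype(float),
            labels=np.asarray(labels, dtype=int),
        )

    def __len__(self) -> int:
        return len(self.ids)

    def take(self, idx) -> "SequenceBatch":
        idx = np.asarray(idx)
        return SequenceBatch(
            ids=[self.ids[i] for i in idx],
            code=self.code[idx],
            ser=self.ser[idx],
            vis=self.vis[idx],
            mask=self.mask[idx],
            labels=self.labels[idx],
        )

    def trimmed(self) -> "SequenceBatch":
        """Copy with the all-PAD tail shared by every row dropped."""
        width = max(1, int(self.mask.sum(axis=1).max()))
        return SequenceBatch(
            ids=self.ids,
            code=self.code[:, :width],
            ser=self.ser[:, :width],
            vis=self.vis[:, :width],
            mask=self.mask[:, :width],
            labels=self.labels,
        )

    def subset_by_ids(self, wanted) -> "SequenceBatch":
        pos = {pid: i for i, pid in enumerate(self.ids)}
        return self.take([pos[w] for w in wanted])


class Predictor:
    """Input representation + prediction head, trained jointly."""

    def __init__(
        self,
        head: str,
        model: MedBERT | None,
        head_params: dict[str, Tensor],
        encoder_mode: str = "encoder",
        static_matrix: np.ndarray | None = None,
        freeze_encoder: bool = False,
    ):
        if encoder_mode not in ("encoder", "embeddings", "static"):
            raise ValueError("encoder_mode must be encoder|embeddings|static")
        if encoder_mode == "static" and static_matrix is None:
            raise ValueError("static mode requires a static embedding matrix")
        self.head = head
        self.model = model
        self.head_params = head_params
        self.encoder_mode = encoder_mode
        self.static_matrix = static_matrix
        self.freeze_encoder = freeze_encoder
        if freeze_encoder and model is not None:
            for p in model.params.values():
                p.requires_grad = False

    def trainable_params(self) -> dict[str, Tensor]:
        params = {f"head/{k}": v for k, v in self.head_params.items()}
        if self.model is not None and not self.freeze_encoder:
            if self.encoder_mode == "encoder":
                params.update(self.model.params)
            else:  # embeddings-only condition: embedding tables + their norm
                params.update(
                    {k: v for k, v in self.model.params.items() if k.startswith("emb/")}
                )
        return params

    def _positions(self, batch: SequenceBatch, training: bool, rng) -> Tensor:
        if self.encoder_mode == "static":
            return Tensor(self.static_matrix[batch.code])
        assert self.model is not None
        if self.encoder_mode == "embeddings":
            return self.model.embed_inputs(batch.code, batch.ser, batch.vis, training, rng)
        out = self.model.forward(
            batch.code, batch.ser, batch.vis, batch.mask, training=training, rng=rng
        )
        return out.hidden_states

    def score(self, batch: SequenceBatch, training: bool = False, rng=None) -> Tensor:
        batch = batch.trimmed()
        x = self._positions(batch, training, rng)
        return head_logit(self.head, self.head_params, x, batch.mask)

    def predict_proba(self, batch: SequenceBatch, chunk: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(batch), chunk):
            z = self.score(batch.take(np.arange(i, min(i + chunk, len(batch)))))
            out.append(1.0 / (1.0 + np.exp(-z.data)))
        return np.concatenate(out)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.head_params):
            h.update(self.head_params[k].data.tobytes())
        if self.model is not None:
            for k in sorted(self.model.params):
                h.update(self.model.params[k].data.tobytes())
        return h.hexdigest()[:16]


def attach_head(
    source: MedBERT | ModelConfig,
    head: str,
    config: FinetuneConfig,
    encoder_mode: str = "encoder",
    static_matrix: np.ndarray | None = None,
    vocab_hash: str | None = None,
) -> Predictor:
    """Build a trainable predictor.

    ``source`` is a pretrained checkpoint when ``config.init == 'pretrained'``
    (cloned, so fine-tuning never mutates the checkpoint) or a
    :class:`ModelConfig` for the randomly initialized ablation.  The head is
    always freshly initialized from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 7919)
    if encoder_mode == "static":
        model = None
        hidden = static_matrix.shape[1]
    elif config.init == "pretrained":
        if not isinstance(source, MedBERT):
            raise ValueError("init='pretrained' requires a MedBERT checkpoint")
        if vocab_hash is not None and source.vocab_hash and source.vocab_hash != vocab_hash:
            raise CompatibilityError("checkpoint vocabulary hash does not match corpus")
        model = source.clone()
        hidden = model.config.hidden
    else:
        cfg = source.config if isinstance(source, MedBERT) else source
        model = MedBERT(replace(cfg, seed=int(rng.integers(2**31))))
        hidden = cfg.hidden
    head_params = init_head_params(head, hidden, rng)
    return Predictor(
        head,
        model,
        head_params,
        encoder_mode=encoder_mode,
        static_matrix=static_matrix,
        freeze_encoder=config.freeze_encoder,
    )


def finetune(
    predictor: Predictor,
    train: SequenceBatch,
    valid: SequenceBatch,
    config: FinetuneConfig,
) -> tuple[Predictor, list[float]]:
    """Fit on binary cross-entropy; returns (predictor at best validation AUC,
    per-epoch validation-AUC history)."""
    if len(set(train.labels.tolist())) < 2:
        raise DegenerateLabelError("training split has a single class")
    if len(set(valid.labels.tolist())) < 2:
        raise DegenerateLabelError(
            "validation split has a single class; AUC early stopping is undefined"
        )

    root = np.random.default_rng(config.seed)
    order_rng = np.random.default_rng(root.integers(2**31))
    drop_rng = np.random.default_rng(root.integers(2**31))

    params = predictor.trainable_params()
    # no warmup here: the schedule's slow start lets validation-AUC early
    # stopping fire before the model escapes its initial plateau
    opt = AdamW(params, lr=config.learning_rate, weight_decay=0.01, clip_norm=1.0)

    def snapshot():
        return {k: p.data.copy() for k, p in params.items()}

    best_auc, best_state, stale = -np.inf, snapshot(), 0
    history: list[float] = []
    for _epoch in range(config.max_epochs):
        order = order_rng.permutation(len(train))
        for i in range(0, len(order), config.batch_size):
            mb = train.take(order[i : i + config.batch_size])
            z = predictor.score(mb, training=True, rng=drop_rng)
            y = mb.labels.astype(float)
            loss = (z.softplus() - z * y).mean()
            for p in params.values():
                p.grad = None
            loss.backward()
            opt.step()
        val_auc = evaluate_auc(predictor.predict_proba(valid), valid.labels)
        history.append(val_auc)
        if val_auc > best_auc + 1e-9:
            best_auc, best_state, stale = val_auc, snapshot(), 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    for k, p in params.items():
        p.data = best_state[k]
    return predictor, history


__all__ = [
    "FinetuneConfig",
    "SequenceBatch",
    "Predictor",
    "attach_head",
    "finetune",
    "DegenerateLabelError",
    "CompatibilityError",
]
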