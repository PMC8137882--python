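"""Joint self-supervised pretraining: masked-code prediction plus
patient-level prolonged-LOS classification.

Each step draws a batch of patients, corrupts exactly one code per patient
(fresh target position every epoch), and combines the cross-entropy at the
supervised position with the binary cross-entropy of the sequence logit
against the prolonged-LOS label.  Optimization is AdamW at the recommended
learning rate of 5e-5 with dropout 0.1 and batch size 32, with linear
warmup over the first 10% of steps.  Early stopping watches the combined
validation loss.

All randomness flows from a single seed through named, independent streams
(data order / masking / dropout / evaluation), so two runs with the same
seed produce identical histories and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import UndefinedAUCError, evaluate_auc
from .masking import make_masked_example
from .model import MedBERT
from .nn import log_softmax
from .nn.optim import AdamW
from .tokenizer import TokenizedSequence


@dataclass(frozen=True)
class PretrainConfig:
    batch_size: int = 32
    learning_rate: float = 5e-5
    weight_decay: float = 0.01
    max_steps: int = 2000
    eval_every: int = 200
    mlm_weight: float = 1.0
    los_weight: float = 1.0
    valid_fraction: float = 0.1
    early_stopping_patience: int = 5  # evals without improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_steps < 1 or self.learning_rate <= 0:
            raise ValueError("sizes and rates must be positive")
        if self.mlm_weight < 0 or self.los_weight < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainingHistory:
    steps: list[int] = field(default_factory=list)
    mlm_loss: list[float] = field(default_factory=list)
    los_loss: list[float] = field(default_factory=list)
    mlm_accuracy: list[float] = field(default_factory=list)
    los_auc: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)  # per-step combined loss

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": self.steps,
                "mlm_loss": self.mlm_loss,
                "los_loss": self.los_loss,
                "mlm_accuracy": self.mlm_accuracy,
                "los_auc": self.los_auc,
            }
        )


class _VocabSize:
    """Masking needs only the vocabulary size; this adapter reads it off the
    model config so pretraining does not require the token table itself."""

    def __init__(self, model: MedBERT):
        self.size = model.config.vocab_size


def _batch_losses(model, seqs, labels, vocab, mask_rng, drop_rng, training=True):
    """Forward one batch; returns (mlm_loss, los_loss, n_correct) Tensors/ints."""
    examples = [make_masked_example(s, vocab, mask_rng) for s in seqs]
    code = np.stack([e.input_ids for e in examples])
    ser = np.stack([s.serialization_ids for s in seqs])
    vis = np.stack([s.visit_ids for s in seqs])
    amask = np.stack([s.attention_mask for s in seqs]).astype(float)
    positions = np.array([e.target_position for e in examples])
    targets = np.array([e.target_id for e in examples])
    # drop the all-PAD tail shared by the batch; targets sit on real positions
    width = max(1, int(np.max([s.n_real for s in seqs])))
    code, ser, vis, amask = code[:, :width], ser[:, :width], vis[:, :width], amask[:, :width]

    out = model.forward(code, ser, vis, amask, training=training, rng=drop_rng)
    logits = model.mlm_logits_at(out, positions)  # (B, V)
    logp = log_softmax(logits, axis=-1)
    B = len(seqs)
    mlm_loss = -(logp[np.arange(B), targets].mean())
    n_correct = int((logits.data.argmax(axis=-1) == targets).sum())

    z = model.sequence_logit_ffl(out, amask)
    y = np.asarray(labels, dtype=float)
    los_loss = (z.softplus() - z * y).mean()
    return mlm_loss, los_loss, n_correct, z


def pretrain(
    model: MedBERT,
    corpus: list[TokenizedSequence],
    labels: list[int] | np.ndarray,
    config: PretrainConfig,
) -> tuple[MedBERT, TrainingHistory]:
    """Train the two pretraining objectives jointly; returns the best model
    (by combined validation loss) and the step-wise history."""
    if len(corpus) != len(labels):
        raise ValueError("one prolonged-LOS label per tokenized patient is required")
    labels = np.asarray(labels, dtype=int)

    root = np.random.default_rng(config.seed)
    order_rng, mask_rng, drop_rng, eval_seed = (
        np.random.default_rng(root.integers(2**31)),
        np.random.default_rng(root.integers(2**31)),
        np.random.default_rng(root.integers(2**31)),
        int(root.integers(2**31)),
    )

    n_valid = max(1, int(len(corpus) * config.valid_fraction))
    perm = order_rng.permutation(len(corpus))
    valid_idx, train_idx = perm[:n_valid], perm[n_valid:]
    if len(train_idx) == 0:
        raise ValueError("corpus too small to hold out a validation split")

    opt = AdamW(
        model.params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
        warmup_steps=max(1, config.max_steps // 10),
        clip_norm=None,  # pretraining batches are large and well-behaved
    )

    history = TrainingHistory()
    best_loss = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0
    cursor, epoch_order = 0, order_rng.permutation(train_idx)

    for step in range(1, config.max_steps + 1):
        if cursor + config.batch_size > len(epoch_order):
            epoch_order = order_rng.permutation(train_idx)
            cursor = 0
        batch_idx = epoch_order[cursor : cursor + config.batch_size]
        cursor += config.batch_size

        seqs = [corpus[i] for i in batch_idx]
        mlm_loss, los_loss, _, _z = _batch_losses(
            model, seqs, labels[batch_idx], _VocabSize(model), mask_rng, drop_rng
        )
        # zero-weight objectives are dropped outright: even a zero gradient
        # would let decoupled weight decay touch that head's parameters
        if config.los_weight == 0.0:
            loss = config.mlm_weight * mlm_loss
        elif config.mlm_weight == 0.0:
            loss = config.los_weight * los_loss
        else:
            loss = config.mlm_weight * mlm_loss + config.los_weight * los_loss
        model.zero_grad()
        loss.backward()
        opt.step()
        history.train_loss.append(float(loss.data))

        if step % config.eval_every == 0 or step == config.max_steps:
            vm, vl, acc, auc = _evaluate(
                model, [corpus[i] for i in valid_idx], labels[valid_idx], eval_seed
            )
            history.steps.append(step)
            history.mlm_loss.append(vm)
            history.los_loss.append(vl)
            history.mlm_accuracy.append(acc)
            history.los_auc.append(auc)
            combined = config.mlm_weight * vm + config.los_weight * vl
            if combined < best_loss - 1e-6:
                best_loss = combined
                best_state = {k: p.data.copy() for k, p in model.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= config.early_stopping_patience:
                    break

    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return model, history


def _evaluate(model, seqs, labels, eval_seed, batch_size=64):
    rng = np.random.default_rng(eval_seed)  # fixed masking for comparable evals
    tot_mlm, tot_los, tot_correct = 0.0, 0.0, 0
    scores = []
    for i in range(0, len(seqs), batch_size):
        chunk = seqs[i : i + batch_size]
        y = labels[i : i + batch_size]
        mlm_loss, los_loss, n_correct, z = _batch_losses(
            model, chunk, y, _VocabSize(model), rng, None, training=False
        )
        w = len(chunk) / len(seqs)
        tot_mlm += float(mlm_loss.data) * w
        tot_los += float(los_loss.data) * w
        tot_correct += n_correct
        scores.extend(z.data.tolist())
    try:
        auc = evaluate_auc(scores, labels)
    except UndefinedAUCError:
        auc = float("nan")
    return tot_mlm, tot_los, tot_correct / len(seqs), auc


__all__ = ["PretrainConfig", "TrainingHistory", "pretrain"]
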