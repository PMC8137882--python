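"""The three evaluation experiments.

* Experiment 1 — added value of the pretrained encoder on top of base
  sequence models (GRU / BiGRU / RETAIN), plus the FFL-only pretrained and
  untrained-architecture ablation rows and the tabular baselines
  (L2 logistic regression, random forest).  Ten runs per condition with
  re-randomized head initialization and data order; mean ± sd test AUC.
* Experiment 2 — the same heads on frozen static skip-gram code vectors,
  the contextual-versus-static comparison.
* Experiment 3 — bootstrap learning curves: for each training size, ten
  with-replacement training subsets are fine-tuned and evaluated on the
  fixed test set.

Every function takes explicit (train, valid, test) batches and a fitted
pretraining checkpoint; nothing here touches the generator's latent truth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .baselines import fit_tabular_baselines
from .evaluate import EvalReport, evaluate_auc
from .finetune import FinetuneConfig, SequenceBatch, attach_head, finetune
from .model import MedBERT

DEFAULT_SIZE_LADDER = (300, 500, 1000, 2000, 5000)


def _run_condition(
    source,
    head: str,
    init: str,
    encoder_mode: str,
    train: SequenceBatch,
    valid: SequenceBatch,
    test: SequenceBatch,
    base_config: FinetuneConfig,
    n_runs: int,
    seed: int,
    static_matrix=None,
) -> list[float]:
    """Fine-tune one condition ``n_runs`` times with re-randomized head init
    and data order; returns test AUCs."""
    aucs = []
    for r in range(n_runs):
        cfg = replace(base_config, head=head, init=init, seed=seed + 1000 * r)
        pred = attach_head(
            source, head, cfg, encoder_mode=encoder_mode, static_matrix=static_matrix
        )
        pred, _ = finetune(pred, train, valid, cfg)
        aucs.append(evaluate_auc(pred.predict_proba(test), test.labels))
    return aucs


def run_experiment_1(
    train: SequenceBatch,
    valid: SequenceBatch,
    test: SequenceBatch,
    checkpoint: MedBERT,
    config: FinetuneConfig,
    heads: tuple[str, ...] = ("gru", "bigru", "retain"),
    n_runs: int = 10,
    seed: int = 0,
    vocab_size: int | None = None,
) -> EvalReport:
    """Base models vs base+pretrained-encoder, FFL-only rows, and baselines."""
    report = EvalReport()
    model_cfg = checkpoint.config
    for head in heads:
        base = _run_condition(
            model_cfg, head, "random", "embeddings", train, valid, test,
            config, n_runs, seed,
        )
        report.add(head.upper(), head, "embeddings", len(train), base)
        plus = _run_condition(
            checkpoint, head, "pretrained", "encoder", train, valid, test,
            config, n_runs, seed,
        )
        report.add(f"{head.upper()} + Med-BERT", head, "pretrained", len(train), plus)
    ffl_pre = _run_condition(
        checkpoint, "ffl", "pretrained", "encoder", train, valid, test,
        config, n_runs, seed,
    )
    report.add("Med-BERT_only (FFL)", "ffl", "pretrained", len(train), ffl_pre)
    ffl_untrained = _run_condition(
        model_cfg, "ffl", "random", "encoder", train, valid, test,
        config, n_runs, seed,
    )
    report.add("untrained Med-BERT only", "ffl", "random", len(train), ffl_untrained)

    V = vocab_size if vocab_size is not None else model_cfg.vocab_size
    tab = fit_tabular_baselines(train, test, V)
    report.add("Logistic Regression (LR)", "lr", "multi-hot", len(train), [tab["logistic"]])
    rf_aucs = [
        fit_tabular_baselines(train, test, V, rf_seed=seed + r)["random_forest"]
        for r in range(min(n_runs, 3))
    ]
    report.add("Random Forest (RF)", "rf", "multi-hot", len(train), rf_aucs)
    return report


def run_experiment_2(
    train: SequenceBatch,
    valid: SequenceBatch,
    test: SequenceBatch,
    checkpoint: MedBERT,
    static_embeddings: np.ndarray,
    config: FinetuneConfig,
    heads: tuple[str, ...] = ("gru", "bigru", "retain"),
    n_runs: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Heads on frozen static code vectors (the skip-gram comparator rows)."""
    if static_embeddings.ndim != 2:
        raise ValueError("static embedding matrix must be 2-D (vocab x dim)")
    if static_embeddings.shape[0] < checkpoint.config.vocab_size:
        raise ValueError("static embedding matrix does not cover the vocabulary")
    report = EvalReport()
    for head in heads:
        aucs = _run_condition(
            None, head, "random", "static", train, valid, test,
            config, n_runs, seed, static_matrix=static_embeddings,
        )
        report.add(f"{head.upper()} + static", head, "static", len(train), aucs)
    return report


def run_experiment_3(
    train: SequenceBatch,
    valid: SequenceBatch,
    test: SequenceBatch,
    checkpoint: MedBERT,
    config: FinetuneConfig,
    sizes: tuple[int, ...] = DEFAULT_SIZE_LADDER,
    heads: tuple[str, ...] = ("gru",),
    n_runs: int = 10,
    seed: int = 0,
    include_base: bool = True,
) -> tuple[EvalReport, pd.DataFrame]:
    """Bootstrap learning curves over the training-size ladder.

    For each size, ten training subsets are drawn with replacement from the
    training partition; validation and test stay fixed.  Raises
    ``ValueError`` for a size exceeding the training partition.
    """
    for s in sizes:
        if s > len(train):
            raise ValueError(f"training size {s} exceeds the partition ({len(train)})")
    rng = np.random.default_rng(seed)
    report = EvalReport()
    model_cfg = checkpoint.config
    for size in sizes:
        for head in heads:
            for cond, source, init, mode in (
                (f"{head.upper()} + Med-BERT", checkpoint, "pretrained", "encoder"),
                (head.upper(), model_cfg, "random", "embeddings"),
            ):
                if not include_base and init == "random":
                    continue
                aucs = []
                for r in range(n_runs):
                    sub = train.take(rng.integers(0, len(train), size=size))
                    if len(set(sub.labels.tolist())) < 2:  # resample degenerate draws
                        sub = train.take(rng.integers(0, len(train), size=size))
                    cfg = replace(config, head=head, init=init, seed=seed + 1000 * r + size)
                    pred = attach_head(source, head, cfg, encoder_mode=mode)
                    pred, _ = finetune(pred, sub, valid, cfg)
                    aucs.append(evaluate_auc(pred.predict_proba(test), test.labels))
                report.add(cond, head, init, size, aucs)
    return report, report.to_frame()


__all__ = [
    "run_experiment_1",
    "run_experiment_2",
    "run_experiment_3",
    "DEFAULT_SIZE_LADDER",
]
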