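"""Evaluation primitives: AUC, patient-level splits, and report containers.

The split follows the protocol of the original evaluation: patients are
partitioned 7:1:2 into train/validation/test, and any patient who also
appears in the pretraining corpus is kept out of the test partition (such
patients are assigned preferentially to train/validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class UndefinedAUCError(ValueError):
    """Raised when scores contain only one class."""


class SplitError(ValueError):
    """Raised when the requested split ratios are unattainable."""


def evaluate_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outranks a random negative.

    Rank (Mann–Whitney) formulation with ties counted one half.  Requires at
    least one positive and one negative label.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC needs both a positive and a negative example")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class SplitSpec:
    """7:1:2 patient-level split with pretraining-id exclusion for test."""

    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    pretraining_ids: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.ratios), 1.0):
            raise ValueError("split ratios must sum to 1")
        if not isinstance(self.pretraining_ids, frozenset):
            object.__setattr__(self, "pretraining_ids", frozenset(self.pretraining_ids))


def split_cohort(
    patient_ids: Sequence[str], spec: SplitSpec
) -> tuple[list[str], list[str], list[str]]:
    """Partition ids into (train, valid, test) honoring the exclusion rule.

    Ids overlapping the pretraining set are shuffled into train/validation
    only; the remainder fills test first, then tops up train/validation.
    Raises :class:`SplitError` when too few non-overlapping ids exist to
    fill the test partition.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise SplitError("patient ids must be unique")
    n = len(ids)
    n_test = round(n * spec.ratios[2])
    n_valid = round(n * spec.ratios[1])
    n_train = n - n_test - n_valid

    rng = np.random.default_rng(spec.seed)
    overlap = [i for i in ids if i in spec.pretraining_ids]
    clean = [i for i in ids if i not in spec.pretraining_ids]
    if len(clean) < n_test:
        raise SplitError(
            f"only {len(clean)} patients outside the pretraining set; "
            f"cannot fill a test partition of {n_test}"
        )
    clean = [clean[k] for k in rng.permutation(len(clean))]
    overlap = [overlap[k] for k in rng.permutation(len(overlap))]

    test = clean[:n_test]
    rest = clean[n_test:] + overlap
    rest = [rest[k] for k in rng.permutation(len(rest))]
    train = rest[:n_train]
    valid = rest[n_train : n_train + n_valid]
    return train, valid, test


@dataclass
class EvalReport:
    """Per-condition AUC summaries, one row per (condition, head, init, size)."""

    rows: list[dict] = field(default_factory=list)

    def add(
        self,
        condition: str,
        head: str,
        init: str,
        train_size: int,
        aucs: Sequence[float],
        extra: dict | None = None,
    ) -> None:
        row = {
            "condition": condition,
            "head": head,
            "init": init,
            "train_size": train_size,
            "mean_auc": float(np.mean(aucs)),
            "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            "n_runs": len(aucs),
            "aucs": [float(a) for a in aucs],
        }
        if extra:
            row.update(extra)
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: v for k, v in r.items() if k != "aucs"} for r in self.rows]
        )

    def row(self, condition: str) -> dict:
        for r in self.rows:
            if r["condition"] == condition:
                return r
        raise KeyError(condition)


def classification_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Precision/recall/F1 at a fixed operating point, reported alongside AUC."""
    s = np.asarray(scores) >= threshold
    y = np.asarray(labels).astype(bool)
    tp = int((s & y).sum())
    fp = int((s & ~y).sum())
    fn = int((~s & y).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"precision": prec, "recall": rec, "f1": f1}


__all__ = [
    "evaluate_auc",
    "UndefinedAUCError",
    "SplitSpec",
    "SplitError",
    "split_cohort",
    "EvalReport",
    "classification_metrics",
]
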