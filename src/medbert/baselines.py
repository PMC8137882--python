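"""Non-contextual comparators: multi-hot tabular baselines and a static
skip-gram code embedding.

The tabular baselines are L2-regularized logistic regression and a random
forest on a patient × vocabulary presence matrix (1 iff the code appears at
least once in the record), fitted with scikit-learn defaults.

The static embedding is a skip-gram with negative sampling trained on the
flattened code sequences with the context window equal to one visit: every
ordered pair of distinct codes inside a visit is a (center, context)
example.  The vectors are context-independent by construction — the same
code maps to the same vector wherever it occurs — which is exactly the
property the contextual encoder is being compared against.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .evaluate import evaluate_auc
from .finetune import SequenceBatch
from .tokenizer import TokenizedSequence
from .vocab import N_RESERVED, Vocabulary


def multi_hot(batch: SequenceBatch, vocab_size: int) -> np.ndarray:
    """(N, V) presence matrix: 1 iff the code id occurs in the record."""
    X = np.zeros((len(batch), vocab_size), dtype=np.float64)
    for i in range(len(batch)):
        real = batch.code[i][batch.mask[i] > 0].astype(int)
        X[i, real] = 1.0
    return X


def fit_tabular_baselines(
    train: SequenceBatch,
    test: SequenceBatch,
    vocab_size: int,
    rf_seed: int = 0,
) -> dict[str, float]:
    """Test AUC of L2 logistic regression and random forest on multi-hot input."""
    Xtr, Xte = multi_hot(train, vocab_size), multi_hot(test, vocab_size)
    lr = LogisticRegression(max_iter=1000)  # default penalty is the L2 ridge
    lr.fit(Xtr, train.labels)
    rf = RandomForestClassifier(random_state=rf_seed)
    rf.fit(Xtr, train.labels)
    return {
        "logistic": evaluate_auc(lr.predict_proba(Xte)[:, 1], test.labels),
        "random_forest": evaluate_auc(rf.predict_proba(Xte)[:, 1], test.labels),
    }


def train_skipgram(
    corpus: list[TokenizedSequence],
    vocab: Vocabulary,
    dim: int,
    epochs: int = 3,
    n_negative: int = 5,
    lr: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Skip-gram with negative sampling over within-visit code pairs.

    Returns a (vocab.size, dim) matrix; reserved rows stay at their random
    initialization (they never occur as training pairs).
    """
    rng = np.random.default_rng(seed)
    V = vocab.size
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    # unigram^(3/4) negative-sampling table over non-reserved ids
    counts = np.zeros(V)
    pairs: list[tuple[int, int]] = []
    for seq in corpus:
        n = seq.n_real
        ids, vis = seq.code_ids[:n], seq.visit_ids[:n]
        counts += np.bincount(ids, minlength=V)
        start = 0
        for i in range(1, n + 1):
            if i == n or vis[i] != vis[start]:
                visit_ids = ids[start:i]
                for a in range(len(visit_ids)):
                    for b in range(len(visit_ids)):
                        if a != b:
                            pairs.append((int(visit_ids[a]), int(visit_ids[b])))
                start = i
    if not pairs:
        return W_in
    probs = counts[N_RESERVED:] ** 0.75
    probs /= probs.sum()
    neg_ids = np.arange(N_RESERVED, V)
    pair_arr = np.asarray(pairs)

    for _ in range(epochs):
        order = rng.permutation(len(pair_arr))
        negs = rng.choice(neg_ids, size=(len(pair_arr), n_negative), p=probs)
        for j, k in enumerate(order):
            c, o = pair_arr[k]
            targets = np.concatenate(([o], negs[j]))
            labels = np.zeros(1 + n_negative)
            labels[0] = 1.0
            vin = W_in[c]
            vout = W_out[targets]
            scores = 1.0 / (1.0 + np.exp(-vout @ vin))
            g = (scores - labels)[:, None]
            W_in[c] -= lr * (g * vout).sum(axis=0)
            W_out[targets] -= lr * g * vin
    return W_in


__all__ = ["multi_hot", "fit_tabular_baselines", "train_skipgram"]
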