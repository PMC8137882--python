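"""Masked-code example construction for self-supervised pretraining.

One diagnosis code per patient is supervised per pass: a target position is
drawn uniformly over the real (non-PAD) positions, then the input at that
position is corrupted with probability 0.8 to the [MASK] token, 0.1 to a
random non-reserved vocabulary code (resampled if it equals the original),
and with probability 0.1 kept unchanged.  The model must predict the true
code at the target position in every branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .tokenizer import TokenizedSequence
from .vocab import MASK_ID, N_RESERVED, Vocabulary

P_MASK = 0.8
P_RANDOM = 0.1
P_KEEP = 0.1


class Branch(str, Enum):
    MASK = "mask"
    RANDOM = "random"
    KEEP = "keep"


class DegenerateInputError(ValueError):
    """Raised when a sequence has no real position to supervise."""


@dataclass(frozen=True)
class MaskedExample:
    input_ids: np.ndarray
    target_position: int
    target_id: int
    branch: Branch


def make_masked_example(
    seq: TokenizedSequence,
    vocab: Vocabulary,
    rng: np.random.Generator,
    force_branch: Branch | None = None,
) -> MaskedExample:
    """Draw one corrupted example from a tokenized patient.

    ``rng`` is a dedicated masking stream, independent of model-init
    randomness, so corpora are reproducible across runs.  ``force_branch``
    bypasses the 80/10/10 draw (used in tests and diagnostics).
    """
    n_real = seq.n_real
    if n_real == 0:
        raise DegenerateInputError("all-PAD sequence cannot be masked")
    pos = int(rng.integers(n_real))
    target = int(seq.code_ids[pos])

    if force_branch is None:
        u = rng.random()
        branch = Branch.MASK if u < P_MASK else (Branch.RANDOM if u < P_MASK + P_RANDOM else Branch.KEEP)
    else:
        branch = force_branch

    input_ids = seq.code_ids.copy()
    if branch is Branch.MASK:
        input_ids[pos] = MASK_ID
    elif branch is Branch.RANDOM:
        lo, hi = N_RESERVED, vocab.size
        if hi - lo <= 1:
            replacement = lo  # single-code vocabulary: nothing else to draw
        else:
            replacement = int(rng.integers(lo, hi))
            while replacement == target:
                replacement = int(rng.integers(lo, hi))
        input_ids[pos] = replacement
    return MaskedExample(input_ids, pos, target, branch)


def mask_batch(
    seqs: list[TokenizedSequence], vocab: Vocabulary, rng: np.random.Generator
) -> list[MaskedExample]:
    """One masked example per patient — fresh target positions every call."""
    return [make_masked_example(s, vocab, rng) for s in seqs]


__all__ = [
    "P_MASK",
    "P_RANDOM",
    "P_KEEP",
    "Branch",
    "MaskedExample",
    "DegenerateInputError",
    "make_masked_example",
    "mask_batch",
]
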