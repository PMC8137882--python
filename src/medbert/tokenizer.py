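"""Flattening patient records into the three parallel index arrays the model
consumes: code ids, serialization ids (within-visit position, 1-based,
restarting each visit) and visit ids (1-based visit ordinal).

No classifier or separator tokens are inserted: visit ids already separate
visits, and sequence-level classification pools over all real positions
rather than a summary token.

Truncation, when a flattened record exceeds ``max_len``, keeps the most
recent whole visits; if a single visit still overflows, its lowest-
serialization (highest-priority) codes are kept.  Visit and serialization
ids are re-based after truncation so they remain 1-based, and are clamped
at the embedding-table cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import PatientRecord
from .vocab import PAD_ID, Vocabulary


class DegenerateSequenceError(ValueError):
    """Raised for a patient that flattens to zero real positions."""


@dataclass(frozen=True)
class TokenizedSequence:
    """Parallel per-position arrays for one patient, padded to max_len."""

    patient_id: str
    code_ids: np.ndarray          # int64, shape (max_len,)
    serialization_ids: np.ndarray
    visit_ids: np.ndarray
    attention_mask: np.ndarray    # 1 on real positions, 0 on PAD

    def __post_init__(self) -> None:
        n = len(self.code_ids)
        if not (len(self.serialization_ids) == len(self.visit_ids) == len(self.attention_mask) == n):
            raise ValueError("all four arrays must share one length")

    @property
    def n_real(self) -> int:
        return int(self.attention_mask.sum())


def _flatten(patient: PatientRecord) -> tuple[list[str], list[int], list[int]]:
    codes: list[str] = []
    ser: list[int] = []
    vis: list[int] = []
    for vi, visit in enumerate(patient.visits, start=1):
        for ci, code in enumerate(visit.codes, start=1):
            codes.append(code.code)
            ser.append(ci)
            vis.append(vi)
    return codes, ser, vis


def tokenize_patient(
    patient: PatientRecord,
    vocab: Vocabulary,
    max_len: int = 512,
) -> TokenizedSequence:
    """Flatten one patient into a padded :class:`TokenizedSequence`.

    Visits must already be time-ordered and codes ordered within each visit
    (see :func:`medbert.cohort.order_patient_codes`).
    """
    codes, ser, vis = _flatten(patient)
    if not codes:
        raise DegenerateSequenceError(f"patient {patient.patient_id} has no codes")

    if len(codes) > max_len:
        # keep the most recent whole visits
        keep_from = len(codes)
        visits_kept: set[int] = set()
        i = len(codes)
        while i > 0:
            v = vis[i - 1]
            start = i
            while start > 0 and vis[start - 1] == v:
                start -= 1
            if (len(codes) - start) > max_len:
                break
            keep_from = start
            visits_kept.add(v)
            i = start
        if keep_from == len(codes):
            # a single visit longer than max_len: keep its highest-priority codes
            last_v = vis[-1]
            idx = [j for j in range(len(codes)) if vis[j] == last_v][:max_len]
        else:
            idx = list(range(keep_from, len(codes)))
        codes = [codes[j] for j in idx]
        ser = [ser[j] for j in idx]
        vis = [vis[j] for j in idx]
        # re-base visit ordinals at 1 after dropping early visits
        base = min(vis) - 1
        vis = [v - base for v in vis]

    n = len(codes)
    code_ids = np.zeros(max_len, dtype=np.int64) + PAD_ID
    ser_ids = np.zeros(max_len, dtype=np.int64)
    vis_ids = np.zeros(max_len, dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.int64)
    code_ids[:n] = [vocab.encode(c) for c in codes]
    # clamp at the table cap so over-long visits/sequences stay in range
    ser_ids[:n] = np.minimum(ser, max_len)
    vis_ids[:n] = np.minimum(vis, max_len)
    mask[:n] = 1
    return TokenizedSequence(patient.patient_id, code_ids, ser_ids, vis_ids, mask)


def detokenize(seq: TokenizedSequence, vocab: Vocabulary) -> list[list[str]]:
    """Recover the per-visit code-string structure (inverse of tokenize for
    untruncated patients)."""
    out: list[list[str]] = []
    prev_v = None
    for i in range(seq.n_real):
        v = int(seq.visit_ids[i])
        if v != prev_v:
            out.append([])
            prev_v = v
        out[-1].append(vocab.decode(int(seq.code_ids[i])))
    return out


def tokenize_cohort(
    patients, vocab: Vocabulary, max_len: int = 512
) -> list[TokenizedSequence]:
    return [tokenize_patient(p, vocab, max_len) for p in patients]


__all__ = [
    "TokenizedSequence",
    "DegenerateSequenceError",
    "tokenize_patient",
    "tokenize_cohort",
    "detokenize",
]
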