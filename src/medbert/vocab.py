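"""Code vocabulary with reserved special tokens.

Diagnosis codes are whole tokens — no subword splitting.  Ids 0..2 are
reserved (PAD=0, MASK=1, UNK=2) so checkpoints stay portable across corpora;
real codes are assigned ids deterministically by descending corpus frequency
with lexicographic tie-break.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable

from .records import PatientRecord

PAD_ID = 0
MASK_ID = 1
UNK_ID = 2
N_RESERVED = 3

PAD_TOKEN = "[PAD]"
MASK_TOKEN = "[MASK]"
UNK_TOKEN = "[UNK]"
RESERVED_TOKENS = (PAD_TOKEN, MASK_TOKEN, UNK_TOKEN)


class EmptyVocabularyError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    token_to_id: dict[str, int]

    @property
    def size(self) -> int:
        """Total id count, reserved tokens included."""
        return len(self.token_to_id) + N_RESERVED

    @property
    def id_to_token(self) -> dict[int, str]:
        inv = {i: t for i, t in enumerate(RESERVED_TOKENS)}
        inv.update({v: k for k, v in self.token_to_id.items()})
        return inv

    def encode(self, code: str) -> int:
        return self.token_to_id.get(code, UNK_ID)

    def decode(self, idx: int) -> str:
        return self.id_to_token.get(idx, UNK_TOKEN)

    def content_hash(self) -> str:
        """Stable hash of the (token, id) mapping, used for checkpoint compatibility."""
        h = hashlib.sha256()
        for tok, idx in sorted(self.token_to_id.items()):
            h.update(f"{tok}\t{idx}\n".encode())
        return h.hexdigest()[:16]

    def to_tsv(self, fh: IO[str]) -> None:
        """Write two-column (token, id) TSV, reserved rows first."""
        for idx, tok in enumerate(RESERVED_TOKENS):
            fh.write(f"{tok}\t{idx}\n")
        for tok, idx in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
            fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def from_tsv(cls, fh: IO[str]) -> "Vocabulary":
        mapping: dict[str, int] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tok, idx = line.split("\t")
            if tok in RESERVED_TOKENS:
                continue
            mapping[tok] = int(idx)
        return cls(mapping)


def build_vocabulary(
    patients: Iterable[PatientRecord], min_count: int = 1
) -> Vocabulary:
    """Assign ids to codes by (frequency desc, code asc); rare codes map to UNK.

    Codes occurring fewer than ``min_count`` times are dropped from the table
    and will encode to UNK.  Raises :class:`EmptyVocabularyError` when the
    corpus yields no retained code.
    """
    counts: Counter[str] = Counter()
    for p in patients:
        for v in p.visits:
            for c in v.codes:
                counts[c.code] += 1
    retained = [(tok, n) for tok, n in counts.items() if n >= min_count]
    if not retained:
        raise EmptyVocabularyError("no code meets min_count; cannot build vocabulary")
    retained.sort(key=lambda kv: (-kv[1], kv[0]))
    return Vocabulary({tok: N_RESERVED + i for i, (tok, _) in enumerate(retained)})


__all__ = [
    "PAD_ID",
    "MASK_ID",
    "UNK_ID",
    "N_RESERVED",
    "PAD_TOKEN",
    "MASK_TOKEN",
    "UNK_TOKEN",
    "Vocabulary",
    "EmptyVocabularyError",
    "build_vocabulary",
]
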