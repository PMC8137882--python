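"""Per-layer, per-head attention export for inspection.

The encoder itself never sees separator tokens; "SEP" rows are inserted
into the *display* token list at visit boundaries purely for rendering, and
carry zero weight.  The export is a plain JSON-serializable document —
``{tokens, sep_positions, maps: [{layer, head, weights}]}`` — so any
front-end can draw it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import MedBERT
from .records import PatientRecord
from .tokenizer import tokenize_patient
from .vocab import Vocabulary

SEP_DISPLAY = "SEP"


@dataclass
class AttentionExport:
    patient_id: str
    checkpoint_id: str
    tokens: list[str]               # display tokens, SEP rows included
    sep_positions: list[int]        # indices of inserted SEP rows
    visit_of: list[int]             # visit ordinal per display token (SEP: boundary's left visit)
    model_position: list[int]       # model position per display token, -1 for SEP
    maps: list[dict] = field(default_factory=list)  # {layer, head, weights: (D,D) ndarray}

    def to_json(self) -> str:
        doc = {
            "patient_id": self.patient_id,
            "checkpoint": self.checkpoint_id,
            "tokens": self.tokens,
            "sep_positions": self.sep_positions,
            "maps": [
                {"layer": m["layer"], "head": m["head"], "weights": m["weights"].tolist()}
                for m in self.maps
            ],
        }
        return json.dumps(doc)

    def rows_for_code(self, code: str) -> list[tuple[int, int]]:
        """All occurrences of a code as (visit ordinal, display row index) —
        the probe for comparing attention of one code across visits."""
        return [
            (self.visit_of[i], i)
            for i, t in enumerate(self.tokens)
            if t == code and i not in self.sep_positions
        ]

    def strip_separators(self, layer: int, head: int) -> np.ndarray:
        """Drop SEP rows/columns, recovering the raw model attention."""
        w = next(m["weights"] for m in self.maps if m["layer"] == layer and m["head"] == head)
        keep = [i for i in range(len(self.tokens)) if i not in set(self.sep_positions)]
        return w[np.ix_(keep, keep)]


def export_attention(
    model: MedBERT,
    patient: PatientRecord,
    vocab: Vocabulary,
    layer_filter: list[int] | None = None,
    head_filter: list[int] | None = None,
    vocab_hash: str | None = None,
) -> AttentionExport:
    """Forward one patient with attention retention and build the display
    document.  ``layer_filter``/``head_filter`` are 1-based; None keeps all.
    A deterministic pure function of (checkpoint, patient)."""
    if vocab_hash is None:
        vocab_hash = vocab.content_hash()
    if model.vocab_hash and model.vocab_hash != vocab_hash:
        raise ValueError("checkpoint was built for a different vocabulary")
    seq = tokenize_patient(patient, vocab, max_len=model.config.max_len)
    n = seq.n_real
    out = model.forward(
        seq.code_ids[None],
        seq.serialization_ids[None],
        seq.visit_ids[None],
        seq.attention_mask[None].astype(float),
        collect_attention=True,
    )
    assert out.attention_maps is not None

    tokens: list[str] = []
    sep_positions: list[int] = []
    visit_of: list[int] = []
    model_position: list[int] = []
    prev_visit: int | None = None
    for i in range(n):
        v = int(seq.visit_ids[i])
        if prev_visit is not None and v != prev_visit:
            sep_positions.append(len(tokens))
            tokens.append(SEP_DISPLAY)
            visit_of.append(prev_visit)
            model_position.append(-1)
        tokens.append(vocab.decode(int(seq.code_ids[i])))
        visit_of.append(v)
        model_position.append(i)
        prev_visit = v

    D = len(tokens)
    real = np.array([p for p in model_position if p >= 0])
    rows = np.array([i for i, p in enumerate(model_position) if p >= 0])
    export = AttentionExport(
        patient_id=patient.patient_id,
        checkpoint_id=model.vocab_hash or "unpinned",
        tokens=tokens,
        sep_positions=sep_positions,
        visit_of=visit_of,
        model_position=model_position,
    )
    layers = layer_filter or list(range(1, model.config.n_layers + 1))
    heads = head_filter or list(range(1, model.config.n_heads + 1))
    for l in layers:
        raw = out.attention_maps[l - 1][0]  # (A, T, T)
        for h in heads:
            w = np.zeros((D, D))
            w[np.ix_(rows, rows)] = raw[h - 1][np.ix_(real, real)]
            export.maps.append({"layer": l, "head": h, "weights": w})
    return export


def top_attended_pairs(
    export: AttentionExport, layer: int, head: int, k: int
) -> list[tuple[str, str, float]]:
    """Top-k off-diagonal (source code, target code, weight) triples.

    Ties break deterministically by (source token, target token, row, col)
    lexicographic order; k larger than the pair count truncates.
    """
    try:
        w = next(
            m["weights"] for m in export.maps if m["layer"] == layer and m["head"] == head
        )
    except StopIteration:
        raise ValueError(f"no exported map for layer {layer}, head {head}") from None
    sep = set(export.sep_positions)
    entries = []
    D = len(export.tokens)
    for i in range(D):
        if i in sep:
            continue
        for j in range(D):
            if j == i or j in sep:
                continue
            entries.append(
                (-w[i, j], export.tokens[i], export.tokens[j], i, j)
            )
    entries.sort()
    return [(src, tgt, -negw) for negw, src, tgt, _i, _j in entries[:k]]


__all__ = ["AttentionExport", "export_attention", "top_attended_pairs", "SEP_DISPLAY"]
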