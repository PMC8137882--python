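"""Export attention maps for one patient and list the strongest code pairs.

Display-only "SEP" rows mark visit boundaries; the model itself never sees
separator tokens.  With an untrained model the weights are near-uniform —
after pretraining, same-condition codes attend to each other.
"""

import numpy as np

from medbert import MedBERT, ModelConfig, build_vocabulary, generate_worked_example
from medbert.attention import export_attention, top_attended_pairs
from medbert.cohort import order_patient_codes

patient = order_patient_codes(generate_worked_example())
vocab = build_vocabulary([patient])
model = MedBERT(
    ModelConfig(vocab_size=vocab.size, n_layers=2, hidden=16, n_heads=2,
                filter_size=16, max_len=16, seed=0),
    vocab_hash=vocab.content_hash(),
)

export = export_attention(model, patient, vocab, layer_filter=[1])
print("display tokens:", export.tokens)
print("SEP rows at   :", export.sep_positions, "(one per visit boundary)")

print("\nstrongest off-diagonal attention pairs (layer 1, head 1):")
for src, tgt, w in top_attended_pairs(export, layer=1, head=1, k=5):
    print(f"  {src:>7} -> {tgt:<7} weight {w:.3f}")

# the same code in different visits gets different attention rows — the
# definition of a contextual (not static) representation
rows = export.rows_for_code("I50.9")
w = export.maps[0]["weights"]
r1, r2 = rows[0][1], rows[1][1]
delta = np.abs(w[r1] - w[r2]).sum()
print(f"\n'I50.9' appears in visits {[v for v, _ in rows]}; "
      f"L1 difference between its two attention rows: {delta:.3f}")
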