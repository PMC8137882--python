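"""Serialization and masking on the fixed worked-example patient.

Shows the three parallel index arrays the model consumes (code /
within-visit serialization / visit ordinal) and one draw of the 80/10/10
masked-code corruption.
"""

import numpy as np

from medbert import build_vocabulary, generate_worked_example, make_masked_example
from medbert.cohort import order_patient_codes
from medbert.tokenizer import tokenize_patient

patient = order_patient_codes(generate_worked_example())
vocab = build_vocabulary([patient])
seq = tokenize_patient(patient, vocab, max_len=16)

n = seq.n_real
print("tokens       ", [vocab.decode(int(i)) for i in seq.code_ids[:n]])
print("serialization", seq.serialization_ids[:n].tolist())
print("visit        ", seq.visit_ids[:n].tolist())
# serialization ids restart at 1 on each visit change; visit ids are the
# 1-based visit ordinals — no separator tokens are inserted.

rng = np.random.default_rng(3)
ex = make_masked_example(seq, vocab, rng)
print(f"\nmasked draw: branch={ex.branch.value}, position={ex.target_position}, "
      f"true code {vocab.decode(ex.target_id)!r}, "
      f"input now {vocab.decode(int(ex.input_ids[ex.target_position]))!r}")
# Over many draws the branch frequencies converge to 80% mask / 10% random /
# 10% keep; exactly one position per patient is supervised per pass.
counts = {"mask": 0, "random": 0, "keep": 0}
for _ in range(10_000):
    counts[make_masked_example(seq, vocab, rng).branch.value] += 1
print("branch frequencies over 10,000 draws:",
      {k: v / 10_000 for k, v in counts.items()})
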