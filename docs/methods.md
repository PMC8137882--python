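# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## The data modality

Structured EHR is modeled as a two-level sequence: a patient is a
time-ordered list of visits, a visit an ordered list of diagnosis codes
(ICD-9/ICD-10 strings treated as opaque vocabulary tokens).  Each code
carries three ordering attributes — present-on-admission flag,
captured-during-visit flag, and integer billing priority — and codes within
a visit are ranked by exactly that key, applied in sequence, with full ties
keeping input order (billing priorities are known to be imperfect, so no
further tie-break is invented).  Within-visit ordering contributes little
predictive signal in practice; the sort is kept as the canonical
serialization and can be bypassed by leaving records unsorted.

Cohort hygiene before pretraining: patients with fewer than three diagnosis
codes in the whole record, or with any visit whose discharge precedes its
admission, are removed.  Length of stay is computed for every encounter
carrying both dates, not only formally inpatient ones — the simplest
faithful reading of a label defined "over the entire EHR sequence".  Age is
event-year minus birth-year; no rule in scope needs day-level resolution.

## Serialization

A patient flattens into three parallel integer arrays: code ids,
serialization ids (1-based position within the visit, restarting at each
visit), and visit ids (1-based visit ordinal).  No classifier or separator
tokens exist anywhere in the model vocabulary; visit ids already delimit
visits, and sequence-level heads pool over all real positions instead of
reading a summary token.  Reserved ids are fixed (PAD=0, MASK=1, UNK=2) so
checkpoints are portable across corpora; real codes get ids by descending
corpus frequency with lexicographic tie-break.

When a flattened record exceeds the maximum length, the most recent whole
visits are kept; if a single visit alone overflows, its lowest-serialization
(highest-priority) codes are kept.  Recency and priority carry the signal;
this is the package's own choice where no canonical rule exists.
Serialization and visit embedding tables are sized `max_len x H` and indices
clamp at the cap.

## Pretraining objectives

*Masked code modeling.*  One code per patient per pass is supervised: the
target position is uniform over real positions, and the input there is
replaced by [MASK] with probability 0.8, by a uniformly drawn non-reserved
code (resampled if equal to the original) with probability 0.1, and kept
with probability 0.1.  The target is resampled fresh every epoch, which
maximizes supervision while keeping one masked code per patient per pass.
Masking randomness is a named stream independent of model-init randomness.

*Prolonged length of stay.*  A patient-level binary label: 1 iff any visit
stayed strictly more than 7 days.  This sequence-level task rewards
cross-visit context; mortality and early-readmission labels are deliberately
not implemented as pretraining tasks because they converge too quickly to
be useful.

The two losses (cross-entropy at the supervised position; binary
cross-entropy on the sequence logit) are combined with equal weights by
default.  A zero weight removes the objective entirely rather than
contributing a zero gradient, so decoupled weight decay cannot silently
drift an unused head.

## Architecture

Summed code + serialization + visit embeddings, layer norm, dropout, then a
post-layer-norm bidirectional transformer encoder with GELU feed-forward
blocks — the original BERT recipe.  The masked-code head is dense + GELU +
layer norm with the output projection tied to the code embedding table plus
a per-code bias.  The sequence head sums final-layer vectors over real
positions, applies one feed-forward layer (width defaults to H, tanh
nonlinearity) and an affine map to a scalar logit.  The visit embedding is
a dedicated learned table, not a reused segment table.  Initialization is
truncated normal, std 0.02, seedable.

The published configuration is L=6 layers, H=192, A=6 heads, feed-forward
width 64, maximum length 512; at the full 82,603-code vocabulary this counts
17,257,004 trainable scalars (about 17 million, dominated by the code
table).  Desk-scale experiments here use L=2, H=32, A=2, filter 64, maximum
length 64 — small enough that the whole study (pretraining plus forty
fine-tuning runs) completes on one CPU core in well under half an hour,
while preserving every architectural ingredient.

All tensor math runs on a small reverse-mode autodiff engine written on
numpy (float64), verified against central finite differences and against a
straight-line per-head attention implementation.  There is no GPU path.

## Training

Pretraining: AdamW (decoupled weight decay 0.01 on matrices only), batch 32
patients, dropout 0.1, linear warmup over the first 10% of steps, early
stopping on combined validation loss with patience 5 evaluations.  The
published learning rate 5e-5 remains the configuration default; the
desk-scale runs use 1e-3, which the small model needs to converge within
2,500 steps.

Fine-tuning attaches a head — feed-forward (FFL), GRU, bidirectional GRU,
or the two-level attention recurrent architecture (RETAIN, run in reverse
time, scalar attention softmaxed over real positions and a tanh vector
gate) — on per-position vectors and updates everything jointly under binary
cross-entropy with early stopping on validation AUC.  Gradients are clipped
to global norm 1; fine-tuning uses no warmup, because a slow schedule start
lets validation-AUC early stopping fire before the model escapes its
initial plateau.  At a few hundred training examples with 15% prevalence
the optimizer can still entrench a degenerate solution in which the score
tracks (negative) sequence length through saturation of the sum-pooled FFL
input; clipping makes such collapses rare, though not impossible (see
Limitations).  Base-model conditions give the heads the trainable
embedding layer without the transformer; the static-embedding comparison
gives them frozen skip-gram vectors (window = one visit, dimension H,
negative sampling with unigram^0.75 noise), so the same code always maps to
the same vector.

## Evaluation protocol

Patient-level 7:1:2 train/validation/test split; patients present in the
pretraining corpus are assigned away from the test partition.  AUC is the
rank (Mann–Whitney) statistic with ties counted one half, verified against
the O(n²) pairwise oracle.  Summary cells are mean ± sd over ten runs with
re-randomized head initialization and data order.  Learning curves draw ten
bootstrap (with-replacement) training subsets per size; validation and test
stay fixed.  The size ladder is configurable; the shipped desk-scale study
uses (150, 300, 500) — the growth region of the default task, whose curve
starts near chance at 150 examples and saturates around 0.75 AUC by 500
(the training partition holds 1,400 patients, so thousands-scale cells are
out of reach at this scale).  Tabular baselines are scikit-learn L2 logistic regression
(deterministic, sd exactly 0) and random forest on patient × code presence
matrices.  Precision/recall/F1 at 0.5 are reported alongside AUC but only
AUC drives conclusions.

## The synthetic cohort

Each patient carries 1–10 latent chronic conditions; each condition owns a
50-code block of the 500-code vocabulary and advances through three
severity stages by a Markov chain, one step per visit.  Visits emit codes
near a stage-specific anchor of each active condition, so same-condition
codes co-occur within visits and drift with severity — the structure masked
-code pretraining can exploit.  Visit counts are negative-binomial
(mean 8), codes per visit 1 + Poisson(1) (≈ 15–16 codes per patient), gaps
irregular, 40% of visits are inpatient with discharge dates.  The
prolonged-stay probability of an inpatient visit rises with current mean
severity; the outcome label is a logistic function of the final severity of
three designated risk conditions.  Both intercepts are calibrated by
bisection on the sampled latent trajectories so that expected prevalences
hit 15%, the regime typical of large general-EHR corpora; defaults are
20,000 patients for pretraining and 2,000 for fine-tuning cohorts.

What the generator does **not** emulate: realistic ICD co-occurrence
semantics, medications/labs/procedures, coding-system drift, site effects,
or informative missingness.  Passing the transfer experiments therefore
shows that the pipeline extracts planted contextual structure end-to-end —
not that it would reach any particular AUC on real claims data.

## Observed desk-scale behavior

On the default synthetic task, fine-tuning the pretrained encoder with only
an FFL head at n=500 reaches test AUC around 0.75–0.80, while the
identically architected random-initialization ablation stays at or below
chance — it cannot even fit its training split, collapsing into the
length-tracking solution described above.  The gap is the desk-scale
analogue of the pretrained-versus-untrained ordering reported at full
scale, amplified because a 500-example cohort is far below what the
untrained architecture needs.  Pretrained code embeddings of same-condition
pairs become measurably more similar than cross-condition pairs (one-sided
permutation test), the contextualization the masked objective is meant to
induce.

## Known limitations

* Roughly one fine-tuning run in ten still collapses to the degenerate
  length solution despite gradient clipping; means over ten runs absorb
  this, and the bootstrap-cell standard deviations make it visible.
* The autodiff engine favors clarity over speed (float64, per-op Python
  dispatch); it is two orders of magnitude slower than a compiled
  framework and is not meant for corpora beyond tens of thousands of
  patients.
* Phenotype medication/lab logic operates on simplified per-patient tables
  (drug-name strings, numeric A1C values), and death status is a
  record-level boolean, so "death before event" excludes conservatively.
* The DHF code lists ship as editable YAML approximations of the published
  prose; claims-grade adjudication is out of scope.
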