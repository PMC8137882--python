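import numpy as np
import pytest

from medbert.cohort import (
    filter_pretraining_cohort,
    order_patient_codes,
    select_pretraining_task_labels,
)
from medbert.simulate import SyntheticConfig, generate_cohort, generate_worked_example
from medbert.tokenizer import tokenize_cohort
from medbert.vocab import build_vocabulary


@pytest.fixture(scope="session")
def worked_example():
    return generate_worked_example()


@pytest.fixture(scope="session")
def small_cohort():
    """300 synthetic patients, fixed seed — shared by the data-layer tests."""
    return generate_cohort(SyntheticConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def prepared(small_cohort):
    """Filtered + ordered patients, vocabulary and tokenized corpus."""
    patients, _ = filter_pretraining_cohort(small_cohort.patients)
    patients = [order_patient_codes(p) for p in patients]
    vocab = build_vocabulary(patients)
    corpus = tokenize_cohort(patients, vocab, max_len=64)
    labels = select_pretraining_task_labels(patients)
    return patients, vocab, corpus, np.asarray(labels)
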