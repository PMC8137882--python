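"""Vocabulary construction, flattening into index arrays, and masking."""

import datetime as dt

import numpy as np
import pytest

from medbert.masking import (
    Branch,
    DegenerateInputError,
    make_masked_example,
)
from medbert.records import CodeSystem, DiagnosisCode, PatientRecord, Sex, VisitRecord
from medbert.tokenizer import (
    DegenerateSequenceError,
    TokenizedSequence,
    detokenize,
    tokenize_patient,
)
from medbert.vocab import (
    MASK_ID,
    N_RESERVED,
    PAD_ID,
    UNK_ID,
    EmptyVocabularyError,
    Vocabulary,
    build_vocabulary,
)

D = dt.date


def patient_with(visit_codes, pid="p"):
    visits = tuple(
        VisitRecord(
            admit_date=D(2015, 1, 1) + dt.timedelta(days=30 * i),
            codes=tuple(DiagnosisCode(CodeSystem.ICD10, c) for c in codes),
        )
        for i, codes in enumerate(visit_codes)
    )
    return PatientRecord(pid, 1960, Sex.FEMALE, visits)


class TestVocabulary:
    def test_frequency_then_lexicographic_ids(self):
        corpus = [patient_with([["A", "A", "B"], ["A"]])]
        v = build_vocabulary(corpus, min_count=1)
        assert v.token_to_id == {"A": 3, "B": 4}
        assert v.size == 5

    def test_min_count_maps_rare_codes_to_unk(self):
        corpus = [patient_with([["A", "A", "B"], ["A"]])]
        v = build_vocabulary(corpus, min_count=2)
        assert v.encode("B") == UNK_ID
        assert v.encode("A") == 3

    def test_empty_corpus_raises(self):
        with pytest.raises(EmptyVocabularyError):
            build_vocabulary([])

    def test_size_matches_set_oracle(self, prepared):
        patients, vocab, _, _ = prepared
        distinct = {c.code for p in patients for v in p.visits for c in v.codes}
        assert vocab.size == len(distinct) + N_RESERVED

    def test_tsv_round_trip(self, prepared, tmp_path):
        _, vocab, _, _ = prepared
        path = tmp_path / "vocab.tsv"
        with open(path, "w") as fh:
            vocab.to_tsv(fh)
        with open(path) as fh:
            again = Vocabulary.from_tsv(fh)
        assert again.token_to_id == vocab.token_to_id
        assert again.content_hash() == vocab.content_hash()


class TestTokenizer:
    def test_visit_and_serialization_layers(self):
        p = patient_with([["A", "B"], ["C", "D"]])
        v = build_vocabulary([p])
        seq = tokenize_patient(p, v, max_len=8)
        assert seq.visit_ids[:4].tolist() == [1, 1, 2, 2]
        assert seq.serialization_ids[:4].tolist() == [1, 2, 1, 2]
        assert seq.attention_mask.tolist() == [1, 1, 1, 1, 0, 0, 0, 0]
        assert (seq.code_ids[4:] == PAD_ID).all()

    def test_single_code_patient(self):
        p = patient_with([["A"]])
        v = build_vocabulary([p])
        seq = tokenize_patient(p, v, max_len=4)
        assert seq.code_ids[0] == v.encode("A")
        assert seq.serialization_ids[0] == 1
        assert seq.visit_ids[0] == 1
        assert seq.n_real == 1

    def test_no_separator_tokens_inserted(self, prepared):
        _, vocab, corpus, _ = prepared
        for seq in corpus[:20]:
            real = seq.code_ids[: seq.n_real]
            assert (real >= N_RESERVED).all()  # only true codes, no specials

    def test_codeless_patient_raises(self):
        p = PatientRecord("x", 1960, Sex.MALE, ())
        with pytest.raises(DegenerateSequenceError):
            tokenize_patient(p, Vocabulary({"A": 3}), max_len=4)

    def test_round_trip_recovers_visit_structure(self, prepared):
        patients, vocab, corpus, _ = prepared
        for p, seq in list(zip(patients, corpus))[:30]:
            if p.total_code_count > 64:
                continue
            structure = [[c.code for c in v.codes] for v in p.visits if v.codes]
            assert detokenize(seq, vocab) == structure

    def test_truncation_keeps_most_recent_whole_visits(self):
        # 5 visits x 3 codes = 15 codes; max_len 7 fits the last 2 visits (6 codes)
        p = patient_with([[f"V{i}C{j}" for j in range(3)] for i in range(5)])
        v = build_vocabulary([p])
        seq = tokenize_patient(p, v, max_len=7)
        kept = [v.decode(int(i)) for i in seq.code_ids[: seq.n_real]]
        assert kept == ["V3C0", "V3C1", "V3C2", "V4C0", "V4C1", "V4C2"]
        assert seq.visit_ids[: seq.n_real].tolist() == [1, 1, 1, 2, 2, 2]

    def test_oversized_single_visit_keeps_highest_priority_codes(self):
        p = patient_with([[f"C{j}" for j in range(10)]])
        v = build_vocabulary([p])
        seq = tokenize_patient(p, v, max_len=4)
        kept = [v.decode(int(i)) for i in seq.code_ids[: seq.n_real]]
        assert kept == ["C0", "C1", "C2", "C3"]  # lowest serialization ids
        assert seq.serialization_ids[:4].tolist() == [1, 2, 3, 4]

    def test_truncation_matches_reference_rule(self):
        # independent reference: walk visits from the end, keep whole visits
        sizes = [4, 5, 6, 7, 8]
        p = patient_with([[f"V{i}C{j}" for j in range(s)] for i, s in enumerate(sizes)])
        v = build_vocabulary([p])
        max_len = 20
        seq = tokenize_patient(p, v, max_len=max_len)
        expected: list[str] = []
        total = 0
        for i in range(len(sizes) - 1, -1, -1):
            if total + sizes[i] > max_len:
                break
            expected = [f"V{i}C{j}" for j in range(sizes[i])] + expected
            total += sizes[i]
        kept = [v.decode(int(x)) for x in seq.code_ids[: seq.n_real]]
        assert kept == expected


class TestMasking:
    @pytest.fixture()
    def seq_and_vocab(self, prepared):
        _, vocab, corpus, _ = prepared
        return corpus[0], vocab

    def test_forced_mask_branch(self, seq_and_vocab):
        seq, vocab = seq_and_vocab
        ex = make_masked_example(seq, vocab, np.random.default_rng(0), force_branch=Branch.MASK)
        assert ex.input_ids[ex.target_position] == MASK_ID
        diffs = np.nonzero(ex.input_ids != seq.code_ids)[0]
        assert diffs.tolist() == [ex.target_position]

    def test_forced_keep_branch_leaves_input_unchanged(self, seq_and_vocab):
        seq, vocab = seq_and_vocab
        ex = make_masked_example(seq, vocab, np.random.default_rng(0), force_branch=Branch.KEEP)
        assert (ex.input_ids == seq.code_ids).all()

    def test_random_branch_never_reserved_never_original(self, seq_and_vocab):
        seq, vocab = seq_and_vocab
        rng = np.random.default_rng(1)
        for _ in range(200):
            ex = make_masked_example(seq, vocab, rng, force_branch=Branch.RANDOM)
            repl = ex.input_ids[ex.target_position]
            assert repl >= N_RESERVED
            assert repl != ex.target_id

    def test_target_always_on_real_position(self, seq_and_vocab):
        seq, vocab = seq_and_vocab
        rng = np.random.default_rng(2)
        for _ in range(300):
            ex = make_masked_example(seq, vocab, rng)
            assert 0 <= ex.target_position < seq.n_real
            assert ex.target_id == seq.code_ids[ex.target_position]

    def test_all_pad_sequence_raises(self, seq_and_vocab):
        _, vocab = seq_and_vocab
        empty = TokenizedSequence(
            "e",
            np.zeros(8, dtype=np.int64),
            np.zeros(8, dtype=np.int64),
            np.zeros(8, dtype=np.int64),
            np.zeros(8, dtype=np.int64),
        )
        with pytest.raises(DegenerateInputError):
            make_masked_example(empty, vocab, np.random.default_rng(0))

    def test_branch_frequencies_match_80_10_10(self, seq_and_vocab):
        # Monte-Carlo vs binomial 3-sigma bands at n=20,000
        seq, vocab = seq_and_vocab
        rng = np.random.default_rng(123)
        n = 20_000
        counts = {b: 0 for b in Branch}
        for _ in range(n):
            counts[make_masked_example(seq, vocab, rng).branch] += 1
        for branch, p in [(Branch.MASK, 0.8), (Branch.RANDOM, 0.1), (Branch.KEEP, 0.1)]:
            sigma = (p * (1 - p) / n) ** 0.5
            assert abs(counts[branch] / n - p) < 3 * sigma
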