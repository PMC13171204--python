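"""Tokenization, co-occurrence counting, PPMI, and word-level measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import semstim as ss
from semstim.corpus import OOVError

from conftest import brute_force_ppmi


class TestTokenize:
    def test_lowercase_and_punctuation(self):
        corpus = ss.tokenize_corpus(["The cat, the cat."])
        assert corpus.documents == [["the", "cat", "the", "cat"]]

    def test_structure_preserved(self):
        corpus = ss.tokenize_corpus(["A b", "c"])
        assert [len(d) for d in corpus.documents] == [2, 1]

    def test_hyphen_kept(self):
        corpus = ss.tokenize_corpus(["mother-in-law arrived!"])
        assert corpus.documents[0][0] == "mother-in-law"

    @pytest.mark.parametrize("docs", [[], [""], ["..."]])
    def test_empty_corpus_errors(self, docs):
        with pytest.raises(ValueError, match="empty corpus"):
            ss.tokenize_corpus(docs)


class TestCooccurrence:
    def test_hand_enumerated_pairs(self):
        corpus = ss.Corpus([["a", "b"], ["a", "c"]])
        counts = ss.build_cooccurrence(corpus, window=1)
        idx = counts.index
        assert counts.total_pairs == 4
        assert counts.pair_counts[idx["a"], idx["b"]] == 1
        assert counts.pair_counts[idx["b"], idx["a"]] == 1
        assert counts.pair_counts[idx["a"], idx["c"]] == 1
        assert counts.pair_counts[idx["b"], idx["c"]] == 0

    def test_single_token_document(self):
        counts = ss.build_cooccurrence(ss.Corpus([["solo"]]), window=5)
        assert counts.total_pairs == 0

    def test_min_count_filter(self):
        corpus = ss.Corpus([["a", "b"], ["a", "c"]])
        counts = ss.build_cooccurrence(corpus, window=1, min_count=2)
        assert counts.vocab == ["a"]

    def test_window_never_crosses_documents(self):
        corpus = ss.Corpus([["a"], ["b"]])
        counts = ss.build_cooccurrence(corpus, window=10)
        assert counts.total_pairs == 0

    def test_symmetric_matrix(self, tiny_corpus):
        counts = ss.build_cooccurrence(tiny_corpus, window=3)
        diff = (counts.pair_counts - counts.pair_counts.T)
        assert abs(diff).sum() == 0

    def test_bad_window(self, tiny_corpus):
        with pytest.raises(ValueError):
            ss.build_cooccurrence(tiny_corpus, window=0)


class TestPpmi:
    def test_hand_value(self):
        corpus = ss.Corpus([["a", "b"], ["a", "c"]])
        model = ss.ppmi_transform(ss.build_cooccurrence(corpus, window=1))
        idx = model.index
        # P(a,b)=1/4, P(a)=2/4, P(b)=1/4 -> log2(2) = 1
        assert model.vectors[idx["a"], idx["b"]] == pytest.approx(1.0)

    def test_zero_pairs_error(self):
        counts = ss.build_cooccurrence(ss.Corpus([["solo"]]), window=2)
        with pytest.raises(ValueError, match="no co-occurrences"):
            ss.ppmi_transform(counts)

    def test_matches_brute_force_oracle(self, tiny_corpus):
        counts = ss.build_cooccurrence(tiny_corpus, window=2)
        model = ss.ppmi_transform(counts)
        expected = brute_force_ppmi(counts)
        np.testing.assert_allclose(np.asarray(model.vectors.todense()),
                                   expected, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.sampled_from("abcdefghijklmno"),
                             min_size=1, max_size=12),
                    min_size=1, max_size=10),
           st.integers(min_value=1, max_value=4))
    def test_oracle_equivalence_random_corpora(self, docs, window):
        counts = ss.build_cooccurrence(ss.Corpus(docs), window=window)
        if counts.total_pairs == 0:
            return
        model = ss.ppmi_transform(counts)
        np.testing.assert_allclose(np.asarray(model.vectors.todense()),
                                   brute_force_ppmi(counts), atol=1e-12)

    def test_entries_nonnegative_and_dissimilarity_in_unit_interval(
            self, topic_setup):
        _, _, _, model = topic_setup
        assert (model.vectors.data >= 0).all()
        rng = np.random.default_rng(0)
        vocab = [w for w in model.vocab
                 if model.vector(w).count_nonzero() > 0]
        for _ in range(25):
            w1, w2 = rng.choice(vocab, 2, replace=False)
            d = model.dissimilarity(w1, w2)
            assert -1e-12 <= d <= 1.0 + 1e-12

    def test_smoothing_alpha_changes_context_distribution(self, tiny_corpus):
        counts = ss.build_cooccurrence(tiny_corpus, window=2)
        m1 = ss.ppmi_transform(counts, smoothing_alpha=1.0)
        m2 = ss.ppmi_transform(counts, smoothing_alpha=0.75)
        assert (m1.vectors - m2.vectors).toarray().any()


class TestCosine:
    def test_identical_and_scale_invariance(self):
        v = np.array([0.3, 1.2, 0.0, 4.0])
        assert ss.cosine_dissimilarity(v, v) == pytest.approx(0.0, abs=1e-12)
        assert ss.cosine_dissimilarity(v, 7.5 * v) == pytest.approx(
            0.0, abs=1e-12)

    def test_orthogonal(self):
        assert ss.cosine_dissimilarity([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert ss.cosine_dissimilarity([1, 1, 0], [0, 1, 1]) == pytest.approx(0.5)

    def test_zero_vector_error(self):
        with pytest.raises(ValueError, match="undefined similarity"):
            ss.cosine_dissimilarity([0, 0], [1, 1])


class TestSurprisal:
    @pytest.fixture
    def counts(self):
        return ss.build_cooccurrence(ss.Corpus([["a", "b"], ["a", "c"]]),
                                     window=1)

    def test_hand_value_one_bit(self, counts):
        assert ss.surprisal("a", "b", counts) == pytest.approx(1.0)

    def test_deterministic_context_zero_bits(self, counts):
        # b's only neighbour is a
        assert ss.surprisal("b", "a", counts) == pytest.approx(0.0)

    def test_unseen_pair_errors_without_smoothing(self, counts):
        with pytest.raises(ValueError, match="infinite surprisal"):
            ss.surprisal("b", "c", counts, add_k=0.0)

    def test_smoothing_makes_finite_and_monotone(self, counts):
        s_unseen = ss.surprisal("b", "c", counts, add_k=0.5)
        s_seen = ss.surprisal("b", "a", counts, add_k=0.5)
        assert np.isfinite(s_unseen)
        assert s_seen < s_unseen  # larger count -> lower surprisal
        assert s_unseen >= 0 and s_seen >= 0

    def test_oov_word(self, counts):
        with pytest.raises(OOVError):
            ss.surprisal("a", "zzz", counts)


class TestFrequencyAndLength:
    def test_log_frequency(self):
        table = ss.FrequencyTable(counts={"the": 1000, "cat": 1}, total=1001)
        assert ss.word_log_frequency("the", table) == pytest.approx(3.0)
        assert ss.word_log_frequency("cat", table) == pytest.approx(0.0)
        with pytest.raises(OOVError):
            ss.word_log_frequency("dog", table)

    def test_word_length(self):
        assert ss.word_length("cat") == 3
        assert ss.word_length("elephant") == 8
        with pytest.raises(ValueError):
            ss.word_length("")

    def test_frequency_table_roundtrip(self, tmp_path):
        path = tmp_path / "freq.csv"
        path.write_text("word,count\nthe,100\ncat,7\n")
        table = ss.FrequencyTable.from_file(path)
        assert table.counts == {"the": 100, "cat": 7}
        assert table.total == 107


class TestWordVectorAdapter:
    def test_word2vec_text_roundtrip(self, tmp_path):
        path = tmp_path / "vecs.txt"
        path.write_text("2 3\ncat 1 0 0\ndog 0 1 0\n")
        table = ss.load_word_vectors(path)
        assert table.vocab == ["cat", "dog"]
        assert table.dissimilarity("cat", "dog") == pytest.approx(1.0)

    def test_duplicate_words_rejected(self, tmp_path):
        path = tmp_path / "vecs.txt"
        path.write_text("2 2\ncat 1 0\ncat 0 1\n")
        with pytest.raises(ValueError, match="duplicate"):
            ss.load_word_vectors(path)
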