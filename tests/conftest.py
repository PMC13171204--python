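import numpy as np
import pytest

import semstim as ss


@pytest.fixture(scope="session")
def tiny_corpus():
    return ss.tokenize_corpus([
        "the cat sat on the mat",
        "the dog sat on the log",
        "wine glass beer glass",
        "cat dog cat dog",
    ])


@pytest.fixture(scope="session")
def lexicon():
    return ss.generate_lexicon(vocab_size=120, seed=11)


@pytest.fixture(scope="session")
def topic_setup(lexicon):
    """Lexicon + topic corpus + PPMI model shared by the slower tests."""
    corpus = ss.generate_corpus(lexicon, n_tokens=20_000, n_topics=4, seed=12)
    counts = ss.build_cooccurrence(corpus, window=5)
    model = ss.ppmi_transform(counts)
    return lexicon, corpus, counts, model


def brute_force_ppmi(counts):
    """Independent PPMI oracle: explicit loops over the probability table."""
    n = len(counts.vocab)
    pair = np.asarray(counts.pair_counts.todense(), dtype=float)
    total = pair.sum()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if pair[i, j] == 0:
                continue
            p_wc = pair[i, j] / total
            p_w = pair[i, :].sum() / total
            p_c = pair[:, j].sum() / total
            out[i, j] = max(0.0, np.log2(p_wc / (p_w * p_c)))
    return out


@pytest.fixture(scope="session")
def copula_experiment():
    table, gt = ss.simulate_copula_experiment(0.5, n_subjects=20,
                                              n_trials=100, seed=42)
    return table, gt


def aligned_predictor(gt, keep, which="z_semantic"):
    """Ground-truth predictor column subset to the prepared table's rows."""
    col = ss.ground_truth_predictor(gt, which)
    return ss.PredictorColumn(name=which, values=col.values[keep],
                              mask=col.mask[keep])
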