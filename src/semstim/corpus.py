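"""Distributional-semantic model and word-level information measures.

Builds a sparse PPMI (Positive Pointwise Mutual Information) word-vector
space from a tokenized corpus and exposes the four word-level measures the
analysis correlates with response times: cosine dissimilarity between two
words' vectors, surprisal of a word given a context word, (negative) log10
frequency, and orthographic length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Corpus",
    "CooccurrenceCounts",
    "PpmiModel",
    "WordVectorTable",
    "FrequencyTable",
    "OOVError",
    "tokenize_corpus",
    "build_cooccurrence",
    "ppmi_transform",
    "cosine_dissimilarity",
    "surprisal",
    "word_log_frequency",
    "word_length",
    "load_word_vectors",
]


class OOVError(KeyError):
    """A word required by a trial is absent from the model/frequency table."""


# Leading/trailing punctuation is stripped; intra-word hyphens survive.
_EDGE_PUNCT = re.compile(r"^[\W_]+|[\W_]+$", flags=re.UNICODE)


@dataclass
class Corpus:
    """Ordered sequences of lowercase word tokens, one list per document."""

    documents: list[list[str]]

    def __post_init__(self) -> None:
        if not self.documents:
            raise ValueError("empty corpus")
        for doc in self.documents:
            if not doc or any(not tok for tok in doc):
                raise ValueError("documents must contain non-empty tokens")

    def __len__(self) -> int:
        return len(self.documents)

    @classmethod
    def from_file(cls, path: str | Path) -> "Corpus":
        """Read a plain-text corpus, one document per line (UTF-8)."""
        text = Path(path).read_text(encoding="utf-8")
        return tokenize_corpus(text.splitlines())


def tokenize_corpus(raw_documents: list[str]) -> Corpus:
    """Lowercase and punctuation-strip raw documents into a :class:`Corpus`.

    Tokens are whitespace-separated; leading/trailing punctuation is removed
    (intra-word hyphens are kept); documents left empty are dropped.
    """
    docs: list[list[str]] = []
    for raw in raw_documents:
        toks = []
        for piece in raw.lower().split():
            # keep internal hyphens, e.g. "mother-in-law"
            tok = _EDGE_PUNCT.sub("", piece)
            if tok:
                toks.append(tok)
        if toks:
            docs.append(toks)
    if not docs:
        raise ValueError("empty corpus")
    return Corpus(docs)


@dataclass
class CooccurrenceCounts:
    """Ordered-pair co-occurrence counts within a symmetric token window.

    ``pair_counts[i, j]`` is the number of (position-level) ordered
    occurrences of word ``j`` within ``window`` tokens of word ``i`` in the
    same document.  With a symmetric window the matrix is symmetric.
    """

    vocab: list[str]
    pair_counts: sparse.csr_matrix
    unigram_counts: np.ndarray
    window: int
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.vocab)}

    @property
    def total_pairs(self) -> int:
        return int(self.pair_counts.sum())


def build_cooccurrence(corpus: Corpus, window: int = 5,
                       min_count: int = 1) -> CooccurrenceCounts:
    """Count ordered co-occurrences within ``±window`` tokens per document.

    Words with corpus unigram count below ``min_count`` are removed from the
    vocabulary; token positions are preserved when counting (a removed word
    does not close the gap between its neighbours).  Windows never cross
    document boundaries.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")

    raw_counts: dict[str, int] = {}
    for doc in corpus.documents:
        for tok in doc:
            raw_counts[tok] = raw_counts.get(tok, 0) + 1
    vocab = sorted(w for w, c in raw_counts.items() if c >= min_count)
    index = {w: i for i, w in enumerate(vocab)}
    n = len(vocab)

    rows: list[int] = []
    cols: list[int] = []
    for doc in corpus.documents:
        ids = [index.get(tok, -1) for tok in doc]
        for pos, wi in enumerate(ids):
            if wi < 0:
                continue
            hi = min(len(ids), pos + window + 1)
            for other in range(pos + 1, hi):
                wj = ids[other]
                if wj < 0:
                    continue
                rows.append(wi)
                cols.append(wj)
                rows.append(wj)
                cols.append(wi)
    data = np.ones(len(rows), dtype=np.int64)
    pair = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    unigrams = np.array([raw_counts[w] for w in vocab], dtype=np.int64)
    return CooccurrenceCounts(vocab=vocab, pair_counts=pair,
                              unigram_counts=unigrams, window=window,
                              index=index)


@dataclass
class PpmiModel:
    """Sparse PPMI word vectors: one row of max(0, log2 P(w,c)/(P(w)P(c))) per word."""

    vocab: list[str]
    vectors: sparse.csr_matrix
    unigram_counts: np.ndarray
    total_pairs: int
    window: int = 5
    smoothing_alpha: float = 1.0
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.vocab)}

    def vector(self, word: str) -> sparse.csr_matrix:
        try:
            i = self.index[word]
        except KeyError:
            raise OOVError(word) from None
        return self.vectors.getrow(i)

    def dissimilarity(self, word1: str, word2: str) -> float:
        """1 − cosine similarity between two words' PPMI vectors."""
        return cosine_dissimilarity(self.vector(word1), self.vector(word2))


def ppmi_transform(counts: CooccurrenceCounts,
                   smoothing_alpha: float = 1.0) -> PpmiModel:
    """PPMI re-weighting of a co-occurrence matrix.

    entry(w, c) = max(0, log2[ P(w,c) / (P(w) · P_α(c)) ]) with
    P(w,c) = pair_count / total_pairs, P(w) the row mass, and P_α(c) the
    context (column) distribution raised to ``smoothing_alpha`` and
    renormalized (α = 1 disables smoothing, the default).
    """
    total = counts.total_pairs
    if total == 0:
        raise ValueError("no co-occurrences")
    pair = counts.pair_counts.tocoo()
    row_mass = np.asarray(counts.pair_counts.sum(axis=1)).ravel() / total
    col_mass = np.asarray(counts.pair_counts.sum(axis=0)).ravel() / total
    ctx = col_mass**smoothing_alpha
    ctx = ctx / ctx.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2((pair.data / total)
                       / (row_mass[pair.row] * ctx[pair.col]))
    vals = np.maximum(vals, 0.0)
    mat = sparse.coo_matrix((vals, (pair.row, pair.col)),
                            shape=pair.shape).tocsr()
    mat.eliminate_zeros()
    return PpmiModel(vocab=list(counts.vocab), vectors=mat,
                     unigram_counts=counts.unigram_counts.copy(),
                     total_pairs=total, window=counts.window,
                     smoothing_alpha=smoothing_alpha)


def cosine_dissimilarity(v1, v2) -> float:
    """1 − cosine similarity; in [0, 1] for nonnegative vectors, else [0, 2].

    Raises ValueError on a zero-norm vector — the caller decides whether the
    trial is excluded.
    """
    a = np.asarray(v1.todense()).ravel() if sparse.issparse(v1) else np.asarray(v1, dtype=float).ravel()
    b = np.asarray(v2.todense()).ravel() if sparse.issparse(v2) else np.asarray(v2, dtype=float).ravel()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("undefined similarity")
    return float(1.0 - (a @ b) / (na * nb))


def surprisal(context_word: str, target_word: str,
              counts: CooccurrenceCounts, add_k: float = 0.0) -> float:
    """−log2 P̂(target | context) in bits, with add-k smoothing.

    P̂ = (pair_count + k) / (context row total + k · |vocab|); finite for any
    pair whenever ``add_k > 0``.
    """
    if add_k < 0:
        raise ValueError("add_k must be >= 0")
    for w in (context_word, target_word):
        if w not in counts.index:
            raise OOVError(w)
    ci = counts.index[context_word]
    ti = counts.index[target_word]
    pair = counts.pair_counts[ci, ti]
    row_total = counts.pair_counts.getrow(ci).sum()
    num = pair + add_k
    den = row_total + add_k * len(counts.vocab)
    if num == 0 or den == 0:
        raise ValueError("infinite surprisal")
    return float(-np.log2(num / den))


@dataclass
class FrequencyTable:
    """Word → occurrence count, with the total token mass of the source."""

    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("frequency counts must be >= 1")

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "FrequencyTable":
        counts: dict[str, int] = {}
        for doc in corpus.documents:
            for tok in doc:
                counts[tok] = counts.get(tok, 0) + 1
        return cls(counts=counts, total=sum(counts.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "FrequencyTable":
        """Two-column delimited text (word, count) with a header row."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise ValueError("frequency table needs two columns (word, count)")
        words = df.iloc[:, 0].astype(str)
        counts = df.iloc[:, 1].astype(int)
        return cls(counts=dict(zip(words, counts)), total=int(counts.sum()))

    def __contains__(self, word: str) -> bool:
        return word in self.counts


def word_log_frequency(word: str, freq: FrequencyTable) -> float:
    """log10 of a word's occurrence count; raises :class:`OOVError` if missing."""
    if word not in freq.counts:
        raise OOVError(word)
    return float(np.log10(freq.counts[word]))


def word_length(word: str) -> int:
    """Number of characters (orthographic length)."""
    if not word:
        raise ValueError("empty word")
    return len(word)


@dataclass
class WordVectorTable:
    """Adapter for externally trained dense embeddings (word2vec text format)."""

    vocab: list[str]
    vectors: np.ndarray
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("duplicate words in vector table")
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocab):
            raise ValueError("one vector row per word required")
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.vocab)}

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self.index[word]]
        except KeyError:
            raise OOVError(word) from None

    def dissimilarity(self, word1: str, word2: str) -> float:
        return cosine_dissimilarity(self.vector(word1), self.vector(word2))


def load_word_vectors(path: str | Path) -> WordVectorTable:
    """Read word2vec text format: header line "vocab_size dim", then rows."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError("empty vector file")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError('expected header line "vocab_size dim"')
    n, dim = int(header[0]), int(header[1])
    vocab: list[str] = []
    rows = np.empty((n, dim), dtype=float)
    for k, line in enumerate(lines[1:n + 1]):
        parts = line.rstrip().split(" ")
        if len(parts) != dim + 1:
            raise ValueError(f"row {k + 1}: expected {dim} values")
        vocab.append(parts[0])
        rows[k] = [float(x) for x in parts[1:]]
    if len(vocab) != n:
        raise ValueError("fewer rows than the header promises")
    return WordVectorTable(vocab=vocab, vectors=rows)
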