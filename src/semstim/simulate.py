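"""Synthetic corpora and multi-subject stimulation experiments.

Ground-truth generators for every pipeline stage: a Zipfian lexicon whose
word lengths correlate negatively with log frequency (as in natural
languages), a topic-structured corpus so that PPMI cosine distances carry
recoverable semantic structure, and a trial-level experiment generator in
which log response time is a linear function of standardized semantic
dissimilarity, negative log10 frequency, and summed word length, plus a
subject-level random intercept and Gaussian noise.  The semantic slope may
differ between the control and effective-stimulation conditions — the
causal effect the pipeline is built to detect.

Because effects are expressed on within-condition standardized predictors
and the default noise completes the latent variance to 1, each beta is
directly the population Pearson correlation between its predictor and
(latent) log RT, which makes closed-form checks possible (for jointly
Gaussian predictor/outcome pairs the expected Spearman correlation is
(6/π)·asin(r/2)).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .corpus import Corpus, FrequencyTable, PpmiModel
from .trials import PredictorColumn, TrialTable

__all__ = ["SimConfig", "Lexicon", "GroundTruth", "generate_lexicon",
           "generate_corpus", "simulate_experiment",
           "simulate_copula_experiment", "ground_truth_predictor"]

_LETTERS = np.array(list(string.ascii_lowercase))


@dataclass
class SimConfig:
    """Generative settings for one simulated stimulation experiment.

    ``beta_*`` are slopes on within-condition z-scored predictors; with
    ``noise_sd=None`` the residual sd is chosen per condition as
    sqrt(1 − Σβ²) so each beta equals the predictor's population
    correlation with latent log RT.  ``rt_log_scale`` maps the latent
    unit-variance effect scale into log-milliseconds (it rescales effect
    and noise jointly, so correlations are unaffected).
    """

    n_subjects: int = 20
    n_trials_per_condition: int = 60
    control_label: str = "vertex"
    effective_labels: tuple[str, ...] = ("effective",)
    beta_semantic: dict[str, float] = field(
        default_factory=lambda: {"vertex": 0.3, "effective": 0.3})
    beta_frequency: float = 0.2
    beta_length: float = 0.1
    subject_intercept_sd: float = 0.1
    noise_sd: float | None = None
    vocab_size: int = 300
    zipf_exponent: float = 1.1
    mean_word_length: float = 6.0
    length_frequency_corr: float = 0.3
    master_seed: int = 0
    predictor_mode: Literal["lexicon", "gaussian"] = "lexicon"
    share_items_across_conditions: bool = True
    p_correct: float = 0.95
    couple_correctness: bool = False
    base_rt_ms: float = 650.0
    rt_log_scale: float = 0.12
    study_id: str = "synthetic"

    @property
    def conditions(self) -> tuple[str, ...]:
        return (self.control_label, *self.effective_labels)

    def __post_init__(self) -> None:
        if self.vocab_size < 50:
            raise ValueError("vocab_size must be >= 50")
        if self.n_trials_per_condition < 25:
            raise ValueError("need at least 25 trials per condition")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        missing = [c for c in self.conditions if c not in self.beta_semantic]
        if missing:
            raise ValueError(f"beta_semantic missing condition(s): {missing}")

    def condition_noise_sd(self, condition: str) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        total = (self.beta_semantic[condition]**2 + self.beta_frequency**2
                 + self.beta_length**2)
        return float(np.sqrt(max(1.0 - total, 0.05)))


@dataclass
class Lexicon:
    """Zipfian vocabulary with lengths anti-correlated with log frequency."""

    words: list[str]
    lengths: np.ndarray
    counts: np.ndarray
    frequency_table: FrequencyTable


@dataclass
class GroundTruth:
    """Realized standardized predictors and the coefficients that made the RTs."""

    predictors: pd.DataFrame      # z_semantic, z_frequency, z_length per trial
    beta_semantic: dict[str, float]
    beta_frequency: float
    beta_length: float
    noise_sd_by_condition: dict[str, float]
    config: SimConfig


def _make_word(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_LETTERS, size=length))


def generate_lexicon(vocab_size: int = 300, zipf_exponent: float = 1.1,
                     mean_word_length: float = 6.0,
                     length_frequency_corr: float = 0.3,
                     total_tokens: int = 1_000_000,
                     seed: int = 0) -> Lexicon:
    """Zipfian frequencies plus correlated word lengths.

    Rank-r frequency is proportional to r^(−zipf_exponent).  Lengths are
    drawn through a Gaussian coupling so that corr(length, log10 freq)
    ≈ −length_frequency_corr, the empirical regularity that frequent words
    tend to be short.
    """
    if vocab_size < 50:
        raise ValueError("vocab_size must be >= 50")
    if not 0 <= length_frequency_corr < 1:
        raise ValueError("length_frequency_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, vocab_size + 1)
    mass = ranks**(-float(zipf_exponent))
    counts = np.maximum(1, np.round(mass / mass.sum() * total_tokens)
                        ).astype(np.int64)
    logf = np.log10(counts)
    zf = (logf - logf.mean()) / logf.std()
    c = length_frequency_corr
    eps = rng.standard_normal(vocab_size)
    latent = -c * zf + np.sqrt(1.0 - c * c) * eps
    lengths = np.clip(np.round(mean_word_length + 2.0 * latent),
                      2, 15).astype(int)

    words: list[str] = []
    seen: set[str] = set()
    for L in lengths:
        w = _make_word(rng, L)
        while w in seen:
            w = _make_word(rng, L)
        seen.add(w)
        words.append(w)
    table = FrequencyTable(counts=dict(zip(words, counts.tolist())),
                           total=int(counts.sum()))
    return Lexicon(words=words, lengths=lengths, counts=counts,
                   frequency_table=table)


def generate_corpus(lexicon: Lexicon, n_tokens: int = 50_000,
                    n_topics: int = 5, doc_length: int = 100,
                    within_topic_prob: float = 0.85,
                    seed: int = 0) -> Corpus:
    """Topic-structured corpus: words of the same latent topic co-occur more.

    Words are assigned to topics by interleaving frequency ranks (each
    topic spans the whole frequency range); each document commits to one
    topic and samples tokens from it with probability ``within_topic_prob``
    (frequency-weighted), otherwise from the full vocabulary.  PPMI cosine
    distances on such a corpus separate within-topic from between-topic
    word pairs.
    """
    V = len(lexicon.words)
    if n_tokens < 10 * V:
        raise ValueError("n_tokens must be at least 10x the vocabulary size")
    rng = np.random.default_rng(seed)
    topic_of = np.arange(V) % n_topics
    global_p = lexicon.counts / lexicon.counts.sum()
    topic_p = []
    for t in range(n_topics):
        w = np.where(topic_of == t, lexicon.counts, 0).astype(float)
        topic_p.append(w / w.sum())
    word_arr = np.array(lexicon.words)

    docs: list[list[str]] = []
    n_docs = max(1, n_tokens // doc_length)
    for _ in range(n_docs):
        t = int(rng.integers(n_topics))
        use_topic = rng.random(doc_length) < within_topic_prob
        ids = np.where(use_topic,
                       rng.choice(V, size=doc_length, p=topic_p[t]),
                       rng.choice(V, size=doc_length, p=global_p))
        docs.append(word_arr[ids].tolist())
    return Corpus(docs)


def _sample_pairs(rng, n, valid_idx, weights):
    i = rng.choice(valid_idx, size=n, p=weights)
    j = rng.choice(valid_idx, size=n, p=weights)
    clash = i == j
    while clash.any():
        j[clash] = rng.choice(valid_idx, size=int(clash.sum()), p=weights)
        clash = i == j
    return i, j


def simulate_experiment(cfg: SimConfig, lexicon: Lexicon | None = None,
                        ppmi: PpmiModel | None = None,
                        ) -> tuple[TrialTable, GroundTruth]:
    """One multi-subject, multi-condition experiment with known ground truth.

    In ``lexicon`` mode the per-trial predictors are computed from sampled
    word pairs through the supplied PPMI model and lexicon (exactly what
    the analysis pipeline will later recompute from the written table); in
    ``gaussian`` mode the three standardized predictors are independent
    standard normals, useful when orthogonal confounds are needed by
    construction.  Log RT = base + subject intercept +
    rt_log_scale · (β·z + noise); correctness is Bernoulli and, by default,
    independent of everything else.
    """
    rng = np.random.default_rng(cfg.master_seed)
    n_cond = len(cfg.conditions)
    n_per = cfg.n_subjects * cfg.n_trials_per_condition
    subjects = [f"S{k:03d}" for k in range(cfg.n_subjects)]
    intercepts = rng.normal(0.0, cfg.subject_intercept_sd, cfg.n_subjects)

    if cfg.predictor_mode == "lexicon":
        if lexicon is None or ppmi is None:
            raise ValueError("lexicon mode needs a lexicon and a PPMI model")
        # dense unit-norm vectors once; words with all-zero vectors excluded
        dense = np.asarray(ppmi.vectors.todense())
        norms = np.linalg.norm(dense, axis=1)
        in_model = np.array([ppmi.index.get(w, -1) for w in lexicon.words])
        valid = np.flatnonzero((in_model >= 0)
                               & (norms[np.maximum(in_model, 0)] > 0))
        if valid.size < 20:
            raise ValueError("too few usable words with nonzero vectors")
        unit = dense / np.where(norms[:, None] > 0, norms[:, None], 1.0)
        weights = lexicon.counts[valid].astype(float)
        weights /= weights.sum()

    def draw_items():
        if cfg.predictor_mode == "lexicon":
            i_idx, j_idx = _sample_pairs(rng, n_per, valid, weights)
            words1 = [lexicon.words[i] for i in i_idx]
            words2 = [lexicon.words[j] for j in j_idx]
            vi = in_model[i_idx]
            vj = in_model[j_idx]
            dissim = 1.0 - np.einsum("ij,ij->i", unit[vi], unit[vj])
            neg_logf = -(np.log10(lexicon.counts[i_idx])
                         + np.log10(lexicon.counts[j_idx]))
            length = (lexicon.lengths[i_idx]
                      + lexicon.lengths[j_idx]).astype(float)
            return words1, words2, np.column_stack([dissim, neg_logf,
                                                    length])
        words1 = [f"w{k % 97:02d}a" for k in range(n_per)]
        words2 = [f"w{k % 89:02d}b" for k in range(n_per)]
        return words1, words2, rng.standard_normal((n_per, 3))

    # within-subject designs typically present the same item set under
    # every stimulation condition; resampling per condition is the switch
    shared = draw_items() if cfg.share_items_across_conditions else None

    rows = []
    gt_rows = []
    for cond in cfg.conditions:
        w1, w2, raw = shared if shared is not None else draw_items()
        z = (raw - raw.mean(axis=0)) / raw.std(axis=0)

        noise_sd = cfg.condition_noise_sd(cond)
        noise = rng.normal(0.0, noise_sd, n_per)
        eta = (cfg.beta_semantic[cond] * z[:, 0]
               + cfg.beta_frequency * z[:, 1]
               + cfg.beta_length * z[:, 2] + noise)
        subj_col = np.repeat(np.arange(cfg.n_subjects),
                             cfg.n_trials_per_condition)
        log_rt = (np.log(cfg.base_rt_ms) + intercepts[subj_col]
                  + cfg.rt_log_scale * eta)
        rt = np.exp(log_rt)
        if cfg.couple_correctness:
            # harder (slower-expected) trials slightly more error-prone
            p = np.clip(cfg.p_correct - 0.05 * eta, 0.5, 1.0)
        else:
            p = np.full(n_per, cfg.p_correct)
        correct = rng.random(n_per) < p

        for k in range(n_per):
            rows.append((subjects[subj_col[k]], cond, w1[k], w2[k],
                         float(rt[k]), bool(correct[k])))
            gt_rows.append((z[k, 0], z[k, 1], z[k, 2]))

    data = pd.DataFrame(rows, columns=["subject", "condition", "word1",
                                       "word2", "rt", "correct"])
    data["word2"] = data["word2"].astype(object)
    data["response_word"] = pd.NA
    table = TrialTable(data=data, study_id=cfg.study_id,
                       control_condition=cfg.control_label)
    gt = GroundTruth(
        predictors=pd.DataFrame(gt_rows, columns=["z_semantic",
                                                  "z_frequency", "z_length"]),
        beta_semantic=dict(cfg.beta_semantic),
        beta_frequency=cfg.beta_frequency,
        beta_length=cfg.beta_length,
        noise_sd_by_condition={c: cfg.condition_noise_sd(c)
                               for c in cfg.conditions},
        config=cfg)
    return table, gt


def simulate_copula_experiment(r: float, n_subjects: int = 20,
                               n_trials: int = 200, seed: int = 0,
                               ) -> tuple[TrialTable, GroundTruth]:
    """Single-condition experiment whose predictor/log-RT pairs are
    bivariate Gaussian with Pearson correlation ``r`` within subject.

    The expected within-subject Spearman correlation is then the classic
    (6/π)·asin(r/2), giving the bootstrap engine a closed-form target.
    """
    cfg = SimConfig(n_subjects=n_subjects, n_trials_per_condition=n_trials,
                    control_label="control", effective_labels=(),
                    beta_semantic={"control": float(r)},
                    beta_frequency=0.0, beta_length=0.0,
                    predictor_mode="gaussian", p_correct=1.0,
                    master_seed=seed)
    return simulate_experiment(cfg)


def ground_truth_predictor(gt: GroundTruth,
                           which: Literal["z_semantic", "z_frequency",
                                          "z_length"]) -> PredictorColumn:
    """Wrap a realized generator predictor as a pipeline PredictorColumn."""
    values = gt.predictors[which].to_numpy(dtype=float)
    return PredictorColumn(name=which, values=values,
                           mask=np.zeros(values.size, dtype=bool))
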