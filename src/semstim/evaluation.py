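"""Model-selection harness: score word-level measures against RT norms.

Candidate word-level predictors (e.g. surprisal given a reference context,
negative log frequency, or any externally computed per-word scalar) are
scored by their Spearman correlation with an independent per-word response
time norm (such as lexical-decision megastudy means), and ranked so the
best-performing model can be carried into the main trial-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import spearman_rho

__all__ = ["NormScore", "evaluate_predictor_vs_norms", "rank_models",
           "load_norm_table"]

MIN_OVERLAP = 10


@dataclass
class NormScore:
    """Spearman score of one candidate against the norm, with its overlap."""

    name: str
    rho: float
    n_overlap: int


def load_norm_table(path: str | Path) -> dict[str, float]:
    """Two-column delimited text (word, mean RT) with a header row."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("norm table needs two columns (word, value)")
    return dict(zip(df.iloc[:, 0].astype(str).str.lower(),
                    df.iloc[:, 1].astype(float)))


def evaluate_predictor_vs_norms(per_word_values: dict[str, float],
                                norm_rts: dict[str, float],
                                name: str = "candidate") -> NormScore:
    """Spearman ρ between predictor values and norm RTs over the word overlap.

    The overlap is computed case-insensitively and must contain at least
    10 words.
    """
    pred = {str(w).lower(): v for w, v in per_word_values.items()}
    norm = {str(w).lower(): v for w, v in norm_rts.items()}
    overlap = sorted(set(pred) & set(norm))
    if len(overlap) < MIN_OVERLAP:
        raise ValueError(
            f"insufficient overlap: {len(overlap)} < {MIN_OVERLAP}")
    x = np.array([pred[w] for w in overlap])
    y = np.array([norm[w] for w in overlap])
    return NormScore(name=name, rho=spearman_rho(x, y),
                     n_overlap=len(overlap))


def rank_models(candidate_scores: dict[str, float],
                ) -> tuple[list[tuple[str, float]], bool]:
    """Order candidates by descending score; ties broken by name, flagged."""
    if not candidate_scores:
        raise ValueError("need at least one candidate")
    ordered = sorted(candidate_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    values = [v for _, v in ordered]
    tie = len(set(values)) < len(values)
    return ordered, tie
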