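"""Trial-level behavioral data: loading, filtering, transforms, predictors.

A trial couples one or two stimulus words (and optionally a response word)
with a response time and a correctness flag under one stimulation condition.
Each competing information model (semantic dissimilarity, surprisal,
negative log frequency, orthographic length) is attached as a per-trial
predictor column, oriented so that larger values mean more predicted
cognitive effort and hence an expected positive correlation with RT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .corpus import (CooccurrenceCounts, FrequencyTable, OOVError, PpmiModel,
                     WordVectorTable, surprisal, word_length,
                     word_log_frequency)

__all__ = [
    "TrialTable",
    "PredictorSpec",
    "PredictorColumn",
    "load_trials",
    "filter_correct",
    "log_transform_rts",
    "attach_predictor",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject", "condition", "word1", "rt", "correct")
OPTIONAL_COLUMNS = ("word2", "response_word")

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


@dataclass
class TrialTable:
    """Per-trial records of one study plus its condition layout.

    ``data`` columns: subject, condition, word1, word2 (may be NA),
    response_word (may be NA), rt, correct.  ``rt`` is milliseconds until
    :func:`log_transform_rts` flips ``log_transformed``.
    """

    data: pd.DataFrame
    study_id: str = "study"
    control_condition: str = "control"
    log_transformed: bool = False
    bad_rows: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing column {missing[0]}")
        for c in OPTIONAL_COLUMNS:
            if c not in self.data.columns:
                self.data[c] = pd.NA

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def replace_data(self, data: pd.DataFrame, **kw) -> "TrialTable":
        out = TrialTable(data=data, study_id=self.study_id,
                         control_condition=self.control_condition,
                         log_transformed=self.log_transformed,
                         bad_rows=self.bad_rows)
        for k, v in kw.items():
            setattr(out, k, v)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _parse_correct(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"unparseable correctness flag: {value!r}")


def load_trials(path: str | Path, column_map: Optional[dict[str, str]] = None,
                study_id: str = "study",
                control_condition: str = "control") -> TrialTable:
    """Read a delimited trial table (comma or tab, sniffed from the header).

    ``column_map`` maps canonical field names (subject, condition, word1,
    word2, response_word, rt, correct) to the file's column names.  Malformed
    rows (non-numeric rt, bad correctness flag) are collected into
    ``TrialTable.bad_rows``, never silently dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column {missing[0]}")

    good_idx, bad_idx, reasons = [], [], []
    rts, corrects = [], []
    for i, row in df.iterrows():
        try:
            rt = float(row["rt"])
            if not np.isfinite(rt) or rt <= 0:
                raise ValueError(f"nonpositive rt {row['rt']!r}")
            corr = _parse_correct(row["correct"])
        except (TypeError, ValueError) as exc:
            bad_idx.append(i)
            reasons.append(str(exc))
            continue
        good_idx.append(i)
        rts.append(rt)
        corrects.append(corr)

    good = df.loc[good_idx].copy()
    good["rt"] = rts
    good["correct"] = corrects
    bad = df.loc[bad_idx].copy()
    bad["error"] = reasons
    if len(bad):
        log.warning("%s: %d malformed rows collected", path, len(bad))
    return TrialTable(data=good.reset_index(drop=True), study_id=study_id,
                      control_condition=control_condition,
                      bad_rows=bad if len(bad) else None)


def filter_correct(table: TrialTable) -> TrialTable:
    """Keep only correct trials; subjects left with zero trials are dropped."""
    kept = table.data[table.data["correct"].astype(bool)]
    for subj in table.subjects:
        n_before = int((table.data["subject"] == subj).sum())
        n_after = int((kept["subject"] == subj).sum())
        if n_after == 0:
            log.warning("subject %s has no correct trials; dropped", subj)
        else:
            log.debug("subject %s: %d/%d correct trials", subj, n_after, n_before)
    return table.replace_data(kept.reset_index(drop=True))


def log_transform_rts(table: TrialTable) -> TrialTable:
    """Replace rt by its natural logarithm (idempotence guarded by a flag)."""
    if table.log_transformed:
        raise ValueError("RTs are already log-transformed")
    rt = table.data["rt"].to_numpy(dtype=float)
    bad = np.flatnonzero(rt <= 0)
    if bad.size:
        raise ValueError(f"nonpositive rt at rows {bad.tolist()}")
    data = table.data.copy()
    data["rt"] = np.log(rt)
    return table.replace_data(data, log_transformed=True)


Level = Literal["semantic_dissimilarity", "surprisal",
                "neg_log_frequency", "length"]
Aggregation = Literal["sum", "first_word", "second_word"]


@dataclass
class PredictorSpec:
    """One competing information model: level × word-aggregation × source.

    ``source`` is a :class:`PpmiModel` or :class:`WordVectorTable` for the
    semantic level, a :class:`CooccurrenceCounts` for surprisal, a
    :class:`FrequencyTable` for frequency, and ``None`` for length.
    ``surprisal_add_k`` is the add-k smoothing constant for surprisal.
    """

    level: Level
    aggregation: Aggregation = "sum"
    source: object = None
    surprisal_add_k: float = 1.0

    @property
    def name(self) -> str:
        return (self.level if self.aggregation == "sum"
                else f"{self.level}:{self.aggregation}")


@dataclass
class PredictorColumn:
    """Per-trial predictor values aligned to a TrialTable, plus exclusions.

    ``values[i]`` is NaN exactly where ``mask[i]`` is True; ``reasons`` maps
    masked row positions to a short exclusion reason (e.g. "oov:word").
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.mask != np.isnan(self.values)):
            raise ValueError("mask and NaN values must coincide")

    @property
    def n_excluded(self) -> int:
        return int(self.mask.sum())


def _trial_words(row, aggregation: Aggregation) -> list[str]:
    w1 = row["word1"] if pd.notna(row["word1"]) else None
    w2 = row["word2"] if pd.notna(row["word2"]) else None
    if aggregation == "first_word":
        words = [w1]
    elif aggregation == "second_word":
        words = [w2]
    else:  # sum: all available words (single-word trials use the one word)
        words = [w for w in (w1, w2) if w is not None]
    if any(w is None for w in words) or not words:
        raise ValueError("missing word")
    return words


def attach_predictor(table: TrialTable, spec: PredictorSpec) -> PredictorColumn:
    """Compute one predictor value per trial under ``spec``.

    Out-of-vocabulary words (or undefined similarities) mask the trial with a
    reason instead of imputing a value; exclusion counts are logged.
    """
    n = len(table.data)
    values = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    reasons: dict[int, str] = {}

    if spec.level == "semantic_dissimilarity":
        if table.data["word2"].isna().any():
            raise ValueError("needs two words")
        model = spec.source
        if not isinstance(model, (PpmiModel, WordVectorTable)):
            raise TypeError("semantic level needs a PpmiModel or WordVectorTable")
        for i, row in enumerate(table.data.itertuples(index=False)):
            try:
                values[i] = model.dissimilarity(row.word1, row.word2)
            except OOVError as exc:
                mask[i] = True
                reasons[i] = f"oov:{exc.args[0]}"
            except ValueError:
                mask[i] = True
                reasons[i] = "undefined_similarity"
    elif spec.level == "surprisal":
        counts = spec.source
        if not isinstance(counts, CooccurrenceCounts):
            raise TypeError("surprisal needs CooccurrenceCounts")
        if table.data["word2"].isna().any():
            raise ValueError("needs two words")
        for i, row in enumerate(table.data.itertuples(index=False)):
            try:
                values[i] = surprisal(row.word1, row.word2, counts,
                                      add_k=spec.surprisal_add_k)
            except OOVError as exc:
                mask[i] = True
                reasons[i] = f"oov:{exc.args[0]}"
            except ValueError:
                mask[i] = True
                reasons[i] = "infinite_surprisal"
    elif spec.level == "neg_log_frequency":
        freq = spec.source
        if not isinstance(freq, FrequencyTable):
            raise TypeError("frequency level needs a FrequencyTable")
        for i, row in table.data.iterrows():
            try:
                words = _trial_words(row, spec.aggregation)
                values[i] = -sum(word_log_frequency(w, freq) for w in words)
            except OOVError as exc:
                mask[i] = True
                reasons[i] = f"oov:{exc.args[0]}"
            except ValueError:
                mask[i] = True
                reasons[i] = "missing_word"
    elif spec.level == "length":
        for i, row in table.data.iterrows():
            try:
                words = _trial_words(row, spec.aggregation)
                values[i] = sum(word_length(w) for w in words)
            except ValueError:
                mask[i] = True
                reasons[i] = "missing_word"
    else:
        raise ValueError(f"unknown predictor level {spec.level!r}")

    if mask.any():
        log.info("predictor %s: %d/%d trials excluded", spec.name,
                 int(mask.sum()), n)
    return PredictorColumn(name=spec.name, values=values, mask=mask,
                           reasons=reasons)
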