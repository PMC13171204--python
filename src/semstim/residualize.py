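"""Cross-validated confound removal (residualization) of response times.

Within every bootstrap iteration and separately per subject, an ordinary
least-squares model predicting log RT from the confound regressors (summed
word length and summed log10 frequency by default) is trained on the
subject's *left-out* trials — those not drawn into the current subsample —
and the subsampled trials' RTs are replaced by their out-of-sample
residuals.  Because the fit never sees the evaluated trials, the removal of
confound variance is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ResidualizationConfig", "ResidualFit",
           "InsufficientTrainingData", "cv_residualize"]


class InsufficientTrainingData(ValueError):
    """The subject's left-out pool is smaller than ``min_training_trials``."""


@dataclass
class ResidualizationConfig:
    """Which confounds to remove and how small a training pool is tolerated."""

    confounds: tuple[str, ...] = ("length", "log_frequency")
    min_training_trials: int = 10

    def __post_init__(self) -> None:
        if not self.confounds:
            raise ValueError("confounds must be non-empty")
        if self.min_training_trials < 2:
            raise ValueError("min_training_trials must be >= 2")


@dataclass
class ResidualFit:
    """Out-of-sample residuals plus the (train-only) fitted coefficients."""

    residuals: np.ndarray
    coef: np.ndarray              # [intercept, one slope per confound column]
    intercept_only: bool = False  # singular design fallback was taken


def cv_residualize(subject_rts: np.ndarray, confounds: np.ndarray,
                   sampled_index_set: np.ndarray,
                   cfg: ResidualizationConfig) -> ResidualFit:
    """Residualize the sampled trials' RTs on confounds fit to left-out trials.

    Parameters
    ----------
    subject_rts
        All usable (log) RTs of one subject, length m.
    confounds
        (m, k) confound regressor matrix aligned with ``subject_rts``.
    sampled_index_set
        Indices (into the subject's pool) of the trials drawn this iteration;
        the training set is their complement.

    Returns observed − predicted for the sampled trials.  Raises
    :class:`InsufficientTrainingData` when the left-out pool is too small
    (the caller skips the subject for this iteration).  A singular design
    (e.g. a constant confound) falls back to an intercept-only fit.
    """
    y = np.asarray(subject_rts, dtype=float)
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    m = y.shape[0]
    sampled = np.asarray(sampled_index_set, dtype=int)
    train = np.setdiff1d(np.arange(m), sampled)
    if train.size < cfg.min_training_trials:
        raise InsufficientTrainingData(
            f"{train.size} left-out trials < min_training_trials="
            f"{cfg.min_training_trials}")

    A_train = np.column_stack([np.ones(train.size), C[train]])
    coef, _, rank, _ = np.linalg.lstsq(A_train, y[train], rcond=None)
    intercept_only = False
    if rank < A_train.shape[1]:
        coef = np.zeros(A_train.shape[1])
        coef[0] = y[train].mean()
        intercept_only = True
    A_samp = np.column_stack([np.ones(sampled.size), C[sampled]])
    resid = y[sampled] - A_samp @ coef
    return ResidualFit(residuals=resid, coef=coef,
                       intercept_only=intercept_only)
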