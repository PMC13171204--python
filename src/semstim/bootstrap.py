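"""Hierarchical bootstrap with subsampling of subjects and trials.

Studies with different numbers of subjects and trials are put on a common
scale by simulating ``n_iterations`` standardized replications of each
experiment: every iteration draws a fixed number of subjects, a fixed
number of trials per drawn subject, computes the Spearman correlation
between a predictor and (log) RT within each subject, and averages across
subjects.  The defaults — 1,000 iterations of 20 subjects × 25 trials —
are the standardization grid used throughout; the distribution of the
1,000 iteration means is what all downstream inference operates on.

Subsampling is without replacement whenever the pool allows (subjects, and
trials within a subject); a pool smaller than the target falls back to
sampling with replacement, which is counted and reported.  Per-iteration
random streams are derived deterministically from ``master_seed`` and the
iteration index, so two bootstraps run with the same master seed share
their draws iteration by iteration — this is what makes per-iteration
pairing across conditions meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .residualize import (InsufficientTrainingData, ResidualizationConfig,
                          cv_residualize)
from .trials import PredictorColumn, TrialTable

__all__ = ["BootstrapConfig", "BootstrapResult", "spearman_rho",
           "run_bootstrap", "summarize"]

log = logging.getLogger(__name__)


@dataclass
class BootstrapConfig:
    """Standardization grid for the hierarchical bootstrap."""

    n_iterations: int = 1000
    n_subjects: int = 20
    n_trials: int = 25
    subject_replacement: bool = False
    trial_replacement: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_iterations, self.n_subjects, self.n_trials) < 1:
            raise ValueError("bootstrap sizes must be positive")


@dataclass
class BootstrapResult:
    """The iteration-mean distribution for one (study, condition, predictor)."""

    iteration_means: np.ndarray
    mean: float
    sd: float
    ci95: tuple[float, float]
    n_subjects_available: int
    n_trials_available_per_subject: dict[str, int]
    degenerate_rho_count: int = 0
    trial_replacement_subjects: int = 0
    subject_replacement_used: bool = False
    residualized: bool = False
    skipped_subject_iterations: int = 0
    intercept_only_fits: int = 0


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson on average ranks (ties averaged).

    Raises ValueError on constant input — the bootstrap engine instead drops
    that subject from the iteration's average (with a logged count).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def _rowwise_spearman(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Spearman per row of two (k, n) matrices; NaN for constant rows."""
    rx = sps.rankdata(xs, axis=1).astype(float)
    ry = sps.rankdata(ys, axis=1).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx * rx).sum(axis=1) * (ry * ry).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    rho[den == 0] = np.nan
    return rho


def iteration_rng(master_seed: int, iteration: int) -> np.random.Generator:
    """The deterministic random stream of one bootstrap iteration."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration,))
    return np.random.default_rng(ss)


def run_bootstrap(table: TrialTable, predictor: PredictorColumn,
                  condition: str, cfg: BootstrapConfig,
                  residualize: ResidualizationConfig | None = None,
                  confounds: np.ndarray | None = None) -> BootstrapResult:
    """Bootstrap the predictor–RT Spearman correlation for one condition.

    ``table`` should already be filtered to correct trials and have
    log-transformed RTs; trials masked by the predictor column are removed.
    When ``residualize`` is given, ``confounds`` must be an (n_trials_total,
    k) matrix aligned with the table, and each subject's sampled RTs are
    replaced by out-of-sample residuals before ranking
    (see :mod:`semstim.residualize`).
    """
    keep = (table.data["condition"] == condition).to_numpy() & ~predictor.mask
    if residualize is not None:
        if confounds is None:
            raise ValueError("residualization requires confound columns")
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        keep &= ~np.isnan(confounds).any(axis=1)
    y_all = table.data["rt"].to_numpy(dtype=float)
    subj_all = table.data["subject"].to_numpy()

    pools_x, pools_y, pools_c, pool_subjects = [], [], [], []
    for subj in table.subjects:
        sel = keep & (subj_all == subj)
        if sel.sum() < 3:
            log.info("subject %s: only %d usable trials in %s; excluded",
                     subj, int(sel.sum()), condition)
            continue
        # canonical within-subject order: results depend on the trial
        # multiset, never on input row order
        px = predictor.values[sel]
        py = y_all[sel]
        order = np.lexsort((px, py))
        pool_subjects.append(subj)
        pools_x.append(px[order])
        pools_y.append(py[order])
        pools_c.append(confounds[sel][order]
                       if residualize is not None else None)
    S = len(pool_subjects)
    if S < 3:
        raise ValueError("insufficient subjects")

    sizes = np.array([len(p) for p in pools_x])
    M = int(sizes.max())
    X = np.full((S, M), np.nan)
    Y = np.full((S, M), np.nan)
    for j in range(S):
        X[j, :sizes[j]] = pools_x[j]
        Y[j, :sizes[j]] = pools_y[j]
    needs_repl = (sizes < cfg.n_trials) | cfg.trial_replacement
    if (sizes < cfg.n_trials).any():
        log.info("%d subjects have < %d trials; trial sampling with "
                 "replacement for them", int((sizes < cfg.n_trials).sum()),
                 cfg.n_trials)
    subject_repl = cfg.subject_replacement or S < cfg.n_subjects

    # invalid (padded) positions get +inf keys so argsort never picks them
    key_mask = np.full((S, M), np.inf)
    for j in range(S):
        key_mask[j, :sizes[j]] = 0.0

    means = np.full(cfg.n_iterations, np.nan)
    degenerate = 0
    skipped = 0
    intercept_only = 0
    for it in range(cfg.n_iterations):
        rng = iteration_rng(cfg.master_seed, it)
        subj_idx = rng.choice(S, size=cfg.n_subjects, replace=subject_repl)
        keys = rng.random((cfg.n_subjects, M)) + key_mask[subj_idx]
        idx = np.argsort(keys, axis=1)[:, :cfg.n_trials]
        if idx.shape[1] < cfg.n_trials:
            # every pool is smaller than n_trials: all rows resampled below
            idx = np.zeros((cfg.n_subjects, cfg.n_trials), dtype=int)
        for row, j in enumerate(subj_idx):
            if needs_repl[j]:
                idx[row] = rng.integers(0, sizes[j], size=cfg.n_trials)
        xs = X[subj_idx[:, None], idx]
        ys = Y[subj_idx[:, None], idx]

        valid = np.ones(cfg.n_subjects, dtype=bool)
        if residualize is not None:
            for row, j in enumerate(subj_idx):
                try:
                    fit = cv_residualize(pools_y[j], pools_c[j], idx[row],
                                         residualize)
                except InsufficientTrainingData:
                    valid[row] = False
                    skipped += 1
                    continue
                ys[row] = fit.residuals
                intercept_only += fit.intercept_only
            xs = xs[valid]
            ys = ys[valid]
            if xs.shape[0] == 0:
                continue

        rho = _rowwise_spearman(xs, ys)
        degenerate += int(np.isnan(rho).sum())
        if np.isnan(rho).all():
            continue
        means[it] = np.nanmean(rho)

    ok = means[~np.isnan(means)]
    mean = float(ok.mean())
    sd = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    if ok.size > 1 and sd > 0:
        half = sps.t.ppf(0.975, ok.size - 1) * sd / np.sqrt(ok.size)
    else:
        half = 0.0
    return BootstrapResult(
        iteration_means=means, mean=mean, sd=sd,
        ci95=(mean - half, mean + half),
        n_subjects_available=S,
        n_trials_available_per_subject={s: int(m) for s, m
                                        in zip(pool_subjects, sizes)},
        degenerate_rho_count=degenerate,
        trial_replacement_subjects=int(needs_repl.sum()),
        subject_replacement_used=bool(subject_repl),
        residualized=residualize is not None,
        skipped_subject_iterations=skipped,
        intercept_only_fits=intercept_only,
    )


def summarize(result: BootstrapResult) -> dict:
    """Mean, sample sd (ddof=1) and 95% CI of the iteration means."""
    return {
        "mean": result.mean,
        "sd": result.sd,
        "ci95_low": result.ci95[0],
        "ci95_high": result.ci95[1],
        "n_iterations": int(result.iteration_means.size),
        "n_subjects_available": result.n_subjects_available,
        "degenerate_rho_count": result.degenerate_rho_count,
        "residualized": result.residualized,
    }
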