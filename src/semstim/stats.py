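"""Inference on bootstrap iteration-mean distributions.

Two families of tests operate on the 1,000-value iteration distributions
produced by the hierarchical bootstrap:

* chance tests — a smoothed two-sided bootstrap p-value against ρ = 0
  plus a one-sample Cohen's d on the iteration distribution;
* condition contrasts — two-sample two-sided Monte-Carlo permutation
  tests between the control and an effective-stimulation distribution,
  with a paired Cohen's d (iteration i paired with iteration i, valid
  because both bootstraps share per-iteration seeds within a run).

All p-values of a run — chance tests and contrasts across every study —
are Benjamini–Hochberg adjusted in one single global pass.  Effect sizes
are classified against percentile thresholds of significant effects in
the cognitive-neuroscience literature (|d| = 0.637 / 0.932 / 1.458 for
small / medium / strong) rather than generic conventions; the reporting
gate requires both p < 0.05 and at least a small effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "EffectThresholds",
    "ChanceTestResult",
    "ConditionComparison",
    "bootstrap_p_two_sided",
    "cohen_d_one_sample",
    "permutation_compare",
    "fdr_correct_global",
    "classify_effect",
    "confidence_interval_95",
    "chance_test",
]


@dataclass(frozen=True)
class EffectThresholds:
    """Absolute-|d| class boundaries (literature percentiles, not Cohen's 0.2/0.5/0.8)."""

    small: float = 0.637
    medium: float = 0.932
    strong: float = 1.458

    def __post_init__(self) -> None:
        if not (0 < self.small < self.medium < self.strong):
            raise ValueError("thresholds must be strictly increasing")


DEFAULT_THRESHOLDS = EffectThresholds()


@dataclass
class ChanceTestResult:
    """Is one iteration distribution different from chance (ρ = 0)?"""

    p_two_sided: float
    cohen_d: float
    ci95_d: tuple[float, float]
    degenerate: bool = False


@dataclass
class ConditionComparison:
    """Control vs. effective-stimulation contrast on iteration distributions."""

    p_perm: float
    cohen_d_paired: float
    ci95_d: tuple[float, float]
    effect_class: str
    direction: int              # sign of (control − effective) mean
    paired: bool = True
    degenerate_d: bool = False
    p_fdr: float | None = None  # filled by the global FDR pass


def bootstrap_p_two_sided(iteration_means, null_value: float = 0.0) -> float:
    """Smoothed two-sided bootstrap p against ``null_value``.

    p_low = (#below + 1)/(n + 1), p_high = (#above + 1)/(n + 1); the result
    is min(1, 2·min(p_low, p_high)).  Adding 1 to numerator and denominator
    keeps p off zero; the floor is 2/(n + 1).
    """
    v = np.asarray(iteration_means, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 1:
        raise ValueError("empty iteration distribution")
    p_low = (np.sum(v < null_value) + 1) / (n + 1)
    p_high = (np.sum(v > null_value) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def cohen_d_one_sample(iteration_means, null_value: float = 0.0) -> float:
    """(mean − null)/sd with sample sd (ddof=1); sd=0 is degenerate."""
    v = np.asarray(iteration_means, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate distribution (sd = 0)")
    return float((v.mean() - null_value) / sd)


def confidence_interval_95(values) -> tuple[float, float]:
    """t-based 95% CI on the mean: mean ± t(0.975, n−1)·sd/√n."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    half = sps.t.ppf(0.975, v.size - 1) * sd / np.sqrt(v.size)
    m = v.mean()
    return (float(m - half), float(m + half))


def _d_ci(d: float, nx: int, ny: int, paired: bool) -> tuple[float, float]:
    lo, hi = pg.compute_esci(stat=d, nx=nx, ny=ny, paired=paired,
                             eftype="cohen", confidence=0.95, decimals=6)
    return (float(lo), float(hi))


def chance_test(iteration_means, null_value: float = 0.0) -> ChanceTestResult:
    """Smoothed bootstrap p plus one-sample d (with CI) against chance."""
    p = bootstrap_p_two_sided(iteration_means, null_value)
    v = np.asarray(iteration_means, dtype=float)
    v = v[~np.isnan(v)]
    try:
        d = cohen_d_one_sample(v, null_value)
    except ValueError:
        return ChanceTestResult(p_two_sided=p, cohen_d=np.nan,
                                ci95_d=(np.nan, np.nan), degenerate=True)
    return ChanceTestResult(p_two_sided=p, cohen_d=d,
                            ci95_d=_d_ci(d, v.size, 1, paired=False))


def permutation_compare(dist_control, dist_effective,
                        n_permutations: int = 10_000, seed: int = 0,
                        thresholds: EffectThresholds = DEFAULT_THRESHOLDS,
                        ) -> ConditionComparison:
    """Two-sample two-sided Monte-Carlo permutation test + paired Cohen's d.

    The statistic is the difference of means (control − effective); pooled
    values are randomly relabelled ``n_permutations`` times and the p-value
    uses the same +1 smoothing as the bootstrap p.  When the two
    distributions have equal length, Cohen's d is computed on per-iteration
    differences (pairing by iteration index); a length mismatch falls back
    to an independent-samples d.
    """
    a = np.asarray(dist_control, dtype=float)
    b = np.asarray(dist_effective, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty distribution")

    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_lo = 0
    n_hi = 0
    chunk = max(1, min(n_permutations, 2_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        perm = rng.permuted(np.broadcast_to(pooled, (k, pooled.size)), axis=1)
        stat = perm[:, :a.size].mean(axis=1) - perm[:, a.size:].mean(axis=1)
        n_lo += int(np.sum(stat <= observed))
        n_hi += int(np.sum(stat >= observed))
        done += k
    p_low = (n_lo + 1) / (n_permutations + 1)
    p_high = (n_hi + 1) / (n_permutations + 1)
    p_perm = float(min(1.0, 2.0 * min(p_low, p_high)))

    paired = a.size == b.size
    degenerate = False
    if paired:
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            d = 0.0 if observed == 0 else np.inf * np.sign(observed)
            degenerate = True
            ci = (np.nan, np.nan)
        else:
            d = float(diff.mean() / sd)
            ci = _d_ci(d, a.size, b.size, paired=True)
    else:
        sp = np.sqrt(((a.size - 1) * a.var(ddof=1)
                      + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
        if sp == 0:
            d = 0.0
            degenerate = True
            ci = (np.nan, np.nan)
        else:
            d = float(observed / sp)
            ci = _d_ci(d, a.size, b.size, paired=False)

    return ConditionComparison(
        p_perm=p_perm, cohen_d_paired=float(d), ci95_d=ci,
        effect_class=classify_effect(d, thresholds) if np.isfinite(d)
        else "strong",
        direction=int(np.sign(observed)), paired=paired,
        degenerate_d=degenerate)


def fdr_correct_global(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, one single global pass.

    Called exactly once per run on every p-value it produced (chance tests
    and condition contrasts across all studies together).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return sps.false_discovery_control(p, method="bh")


def classify_effect(d: float,
                    thresholds: EffectThresholds = DEFAULT_THRESHOLDS) -> str:
    """Label |d| against the small/medium/strong boundaries (sign ignored)."""
    a = abs(d)
    if a < thresholds.small:
        return "negligible"
    if a < thresholds.medium:
        return "small"
    if a < thresholds.strong:
        return "medium"
    return "strong"


def significance_gate(p: float, d: float,
                      thresholds: EffectThresholds = DEFAULT_THRESHOLDS,
                      alpha: float = 0.05) -> bool:
    """Dual reporting gate: p below alpha AND at least a small effect."""
    return bool(p < alpha and abs(d) >= thresholds.small)
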