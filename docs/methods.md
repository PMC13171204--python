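# Methods

This note documents the models, the statistical procedures, the synthetic
data generator, and the numerical and design choices behind `semstim`.

## Distributional semantics

The semantic space is a count-based PPMI model. Co-occurrence counting
uses a symmetric window (default ±5 tokens, no distance weighting, no
cross-document windows); token positions are preserved when low-frequency
words are removed (`min_count`, default 1), so dropping a word does not
pull its neighbours together. The transform is

entry(w, c) = max(0, log₂ [ P(w,c) / (P(w) · P_α(c)) ]),

with P(w,c) the pair probability, P(w) the row mass, and P_α(c) the
context distribution raised to `smoothing_alpha` and renormalized
(α = 1, the default, disables context smoothing). The log base is 2
(bits); any base gives identical downstream results because Spearman
correlation is invariant to monotone rescaling. These hyperparameters are
deliberately plain defaults — count-based spaces are robust to them for
rank-based analyses — and all are recorded in run metadata so that two
runs can never silently mix spaces.

Semantic dissimilarity is 1 − cosine similarity, in [0, 1] for the
nonnegative PPMI vectors. A word whose vector is all zero (it never
co-occurs above independence) has no defined direction; trials touching
such a word, or any out-of-vocabulary word, are excluded with a logged
reason rather than imputed — imputation would bias the correlations
toward whatever constant is imputed. Externally trained dense embeddings
can be substituted through the word2vec-text adapter; similarity is
computed identically.

Surprisal is −log₂ P̂(target | context) with add-k smoothing,
P̂ = (pair + k)/(row total + k·|V|). The conditioning word is an explicit
argument: for two-word trials the first word is the context by default,
but nothing in the data constrains which word "primes" which, so the
choice is surfaced in the API rather than hidden.

Word frequency enters as −Σ log₁₀(count) over the trial's words and
length as Σ characters; both sum over the available words, so single-word
trials use the one word. Characters, not graphemes, are counted — a
limitation for non-Latin scripts. Frequency counts may come from the PPMI
training corpus or an external norm table; the source matters (log
frequencies differ across corpora) and is recorded in metadata.

## Hierarchical bootstrap with subsampling

One cell = (study, condition, predictor). Each of `n_iterations` = 1,000
iterations draws `n_subjects` = 20 subjects and `n_trials` = 25 usable
correct trials per drawn subject, computes the within-subject Spearman ρ
between predictor and log RT, and averages across subjects. The iteration
means form the cell's distribution; the grid (1,000 × 20 × 25) is the
standardization that makes cells comparable across studies of different
sizes.

Design choices:

* **Replacement policy.** "Subsampling" is implemented as sampling
  without replacement whenever the pool allows, at both levels; a pool
  smaller than the target (a study with < 20 subjects, a subject with
  < 25 usable trials) falls back to with-replacement sampling, counted
  and reported. A config switch (`subject_replacement`,
  `trial_replacement`) exposes the fully with-replacement hierarchical
  bootstrap. Note a consequence of the default: when a study has exactly
  20 subjects, every iteration uses all of them, so the iteration spread
  reflects trial subsampling only and the chance test is conservative
  (observed Type-I ≈ 1–2% at nominal 5%; see the calibration test).
* **Seed discipline.** Iteration i's random stream is derived from
  (master_seed, i) alone, so every bootstrap in a run shares its draw
  pattern iteration-by-iteration. This is what makes a *paired* effect
  size between two conditions' iteration distributions meaningful.
  Bit-level reproducibility is guaranteed within this implementation;
  other implementations should match distributional summaries only.
* **Canonical trial order.** Each subject's pool is sorted by (log RT,
  predictor) before sampling, so results depend on the trial multiset and
  never on input row order; jointly permuting a subject's trials changes
  nothing, bit for bit.
* **Degenerate correlations.** A subject whose sampled ranks are constant
  has no defined ρ and is dropped from that iteration's average (counted),
  not imputed as 0 — imputation would shrink every iteration mean toward
  zero by an amount depending on tie rates.

Summaries are the mean, sample sd (ddof = 1), and a t-based 95% CI of the
iteration means.

## Chance tests, contrasts, FDR, effect sizes

The two-sided smoothed bootstrap p counts iteration means below and above
the null (ρ = 0), adds 1 to numerator and denominator of each tail
proportion, doubles the smaller, and caps at 1; its floor is 2/(N+1).
The add-one smoothing keeps p off zero at finite N. Cohen's d against
chance is (mean − 0)/sd on the iteration distribution; t-statistics are
deliberately not reported because N_iterations is an analysis choice, not
a sample size.

Condition contrasts are two-sample, two-sided Monte-Carlo permutation
tests on the difference of means (default 10,000 relabelings — the count
is an implementation default, exposed in config), with the same add-one
smoothing for consistency. The paired Cohen's d is computed on
per-iteration differences (valid because of the shared seeds above); a
length mismatch falls back to an independent-samples d with a log entry.
Sign convention: d and `direction` are computed as control − effective,
so a *decrease* of correlation under effective stimulation gives positive
d, an *increase* negative d. Confidence intervals for d use pingouin's
effect-size CI; the CI for mean ρ is t-based on the iteration
distribution (percentile CIs can be substituted).

All p-values a run produces — every chance test and every contrast,
across all studies — are Benjamini–Hochberg adjusted in exactly one
global pass (scipy's `false_discovery_control`). Effect classes use
percentiles of significant effect sizes reported across the cognitive-
neuroscience literature (small 0.637, medium 0.932, strong 1.458) rather
than the generic 0.2/0.5/0.8, and the reporting gate requires both
p < 0.05 and at least a small effect.

A caveat the worked example in the README makes visible: the permutation
test compares two *realized* datasets' bootstrap distributions, which are
narrow; chance-level differences between the conditions' realized
correlations are therefore often detectable as small p-values. The
effect-size half of the dual gate is what keeps such fluctuations out of
the reported results.

## Cross-validated residualization

To test the semantic effect net of lower-level variables, log RTs are
replaced by out-of-sample residuals: per subject and per iteration, OLS
of log RT on summed word length and summed log₁₀ frequency (plus
intercept) is fit on the subject's trials *not* drawn this iteration and
used to predict the drawn trials. The evaluated trials never influence
the fit, so confound removal is unbiased. Numerical rules: a left-out
pool below `min_training_trials` (default 10) skips the subject for that
iteration (logged) — pooling across subjects would contradict the
strictly within-subject procedure; a rank-deficient design (e.g. a
constant confound) falls back to an intercept-only fit (logged). The OLS
itself is a least-squares solve; it runs ~20,000 times per cell, and is
cross-checked against scikit-learn in the test suite. Output rows carry a
`residualized` flag so raw and residualized results are never conflated.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with known
ground truth:

* **Lexicon**: Zipfian frequencies (exponent 1.1 over 300 words by
  default, counts scaled to 10⁶ tokens), word lengths coupled to log
  frequency through a Gaussian copula so corr(length, log f) ≈ −0.3,
  matching the robust empirical tendency of frequent words to be short.
* **Corpus**: documents commit to one of a few latent topics and sample
  words within-topic with probability 0.85 (frequency-weighted), so PPMI
  cosine separates within- from between-topic pairs.
* **Experiment**: per trial, log RT = log(650 ms) + subject intercept
  (sd 0.1) + 0.12 · (β_sem[condition]·z_sem + β_freq·z_freq +
  β_len·z_len + ε). Predictors are z-scored within condition and the
  default noise sd completes the latent variance to 1, so each β *is* the
  population Pearson correlation between its predictor and latent log RT
  — which is what makes the closed-form check possible: for jointly
  Gaussian pairs the expected Spearman is (6/π)·asin(r/2) (0.4826 at
  r = 0.5). The 0.12 log-scale factor only places RTs in a plausible
  450–950 ms band; it rescales signal and noise together and cancels from
  every correlation. Correctness is Bernoulli(0.95), independent of the
  predictors by default (the analysis filters on accuracy, it does not
  model it); a switch couples it to trial difficulty for robustness
  checks.
* **Item sharing**: by default the same word-pair set appears in every
  condition, as in real within-subject stimulation designs; a flag
  resamples items per condition.
* Two predictor modes: `lexicon` derives the predictors from sampled word
  pairs through the real PPMI/frequency/length machinery (what the
  pipeline later recomputes from the written files — round-trip tested);
  `gaussian` draws the three standardized predictors as independent
  normals, used where orthogonal confounds or exact distributional
  control are needed.

What the generator does *not* emulate: realistic RT skew beyond
log-normality, sequential effects, fatigue or practice drifts, item-level
random effects beyond the shared predictors, or any neural mechanism of
stimulation. Passing tests therefore certify the statistical machinery
under the analysis' own assumptions, not the realism of those assumptions
for any particular dataset. One consequence visible in lexicon mode: the
PPMI dissimilarity distribution is strongly left-skewed (most sampled
pairs are nearly orthogonal), which attenuates rank correlations relative
to the generating β — realized semantic correlations land in the 0.05–0.3
range rather than at β, conveniently similar to the magnitudes real
studies report.

## Problem sizes in the verification suite

The calibration checks use 200 null experiments (20 subjects × 60
trials) for the chance-test Type-I rate, 500 null draws (n = 100 per
group, 1,000 relabelings) for the permutation test, one 20-subject ×
200-trial experiment for the copula recovery and for the residualization
checks, and 20 replicate experiments for direction recovery — sizes at
which the binomial error of the measured rates is well inside the
asserted bands while the full suite stays in the minutes range on one
core.

## Known limitations

* PPMI hyperparameters (window, weighting, smoothing) are plain defaults,
  not tuned against behavioral norms; the model-evaluation harness exists
  precisely to compare candidate measures against an external per-word RT
  norm before committing to one.
* With the default no-replacement subsampling, studies at or below the
  20-subject grid yield conservative chance tests (see above).
* The effect-size thresholds are global literature percentiles; they are
  configurable (`EffectThresholds`) and results near a boundary should be
  read with the CI, not the label.
* Production (picture-naming) trials are represented as two-word trials
  (presented label + uttered word); which orthographic form should enter
  the frequency lookup for a pictured object is a corpus decision the
  caller makes, not the package.
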