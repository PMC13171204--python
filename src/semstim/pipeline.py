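"""End-to-end orchestration: grid of (study × condition × predictor) cells.

For every cell the pipeline runs the hierarchical bootstrap (optionally a
second, residualized pass for the semantic predictor), tests the iteration
distribution against chance, contrasts every effective-stimulation
condition with the control by permutation, and finally adjusts *all*
p-values of the run — chance tests and contrasts across all studies — in
one single Benjamini–Hochberg pass.  Bootstraps of one run share per-
iteration seeds, so iteration i is the same subject/trial draw pattern in
every condition, which is what justifies the paired effect size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import BootstrapConfig, BootstrapResult, run_bootstrap
from .corpus import (Corpus, FrequencyTable, build_cooccurrence,
                     load_word_vectors, ppmi_transform)
from .residualize import ResidualizationConfig
from .stats import (DEFAULT_THRESHOLDS, EffectThresholds, chance_test,
                    classify_effect, fdr_correct_global, permutation_compare,
                    significance_gate)
from .trials import (PredictorColumn, PredictorSpec, TrialTable,
                     attach_predictor, filter_correct, load_trials,
                     log_transform_rts)

__all__ = ["StudyInput", "PipelineResult", "analyze_studies", "run_pipeline",
           "render_summary", "prepare_table"]

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["study", "row_type", "condition", "predictor",
                  "residualized", "mean_rho", "sd", "ci_low", "ci_high",
                  "p_raw", "p_fdr", "d", "d_ci_low", "d_ci_high",
                  "effect_class", "direction", "significant"]


@dataclass
class StudyInput:
    """One study ready for analysis: prepared table + aligned predictors.

    ``table`` must be correct-filtered and log-transformed (see
    :func:`prepare_table`); every PredictorColumn and the optional confound
    matrix are aligned row-by-row with ``table.data``.
    """

    table: TrialTable
    predictors: dict[str, PredictorColumn]
    confounds: np.ndarray | None = None  # (n_trials, k) for residualization


@dataclass
class PipelineResult:
    results: pd.DataFrame
    iterations: pd.DataFrame
    metadata: dict


def prepare_table(table: TrialTable) -> tuple[TrialTable, np.ndarray]:
    """Correct-trials filter followed by log-RT transform.

    Returns the prepared table plus the integer positions of the retained
    rows in the original table, for aligning externally held per-trial
    arrays (e.g. simulation ground truth).
    """
    keep = np.flatnonzero(table.data["correct"].astype(bool).to_numpy())
    filtered = filter_correct(table)
    if not filtered.log_transformed:
        filtered = log_transform_rts(filtered)
    return filtered, keep


def analyze_studies(studies: dict[str, StudyInput],
                    bootstrap_cfg: BootstrapConfig,
                    residualize_cfg: ResidualizationConfig | None = None,
                    n_permutations: int = 10_000,
                    thresholds: EffectThresholds = DEFAULT_THRESHOLDS,
                    residualize_predictors: tuple[str, ...] = (
                        "semantic_dissimilarity",),
                    ) -> PipelineResult:
    """Run the full cell grid and apply one global FDR pass.

    ``studies`` maps study id → :class:`StudyInput`.  When
    ``residualize_cfg`` is given, every predictor named in
    ``residualize_predictors`` gets a second, residualized pass (requires
    the study's confound matrix).
    """
    rows: list[dict] = []
    iter_rows: list[pd.DataFrame] = []
    boot_store: dict[tuple, BootstrapResult] = {}

    for study_id in sorted(studies):
        s = studies[study_id]
        control = s.table.control_condition
        conditions = s.table.conditions
        if control not in conditions:
            raise ValueError(f"{study_id}: control condition {control!r} "
                             "absent from the data")
        for pname in sorted(s.predictors):
            variants = [(False, None)]
            if residualize_cfg is not None and pname in residualize_predictors:
                if s.confounds is None:
                    raise ValueError(f"{study_id}: residualization requested "
                                     "but no confound columns supplied")
                variants.append((True, residualize_cfg))
            for resid_flag, rcfg in variants:
                for cond in conditions:
                    res = run_bootstrap(
                        s.table, s.predictors[pname], cond, bootstrap_cfg,
                        residualize=rcfg,
                        confounds=s.confounds if resid_flag else None)
                    boot_store[(study_id, pname, resid_flag, cond)] = res
                    ct = chance_test(res.iteration_means)
                    rows.append({
                        "study": study_id, "row_type": "chance",
                        "condition": cond, "predictor": pname,
                        "residualized": resid_flag,
                        "mean_rho": res.mean, "sd": res.sd,
                        "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                        "p_raw": ct.p_two_sided, "d": ct.cohen_d,
                        "d_ci_low": ct.ci95_d[0], "d_ci_high": ct.ci95_d[1],
                        "effect_class": (classify_effect(ct.cohen_d, thresholds)
                                         if np.isfinite(ct.cohen_d)
                                         else "degenerate"),
                        "direction": int(np.sign(res.mean)),
                    })
                    it = res.iteration_means
                    iter_rows.append(pd.DataFrame({
                        "study": study_id, "condition": cond,
                        "predictor": pname, "residualized": resid_flag,
                        "iteration": np.arange(it.size), "mean_rho": it}))

    # condition contrasts, seeded per comparison in deterministic order
    comp_index = 0
    for study_id in sorted(studies):
        s = studies[study_id]
        control = s.table.control_condition
        for pname in sorted(s.predictors):
            for resid_flag in (False, True):
                key = (study_id, pname, resid_flag, control)
                if key not in boot_store:
                    continue
                ctrl = boot_store[key]
                for cond in s.table.conditions:
                    if cond == control:
                        continue
                    eff = boot_store[(study_id, pname, resid_flag, cond)]
                    seed = int(np.random.SeedSequence(
                        entropy=bootstrap_cfg.master_seed,
                        spawn_key=(10_000 + comp_index,)
                    ).generate_state(1)[0] % (2**31))
                    comp_index += 1
                    cmp_ = permutation_compare(
                        ctrl.iteration_means, eff.iteration_means,
                        n_permutations=n_permutations, seed=seed,
                        thresholds=thresholds)
                    rows.append({
                        "study": study_id, "row_type": "comparison",
                        "condition": cond, "predictor": pname,
                        "residualized": resid_flag,
                        "mean_rho": ctrl.mean - eff.mean,
                        "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p_raw": cmp_.p_perm, "d": cmp_.cohen_d_paired,
                        "d_ci_low": cmp_.ci95_d[0],
                        "d_ci_high": cmp_.ci95_d[1],
                        "effect_class": cmp_.effect_class,
                        "direction": cmp_.direction,
                    })

    results = pd.DataFrame(rows)
    results["p_fdr"] = fdr_correct_global(results["p_raw"].to_numpy())
    results["significant"] = [
        significance_gate(p, d, thresholds) if np.isfinite(d) else False
        for p, d in zip(results["p_fdr"], results["d"])]
    results = results[RESULT_COLUMNS]

    metadata = {
        "bootstrap": {"n_iterations": bootstrap_cfg.n_iterations,
                      "n_subjects": bootstrap_cfg.n_subjects,
                      "n_trials": bootstrap_cfg.n_trials,
                      "master_seed": bootstrap_cfg.master_seed,
                      "subject_replacement": bootstrap_cfg.subject_replacement,
                      "trial_replacement": bootstrap_cfg.trial_replacement},
        "n_permutations": n_permutations,
        "residualized": residualize_cfg is not None,
        "thresholds": {"small": thresholds.small,
                       "medium": thresholds.medium,
                       "strong": thresholds.strong},
        "n_tests_fdr": int(len(results)),
        "exclusions": {
            f"{k[0]}/{k[1]}/{'resid' if k[2] else 'raw'}/{k[3]}": {
                "degenerate_rho": v.degenerate_rho_count,
                "trial_replacement_subjects": v.trial_replacement_subjects,
                "skipped_subject_iterations": v.skipped_subject_iterations,
                "intercept_only_fits": v.intercept_only_fits,
            } for k, v in sorted(boot_store.items())},
    }
    iterations = (pd.concat(iter_rows, ignore_index=True) if iter_rows
                  else pd.DataFrame())
    return PipelineResult(results=results, iterations=iterations,
                          metadata=metadata)


def _build_semantics(cfg: dict):
    sem = cfg.get("semantics", {})
    if "vectors" in sem:
        return load_word_vectors(sem["vectors"]), None
    corpus = Corpus.from_file(sem["corpus"])
    counts = build_cooccurrence(corpus, window=int(sem.get("window", 5)),
                                min_count=int(sem.get("min_count", 1)))
    model = ppmi_transform(counts,
                           smoothing_alpha=float(sem.get("smoothing_alpha", 1.0)))
    return model, counts


def run_pipeline(config: dict | str | Path,
                 out_dir: str | Path | None = None,
                 seed: int | None = None) -> PipelineResult:
    """File-driven entry point: read config, build models, analyze, write.

    The configuration is a nested mapping (YAML when given as a path) with
    sections ``run`` (seed, out_dir), ``semantics`` (corpus or vectors),
    ``frequency`` (table path, or "corpus"), ``predictors`` (list of
    level/aggregation), ``bootstrap``, ``stats`` and ``studies`` (each with
    id, trials path, control_condition, optional column_map).
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    run_cfg = config.get("run", {})
    seed = int(run_cfg.get("seed", 0) if seed is None else seed)
    out_dir = Path(out_dir or run_cfg.get("out_dir", "semstim_out"))

    pred_specs = config.get("predictors",
                            [{"level": "semantic_dissimilarity"},
                             {"level": "neg_log_frequency"},
                             {"level": "length"}])
    levels = {p["level"] for p in pred_specs}
    known = {"semantic_dissimilarity", "surprisal", "neg_log_frequency",
             "length"}
    bad = levels - known
    if bad:
        raise ValueError(f"unknown predictor level(s): {sorted(bad)}")

    model = counts = None
    if levels & {"semantic_dissimilarity", "surprisal"}:
        model, counts = _build_semantics(config)
    freq = None
    freq_cfg = config.get("frequency", {})
    needs_freq = ("neg_log_frequency" in levels
                  or config.get("residualize", False))
    if needs_freq:
        if freq_cfg.get("table"):
            freq = FrequencyTable.from_file(freq_cfg["table"])
        else:
            freq = FrequencyTable.from_corpus(
                Corpus.from_file(config["semantics"]["corpus"]))

    boot = config.get("bootstrap", {})
    bcfg = BootstrapConfig(
        n_iterations=int(boot.get("n_iterations", 1000)),
        n_subjects=int(boot.get("n_subjects", 20)),
        n_trials=int(boot.get("n_trials", 25)),
        subject_replacement=bool(boot.get("subject_replacement", False)),
        trial_replacement=bool(boot.get("trial_replacement", False)),
        master_seed=seed)
    rcfg = (ResidualizationConfig() if config.get("residualize", False)
            else None)
    n_perm = int(config.get("stats", {}).get("n_permutations", 10_000))

    studies: dict[str, StudyInput] = {}
    for st in config["studies"]:
        raw = load_trials(st["trials"], column_map=st.get("column_map"),
                          study_id=st["id"],
                          control_condition=st["control_condition"])
        table, _ = prepare_table(raw)
        predictors: dict[str, PredictorColumn] = {}
        for p in pred_specs:
            level = p["level"]
            source = {"semantic_dissimilarity": model, "surprisal": counts,
                      "neg_log_frequency": freq, "length": None}[level]
            spec = PredictorSpec(level=level,
                                 aggregation=p.get("aggregation", "sum"),
                                 source=source)
            predictors[spec.name] = attach_predictor(table, spec)
        confounds = None
        if rcfg is not None:
            len_col = attach_predictor(table, PredictorSpec(level="length"))
            frq_col = attach_predictor(
                table, PredictorSpec(level="neg_log_frequency", source=freq))
            # regressors: summed length and summed log10 frequency
            confounds = np.column_stack([len_col.values, -frq_col.values])
        studies[st["id"]] = StudyInput(table=table, predictors=predictors,
                                       confounds=confounds)

    out = analyze_studies(studies, bcfg, residualize_cfg=rcfg,
                          n_permutations=n_perm)
    out.metadata["config"] = _jsonable(config)
    out.metadata["seed"] = seed
    write_outputs(out, out_dir)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Deterministic text outputs: results, per-iteration table, metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(out_dir / "results.csv", index=False,
                          float_format="%.10g")
    result.iterations.to_csv(out_dir / "iterations.csv", index=False,
                             float_format="%.10g")
    (out_dir / "metadata.json").write_text(
        json.dumps(_jsonable(result.metadata), indent=2, sort_keys=True))
    (out_dir / "summary.txt").write_text(render_summary(result))


def render_summary(result: PipelineResult) -> str:
    """Human-readable per-cell report with the dual significance gate."""
    lines: list[str] = []
    df = result.results
    if df.empty:
        return "(no results)\n"
    for study in df["study"].unique():
        lines.append(f"== {study} ==")
        sub = df[df["study"] == study]
        for _, r in sub[sub["row_type"] == "chance"].iterrows():
            tag = " [resid]" if r["residualized"] else ""
            if not np.isfinite(r["d"]):
                lines.append(
                    f"  {r['predictor']}{tag} @ {r['condition']}: "
                    f"rho={r['mean_rho']:.3f} DEGENERATE d")
                continue
            lines.append(
                f"  {r['predictor']}{tag} @ {r['condition']}: "
                f"rho={r['mean_rho']:.3f} +/- {r['sd']:.3f} "
                f"CI[{r['ci_low']:.3f}, {r['ci_high']:.3f}] "
                f"p_fdr={r['p_fdr']:.4g} d={r['d']:.2f} "
                f"({r['effect_class']})"
                + (" *" if r["significant"] else ""))
        for _, r in sub[sub["row_type"] == "comparison"].iterrows():
            tag = " [resid]" if r["residualized"] else ""
            arrow = {1: "decreased", -1: "increased", 0: "unchanged"}[
                int(r["direction"])]
            lines.append(
                f"  {r['predictor']}{tag} control vs {r['condition']}: "
                f"d={r['d']:.2f} ({r['effect_class']}) "
                f"p_fdr={r['p_fdr']:.4g} -> correlation {arrow} "
                f"under effective stimulation"
                + (" *" if r["significant"] else ""))
    lines.append("")
    lines.append("* = p_fdr < 0.05 AND |d| >= small-effect threshold")
    return "\n".join(lines) + "\n"
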