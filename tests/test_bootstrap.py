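"""Spearman correctness and the hierarchical bootstrap engine."""

import numpy as np
import pytest
from scipy import stats as sps

import semstim as ss

from conftest import aligned_predictor


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([3.0, 9.0, 27.0, 81.0])
        assert ss.spearman_rho(x, np.log(x)) == pytest.approx(1.0)
        assert ss.spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_hand_ranked_tie_case(self):
        # ranks of x: [1, 2.5, 2.5, 4]; Pearson on ranks = 4.5/sqrt(22.5)
        rho = ss.spearman_rho([1, 2, 2, 3], [1, 2, 3, 4])
        assert rho == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 6, size=30).astype(float)  # heavy ties
            y = rng.random(30)
            assert ss.spearman_rho(x, y) == pytest.approx(
                sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            ss.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(ValueError):
            ss.spearman_rho([1.0, 2.0], [1.0, 2.0])


def simple_study(n_subjects=8, n_trials=40, rho_map=None, seed=0):
    """One-condition study where the predictor IS a noisy copy of rt ranks."""
    table, gt = ss.simulate_copula_experiment(
        rho_map if rho_map is not None else 0.5,
        n_subjects=n_subjects, n_trials=n_trials, seed=seed)
    prep, keep = ss.prepare_table(table)
    return prep, aligned_predictor(gt, keep)


class TestRunBootstrap:
    def test_predictor_equal_to_rt_gives_unit_means(self):
        table, gt = ss.simulate_copula_experiment(0.3, n_subjects=6,
                                                  n_trials=40, seed=2)
        prep, _ = ss.prepare_table(table)
        pred = ss.PredictorColumn(
            name="rt_itself", values=prep.data["rt"].to_numpy(dtype=float),
            mask=np.zeros(len(prep.data), dtype=bool))
        res = ss.run_bootstrap(prep, pred, "control",
                               ss.BootstrapConfig(n_iterations=50,
                                                  master_seed=3))
        np.testing.assert_allclose(res.iteration_means, 1.0)

    def test_default_grid_shape(self):
        prep, pred = simple_study(n_subjects=22, n_trials=30, seed=4)
        cfg = ss.BootstrapConfig(master_seed=5)
        assert (cfg.n_iterations, cfg.n_subjects, cfg.n_trials) == (1000, 20, 25)
        res = ss.run_bootstrap(prep, pred, "control",
                               ss.BootstrapConfig(n_iterations=40,
                                                  master_seed=5))
        assert res.iteration_means.shape == (40,)
        assert np.all(np.abs(res.iteration_means[
            ~np.isnan(res.iteration_means)]) <= 1.0)

    def test_null_predictor_mean_near_zero(self):
        prep, pred = simple_study(rho_map=0.0, n_subjects=20, n_trials=60,
                                  seed=6)
        res = ss.run_bootstrap(prep, pred, "control",
                               ss.BootstrapConfig(n_iterations=1000,
                                                  master_seed=7))
        assert abs(res.mean) < 0.05

    def test_bit_identical_under_same_seed(self):
        prep, pred = simple_study(seed=8)
        cfg = ss.BootstrapConfig(n_iterations=60, master_seed=99)
        a = ss.run_bootstrap(prep, pred, "control", cfg)
        b = ss.run_bootstrap(prep, pred, "control", cfg)
        np.testing.assert_array_equal(a.iteration_means, b.iteration_means)

    def test_monotone_rt_transform_leaves_means_unchanged(self):
        prep, pred = simple_study(seed=9)
        cfg = ss.BootstrapConfig(n_iterations=60, master_seed=10)
        a = ss.run_bootstrap(prep, pred, "control", cfg)
        warped = prep.replace_data(prep.data.assign(
            rt=np.exp(prep.data["rt"].to_numpy() * 2.0)))
        b = ss.run_bootstrap(warped, pred, "control", cfg)
        np.testing.assert_array_equal(a.iteration_means, b.iteration_means)

    def test_within_subject_permutation_is_invariant(self):
        """Jointly permuting (x, y) within subjects changes nothing."""
        prep, pred = simple_study(n_subjects=6, n_trials=40, seed=11)
        cfg = ss.BootstrapConfig(n_iterations=60, master_seed=12)
        a = ss.run_bootstrap(prep, pred, "control", cfg)

        rng = np.random.default_rng(13)
        df = prep.data.copy()
        values = pred.values.copy()
        for subj in prep.subjects:
            idx = np.flatnonzero((df["subject"] == subj).to_numpy())
            perm = rng.permutation(idx)
            df.iloc[idx, df.columns.get_loc("rt")] = \
                df["rt"].to_numpy()[perm]
            df.iloc[idx, df.columns.get_loc("word1")] = \
                df["word1"].to_numpy()[perm]
            values[idx] = pred.values[perm]
        shuffled = prep.replace_data(df)
        pcol = ss.PredictorColumn(name=pred.name, values=values,
                                  mask=np.zeros(values.size, dtype=bool))
        b = ss.run_bootstrap(shuffled, pcol, "control", cfg)
        np.testing.assert_array_equal(a.iteration_means, b.iteration_means)

    def test_across_subject_rt_shuffle_kills_signal(self):
        prep, pred = simple_study(n_subjects=20, n_trials=60, seed=14)
        cfg = ss.BootstrapConfig(n_iterations=300, master_seed=15)
        signal = ss.run_bootstrap(prep, pred, "control", cfg)
        rng = np.random.default_rng(16)
        df = prep.data.copy()
        df["rt"] = rng.permutation(df["rt"].to_numpy())
        nulled = ss.run_bootstrap(prep.replace_data(df), pred, "control", cfg)
        assert signal.mean > 0.3
        assert abs(nulled.mean) < 0.08

    def test_insufficient_subjects(self):
        prep, pred = simple_study(n_subjects=20, seed=17)
        two = prep.replace_data(
            prep.data[prep.data["subject"].isin(prep.subjects[:2])]
            .reset_index(drop=True))
        pcol = ss.PredictorColumn(
            name="x", values=pred.values[:len(two.data)],
            mask=np.zeros(len(two.data), dtype=bool))
        with pytest.raises(ValueError, match="insufficient subjects"):
            ss.run_bootstrap(two, pcol, "control",
                             ss.BootstrapConfig(n_iterations=5))

    def test_small_pools_fall_back_to_replacement(self):
        cfg = ss.SimConfig(n_subjects=6, n_trials_per_condition=25,
                           control_label="control", effective_labels=(),
                           beta_semantic={"control": 0.5},
                           beta_frequency=0.0, beta_length=0.0,
                           predictor_mode="gaussian", p_correct=0.8,
                           master_seed=18)
        table, gt = ss.simulate_experiment(cfg)
        prep, keep = ss.prepare_table(table)
        pred = aligned_predictor(gt, keep)
        # after the 80% correctness filter most subjects have < 25 trials
        res = ss.run_bootstrap(prep, pred, "control",
                               ss.BootstrapConfig(n_iterations=30,
                                                  master_seed=19))
        assert res.trial_replacement_subjects > 0
        assert res.subject_replacement_used  # 6 < 20 subjects


class TestSummarize:
    def test_constant_distribution(self):
        r = ss.BootstrapResult(iteration_means=np.full(10, 0.3), mean=0.3,
                               sd=0.0, ci95=(0.3, 0.3),
                               n_subjects_available=5,
                               n_trials_available_per_subject={})
        s = ss.summarize(r)
        assert s["mean"] == 0.3 and s["sd"] == 0.0

    def test_hand_arithmetic(self):
        vals = np.array([0.1, 0.2, 0.3])
        assert vals.std(ddof=1) == pytest.approx(0.1)
        lo, hi = ss.confidence_interval_95(vals)
        assert lo <= vals.mean() <= hi
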