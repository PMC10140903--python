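"""Synthetic cohort generator: design balance, population structure,
behavioral plausibility."""

import numpy as np
import pandas as pd
import pytest

from switchddm import synthetic as syn


class TestTrialList:
    def test_block_structure(self):
        tl = syn.make_trial_list(0)
        assert len(tl[tl.phase == "pure"]) == 88
        assert len(tl[tl.phase == "practice"]) == 24
        scored = tl[(tl.phase == "test") & (~tl.warmup)]
        assert scored.groupby("block").size().tolist() == [128, 128, 128]
        assert len(tl[(tl.phase == "test") & tl.warmup]) == 24

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_cell_balance(self, seed):
        tl = syn.make_trial_list(seed)
        scored = tl[(tl.phase == "test") & (~tl.warmup)]
        for _b, g in scored.groupby("block"):
            counts = g.groupby(["switch_flag", "incon_flag"]).size()
            assert counts.tolist() == [32, 32, 32, 32]

    def test_repeat_runs_capped(self):
        tl = syn.make_trial_list(3)
        scored = tl[(tl.phase == "test") & (~tl.warmup)]
        for _b, g in scored.groupby("block"):
            s = g.switch_flag.to_numpy()
            run = longest = 0
            for x in s:
                run = run + 1 if x == 0 else 0
                longest = max(longest, run)
            assert longest <= 3  # identical-task runs of at most 4 trials

    def test_task_consistent_with_switch_flags(self):
        tl = syn.make_trial_list(5)
        test = tl[tl.phase == "test"]
        for _b, g in test.groupby("block"):
            tasks = g.task.tolist()
            flags = g.switch_flag.tolist()
            for k in range(1, len(tasks)):
                assert (tasks[k] != tasks[k - 1]) == bool(flags[k])

    def test_determinism(self):
        pd.testing.assert_frame_equal(syn.make_trial_list(7), syn.make_trial_list(7))


class TestPopulation:
    def test_degenerate_population_hits_means(self):
        spec = syn.PopulationSpec(n_subjects=5, sds={n: 0.0 for n in syn.LATENT_NAMES})
        lat, _cp, _ = syn.sample_population(spec, seed=0)
        for n in syn.LATENT_NAMES:
            assert np.allclose(lat[n], spec.means[n])

    def test_target_correlation_recovered(self):
        spec = syn.PopulationSpec(n_subjects=2000, rng_seed=1)
        lat, _cp, _ = syn.sample_population(spec)
        r = np.corrcoef(lat.wmc, lat.dt0_switch)[0, 1]
        assert r == pytest.approx(-0.40, abs=0.06)

    def test_truncation_rare_under_defaults(self):
        spec = syn.PopulationSpec(n_subjects=2000, rng_seed=2)
        _lat, _cp, trunc = syn.sample_population(spec)
        assert trunc < 0.01

    def test_non_psd_matrix_rejected(self):
        bad = np.eye(len(syn.LATENT_NAMES))
        bad[0, 1] = bad[1, 0] = 0.9
        bad[1, 2] = bad[2, 1] = 0.9
        bad[0, 2] = bad[2, 0] = -0.9
        with pytest.raises(ValueError, match="positive semi-definite"):
            syn.PopulationSpec(n_subjects=10, corr=bad).validate()

    def test_cell_parameter_assembly(self):
        spec = syn.PopulationSpec(n_subjects=3, sds={n: 0.0 for n in syn.LATENT_NAMES})
        _lat, cp, _ = syn.sample_population(spec, seed=0)
        m = spec.means
        be = spec.block_effects
        row = cp[(cp.subject == 0) & (cp.block == 2) & (cp.s == 1) & (cp.i == 1)].iloc[0]
        assert row.a == pytest.approx(m["a"] + be["a"][1])
        assert row.t0 == pytest.approx(m["t0_base"] + be["t0_base"][1] + m["dt0_switch"])
        assert row.v == pytest.approx(m["v_base"] + be["v_base"][1] + m["dv_switch"] + m["dv_incon"])


class TestSwitchTaskSimulation:
    def test_missing_cell_raises_with_name(self, rng):
        spec = syn.PopulationSpec(n_subjects=2)
        _lat, cp, _ = syn.sample_population(spec, seed=3)
        tl = syn.make_trial_list(4)
        broken = cp[~((cp.subject == 1) & (cp.block == 2) & (cp.s == 1) & (cp.i == 0))]
        with pytest.raises(ValueError, match="subject 1.*block 2"):
            syn.simulate_switch_task(broken, tl, seed=5)

    def test_determinism(self):
        spec = syn.PopulationSpec(n_subjects=2, rng_seed=6)
        _lat, cp, _ = syn.sample_population(spec)
        tl = syn.make_trial_list(6)
        t1 = syn.simulate_switch_task(cp, tl, seed=8)
        t2 = syn.simulate_switch_task(cp, tl, seed=8)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_drift_gives_chance_accuracy(self):
        means = dict(t0_base=0.3, dt0_switch=0.0, v_base=0.0, dv_switch=0.0,
                     dv_incon=0.0, a=1.5, wmc=0.0)
        spec = syn.PopulationSpec(
            n_subjects=6, means=means, sds={n: 0.0 for n in syn.LATENT_NAMES},
            block_effects={}, pi_cont=0.0)
        _lat, cp, _ = syn.sample_population(spec, seed=1)
        tl = syn.make_trial_list(2)
        trials = syn.simulate_switch_task(cp, tl, seed=3, pi_cont=0.0)
        acc = trials.accuracy.mean()
        n = len(trials)
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_t0_increment_appears_in_mean_rt(self):
        """With drift equal across conditions, the switch-repeat RT gap
        equals the generated non-decision increment."""
        means = dict(t0_base=0.30, dt0_switch=0.10, v_base=2.0, dv_switch=0.0,
                     dv_incon=0.0, a=1.5, wmc=0.0)
        spec = syn.PopulationSpec(
            n_subjects=15, means=means, sds={n: 0.0 for n in syn.LATENT_NAMES},
            block_effects={}, pi_cont=0.0)
        _lat, cp, _ = syn.sample_population(spec, seed=2)
        tl = syn.make_trial_list(9)
        trials = syn.simulate_switch_task(cp, tl, seed=10, pi_cont=0.0)
        sc = trials[(~trials.warmup) & (trials.accuracy == 1)]
        gap = sc[sc.switch_flag == 1].rt.mean() - sc[sc.switch_flag == 0].rt.mean()
        se = np.sqrt(sc[sc.switch_flag == 1].rt.var() / (sc.switch_flag == 1).sum()
                     + sc[sc.switch_flag == 0].rt.var() / (sc.switch_flag == 0).sum())
        assert abs(gap - 0.10) < 3 * se


class TestRnb:
    def test_design_crosses_load_and_updates(self):
        d = syn.rnb_design()
        test = d[d.phase == "test"]
        assert len(test) == 12
        assert set(zip(test.load, test.n_updates)) == {
            (l, u) for l in (1, 2, 3, 4) for u in (6, 9, 12)}

    def test_ceiling_subject_scores_81(self):
        lat = pd.DataFrame(dict(subject=[0], wmc=[0.0]))
        r = syn.simulate_rnb(lat, seed=1, intercept=14.0, slope_wmc=0.0, slope_load=0.0)
        test = r[(r.phase == "test") & (r.load >= 2)]
        assert int(test.correct.sum()) == 81

    def test_flat_link_uncorrelated_with_wmc(self):
        rng = np.random.default_rng(0)
        lat = pd.DataFrame(dict(subject=np.arange(400), wmc=rng.standard_normal(400)))
        r = syn.simulate_rnb(lat, seed=2, slope_wmc=0.0)
        totals = r[(r.phase == "test") & (r.load >= 2)].groupby("subject").correct.sum()
        rho = np.corrcoef(lat.set_index("subject").wmc[totals.index], totals)[0, 1]
        assert abs(rho) < 0.12

    def test_accuracy_decreasing_in_load(self):
        lat = pd.DataFrame(dict(subject=np.arange(200), wmc=np.zeros(200)))
        r = syn.simulate_rnb(lat, seed=3)
        means = r[r.phase == "test"].groupby("load").correct.mean()
        assert np.all(np.diff(means.to_numpy()) < 0)


def test_observable_summaries_reproduce_latent_sign_pattern():
    """End to end: working-memory score correlates negatively with the
    observed switch cost and with baseline RT, as the generating latent
    correlations dictate."""
    spec = syn.PopulationSpec(n_subjects=300, rng_seed=17)
    lat, cp, _ = syn.sample_population(spec)
    tl = syn.make_trial_list(18)
    trials = syn.simulate_switch_task(cp, tl, seed=19, dt=2e-3)
    sc = trials[(~trials.warmup) & (trials.accuracy == 1)]
    per = sc.groupby(["subject", "switch_flag"]).rt.mean().unstack()
    switch_cost = per[1] - per[0]
    baseline_rt = per[0]
    rnb = syn.simulate_rnb(lat, seed=20)
    totals = rnb[(rnb.phase == "test") & (rnb.load >= 2)].groupby("subject").correct.sum()
    assert np.corrcoef(totals, switch_cost[totals.index])[0, 1] < -0.05
    assert np.corrcoef(totals, baseline_rt[totals.index])[0, 1] < 0.0
    assert np.corrcoef(totals, lat.set_index("subject").wmc[totals.index])[0, 1] > 0.3
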