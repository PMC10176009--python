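"""Risk-preference computation and within-subject inference helpers."""

import numpy as np
import pytest
from scipy import stats as sps

import peirs_risk as pr
from peirs_risk import behavior as bh
from peirs_risk import task_design as td
from peirs_risk.errors import DataError


class TestExperiencePreferences:
    def test_handcrafted_log_matches_hand_count(self, trial_log_builder):
        # B and D are the high-SD stimuli; C, D the high-mean ones
        trials = trial_log_builder([
            ("high_context", "C", "D", "D", 60),   # risky
            ("high_context", "C", "D", "C", 60),   # safe
            ("low_context", "A", "B", "B", 30),    # risky
            ("low_context", "A", "B", "B", 35),    # risky
            ("mixed", "C", "A", "C", 70),          # correct
            ("mixed", "B", "D", "B", 20),          # wrong
            ("forced", "A", "", "A", 40),
            ("high_context", "D", "C", "D", 80),   # risky
        ])
        rp = pr.risk_preference_experience(trials)
        # second half of the single set = last 4 rows: 1 high (risky), mixed x1
        assert rp.n_high == 1 and rp.p_risky_high == 1.0
        assert rp.n_low == 0 and np.isnan(rp.p_risky_low)
        assert rp.n_mixed == 2 and rp.accuracy_mixed == 0.5

    def test_always_risky_agent_hits_one(self, default_schedule):
        trials = default_schedule.copy()
        set1, set2 = td.default_stimulus_sets()
        risky = {s.id for s in set1 + set2 if s.sd == 20}
        chosen = []
        for row in trials.itertuples(index=False):
            opts = [row.option_left] + ([row.option_right] if row.option_right else [])
            risky_opts = [o for o in opts if o in risky]
            chosen.append(risky_opts[0] if risky_opts else opts[0])
        trials["chosen"] = chosen
        trials["reward"] = 50.0
        rp = pr.risk_preference_experience(trials)
        assert rp.p_risky_high == 1.0 and rp.p_risky_low == 1.0

    def test_proportions_match_brute_force_on_simulated_log(self, sim_dataset):
        rp = pr.risk_preference_experience(sim_dataset.trials, sim_dataset.stimuli)
        t = sim_dataset.trials
        risky_ids = {"B", "D", "F", "H"}
        hits = n = 0
        for set_id, half in ((1, t[t.stim_set == 1]), (2, t[t.stim_set == 2])):
            second = half.iloc[len(half) // 2:]
            sel = second[second.trial_type == "high_context"]
            hits += sel.chosen.isin(risky_ids).sum()
            n += len(sel)
        assert rp.p_risky_high == pytest.approx(hits / n)


class TestDescriptionPreferences:
    def test_risk_proportions_from_context_gambles(self):
        sched, gambles = td.make_description_schedule(seed=1)
        trials = pr.simulate_description_choices(lambda g: 1.0, sched, gambles, 0)
        rp = pr.risk_preference_description(trials, gambles)
        assert rp.p_risky_high == 1.0 and rp.p_risky_low == 1.0
        assert rp.n_high == 8 and rp.n_low == 8

    def test_half_policy_mean_near_half_across_subjects(self):
        sched, gambles = td.make_description_schedule(seed=2)
        props = []
        for s in range(40):
            trials = pr.simulate_description_choices(lambda g: 0.5, sched,
                                                     gambles, seed=s)
            rp = pr.risk_preference_description(trials, gambles)
            props.append((rp.p_risky_high + rp.p_risky_low) / 2)
        assert abs(np.mean(props) - 0.5) < 0.05

    def test_hunger_flag_is_inert_for_description_analysis(self):
        """Same policy under both condition labels -> identical statistics."""
        sched, gambles = td.make_description_schedule(seed=3)
        pol = pr.prospect_policy()
        a = pr.simulate_description_choices(pol, sched, gambles, seed=4)
        rp_sated = pr.risk_preference_description(a, gambles, condition="sated")
        rp_hungry = pr.risk_preference_description(a, gambles, condition="hungry")
        assert rp_sated.p_risky_high == rp_hungry.p_risky_high
        assert rp_sated.p_risky_low == rp_hungry.p_risky_low


class TestRmAnova:
    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cells = rng.normal(0.5, 0.2, size=(12, 2, 2))
            res = bh.rm_anova_2x2(cells)
            inter = (cells[:, 0, 0] - cells[:, 0, 1]) - (cells[:, 1, 0] - cells[:, 1, 1])
            t = sps.ttest_1samp(inter, 0.0)
            assert res[2].F == pytest.approx(t.statistic**2, abs=1e-10)
            assert res[2].p == pytest.approx(t.pvalue, abs=1e-12)

    def test_against_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(6)
        for rep in range(5):
            cells = rng.normal(0.5, 0.2, size=(10, 2, 2))
            res = bh.rm_anova_2x2(cells, ("a", "b"))
            long = pd.DataFrame([
                {"subj": i, "a": ai, "b": bi, "y": cells[i, ai, bi]}
                for i in range(10) for ai in range(2) for bi in range(2)])
            oracle = pg.rm_anova(data=long, dv="y", within=["a", "b"],
                                 subject="subj", detailed=True)
            for name, row in zip(("a", "b", "a * b"), oracle.itertuples()):
                mine = next(r for r in res if r.effect.replace(" x ", " * ") == name)
                assert mine.F == pytest.approx(row.F, rel=1e-8)
                assert mine.p == pytest.approx(getattr(row, "p_unc"), rel=1e-6)

    def test_zero_variance_contrast_flagged(self):
        cells = np.tile([[0.6, 0.4], [0.6, 0.4]], (8, 1, 1))
        res = bh.rm_anova_2x2(cells)
        assert res[0].undefined  # no between-condition variation at all

    def test_partial_eta_squared_definition(self):
        rng = np.random.default_rng(7)
        cells = rng.normal(0, 1, size=(9, 2, 2))
        res = bh.rm_anova_2x2(cells)
        for r in res:
            assert r.partial_eta_sq == pytest.approx(r.F / (r.F + r.df[1]))

    def test_crossover_cohorts_detect_interaction(self):
        """Small power check: built-in hunger x context crossover is found."""
        sig = 0
        n_rep = 10
        from peirs_risk import agents as ag
        for rep in range(n_rep):
            p_s, p_h, _, _ = ag.sample_paired_conditions(
                ag.DEFAULT_SATED, ag.DEFAULT_HUNGRY, seed=300 + rep, n_subjects=16)
            cells = np.empty((16, 2, 2))
            for i in range(16):
                for a, plist in enumerate((p_s, p_h)):
                    sched = pr.make_experience_schedule(seed=1300 + rep * 40 + i * 2 + a)
                    d = pr.simulate_subject(plist[i], sched,
                                            seed=2300 + rep * 40 + i * 2 + a)
                    rp = pr.risk_preference_experience(d.trials, d.stimuli)
                    cells[i, a, 0] = rp.p_risky_high
                    cells[i, a, 1] = rp.p_risky_low
            if bh.rm_anova_2x2(cells)[2].p < 0.05:
                sig += 1
        assert sig >= 5  # n=16 cohorts: sizeable but not certain detection


class TestWilcoxon:
    def test_antisymmetric_data_gives_near_zero_z(self):
        d = np.array([3.0, -3.0, 1.5, -1.5, 2.0, -2.0, 4.0, -4.0])
        z, p = pr.wilcoxon_signed_rank(d)
        assert abs(z) < 0.2 and p > 0.8

    def test_matches_exact_enumeration_oracle(self):
        """Ten distinct pairs: p from all 2^10 sign flips vs normal approx."""
        rng = np.random.default_rng(9)
        d = rng.normal(0.8, 1.0, size=10)
        assert np.all(d != 0)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        mu = 10 * 11 / 4
        count = 0
        for mask in range(1 << 10):
            w = sum(ranks[i] for i in range(10) if mask >> i & 1)
            if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                count += 1
        p_exact = count / (1 << 10)
        z, p_norm = pr.wilcoxon_signed_rank(d)
        assert p_norm == pytest.approx(p_exact, abs=0.03)

    def test_matches_scipy_approximation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0.3, 1.0, size=25)
        z, p = pr.wilcoxon_signed_rank(x)
        ref = sps.wilcoxon(x, zero_method="wilcox", correction=True,
                           method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_positive_differences_approach_maximum_z(self):
        n = 32
        d = np.arange(1.0, n + 1)
        z, p = pr.wilcoxon_signed_rank(d)
        mu = n * (n + 1) / 4
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        z_max = (n * (n + 1) / 2 - mu - 0.5) / sd
        assert z == pytest.approx(z_max)
        assert p < 1e-6

    def test_all_zero_differences_raise(self):
        with pytest.raises(DataError):
            pr.wilcoxon_signed_rank(np.zeros(8))


class TestStimulusUtility:
    def test_zero_gammas_return_q(self):
        p = pr.PeirsParams(0.3, 0.3, 0.2, 0.0, 0.0)
        u = pr.stimulus_utility([35, 35, 65, 65], [4, 16, 4, 16], p)
        assert np.allclose(u, [35, 35, 65, 65])

    def test_context_weighting_flips_risk_premium_by_mean(self):
        """gamma1 > 0: spread helps high-mean stimuli, hurts low-mean ones."""
        p = pr.PeirsParams(0.3, 0.3, 0.2, 0.0, 0.05)
        q = np.array([35.0, 35.0, 65.0, 65.0])
        s = np.array([4.0, 16.0, 4.0, 16.0])
        u = pr.stimulus_utility(q, s, p)
        assert u[3] > u[2]   # high-mean risky above high-mean safe
        assert u[1] < u[0]   # low-mean risky below low-mean safe

    def test_hand_computed_example(self):
        p = pr.PeirsParams(0.3, 0.3, 0.2, 0.1, 0.01)
        q = np.array([40.0, 60.0, 50.0, 50.0])
        s = np.array([10.0, 10.0, 5.0, 5.0])
        # delta_i = q_i - 50; u_i = q_i + 0.1 s_i + 0.01 delta_i s_i
        expected = np.array([40 + 1.0 + 0.01 * (-10) * 10,
                             60 + 1.0 + 0.01 * 10 * 10,
                             50 + 0.5 + 0.0,
                             50 + 0.5 + 0.0])
        assert np.allclose(pr.stimulus_utility(q, s, p), expected)

    def test_dataset_utilities_average_sets(self, sim_dataset):
        out = pr.dataset_stimulus_utilities(sim_dataset)
        assert set(out) == {"set1", "set2", "mean"}
        assert np.allclose(out["mean"], (out["set1"] + out["set2"]) / 2)


class TestFullSyntheticPattern:
    def test_sated_vs_hungry_qualitative_pattern(self):
        """Cohort means reproduce the learned-risk signature: sated
        risk-seeking in rich contexts and risk-averse in poor ones,
        hungry attenuated toward indifference."""
        from peirs_risk import agents as ag
        p_s, p_h, _, _ = ag.sample_paired_conditions(
            ag.DEFAULT_SATED, ag.DEFAULT_HUNGRY, seed=77, n_subjects=24)
        cells = np.empty((24, 2, 2))
        for i in range(24):
            for a, plist in enumerate((p_s, p_h)):
                sched = pr.make_experience_schedule(seed=6000 + i * 2 + a)
                d = pr.simulate_subject(plist[i], sched, seed=7000 + i * 2 + a)
                rp = pr.risk_preference_experience(d.trials, d.stimuli)
                cells[i, a, 0] = rp.p_risky_high
                cells[i, a, 1] = rp.p_risky_low
        sated_high, sated_low = cells[:, 0, 0].mean(), cells[:, 0, 1].mean()
        hungry_high, hungry_low = cells[:, 1, 0].mean(), cells[:, 1, 1].mean()
        assert sated_high > 0.5 > sated_low
        assert abs(hungry_high - 0.5) < abs(sated_high - 0.5)
        assert abs(hungry_low - 0.5) < abs(sated_low - 0.5)

    def test_description_pattern_reversed_and_hunger_insensitive(self):
        sched, gambles = td.make_description_schedule(seed=8)
        pol = pr.prospect_policy()
        highs, lows = [], []
        for s in range(24):
            trials = pr.simulate_description_choices(pol, sched, gambles, seed=s)
            rp = pr.risk_preference_description(trials, gambles)
            highs.append(rp.p_risky_high)
            lows.append(rp.p_risky_low)
        assert np.mean(lows) > 0.5 > np.mean(highs)
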