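"""Learning rules, context signal, utility, softmax, and session likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import peirs_risk as pr
from peirs_risk import model_core as mc
from peirs_risk.errors import DataError


class TestUpdateRules:
    @pytest.mark.parametrize("q,r,alpha,expected", [
        (50.0, 50.0, 0.3, 50.0),     # zero prediction error
        (50.0, 65.0, 0.2, 53.0),     # 50 + 0.2*15
        (50.0, 80.0, 0.999999, pytest.approx(80.0, abs=1e-4)),
    ])
    def test_update_q(self, q, r, alpha, expected):
        assert mc.update_q(q, r, alpha) == expected

    @pytest.mark.parametrize("s,q,r,alpha,expected", [
        (5.0, 50.0, 55.0, 0.3, 5.0),   # |r-q| = s: fixed point
        (5.0, 50.0, 50.0, 0.5, 2.5),   # 5 + 0.5*(0-5)
        (5.0, 50.0, 30.0, 1.0, 20.0),  # alpha->1: s' = |r-q|
    ])
    def test_update_s(self, s, q, r, alpha, expected):
        assert mc.update_s(s, q, r, alpha) == expected

    def test_spread_converges_to_mean_absolute_deviation(self):
        # with q held at the true mean, s -> E|r - mu| = sigma*sqrt(2/pi)
        rng = np.random.default_rng(8)
        sigma = 20.0
        s = 5.0
        trace = []
        for r in rng.normal(50.0, sigma, size=40_000):
            s = mc.update_s(s, 50.0, r, 0.05)
            trace.append(s)
        longrun = np.mean(trace[20_000:])
        assert longrun == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.03)

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100),
           st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50)
    def test_spread_stays_nonnegative(self, s, q, r, alpha):
        assert mc.update_s(s, q, r, alpha) >= 0.0


class TestContextSignal:
    def test_high_context_is_plus_15(self):
        assert mc.delta_context([65, 65], [35, 35, 65, 65]) == 15.0

    def test_low_context_is_minus_15(self):
        assert mc.delta_context([35, 35], [35, 35, 65, 65]) == -15.0

    def test_all_equal_gives_zero(self):
        assert mc.delta_context([50, 50], [50, 50, 50, 50]) == 0.0

    def test_single_stimulus_presented(self):
        assert mc.delta_context([65], [35, 35, 65, 65]) == 15.0

    def test_empty_presented_raises(self):
        with pytest.raises(DataError):
            mc.delta_context([], [35, 35, 65, 65])

    def test_symmetry_over_contexts(self):
        # with true Q values the high/low context signals cancel exactly
        high = mc.delta_context([65, 65], [35, 35, 65, 65])
        low = mc.delta_context([35, 35], [35, 35, 65, 65])
        assert high + low == 0.0


class TestUtilityAndSoftmax:
    def test_rw_reduction(self):
        p = pr.PeirsParams(0.3, 0.3, 1.0, 0.0, 0.0)
        assert mc.utility(65.0, 20.0, 15.0, p) == 65.0

    def test_risk_propensity_term(self):
        p = pr.PeirsParams(0.3, 0.3, 1.0, 0.1, 0.0)
        assert mc.utility(65.0, 20.0, 0.0, p) == pytest.approx(67.0)

    def test_context_term(self):
        p = pr.PeirsParams(0.3, 0.3, 1.0, 0.0, 0.05)
        assert mc.utility(35.0, 20.0, -15.0, p) == pytest.approx(20.0)

    @pytest.mark.parametrize("uc,uu,beta,expected", [
        (50.0, 50.0, 1.0, 0.5),
        (80.0, 20.0, 0.0, 0.5),
        (60.0, 50.0, 0.1, 1 / (1 + np.exp(-1.0))),
    ])
    def test_choice_probability(self, uc, uu, beta, expected):
        assert mc.choice_probability(uc, uu, beta) == pytest.approx(expected)

    def test_softmax_numerically_stable(self):
        # |beta * dU| up to 1e3 must neither overflow nor return 0-prob logs
        assert mc.choice_probability(1000.0, 0.0, 1.0) == pytest.approx(1.0)
        assert mc.choice_probability(0.0, 1000.0, 1.0) >= 0.0
        assert np.isfinite(mc.log_choice_probability(0.0, 1000.0, 1.0))


def _hand_session():
    """A 6-trial session whose log-likelihood is computed by hand below."""
    import pandas as pd

    rows = [
        ("forced", "D", "", "D", 80.0),
        ("high_context", "C", "D", "D", 60.0),
        ("low_context", "A", "B", "A", 30.0),
        ("mixed", "D", "A", "D", 70.0),
        ("forced", "B", "", "B", 20.0),
        ("high_context", "D", "C", "C", 64.0),
    ]
    return pd.DataFrame([
        {"trial": i, "block": 1, "stim_set": 1, "trial_type": t,
         "option_left": l, "option_right": r, "chosen": c, "reward": rew}
        for i, (t, l, r, c, rew) in enumerate(rows, start=1)])


def _hand_loglik(params):
    """Spreadsheet-style independent recomputation, state written out."""
    import math

    aq, as_, beta, g0, g1 = (params.alpha_q, params.alpha_s, params.beta,
                             params.gamma0, params.gamma1)
    q = {k: 50.0 for k in "ABCD"}
    s = {k: 5.0 for k in "ABCD"}
    ll = 0.0

    def upd(c, r):
        pe = r - q[c]
        s[c] = s[c] + as_ * (abs(pe) - s[c])
        q[c] = q[c] + aq * pe

    def u(c, dc):
        return q[c] + g0 * s[c] + g1 * dc * s[c]

    def logp(c, o):
        dc = 0.5 * (q[c] + q[o]) - sum(q.values()) / 4.0
        return -math.log(1.0 + math.exp(-beta * (u(c, dc) - u(o, dc))))

    upd("D", 80.0)                      # t1 forced: no likelihood
    ll += logp("D", "C"); upd("D", 60.0)   # t2
    ll += logp("A", "B"); upd("A", 30.0)   # t3
    ll += logp("D", "A"); upd("D", 70.0)   # t4
    upd("B", 20.0)                      # t5 forced
    ll += logp("C", "D"); upd("C", 64.0)   # t6
    return ll


class TestSessionLoglik:
    def test_matches_hand_stepped_oracle(self):
        params = pr.PeirsParams(0.25, 0.4, 0.2, 0.1, 0.04)
        trials = _hand_session()
        assert pr.session_loglik(params, trials) == pytest.approx(
            _hand_loglik(params), abs=1e-12)

    def test_hand_oracle_rw_mode(self):
        params = pr.PeirsParams(0.25, 0.4, 0.2, 0.0, 0.0)
        trials = _hand_session()
        assert pr.session_loglik(params, trials, model="rw") == pytest.approx(
            _hand_loglik(params), abs=1e-12)

    def test_beta_zero_gives_n_log_half(self):
        trials = _hand_session()
        params = pr.PeirsParams(0.3, 0.3, 0.0)
        # 4 two-option trials
        assert pr.session_loglik(params, trials) == pytest.approx(
            4 * np.log(0.5))

    def test_per_trial_probabilities_are_valid(self, sim_dataset):
        params = sim_dataset.params
        ll = pr.session_loglik(params, sim_dataset.trials)
        n_choice = (sim_dataset.trials.option_right != "").sum()
        assert ll <= 0.0
        assert ll / n_choice > np.log(1e-6)  # no degenerate trials

    def test_equals_replayed_choice_probabilities(self, sim_dataset):
        """Dual route: compiled kernel vs python replay + softmax chain."""
        params = sim_dataset.params
        q_trace, s_trace = pr.replay_latent_trace(params, sim_dataset.trials)
        idx = {sid: i for i, sid in enumerate(mc.STIMULUS_IDS)}
        total = 0.0
        for t, row in enumerate(sim_dataset.trials.itertuples(index=False)):
            if row.option_right == "":
                continue
            base = 0 if row.stim_set == 1 else 4
            q = q_trace[t]
            s = s_trace[t]
            c, o = idx[row.chosen], idx[
                row.option_left if row.chosen != row.option_left else row.option_right]
            dc = 0.5 * (q[c] + q[o]) - q[base:base + 4].mean()
            uc = mc.utility(q[c], s[c], dc, params)
            uo = mc.utility(q[o], s[o], dc, params)
            total += mc.log_choice_probability(uc, uo, params.beta)
        assert pr.session_loglik(params, sim_dataset.trials) == pytest.approx(
            total, abs=1e-9)

    def test_likelihood_peaks_near_generating_parameters(self):
        """Average log-likelihood at the truth beats clearly perturbed values."""
        truth = pr.PeirsParams(0.3, 0.3, 0.3, 0.0, 0.06)
        lls = {"truth": 0.0, "aq": 0.0, "beta": 0.0, "g1": 0.0}
        for i in range(6):
            sched = pr.make_experience_schedule(seed=300 + i)
            ds = pr.simulate_subject(truth, sched, seed=400 + i)
            lls["truth"] += pr.session_loglik(truth, ds.trials)
            lls["aq"] += pr.session_loglik(
                pr.PeirsParams(0.85, 0.3, 0.3, 0.0, 0.06), ds.trials)
            lls["beta"] += pr.session_loglik(
                pr.PeirsParams(0.3, 0.3, 0.05, 0.0, 0.06), ds.trials)
            lls["g1"] += pr.session_loglik(
                pr.PeirsParams(0.3, 0.3, 0.3, 0.0, -0.06), ds.trials)
        assert lls["truth"] > lls["aq"]
        assert lls["truth"] > lls["beta"]
        assert lls["truth"] > lls["g1"]

    def test_missing_reward_raises(self, trial_log_builder):
        trials = trial_log_builder([("mixed", "D", "A", "D", np.nan)])
        with pytest.raises(DataError):
            pr.session_loglik(pr.PeirsParams(0.3, 0.3, 0.2), trials)

    def test_chosen_not_offered_raises(self, trial_log_builder):
        trials = trial_log_builder([("mixed", "D", "A", "C", 50.0)])
        with pytest.raises(DataError):
            pr.session_loglik(pr.PeirsParams(0.3, 0.3, 0.2), trials)
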