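"""Choice models: recursions, likelihoods, fitting, model comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import explicit_rho_sum
from revenc.choice_models import (ChoiceOutcomeSeries, LogRegParams,
                                  QForgetParams, RLogRegParams, WSLSParams,
                                  compare_models, fit_model,
                                  latent_correlation, model_loglik,
                                  q_trajectory, rlogreg_state,
                                  series_from_session, softmax_p)
from revenc.task import AgentParams, simulate_agent


def series(c, R):
    c = np.asarray(c, dtype=float)
    R = np.asarray(R, dtype=float)
    return ChoiceOutcomeSeries(c=c, R=R, r=c * R)


class TestQTrajectory:
    def test_hand_evaluated_updates(self):
        # alpha=0.5, phi=0.1: right rewarded then left unrewarded
        s = series([1, -1, 1], [1, 0, 0])
        lat = q_trajectory(s, QForgetParams(alpha=0.5, beta=1.0, phi=0.1))
        # values recorded at choice time (pre-update)
        assert lat.q_right[0] == 0.0 and lat.q_left[0] == 0.0
        assert lat.q_right[1] == pytest.approx(0.5)  # after trial-1 update
        assert lat.q_left[1] == 0.0
        # trial 2: left chosen, R=0 -> left stays 0; right decays 0.5*0.9
        assert lat.q_right[2] == pytest.approx(0.45)
        assert lat.q_left[2] == 0.0

    def test_rpe_is_reward_minus_chosen_value(self):
        s = series([1, 1], [1, 1])
        lat = q_trajectory(s, QForgetParams(alpha=0.5, beta=1.0, phi=0.0))
        assert lat.rpe[0] == pytest.approx(1.0)
        assert lat.rpe[1] == pytest.approx(0.5)

    def test_no_forgetting_freezes_unchosen_value(self):
        rng = np.random.default_rng(0)
        c = np.where(rng.random(50) < 0.5, 1.0, -1.0)
        R = (rng.random(50) < 0.5).astype(float)
        lat = q_trajectory(series(c, R),
                           QForgetParams(alpha=0.3, beta=1.0, phi=0.0))
        # left never chosen before the first left choice -> Q_left stays 0
        first_left = np.argmax(c < 0)
        assert np.all(lat.q_left[:first_left + 1] == 0.0)

    def test_dq_sq_algebraically_consistent(self):
        s = series([1, -1, 1, 1], [1, 1, 0, 1])
        lat = q_trajectory(s, QForgetParams(alpha=0.7, beta=2.0, phi=0.3))
        np.testing.assert_allclose(lat.dq, lat.q_left - lat.q_right)
        np.testing.assert_allclose(lat.sq, lat.q_left + lat.q_right)


class TestSoftmax:
    def test_symmetry_and_flatness(self):
        assert softmax_p(0.0, 3.0) == 0.5
        assert softmax_p(2.0, 0.0) == 0.5
        assert softmax_p(-5.0, 0.0) == 0.5

    def test_direct_evaluation(self):
        assert softmax_p(0.5, 3.0) == pytest.approx(0.81757, abs=1e-5)

    def test_overflow_safe(self):
        assert softmax_p(1e4, 50.0) == 1.0
        assert softmax_p(-1e4, 50.0) == 0.0


class TestRLogRegState:
    def test_hand_recursion(self):
        s = series([1, 1, 1], [1, 0, 1])
        p = RLogRegParams(alpha_stick=0.0, beta_rew=1.0, gamma=0.0, tau=1.0)
        lat = rlogreg_state(s, p)
        np.testing.assert_allclose(lat.rho, [1.0, 0.36788, 1.13534],
                                   atol=1e-5)

    def test_zero_rewards_give_zero_state(self):
        s = series([1, -1, 1, -1], [0, 0, 0, 0])
        p = RLogRegParams(alpha_stick=0.5, beta_rew=2.0, gamma=0.1, tau=3.0)
        assert np.all(rlogreg_state(s, p).rho == 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 20.0))
    def test_recursion_equals_explicit_sum(self, seed, tau):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        c = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        R = (rng.random(n) < 0.6).astype(float)
        s = series(c, R)
        beta = float(rng.uniform(-3, 3))
        p = RLogRegParams(alpha_stick=0.0, beta_rew=beta, gamma=0.0, tau=tau)
        got = rlogreg_state(s, p).rho
        expected = explicit_rho_sum(s.r, beta, tau)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestLoglik:
    def test_wsls_stay_after_win_probability(self):
        # two trials: win then stay
        s = series([1, 1], [1, 1])
        nll = model_loglik("wsls", s, WSLSParams(epsilon=0.2))
        # trial 1: P=0.5; trial 2: stay after win -> (1-eps)+eps/2 = 0.9
        assert nll == pytest.approx(-math.log(0.5) - math.log(0.9))

    def test_wsls_pure_lapse_is_coin_flip(self):
        rng = np.random.default_rng(3)
        c = np.where(rng.random(40) < 0.5, 1.0, -1.0)
        R = (rng.random(40) < 0.5).astype(float)
        nll = model_loglik("wsls", series(c, R), WSLSParams(epsilon=1.0))
        assert nll == pytest.approx(40 * math.log(2))

    def test_flat_softmax_is_coin_flip(self):
        rng = np.random.default_rng(4)
        c = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        R = (rng.random(30) < 0.5).astype(float)
        nll = model_loglik("qforget", series(c, R),
                           QForgetParams(alpha=0.5, beta=0.0, phi=0.1))
        assert nll == pytest.approx(30 * math.log(2))

    def test_qforget_nll_matches_trial_by_trial_hand_recursion(self):
        # independent recursion written out longhand, 12 trials
        rng = np.random.default_rng(5)
        c = np.where(rng.random(12) < 0.5, 1.0, -1.0)
        R = (rng.random(12) < 0.6).astype(float)
        alpha, beta, phi = 0.4, 2.5, 0.15
        ql = qr = 0.0
        nll = 0.0
        for t in range(12):
            p_right = 1.0 / (1.0 + math.exp(-beta * (qr - ql)))
            nll -= math.log(p_right if c[t] > 0 else 1 - p_right)
            if c[t] > 0:
                qr, ql = qr + alpha * (R[t] - qr), ql * (1 - phi)
            else:
                ql, qr = ql + alpha * (R[t] - ql), qr * (1 - phi)
        got = model_loglik("qforget", series(c, R),
                           QForgetParams(alpha=alpha, beta=beta, phi=phi))
        assert got == pytest.approx(nll, abs=1e-12)

    def test_rlogreg_nll_matches_hand_recursion(self):
        rng = np.random.default_rng(6)
        c = np.where(rng.random(10) < 0.5, 1.0, -1.0)
        R = (rng.random(10) < 0.6).astype(float)
        a, b, g, tau = 0.4, 1.2, -0.2, 2.0
        rho_prev, c_prev = 0.0, 0.0
        nll = 0.0
        for t in range(10):
            h = g + a * c_prev + rho_prev
            p_right = 1.0 / (1.0 + math.exp(-h))
            nll -= math.log(p_right if c[t] > 0 else 1 - p_right)
            rho_prev = b * c[t] * R[t] + math.exp(-1 / tau) * rho_prev
            c_prev = c[t]
        got = model_loglik(
            "rlogreg", series(c, R),
            RLogRegParams(alpha_stick=a, beta_rew=b, gamma=g, tau=tau))
        assert got == pytest.approx(nll, abs=1e-12)

    def test_logreg_drops_first_five_trials(self):
        s = series([1.0] * 7, [1.0] * 7)
        p = LogRegParams(beta0=0.0, beta1=(0,) * 5, beta2=(0,) * 5)
        assert model_loglik("logreg", s, p) == pytest.approx(2 * math.log(2))

    def test_qforget_with_phi_zero_equals_plain_q_model(self):
        s = simulate_agent(AgentParams(), n_trials=200, seed=8)
        ser = series_from_session(s)
        p3 = QForgetParams(alpha=0.37, beta=4.1, phi=0.0)
        assert model_loglik("qforget", ser, p3) == \
            model_loglik("qlearn", ser, QForgetParams(alpha=0.37, beta=4.1))


class TestFitting:
    def test_refit_is_deterministic(self):
        s = simulate_agent(AgentParams(), n_trials=300, seed=9)
        a = fit_model("qforget", s, n_restarts=3, seed=5)
        b = fit_model("qforget", s, n_restarts=3, seed=5)
        assert a.params == b.params and a.nll == b.nll

    def test_aic_bic_identities(self):
        s = simulate_agent(AgentParams(), n_trials=300, seed=10)
        for name in ("wsls", "qlearn", "qforget", "rlogreg", "logreg"):
            f = fit_model(name, s, n_restarts=3, seed=0)
            assert f.aic == pytest.approx(2 * f.n_params + 2 * f.nll)
            n_pred = f.n_trials - 5 if name == "logreg" else f.n_trials
            assert f.bic == pytest.approx(
                f.n_params * math.log(n_pred) + 2 * f.nll)
            assert np.all((f.p_right[~np.isnan(f.p_right)] > 0)
                          & (f.p_right[~np.isnan(f.p_right)] < 1))

    def test_deterministic_chooser_drives_beta_to_bound(self):
        # an always-right agent admits arbitrarily large beta
        c = np.ones(100)
        R = np.tile([1.0, 0.0], 50)
        f = fit_model("qforget", series(c, R), n_restarts=5, seed=0)
        assert f.boundary

    def test_too_few_trials_rejected(self):
        s = simulate_agent(AgentParams(), n_trials=20, seed=0)
        with pytest.raises(ValueError, match="50"):
            fit_model("qforget", s)

    def test_single_model_comparison_rejected(self):
        s = simulate_agent(AgentParams(), n_trials=100, seed=0)
        with pytest.raises(ValueError, match="2 models"):
            compare_models(s, model_names=["qforget"])


class TestLatentCorrelation:
    def test_identical_and_negated_series(self):
        x = np.array([0.1, 0.5, -0.3, 0.8])
        assert latent_correlation(x, x) == pytest.approx(1.0)
        assert latent_correlation(x, -x) == pytest.approx(-1.0)

    def test_constant_series_undefined(self):
        assert math.isnan(latent_correlation(np.ones(5),
                                             np.array([1, 2, 3, 4, 5.0])))

    def test_state_estimate_tracks_value_difference(self):
        # rLogReg rho and Q-model dQ are strongly correlated on sessions
        # generated by the value-guided agent
        s = simulate_agent(AgentParams(alpha=0.6, beta=5.0, phi=0.2),
                           n_trials=500, seed=12)
        fq = fit_model("qforget", s, n_restarts=5, seed=0)
        fr = fit_model("rlogreg", s, n_restarts=5, seed=0)
        r = latent_correlation(fr.latents.rho, -fq.latents.dq)
        assert abs(r) > 0.7
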