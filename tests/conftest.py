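import numpy as np
import pytest

from revenc.choice_models import compare_models, fit_model
from revenc.neural_sim import synthesize_head_velocity
from revenc.task import AgentParams, simulate_agent

TRUE_QFORGET = AgentParams(policy="qforget", alpha=0.6, beta=5.0, phi=0.2)


@pytest.fixture(scope="session")
def encoding_session():
    """A 60-trial session with fitted behavior latents and head velocity."""
    session = simulate_agent(TRUE_QFORGET, n_trials=60, seed=7)
    bfit = fit_model("qforget", session, n_restarts=5, seed=0)
    hv = synthesize_head_velocity(session, seed=1)
    return session, bfit, hv


@pytest.fixture(scope="session")
def encoding_recovery_suite(encoding_session):
    """Synthetic-neuron recovery runs shared by unit and acceptance tests.

    Part A: noiseless neurons spanning the tuned profiles — round-trip FVE
    and kernel-peak recovery.  Part B: noisy neurons carrying a reward
    kernel (peak 1.0 dF/F vs noise sigma 0.15, i.e. >3x) — tuning indices
    for the injected effect and for a predictor with zero true effect.
    """
    from revenc.encoding import EncodingConfig, extract_kernel, \
        fit_encoding, tuning_index
    from revenc.neural_sim import sample_ground_truth, synthesize_trace

    session, bfit, hv = encoding_session
    config = EncodingConfig(n_folds=50, seed=0)
    profiles = ["reward_brief", "noreward_persistent"]
    tuned_event = {"reward_brief": "o_plus",
                   "noreward_persistent": "o_minus"}
    noiseless = []
    for i in range(8):
        profile = profiles[i % 2]
        gt = sample_ground_truth(tuning_profile=profile, seed=300 + i,
                                 noise_sigma=0.0)
        trace, design = synthesize_trace(session, gt, bfit.latents,
                                         head_velocity=hv, seed=400 + i)
        fit = fit_encoding(design, trace, config)
        name = tuned_event[profile]
        est = extract_kernel(fit, name)
        _, true_k = gt.event_kernel(name)
        peak = np.max(np.abs(true_k))
        noiseless.append({
            "profile": profile, "fve": fit.fve, "fit": fit,
            "kernel_peak_err": np.max(np.abs(est.values - true_k)) / peak,
        })

    # predictors carrying reward-outcome information; dropping them all is
    # how tuning to the injected outcome effect is classified (the fixed
    # 0.5 s choice-outcome delay makes single-predictor drops absorbable
    # by the remaining outcome-tethered predictors)
    outcome_set = ["o_plus", "o_minus", "ch_o_plus", "ch_o_minus",
                   "rpe_plus", "rpe_minus"]
    noisy = []
    for i in range(12):
        gt = sample_ground_truth(tuning_profile="reward_brief",
                                 seed=500 + i, noise_sigma=0.15)
        trace, design = synthesize_trace(session, gt, bfit.latents,
                                         head_velocity=hv, seed=600 + i)
        fit = fit_encoding(design, trace, config)
        effect = tuning_index(fit, design, trace, outcome_set, config)
        null = tuning_index(fit, design, trace, ["cue"], config)
        noisy.append({"fit": fit, "effect": effect, "null": null})
    return noiseless, noisy


@pytest.fixture(scope="session")
def qforget_recovery():
    """Refit the generating model on 20 agents of 1000 trials each."""
    fits = []
    for seed in range(20):
        s = simulate_agent(TRUE_QFORGET, n_trials=1000, seed=100 + seed)
        fits.append(fit_model("qforget", s, n_restarts=10, seed=seed))
    return TRUE_QFORGET, fits


@pytest.fixture(scope="session")
def model_recovery_tables():
    """AIC comparison of all five models on 20 sessions from the RL agent."""
    tables = []
    for seed in range(20):
        s = simulate_agent(TRUE_QFORGET, n_trials=1000, seed=200 + seed)
        tables.append(compare_models(s, n_restarts=10, seed=seed))
    return tables
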