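#!/usr/bin/env python
"""Synthesize calcium traces for two pathway populations.

Builds a 60-trial session, fits the forgetting Q-learner to obtain the
value latents, and generates 16 synthetic neurons at 20 Hz: pathway "A"
neurons carry a brief reward kernel, pathway "P" neurons a slow
persistent no-reward kernel (three-fold weaker), both plus Gaussian
noise.  Writes results/traces.h5 and results/neural_trials.csv.
"""

from pathlib import Path

from revenc import io
from revenc.choice_models import fit_model
from revenc.neural_sim import (sample_ground_truth,
                               synthesize_head_velocity, synthesize_trace)
from revenc.task import AgentParams, simulate_agent

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

session = simulate_agent(AgentParams(alpha=0.6, beta=5.0, phi=0.2),
                         n_trials=60, seed=7)
session.session_id = "neural000"
bfit = fit_model("qforget", session, n_restarts=10, seed=0)
hv = synthesize_head_velocity(session, seed=1)

traces, truths = [], {}
for i in range(16):
    pathway = "A" if i < 8 else "P"
    profile = ({"o_plus": (1.0, 1.0)} if pathway == "A"
               else {"o_minus": (0.35, 5.8)})
    gt = sample_ground_truth(tuning_profile=profile, seed=20 + i,
                             noise_sigma=0.15)
    trace, _ = synthesize_trace(session, gt, bfit.latents,
                                head_velocity=hv, seed=50 + i,
                                neuron_id=f"n{i:03d}",
                                pathway_label=pathway)
    traces.append(trace)
    truths[trace.neuron_id] = gt

io.write_trial_table(session, OUT / "neural_trials.csv")
io.write_traces(traces, OUT / "traces.h5", ground_truths=truths)
print(f"wrote {len(traces)} neurons ({len(traces[0].frame_times)} frames "
      f"at 20 Hz) to {OUT / 'traces.h5'}")
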