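#!/usr/bin/env python
"""Fit the five trial-by-trial choice models and compare them by AIC/BIC.

Reads results/trial_table.csv (from 01_simulate_behavior.py), fits the
win-stay/lose-shift, Q-learning, Q-learning-with-forgetting, recursive
logistic regression and 5-lag logistic regression models to each
session, and writes results/model_comparison.csv.  Because the sessions
were generated by the forgetting Q-learner, that model should win the
comparison, with the recursive logistic regression close behind — and
its fitted state estimate should correlate strongly with the Q-value
difference.
"""

from pathlib import Path

import pandas as pd

from revenc import io
from revenc.choice_models import compare_models, fit_model, \
    latent_correlation

OUT = Path(__file__).resolve().parent.parent / "results"
sessions = io.read_trial_table(OUT / "trial_table.csv")

tables = []
for s in sessions:
    table = compare_models(s, n_restarts=10, seed=0)
    table.insert(0, "session_id", s.session_id)
    tables.append(table)
    print(f"\n{s.session_id} (AIC ranking):")
    print(table[["model", "n_params", "nll", "aic", "bic"]]
          .to_string(index=False))
    fq = fit_model("qforget", s, n_restarts=10, seed=0)
    fr = fit_model("rlogreg", s, n_restarts=10, seed=0)
    r = latent_correlation(fr.latents.rho, fq.latents.dq)
    p = fq.params
    print(f"  qforget fit: alpha={p.alpha:.3f} beta={p.beta:.2f} "
          f"phi={p.phi:.3f};  corr(rho, dQ) = {r:.3f}")

pd.concat(tables).to_csv(OUT / "model_comparison.csv", index=False)
print(f"\nwrote {OUT / 'model_comparison.csv'}")
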