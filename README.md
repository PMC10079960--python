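# revenc

Reversal-learning choice models and a penalized linear encoding model for
calcium imaging, built for studies of prefrontal→striatal circuits during
value-based choice.

Mice in a two-alternative forced-choice (2AFC) serial-reversal task choose
between two side ports; the "correct" port delivers a 12 μl reward with
probability 0.85 (an incorrect choice triggers a punishment tone with the
same probability, and nothing happens otherwise), and the contingency
reverses whenever 8 of the last 10 choices were to the rewarded port. This
package implements, end to end and on synthetic data it generates itself:

* **Task & agent simulation** — the reversal schedule, trial timing, and
  reward-sensitive agents (Q-learning with forgetting, win-stay/lose-shift
  with lapse, random), producing trial tables structurally identical to
  operant session logs.
* **Choice models** — five trial-by-trial models of choice fit by maximum
  likelihood and compared by AIC/BIC:
  - Q-learning: `Q ← Q + α(R − Q)` for the chosen port; with *forgetting*,
    the unchosen port decays `Q ← Q(1 − φ)`; choice via softmax
    `P_A = 1/(1 + exp(−β(Q_A − Q_B)))`.
  - Logistic regression on the previous 5 choices and rewarded sides.
  - Recursive logistic regression with state estimate
    `ρ(t) = β r(t) + e^{−1/τ} ρ(t−1)` and logit
    `h(t+1) = γ + α c(t) + ρ(t)`.
  - Win-stay/lose-shift with lapse rate ε.
* **Behavioral metrics** — win-stay/lose-stay probabilities, the relative
  reward stay `ln[(p_ws/(1−p_ws)) / (p_ls/(1−p_ls))]` (training criterion
  > 2), optogenetic ΔWinStay/ΔLoseStay contrasts conditioned on the prior
  trial's light status, local reward rate (μl/min over the prior 5
  trials), and engagement summaries.
* **Neural encoding model** — a neuron's dF/F trace modeled as
  `y(t) = α + Σᵢ βᵢ xᵢ(t) + Σⱼₖₙ γₖ⁽ʲ⁾ fₖ⁽ʲ⁾(t − tₙ⁽ʲ⁾) + ε`:
  cubic B-spline event kernels (cue, initiation, choice, outcome ±,
  choice×outcome ±, RPE ±) plus continuous predictors (ΔQ, ΣQ, reward
  rate, head velocity), fit with a near-lasso elastic net (mixing 0.95),
  50-fold trial-stratified cross-validation on 200 ms chunks, and the
  one-standard-error λ rule. Model quality is the cross-validated
  fraction of variance explained (FVE); tuning is
  `FVE(full) − FVE(reduced)` with 5% thresholds.
* **Pathway statistics** — per-lag RMS kernels over task-tuned neurons,
  95% BCa bootstrap bands, per-lag pathway difference tests, and KS
  comparisons of tuning-index distributions.
* **Synthetic neural data** — traces built with exactly the encoding
  model's generative structure (kernels in the model's own spline bases),
  so noiseless round trips are exact and recovery is testable against
  stored ground truth.

## Worked example

The `analysis/` scripts run the whole pipeline on synthetic data; each is
a thin driver over the library. For example:

```bash
python analysis/01_simulate_behavior.py
python analysis/02_fit_choice_models.py
```

prints (abridged):

```
sim000: 500 trials, 43 blocks, correct 0.702, relative reward stay 2.89 (recording-ready)
...
sim002 (AIC ranking):
  model  n_params        nll        aic        bic
qforget         3 133.731574 273.463149 286.106973
 qlearn         2 135.063288 274.126577 282.555793
 logreg        11 126.806571 275.613142 321.863277
rlogreg         4 133.910755 275.821511 292.679943
   wsls         1 297.777635 597.555271 601.769879
  qforget fit: alpha=0.525 beta=5.82 phi=0.055;  corr(rho, dQ) = -0.887
```

The agent (generated with α=0.6, β=5, φ=0.2) completes ~43 blocks in 500
trials with a relative reward stay above the >2 criterion; refitting
recovers the generating model as the AIC winner, with the recursive
logistic regression's state estimate strongly correlated with the
Q-value difference. Scripts 03–06 compute the behavioral metrics,
synthesize two pathway populations of calcium traces (a brief reward
kernel in pathway A, a slow persistent no-reward kernel in pathway P),
fit the encoding model per neuron, and run the pathway bootstrap
statistics:

```
o_plus / pathway A: 8 neurons, peak RMS 0.424 dF/F
o_minus: A vs P differs at 99% of lags (per-lag BCa bootstrap, 5% level)
```

A `revenc` command-line interface exposes the same stages
(`simulate-behavior`, `fit-behavior`, `metrics`, `simulate-neural`,
`fit-encoding`, `population-report`), each writing its artifacts plus a
JSON run manifest.

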