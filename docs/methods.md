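# Methods

## Task simulator

The task is a 2AFC serial reversal: one side port is rewarded (12 μl,
probability `p_outcome = 0.85` given a correct choice), the other
punished (500 ms tone, same probability given an incorrect choice); the
remaining trials deliver no outcome. Completed choices of the current
block are monitored and the contingency flips when at least 8 of the
last `min(elapsed, 10)` block trials were to the rewarded port.

Conventions chosen where the protocol leaves room:

* **The reversal window resets at each switch.** Without a reset, the
  first trials of a new block would count the old block's "correct"
  labels against the new contingency. A consequence used as an exact
  check: a perfectly accurate agent completes exactly 8 trials per
  block.
* **Omission trials** (no choice within the 3 s window) are generated
  with a configurable probability (default 0), excluded from the
  reversal window, from the choice/outcome series given to the models,
  and from stay metrics (the previous *completed* trial is the stay
  reference).
* **Timestamps**: fixed protocol delays (0.5 s hold, 0.5 s outcome
  delay, 3 s ITI, 3 s punishment timeout) plus log-normal animal
  latencies (median 0.4 s to initiate, 0.8 s to choose, capped at the
  3 s choice window). These latencies are a fixture choice; only their
  orderings and the fixed delays matter to downstream code.
* One seeded NumPy generator per session; identical (params, config,
  seed) gives an identical session, bit for bit.

## Choice models

All five models predict P(right) per completed trial; fitting minimizes
the negative log-likelihood (NLL) of the observed choices.

* **qlearn / qforget**: values start at (0, 0); chosen port
  `Q ← Q + α(R − Q)`, unchosen port `Q ← Q(1 − φ)` (φ = 0 recovers the
  plain model); softmax with inverse temperature β. Latents recorded at
  choice time (pre-update); the reward prediction error is `R − Q_chosen`
  (pre-update).
* **logreg**: logit = intercept plus weights on the signed choices and
  signed rewarded sides of lags 1–5; the first five trials are dropped
  from the likelihood (insufficient history). 11 parameters.
* **rlogreg**: `h(t+1) = γ + α c(t) + ρ(t)` with
  `ρ(t) = β r(t) + e^{−1/τ} ρ(t−1)`, `ρ(0) = 0`, and no stickiness term
  on trial 1. The recursion equals the explicit exponentially weighted
  sum to 1e−10 (property-tested).
* **wsls**: with probability ε the choice is uniform random; otherwise
  repeat after a win, switch after a loss, so
  P(rule-consistent) = (1 − ε) + ε/2. Trial 1 is a coin flip.

Fitting: bounds α, φ, ε ∈ [0,1], β ∈ [0,50], τ ∈ [0.01, 50],
stickiness/bias/regression weights ∈ [−10,10]; 20 seeded uniform-random
restarts of L-BFGS-B by default, best NLL wins, ties to the first
restart; optima on a bound are flagged. The 5-lag logistic regression is
convex and fit exactly by statsmodels `Logit`; under quasi-separation
(e.g. near-deterministic agents) it falls back to the same bounded
L-BFGS-B box and flags the boundary. Probabilities are clamped to
[1e−12, 1−1e−12] before logs. AIC = 2k + 2·NLL;
BIC = k·ln(n) + 2·NLL with n the number of predicted trials.

Recovery at the study's scale (20 agents × 1000 trials, true
α=0.6, β=5, φ=0.2): median absolute errors of α and φ below 0.1, β
within 20% relative error, and the generating model wins the five-way
AIC comparison in ≥80% of sessions.

## Behavioral metrics

* "Win" = previous completed trial rewarded; "lose" = any unrewarded
  completed trial (punishment *or* no outcome) — the protocol does not
  disambiguate, and no-outcome trials are behaviorally unrewarded.
* Relative reward stay = log odds-ratio of win-stay vs lose-stay; when
  any count is zero a Haldane–Anscombe 0.5 correction is applied to all
  four cells and the value is flagged.
* ΔWinStay/ΔLoseStay condition on the *prior* trial's light status for
  the named epoch; empty cells propagate as NaN with an explicit flag,
  never as 0.
* Local reward rate for trial t: rewards in trials t−w..t−1 times the
  reward volume, divided by the t−w→t trial-start span, in μl/min
  (w = 5); shorter histories are used verbatim early in the session.

## Synthetic calcium traces

Traces are generated with exactly the structure the encoding model
assumes: intercept + design matrix × ground-truth coefficients +
Gaussian white noise, at 20 Hz (the frame rate consistent with 200 ms
CV chunks spanning ~4 frames). Ground-truth event kernels are sums of
1–3 raised cosines projected onto the encoding model's own spline basis
and stored as coefficient vectors, so a noiseless trace equals the
design matrix times the truth to machine precision — the round-trip
identity that anchors the whole pipeline's tests. Named tuning profiles
emulate the phenomenology of interest: brief (~1 s) reward transients
and slow persistent (>5 s support) responses to unrewarded outcomes.
Default noise σ = 0.15 dF/F against ~1 dF/F kernel peaks; an optional
AR(1) switch exists for robustness checks only. Head velocity is a
rectified Ornstein–Uhlenbeck baseline with Gaussian bursts at every
initiation and choice poke.

What the generator does *not* emulate: calcium indicator dynamics and
spike-to-fluorescence convolution, autocorrelated and signal-dependent
noise, motion artifacts, or neuron-to-neuron correlations. Passing
recovery tests therefore demonstrate correctness of the fitting
machinery under the model's own assumptions, not robustness to real
calcium data.

## Encoding model

* **Bases**: clamped cubic B-splines on uniform interior knots.
  Defaults: cue/initiation/choice windows [−1, +2] s with 7 bases;
  outcome (O±), choice×outcome (Ch×O±) and RPE± windows [−0.5, +6] s
  with 10 bases (long enough for the persistent no-reward signals); all
  configurable per predictor.
* **Design**: event columns sum the basis over event occurrences,
  scaled by the event amplitude (±1 choice sign for Ch×O, the positive
  or negative prediction-error magnitude for RPE±). ΔQ and ΣQ are
  constant within a trial and step at outcome (the value after the last
  outcome is held). Reward rate steps at trial start; head velocity is
  linearly interpolated to frame times. Ch×O is coded by left/right
  choice sign; a session-level hemisphere field supports ipsi/contra
  relabeling.
* **Fitting**: elastic net, mixing fixed at 0.95, intercept unpenalized
  (handled by centering), continuous columns z-scored for fitting and
  coefficients reported on the original scale. A 30-point geometric λ
  path from the data-driven λ_max down to λ_max·1e−3.
* **Cross-validation**: frames grouped in 200 ms chunks; each trial's
  chunks are shuffled and dealt round-robin to the 50 folds through a
  global rotating pointer, so chunks are never split, trials are
  represented roughly equally in each fold, and fold sizes stay within
  a few chunks of each other.
* **λ rule**: the largest λ whose mean CV FVE is within one standard
  error (SD across folds / √K — the established cv.glmnet rule) of the
  maximum; ties on the path resolve toward larger λ (sparser model).
* **FVE**: reported FVE is computed from the assembled out-of-fold
  predictions at the selected λ (a training-FVE field also exists).
  Task-relevance gate: FVE ≥ 5%.
* **Tuning**: `FVE(full) − FVE(reduced)`, with the reduced model refit
  from scratch (own λ selection) on the pruned design; "tuned" requires
  the task gate plus an index above 5%.

**Identifiability caveat.** The protocol's fixed 0.5 s choice→outcome
delay makes the choice event and the outcome events nearly collinear:
every completed trial has a choice and, 0.5 s later, exactly one of O+
or O−, so a choice kernel plus compensating O± kernels can reproduce
any single outcome kernel. Consequences, measured on noiseless
synthetic neurons: single-predictor tuning drops are largely absorbed
by the remaining outcome-tethered predictors (index ≈ 0.03 for a
3σ-amplitude reward kernel when dropping O+ alone, vs ≈ 0.2 when
dropping all outcome-carrying predictors), and kernel amplitude in
multi-kernel or signed-interaction profiles can shift 10–20% into
collinear partners while shape correlation stays ≥ 0.99. Tuning is
therefore classified at the predictor-group level (the index is a lower
bound on a predictor's contribution), and exact kernel-amplitude
recovery is guaranteed only for isolated kernels. This is a property of
the task design, not of the optimizer.

## Pathway statistics

RMS kernels are per-lag root-mean-squares over task-tuned neurons —
magnitudes, never negative. Confidence bands and the per-lag pathway
difference test use the BCa bootstrap over neurons
(`scipy.stats.bootstrap`, jackknife acceleration), 10,000 resamples by
default, 95% level; degenerate BCa cases fall back to percentile
intervals and are flagged. Per-lag tests are not corrected for multiple
comparisons across lags. Tuning-index distributions are compared with
two-sample two-sided KS tests plus tuned proportions at the 5%
threshold.

Null calibration of the difference test is checked with 200 replicate
pathway pairs of 30 task-relevant neurons each (a realistic population
for these recordings) at 1000 resamples, where the pointwise type-I
error sits near the nominal 5%. Known limitation: like most bootstrap
tests, it is anticonservative for small populations — with 8–20 neurons
per pathway the pointwise rate rises to roughly 10%, so pathway
comparisons on very small populations should be read cautiously.

## Problem sizes used in the test suite

Simulator statistics use 10,000 draws (3 binomial SE tolerance);
behavior recovery uses 20 sessions × 1000 trials; encoding round trips
use a 60-trial session (~7200 frames at 20 Hz, 85 design columns) with
8 noiseless + 12 noisy neurons at 50 folds, and 100 neurons at 20 folds
for the tuning false-positive rate; bootstrap calibration uses 1000
resamples instead of the 10,000 used for final inference. These sizes
were chosen so the full suite runs on a single CPU in minutes while
keeping every statistical check at its stated tolerance.
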