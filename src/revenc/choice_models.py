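"""Trial-by-trial models of choice in the serial-reversal task.

Five models are implemented, all predicting the probability of a right
choice on each trial from the history of choices and outcomes:

* ``qlearn`` — delta-rule Q-learning with softmax choice (learning rate
  alpha, inverse temperature beta).
* ``qforget`` — the same with the unchosen option's value decaying toward
  zero at a forgetting rate phi; phi = 0 recovers ``qlearn``.
* ``logreg`` — logistic regression on the signed choices and rewarded
  sides of the previous five trials (11 parameters).
* ``rlogreg`` — recursive logistic regression: a choice-stickiness term
  plus an exponentially decaying sum of past signed rewards, which admits
  a one-step recursive "state estimate" rho.
* ``wsls`` — win-stay/lose-shift with a lapse rate epsilon (random choice
  with probability epsilon).

Fitting is by bounded maximum likelihood with multiple random restarts;
models are compared by AIC/BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .task import Session

__all__ = [
    "ChoiceOutcomeSeries",
    "QForgetParams",
    "RLogRegParams",
    "WSLSParams",
    "LogRegParams",
    "LatentSeries",
    "ModelFit",
    "MODEL_N_PARAMS",
    "series_from_session",
    "softmax_p",
    "q_trajectory",
    "rlogreg_state",
    "model_loglik",
    "fit_model",
    "compare_models",
    "latent_correlation",
]

MODEL_N_PARAMS = {"wsls": 1, "qlearn": 2, "qforget": 3, "rlogreg": 4,
                  "logreg": 11}

_P_FLOOR = 1e-12


@dataclass
class ChoiceOutcomeSeries:
    """Signed per-trial choice/outcome codes for completed trials.

    c: +1 right, -1 left.  R: 1 if rewarded else 0.  r: signed rewarded
    side (+1 reward after a right choice, -1 after a left choice, 0 when
    no reward was delivered); r == c * R by construction.
    """

    c: np.ndarray
    R: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if not (len(self.c) == len(self.R) == len(self.r)):
            raise ValueError("c, R, r must have equal length")
        if np.any(np.abs(self.c) != 1):
            raise ValueError("c must be +1/-1 on completed trials")
        bad = (self.r != 0) & ((self.R != 1) | (np.sign(self.r) != self.c))
        if np.any(bad):
            raise ValueError("r must equal c*R")

    def __len__(self) -> int:
        return len(self.c)


def series_from_session(session: Session) -> ChoiceOutcomeSeries:
    """Extract the signed choice/outcome series, dropping omission trials."""
    trials = session.completed_trials()
    c = np.array([1.0 if t.choice == "right" else -1.0 for t in trials])
    R = np.array([1.0 if t.outcome == "reward" else 0.0 for t in trials])
    return ChoiceOutcomeSeries(c=c, R=R, r=c * R)


@dataclass(frozen=True)
class QForgetParams:
    alpha: float
    beta: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")


@dataclass(frozen=True)
class RLogRegParams:
    alpha_stick: float
    beta_rew: float
    gamma: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class WSLSParams:
    epsilon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")


@dataclass(frozen=True)
class LogRegParams:
    beta0: float
    beta1: tuple  # 5 choice-history weights, lag 1..5
    beta2: tuple  # 5 reward-history weights, lag 1..5

    def __post_init__(self) -> None:
        if len(self.beta1) != 5 or len(self.beta2) != 5:
            raise ValueError("beta1 and beta2 must each have 5 lags")


@dataclass
class LatentSeries:
    """Per-trial model latents aligned to completed trials."""

    q_left: Optional[np.ndarray] = None
    q_right: Optional[np.ndarray] = None
    dq: Optional[np.ndarray] = None
    sq: Optional[np.ndarray] = None
    rpe: Optional[np.ndarray] = None
    rho: Optional[np.ndarray] = None
    h: Optional[np.ndarray] = None


@dataclass
class ModelFit:
    model_name: str
    params: object
    nll: float
    n_params: int
    n_trials: int
    aic: float
    bic: float
    p_right: np.ndarray
    latents: LatentSeries
    n_restarts: int
    seed: int
    converged: bool
    boundary: bool = False


def softmax_p(dq: float | np.ndarray, beta: float) -> float | np.ndarray:
    """P(choose A) under the softmax rule, 1/(1+exp(-beta*(Q_A-Q_B)))."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return expit(beta * np.asarray(dq, dtype=float))


def q_trajectory(series: ChoiceOutcomeSeries,
                 params: QForgetParams) -> LatentSeries:
    """Run the Q-learning-with-forgetting recursion over a session.

    Values start at (0, 0).  The latents recorded for trial t are the
    values *at the time of the choice* (before the trial's update); the
    reward prediction error is R_t minus the chosen option's pre-update
    value.  After the outcome the chosen port moves toward R_t at rate
    alpha and the unchosen port decays toward zero at rate phi.
    """
    n = len(series)
    ql = np.empty(n)
    qr = np.empty(n)
    rpe = np.empty(n)
    vl = vr = 0.0
    for t in range(n):
        ql[t], qr[t] = vl, vr
        R = series.R[t]
        if series.c[t] > 0:
            rpe[t] = R - vr
            vr += params.alpha * (R - vr)
            vl *= 1.0 - params.phi
        else:
            rpe[t] = R - vl
            vl += params.alpha * (R - vl)
            vr *= 1.0 - params.phi
    return LatentSeries(q_left=ql, q_right=qr, dq=ql - qr, sq=ql + qr,
                        rpe=rpe)


def rlogreg_state(series: ChoiceOutcomeSeries,
                  params: RLogRegParams) -> LatentSeries:
    """State estimate rho(t) = beta*r(t) + exp(-1/tau)*rho(t-1), rho(0)=0.

    Also returns the logit h used to predict the *next* trial's choice:
    h(t+1) = gamma + alpha*c(t) + rho(t); h(1) = gamma (no history).
    """
    n = len(series)
    decay = math.exp(-1.0 / params.tau)
    rho = np.empty(n)
    acc = 0.0
    for t in range(n):
        acc = params.beta_rew * series.r[t] + decay * acc
        rho[t] = acc
    h = np.empty(n)
    h[0] = params.gamma
    if n > 1:
        h[1:] = params.gamma + params.alpha_stick * series.c[:-1] + rho[:-1]
    return LatentSeries(rho=rho, h=h)


def _p_right(model_name: str, series: ChoiceOutcomeSeries,
             params) -> np.ndarray:
    """Predicted P(right) per trial; NaN where the model makes no prediction."""
    n = len(series)
    if model_name in ("qforget", "qlearn"):
        lat = q_trajectory(series, params)
        return expit(params.beta * (lat.q_right - lat.q_left))
    if model_name == "rlogreg":
        lat = rlogreg_state(series, params)
        return expit(lat.h)
    if model_name == "logreg":
        p = np.full(n, np.nan)
        if n > 5:
            X = _logreg_lag_matrix(series)
            w = np.concatenate([[params.beta0], params.beta1, params.beta2])
            p[5:] = expit(X @ w)
        return p
    if model_name == "wsls":
        eps = params.epsilon
        p = np.full(n, 0.5)
        for t in range(1, n):
            # rule: repeat previous choice after a win, switch after a loss
            rule_right = (series.c[t - 1] > 0) == (series.R[t - 1] == 1)
            p[t] = (1 - eps) * float(rule_right) + eps / 2.0
        return p
    raise ValueError(f"unknown model {model_name!r}")


def model_loglik(model_name: str, series: ChoiceOutcomeSeries,
                 params) -> float:
    """Negative log-likelihood of the observed choices under a model.

    Trials where the model makes no prediction (the first five for the
    lagged logistic regression) are excluded from the sum.
    """
    p = _p_right(model_name, series, params)
    mask = ~np.isnan(p)
    p_obs = np.where(series.c > 0, p, 1.0 - p)[mask]
    p_obs = np.clip(p_obs, _P_FLOOR, 1.0 - _P_FLOOR)
    return float(-np.sum(np.log(p_obs)))


# ---------------------------------------------------------------------------
# Fitting


_BOUNDS = {
    "qforget": [(0.0, 1.0), (0.0, 50.0), (0.0, 1.0)],
    "qlearn": [(0.0, 1.0), (0.0, 50.0)],
    "rlogreg": [(-10.0, 10.0), (-10.0, 10.0), (-10.0, 10.0), (0.01, 50.0)],
    "wsls": [(0.0, 1.0)],
}


def _vec_to_params(model_name: str, x: np.ndarray):
    if model_name == "qforget":
        return QForgetParams(alpha=x[0], beta=x[1], phi=x[2])
    if model_name == "qlearn":
        return QForgetParams(alpha=x[0], beta=x[1], phi=0.0)
    if model_name == "rlogreg":
        return RLogRegParams(alpha_stick=x[0], beta_rew=x[1], gamma=x[2],
                             tau=x[3])
    if model_name == "wsls":
        return WSLSParams(epsilon=x[0])
    raise ValueError(model_name)


def _logreg_lag_matrix(series: ChoiceOutcomeSeries) -> np.ndarray:
    """[1, c(t-1..t-5), r(t-1..t-5)] rows for trials 6..n."""
    n = len(series)
    rows = [np.concatenate([[1.0], series.c[t - 5:t][::-1],
                            series.r[t - 5:t][::-1]])
            for t in range(5, n)]
    return np.asarray(rows)


def _fit_logreg(series: ChoiceOutcomeSeries
                ) -> tuple[LogRegParams, float, bool, bool]:
    """MLE of the 5-lag logistic regression.

    statsmodels Logit gives the exact MLE of this convex problem; under
    (quasi-)separation, where the MLE diverges, a bounded L-BFGS-B fit
    with the same [-10, 10] weight box as the other regression models is
    used and the boundary solution is flagged.
    """
    import statsmodels.api as sm

    n = len(series)
    if n <= 10:
        raise ValueError("need more than 10 completed trials for logreg")
    X = _logreg_lag_matrix(series)
    y = (series.c[5:] > 0).astype(float)

    def params_from(coef):
        return LogRegParams(beta0=coef[0], beta1=tuple(coef[1:6]),
                            beta2=tuple(coef[6:11]))

    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef = np.asarray(res.params)
        if np.all(np.abs(coef) < 1e3) and res.mle_retvals.get(
                "converged", True):
            return params_from(coef), float(-res.llf), True, False
    except Exception:
        pass
    # separation fallback: convex objective, bounded box, start at zero
    def objective(w):
        z = X @ w
        return float(np.sum(np.logaddexp(0.0, -z) * y
                            + np.logaddexp(0.0, z) * (1 - y)))

    bounds = [(-10.0, 10.0)] * 11
    res = optimize.minimize(objective, np.zeros(11), method="L-BFGS-B",
                            bounds=bounds)
    return params_from(res.x), float(res.fun), bool(res.success), True


def fit_model(model_name: str, session_or_series, n_restarts: int = 20,
              seed: int = 0) -> ModelFit:
    """Maximum-likelihood fit of one choice model.

    Runs ``n_restarts`` bounded L-BFGS-B optimizations from seeded uniform
    random starting points and keeps the best negative log-likelihood (the
    lagged logistic regression is convex and fit once, exactly).  A fit
    whose optimum sits on a parameter bound is flagged ``boundary``.
    """
    if isinstance(session_or_series, Session):
        series = series_from_session(session_or_series)
    else:
        series = session_or_series
    n = len(series)
    if n < 50:
        raise ValueError("need at least 50 completed trials to fit")

    if model_name == "logreg":
        params, nll, converged, boundary = _fit_logreg(series)
    else:
        bounds = _BOUNDS[model_name]
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        def objective(x):
            return model_loglik(model_name, series,
                                _vec_to_params(model_name, x))

        best = None
        any_converged = False
        for _ in range(max(1, n_restarts)):
            x0 = lo + rng.random(len(bounds)) * (hi - lo)
            res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                    bounds=bounds)
            any_converged = any_converged or res.success
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        best_x = np.asarray(best.x)
        params = _vec_to_params(model_name, best_x)
        nll = float(best.fun)
        converged = any_converged
        atol = 1e-8 * (hi - lo)
        boundary = bool(np.any((best_x - lo <= atol) | (hi - best_x <= atol)))

    k = MODEL_N_PARAMS[model_name]
    n_pred = n - 5 if model_name == "logreg" else n
    aic = 2.0 * k + 2.0 * nll
    bic = k * math.log(n_pred) + 2.0 * nll

    p = _p_right(model_name, series, params)
    if model_name in ("qforget", "qlearn"):
        latents = q_trajectory(series, params)
    elif model_name == "rlogreg":
        latents = rlogreg_state(series, params)
    else:
        latents = LatentSeries()
    return ModelFit(model_name=model_name, params=params, nll=nll,
                    n_params=k, n_trials=n, aic=aic, bic=bic, p_right=p,
                    latents=latents, n_restarts=n_restarts, seed=seed,
                    converged=converged, boundary=boundary)


def compare_models(session_or_series,
                   model_names: Sequence[str] = ("wsls", "qlearn", "qforget",
                                                 "rlogreg", "logreg"),
                   n_restarts: int = 20, seed: int = 0) -> pd.DataFrame:
    """Fit several models to one session and rank them by AIC.

    Returns a DataFrame (one row per model) with nll, parameter count,
    AIC, BIC and the AIC rank (1 = best).
    """
    if len(model_names) < 2:
        raise ValueError("need at least 2 models to compare")
    fits = {m: fit_model(m, session_or_series, seed=seed + i)
            for i, m in enumerate(model_names)}
    table = pd.DataFrame({
        "model": list(fits),
        "nll": [f.nll for f in fits.values()],
        "n_params": [f.n_params for f in fits.values()],
        "aic": [f.aic for f in fits.values()],
        "bic": [f.bic for f in fits.values()],
        "converged": [f.converged for f in fits.values()],
    })
    table["aic_rank"] = table["aic"].rank(method="first").astype(int)
    return table.sort_values("aic_rank").reset_index(drop=True)


def latent_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two latent series (NaN if degenerate)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])
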