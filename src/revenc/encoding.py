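"""Penalized linear encoding model for single-neuron calcium activity.

A neuron's dF/F trace is modeled as a linear superposition of

* event-tethered kernels — each behavioral event type (trial-start cue,
  self-initiation, choice, reward/no-reward outcome and its interaction
  with choice side, signed reward-prediction errors) contributes a
  temporal kernel expressed in a cubic B-spline basis over a fixed lag
  window around each event occurrence, and
* continuous predictors — head velocity, local reward rate, and the
  trial-level value variables Sigma-Q and Delta-Q that stay constant
  within a trial and step instantaneously at outcome,

plus an unpenalized intercept and Gaussian noise.  Coefficients are fit
with a near-lasso elastic net (mixing 0.95); the shrinkage strength is
selected by chunked, trial-stratified cross-validation and the
one-standard-error rule; model quality is summarized as the fraction of
calcium-signal variance explained (FVE) and per-predictor tuning indices
FVE(full) - FVE(reduced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline
from sklearn.linear_model import enet_path

from .choice_models import LatentSeries
from .metrics import local_reward_rate
from .task import Session

__all__ = [
    "SplineBasisSpec",
    "PredictorSpec",
    "DesignMatrix",
    "EncodingConfig",
    "EncodingFit",
    "TuningResult",
    "KernelEstimate",
    "default_predictor_specs",
    "build_spline_basis",
    "spline_knots",
    "build_design_matrix",
    "make_cv_folds",
    "fit_encoding",
    "compute_fve",
    "tuning_index",
    "extract_kernel",
]


# ---------------------------------------------------------------------------
# Spline basis


@dataclass(frozen=True)
class SplineBasisSpec:
    """Cubic B-spline basis over a lag window relative to an event (s)."""

    window: tuple[float, float]
    n_basis: int
    degree: int = 3

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window must satisfy lag_min < lag_max")
        if self.n_basis < 4:
            raise ValueError("need at least 4 cubic B-spline functions")
        if self.degree != 3:
            raise ValueError("basis is fixed at cubic (degree 3)")


def spline_knots(spec: SplineBasisSpec) -> np.ndarray:
    """Clamped knot vector: n_basis + 4 knots, 4-fold repeated endpoints."""
    lo, hi = spec.window
    interior = np.linspace(lo, hi, spec.n_basis - 2)[1:-1]
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def build_spline_basis(spec: SplineBasisSpec,
                       lags: Optional[np.ndarray] = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the basis on a lag grid.

    Returns (lags, B) with B of shape (n_lags, n_basis); rows sum to one
    inside the window (partition of unity) and are zero outside it.
    """
    lo, hi = spec.window
    if lags is None:
        lags = np.linspace(lo, hi, max(2, int(round((hi - lo) / 0.05)) + 1))
    lags = np.asarray(lags, dtype=float)
    t = spline_knots(spec)
    B = np.zeros((len(lags), spec.n_basis))
    inside = (lags >= lo) & (lags <= hi)
    if np.any(inside):
        D = BSpline.design_matrix(lags[inside], t, spec.degree).toarray()
        B[inside] = D
    return lags, B


# ---------------------------------------------------------------------------
# Predictors and design matrix


@dataclass(frozen=True)
class PredictorSpec:
    name: str
    kind: str  # event | continuous
    basis: Optional[SplineBasisSpec] = None
    group: str = "outcome"  # pre_outcome | outcome | internal_value | movement

    def __post_init__(self) -> None:
        if self.kind not in ("event", "continuous"):
            raise ValueError("kind must be 'event' or 'continuous'")
        if self.kind == "event" and self.basis is None:
            raise ValueError(f"event predictor {self.name!r} needs a basis")


_SHORT = SplineBasisSpec(window=(-1.0, 2.0), n_basis=7)
_LONG = SplineBasisSpec(window=(-0.5, 6.0), n_basis=10)


def default_predictor_specs(include_movement: bool = True
                            ) -> list[PredictorSpec]:
    """The default predictor set.

    Brief windows around the pre-outcome events; long windows for outcome
    and prediction-error kernels, accommodating the slow persistent
    signals that follow unrewarded outcomes.
    """
    specs = [
        PredictorSpec("cue", "event", _SHORT, "pre_outcome"),
        PredictorSpec("init", "event", _SHORT, "pre_outcome"),
        PredictorSpec("choice", "event", _SHORT, "pre_outcome"),
        PredictorSpec("o_plus", "event", _LONG, "outcome"),
        PredictorSpec("o_minus", "event", _LONG, "outcome"),
        PredictorSpec("ch_o_plus", "event", _LONG, "outcome"),
        PredictorSpec("ch_o_minus", "event", _LONG, "outcome"),
        PredictorSpec("rpe_plus", "event", _LONG, "internal_value"),
        PredictorSpec("rpe_minus", "event", _LONG, "internal_value"),
        PredictorSpec("dq", "continuous", None, "internal_value"),
        PredictorSpec("sq", "continuous", None, "internal_value"),
        PredictorSpec("reward_rate", "continuous", None, "internal_value"),
    ]
    if include_movement:
        specs.append(PredictorSpec("head_velocity", "continuous", None,
                                   "movement"))
    return specs


@dataclass
class DesignMatrix:
    """Time-resolved predictor matrix with per-column metadata."""

    frame_times: np.ndarray
    X: np.ndarray
    column_names: list[str]  # predictor name per column
    column_basis: list[object]  # basis index (int) or "continuous"
    specs: list[PredictorSpec]
    trial_id: np.ndarray
    chunk_id: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def columns_for(self, names: Sequence[str]) -> np.ndarray:
        names = set(names)
        return np.array([i for i, n in enumerate(self.column_names)
                         if n in names], dtype=int)

    def group_members(self, group: str) -> list[str]:
        return [s.name for s in self.specs if s.group == group]

    def drop(self, names: Sequence[str]) -> "DesignMatrix":
        """A new DesignMatrix without the named predictors' columns."""
        drop = set(names)
        keep = [i for i, n in enumerate(self.column_names) if n not in drop]
        return DesignMatrix(
            frame_times=self.frame_times, X=self.X[:, keep],
            column_names=[self.column_names[i] for i in keep],
            column_basis=[self.column_basis[i] for i in keep],
            specs=[s for s in self.specs if s.name not in drop],
            trial_id=self.trial_id, chunk_id=self.chunk_id)


def _event_times(session: Session, latents: Optional[LatentSeries]
                 ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Event (times, amplitudes) per event-predictor name."""
    completed = session.completed_trials()
    t_cue = np.array([t.t_cue for t in session.trials])
    t_init = np.array([t.t_init for t in session.trials])
    t_choice = np.array([t.t_choice for t in completed])
    t_out = np.array([t.t_outcome for t in completed])
    rewarded = np.array([t.outcome == "reward" for t in completed])
    right = np.array([t.choice == "right" for t in completed])
    sign = np.where(right, 1.0, -1.0)

    ev = {
        "cue": (t_cue, np.ones_like(t_cue)),
        "init": (t_init, np.ones_like(t_init)),
        "choice": (t_choice, np.ones_like(t_choice)),
        "o_plus": (t_out[rewarded], np.ones(int(rewarded.sum()))),
        "o_minus": (t_out[~rewarded], np.ones(int((~rewarded).sum()))),
        "ch_o_plus": (t_out[rewarded], sign[rewarded]),
        "ch_o_minus": (t_out[~rewarded], sign[~rewarded]),
    }
    if latents is not None and latents.rpe is not None:
        rpe = np.asarray(latents.rpe)
        if len(rpe) != len(completed):
            raise ValueError("latents not aligned to completed trials")
        ev["rpe_plus"] = (t_out, np.maximum(rpe, 0.0))
        ev["rpe_minus"] = (t_out, np.maximum(-rpe, 0.0))
    return ev


def _step_series(frame_times: np.ndarray, step_times: np.ndarray,
                 values_after: np.ndarray, value_before: float) -> np.ndarray:
    """Piecewise-constant series jumping to values_after[i] at step_times[i]."""
    idx = np.searchsorted(step_times, frame_times, side="right")
    padded = np.concatenate([[value_before], values_after])
    return padded[idx]


def build_design_matrix(
    session: Session,
    frame_times: np.ndarray,
    predictor_specs: Optional[Sequence[PredictorSpec]] = None,
    latents: Optional[LatentSeries] = None,
    head_velocity: Optional[tuple[np.ndarray, np.ndarray]] = None,
    reward_rate: Optional[np.ndarray] = None,
    chunk_s: float = 0.2,
) -> DesignMatrix:
    """Assemble the encoding model's design matrix on imaging frame times.

    Event predictors contribute one column per spline basis function,
    summing the basis evaluated at the lag of every event occurrence
    (scaled by the event amplitude — choice sign for the choice-outcome
    interactions, prediction-error magnitude for the RPE predictors).
    Delta-Q and Sigma-Q are constant within a trial and step at outcome;
    the local reward rate steps at trial start; head velocity (given as a
    (times, values) pair) is linearly interpolated onto frame_times.
    """
    specs = list(predictor_specs) if predictor_specs is not None \
        else default_predictor_specs(include_movement=head_velocity is not None)
    frame_times = np.asarray(frame_times, dtype=float)
    events = _event_times(session, latents)
    completed = session.completed_trials()
    t_out = np.array([t.t_outcome for t in completed])

    cols, names, basis_ids = [], [], []
    for spec in specs:
        if spec.kind == "event":
            if spec.name not in events:
                raise ValueError(f"no event stream for predictor {spec.name!r}")
            times, amps = events[spec.name]
            lo, hi = spec.basis.window
            block = np.zeros((len(frame_times), spec.basis.n_basis))
            for tn, an in zip(times, amps):
                if an == 0.0:
                    continue
                lags = frame_times - tn
                m = (lags >= lo) & (lags <= hi)
                if not np.any(m):
                    continue
                _, B = build_spline_basis(spec.basis, lags[m])
                block[m] += an * B
            cols.append(block)
            names.extend([spec.name] * spec.basis.n_basis)
            basis_ids.extend(range(spec.basis.n_basis))
        else:
            if spec.name in ("dq", "sq"):
                if latents is None or getattr(latents, spec.name) is None:
                    raise ValueError(f"{spec.name} requires fitted latents")
                vals = np.asarray(getattr(latents, spec.name))
                if len(vals) != len(completed):
                    raise ValueError("latents not aligned to completed trials")
                # pre-choice value of trial j+1 is the post-outcome value of
                # trial j; the value after the final outcome is held
                after = np.concatenate([vals[1:], vals[-1:]])
                col = _step_series(frame_times, t_out, after, vals[0])
            elif spec.name == "reward_rate":
                rr = (np.asarray(reward_rate) if reward_rate is not None
                      else local_reward_rate(session))
                t_cue_all = np.array([t.t_cue for t in session.trials])
                col = _step_series(frame_times, t_cue_all, rr, 0.0)
            elif spec.name == "head_velocity":
                if head_velocity is None:
                    raise ValueError("head_velocity series not provided")
                hv_t, hv_v = head_velocity
                col = np.interp(frame_times, hv_t, hv_v)
            else:
                raise ValueError(f"unknown continuous predictor {spec.name!r}")
            cols.append(col[:, None])
            names.append(spec.name)
            basis_ids.append("continuous")

    X = np.hstack(cols)
    t_cue_all = np.array([t.t_cue for t in session.trials])
    trial_id = np.searchsorted(t_cue_all, frame_times, side="right") - 1
    trial_id = np.clip(trial_id, 0, None)
    chunk_id = np.floor(frame_times / chunk_s).astype(int)
    return DesignMatrix(frame_times=frame_times, X=X, column_names=names,
                        column_basis=basis_ids, specs=specs,
                        trial_id=trial_id, chunk_id=chunk_id)


# ---------------------------------------------------------------------------
# Elastic-net fitting with chunked, trial-stratified cross-validation


@dataclass(frozen=True)
class EncodingConfig:
    alpha_mixing: float = 0.95
    n_folds: int = 50
    n_lambda: int = 30
    lambda_min_ratio: float = 1e-3
    chunk_s: float = 0.2
    standardize_continuous: bool = True
    fve_threshold: float = 0.05
    tuning_threshold: float = 0.05
    seed: int = 0


@dataclass
class EncodingFit:
    intercept: float
    coef: np.ndarray  # on the original predictor scale
    column_names: list[str]
    column_basis: list[object]
    specs: list[PredictorSpec]
    lambda_selected: float
    lambda_path: np.ndarray
    cv_fve_mean: np.ndarray
    cv_fve_sd: np.ndarray
    fold_id: np.ndarray  # per frame
    fve: float  # cross-validated FVE at the selected lambda
    fve_train: float
    cv_pred: np.ndarray
    config: EncodingConfig
    flags: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef


@dataclass
class TuningResult:
    dropped: tuple
    index: float
    fve_full: float
    fve_reduced: float
    task_tuned: bool
    tuned: bool


@dataclass
class KernelEstimate:
    predictor: str
    lags: np.ndarray
    values: np.ndarray  # dF/F


def compute_fve(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Fraction of variance explained, 1 - Var(obs - pred)/Var(obs)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    denom = np.var(observed)
    if denom == 0:
        return float("nan")
    return float(1.0 - np.var(observed - predicted) / denom)


def make_cv_folds(design: DesignMatrix, n_folds: int,
                  seed: int = 0) -> np.ndarray:
    """Per-frame fold labels: chunks stay whole, trials spread over folds.

    The 200-ms chunks of each trial are shuffled and dealt round-robin to
    folds from a random starting fold, so each trial is represented
    roughly equally in each fold and no chunk is split across folds.
    """
    rng = np.random.default_rng(seed)
    fold_of_chunk: dict[int, int] = {}
    # chunk -> trial of its first frame
    order = np.argsort(design.frame_times, kind="stable")
    chunk_trial: dict[int, int] = {}
    for i in order:
        ck = int(design.chunk_id[i])
        if ck not in chunk_trial:
            chunk_trial[ck] = int(design.trial_id[i])
    trials = {}
    for ck, tr in chunk_trial.items():
        trials.setdefault(tr, []).append(ck)
    pointer = int(rng.integers(n_folds))
    for tr in sorted(trials):
        chunks = sorted(trials[tr])
        rng.shuffle(chunks)
        for ck in chunks:
            fold_of_chunk[ck] = pointer % n_folds
            pointer += 1
    return np.array([fold_of_chunk[int(ck)] for ck in design.chunk_id])


def _lambda_path(Xc: np.ndarray, yc: np.ndarray,
                 config: EncodingConfig) -> np.ndarray:
    lam_max = np.max(np.abs(Xc.T @ yc)) / (len(yc) * config.alpha_mixing)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                        config.n_lambda)


def fit_encoding(design: DesignMatrix, trace, config: EncodingConfig
                 | None = None) -> EncodingFit:
    """Fit the encoding model to one neuron's trace.

    Elastic net (mixing 0.95, intercept unpenalized) over a geometric
    lambda path; lambda selected by the one-standard-error rule on the
    cross-validated FVE (largest lambda whose mean CV FVE is within one
    across-fold SD of the maximum); the reported FVE is computed from the
    assembled out-of-fold predictions at the selected lambda.
    """
    config = config or EncodingConfig()
    y = np.asarray(getattr(trace, "values", trace), dtype=float)
    if len(y) != design.n_frames:
        raise ValueError("trace and design are not frame-aligned")
    n_chunks = len(np.unique(design.chunk_id))
    if n_chunks < 50:
        raise ValueError("need at least 50 temporal chunks")
    flags = []
    if np.var(y) == 0:
        flags.append("zero-variance trace")

    X = design.X.copy()
    scale = np.ones(X.shape[1])
    if config.standardize_continuous:
        for j, b in enumerate(design.column_basis):
            if b == "continuous":
                sd = X[:, j].std()
                mu = X[:, j].mean()
                if sd > 0:
                    X[:, j] = (X[:, j] - mu) / sd
                    scale[j] = sd

    n_folds = min(config.n_folds, n_chunks)
    fold_id = make_cv_folds(design, n_folds, seed=config.seed)

    Xm, ym = X.mean(axis=0), y.mean()
    lambdas = _lambda_path(X - Xm, y - ym, config)

    n_lam = len(lambdas)
    fold_fve = np.full((n_folds, n_lam), np.nan)
    cv_pred = np.zeros((n_lam, len(y)))
    for f in range(n_folds):
        te = fold_id == f
        tr = ~te
        Xtr, ytr = X[tr], y[tr]
        xm, ym_f = Xtr.mean(axis=0), ytr.mean()
        _, coefs, _ = enet_path(Xtr - xm, ytr - ym_f, alphas=lambdas,
                                l1_ratio=config.alpha_mixing)
        pred = (X[te] - xm) @ coefs + ym_f  # (n_te, n_lam)
        cv_pred[:, te] = pred.T
        var_te = np.var(y[te])
        if var_te > 0:
            resid = y[te][:, None] - pred
            fold_fve[f] = 1.0 - np.mean(resid ** 2, axis=0) / var_te

    cv_mean = np.nanmean(fold_fve, axis=0)
    cv_sd = np.nanstd(fold_fve, axis=0, ddof=1)
    best = int(np.nanargmax(cv_mean))
    # one-standard-error rule on the CV estimate of the FVE: the SD across
    # folds scaled to the standard error of the fold mean
    n_eff = np.sum(~np.isnan(fold_fve[:, best]))
    threshold = cv_mean[best] - cv_sd[best] / math.sqrt(max(n_eff, 1))
    # path is descending in lambda: first index meeting the threshold is
    # the largest (sparsest) such lambda
    sel = int(np.nonzero(cv_mean >= threshold)[0][0])
    lam_sel = float(lambdas[sel])

    _, coefs_full, _ = enet_path(X - Xm, y - ym, alphas=lambdas,
                                 l1_ratio=config.alpha_mixing)
    coef_std = coefs_full[:, sel]
    # back to the raw predictor scale (x_std = (x - mu)/sd); the intercept
    # absorbs the centering
    coef = coef_std / scale
    intercept = float(y.mean() - design.X.mean(axis=0) @ coef)

    fve_cv = compute_fve(cv_pred[sel], y)
    fve_train = compute_fve(intercept + design.X @ coef, y)
    if math.isnan(fve_cv):
        flags.append("undefined FVE")

    return EncodingFit(intercept=intercept, coef=coef,
                       column_names=list(design.column_names),
                       column_basis=list(design.column_basis),
                       specs=list(design.specs),
                       lambda_selected=lam_sel, lambda_path=lambdas,
                       cv_fve_mean=cv_mean, cv_fve_sd=cv_sd,
                       fold_id=fold_id, fve=fve_cv, fve_train=fve_train,
                       cv_pred=cv_pred[sel], config=config, flags=flags)


def tuning_index(full: EncodingFit, design: DesignMatrix, trace,
                 drop_predictors: Sequence[str],
                 config: EncodingConfig | None = None) -> TuningResult:
    """FVE(full) - FVE(reduced) after refitting without some predictors.

    The reduced model is refit from scratch on the pruned design with its
    own lambda selection.  A neuron is ``task_tuned`` when the full model
    explains at least the FVE threshold (default 5%); it is ``tuned`` to
    the dropped predictors when additionally the index exceeds the tuning
    threshold.
    """
    config = config or full.config
    drop = tuple(drop_predictors)
    if not drop:
        return TuningResult(dropped=(), index=0.0, fve_full=full.fve,
                            fve_reduced=full.fve,
                            task_tuned=full.fve >= config.fve_threshold,
                            tuned=False)
    known = set(design.column_names)
    unknown = [d for d in drop if d not in known]
    if unknown:
        raise ValueError(f"unknown predictors {unknown}")
    reduced_design = design.drop(drop)
    if reduced_design.X.shape[1] == 0:
        # intercept-only model explains nothing beyond the mean
        fve_reduced = 0.0
    else:
        reduced = fit_encoding(reduced_design, trace, config)
        fve_reduced = reduced.fve
    index = full.fve - fve_reduced
    task_tuned = full.fve >= config.fve_threshold
    return TuningResult(dropped=drop, index=index, fve_full=full.fve,
                        fve_reduced=fve_reduced, task_tuned=task_tuned,
                        tuned=bool(task_tuned
                                   and index > config.tuning_threshold))


def extract_kernel(fit: EncodingFit, predictor: str,
                   lag_step: float = 0.05) -> KernelEstimate:
    """Reconstruct an event predictor's kernel from its fitted weights."""
    spec = next((s for s in fit.specs if s.name == predictor), None)
    if spec is None:
        raise ValueError(f"no predictor named {predictor!r} in fit")
    if spec.kind != "event":
        raise ValueError(
            f"{predictor!r} is continuous; report its scalar coefficient")
    idx = [i for i, n in enumerate(fit.column_names) if n == predictor]
    gamma = fit.coef[idx]
    lo, hi = spec.basis.window
    lags = np.arange(lo, hi + lag_step / 2, lag_step)
    _, B = build_spline_basis(spec.basis, lags)
    return KernelEstimate(predictor=predictor, lags=lags, values=B @ gamma)
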