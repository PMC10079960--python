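"""Synthetic calcium traces with the encoding model's generative structure.

Traces are built exactly as the encoding model assumes: an intercept plus
event-tethered kernels placed at behavioral event times, plus scalar
gains on the continuous predictors, plus Gaussian noise, sampled at the
imaging frame rate (20 Hz).  Ground-truth kernels are stored as
coefficient vectors in the encoding model's own cubic B-spline bases, so
a noiseless trace equals the design matrix times the true coefficients
to machine precision — the strongest structural check available for the
fitting pipeline.

Kernel shapes are sums of raised cosines projected onto the spline basis,
emulating the phenomenology of prefrontal-striatal recordings: brief
(~1 s) transients after reward, and slow persistent (>5 s) increases
after unrewarded outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .choice_models import LatentSeries
from .encoding import (DesignMatrix, PredictorSpec, build_design_matrix,
                       build_spline_basis, default_predictor_specs)
from .task import Session

__all__ = [
    "GroundTruth",
    "CalciumTrace",
    "TUNING_PROFILES",
    "sample_ground_truth",
    "synthesize_trace",
    "synthesize_head_velocity",
    "coefficient_vector",
]

FRAME_RATE = 20.0  # Hz

# named profiles: predictor -> (peak dF/F, duration s) for events,
# or scalar gain for continuous predictors
TUNING_PROFILES: dict[str, dict] = {
    "untuned": {},
    "reward_brief": {"o_plus": (1.0, 1.0)},
    "noreward_persistent": {"o_minus": (0.8, 5.8)},
    "choice_outcome_persistent": {"ch_o_plus": (0.8, 5.5)},
    "value": {"dq": 0.5, "sq": 0.3},
    "movement": {"head_velocity": 0.05},
    "mixed": {"o_plus": (1.0, 1.0), "o_minus": (0.6, 5.5), "dq": 0.4},
}


@dataclass
class GroundTruth:
    """True generative parameters of one synthetic neuron."""

    intercept: float
    specs: list[PredictorSpec]
    kernel_coefs: dict[str, np.ndarray]  # spline coefficients per event
    continuous_gains: dict[str, float]
    noise_sigma: float
    frame_rate: float = FRAME_RATE
    ar1_phi: float = 0.0  # optional autocorrelated-noise switch
    seed: int = 0

    def event_kernel(self, name: str,
                     lag_step: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """The true kernel curve (lags, values) of one event predictor."""
        spec = next(s for s in self.specs if s.name == name)
        lo, hi = spec.basis.window
        lags = np.arange(lo, hi + lag_step / 2, lag_step)
        _, B = build_spline_basis(spec.basis, lags)
        return lags, B @ self.kernel_coefs[name]


@dataclass
class CalciumTrace:
    frame_times: np.ndarray
    values: np.ndarray  # dF/F
    neuron_id: str = "n0"
    pathway_label: str = "A"  # A (anterior DMS) or P (posterior DMS)


def _raised_cosine_curve(lags: np.ndarray, peak: float, duration: float,
                         rng: np.random.Generator) -> np.ndarray:
    """A smooth positive bump of given support built from raised cosines."""
    n_bumps = int(rng.integers(1, 4))
    centers = np.sort(rng.uniform(0.15, 0.85, n_bumps)) * duration
    widths = rng.uniform(0.4, 0.9, n_bumps) * duration
    amps = rng.uniform(0.5, 1.0, n_bumps)
    curve = np.zeros_like(lags)
    for c, w, a in zip(centers, widths, amps):
        m = np.abs(lags - c) < w / 2
        curve[m] += a * 0.5 * (1 + np.cos(2 * np.pi * (lags[m] - c) / w))
    curve[(lags < 0) | (lags > duration)] = 0.0
    m = np.max(np.abs(curve))
    return curve * (peak / m) if m > 0 else curve


def _project_to_basis(spec: PredictorSpec, curve_fn) -> np.ndarray:
    """Least-squares projection of a target curve onto the spline basis."""
    lo, hi = spec.basis.window
    lags = np.linspace(lo, hi, 400)
    _, B = build_spline_basis(spec.basis, lags)
    target = curve_fn(lags)
    coef, *_ = np.linalg.lstsq(B, target, rcond=None)
    return coef


def sample_ground_truth(
    predictor_specs: Optional[Sequence[PredictorSpec]] = None,
    tuning_profile: str | dict = "untuned",
    seed: int = 0,
    intercept: float = 0.05,
    noise_sigma: float = 0.15,
    ar1_phi: float = 0.0,
) -> GroundTruth:
    """Draw ground-truth kernels and gains for one synthetic neuron.

    ``tuning_profile`` is a named profile from TUNING_PROFILES or a dict
    mapping predictor names to (peak, duration) for events or a scalar
    gain for continuous predictors; every predictor not named carries an
    exactly zero effect.
    """
    specs = list(predictor_specs) if predictor_specs is not None \
        else default_predictor_specs()
    if isinstance(tuning_profile, str):
        try:
            profile = TUNING_PROFILES[tuning_profile]
        except KeyError:
            raise ValueError(f"unknown tuning profile {tuning_profile!r}")
    else:
        profile = dict(tuning_profile)
    rng = np.random.default_rng(seed)

    kernel_coefs: dict[str, np.ndarray] = {}
    gains: dict[str, float] = {}
    for spec in specs:
        if spec.kind == "event":
            if spec.name in profile:
                peak, duration = profile[spec.name]
                lo, hi = spec.basis.window
                duration = min(duration, hi)
                kernel_coefs[spec.name] = _project_to_basis(
                    spec, lambda l: _raised_cosine_curve(l, peak, duration,
                                                         rng))
            else:
                kernel_coefs[spec.name] = np.zeros(spec.basis.n_basis)
        else:
            gains[spec.name] = float(profile.get(spec.name, 0.0))
    unknown = set(profile) - {s.name for s in specs}
    if unknown:
        raise ValueError(f"profile names unknown predictors {sorted(unknown)}")
    return GroundTruth(intercept=intercept, specs=specs,
                       kernel_coefs=kernel_coefs, continuous_gains=gains,
                       noise_sigma=noise_sigma, ar1_phi=ar1_phi, seed=seed)


def coefficient_vector(truth: GroundTruth,
                       design: DesignMatrix) -> np.ndarray:
    """Ground-truth coefficients ordered to match a design matrix's columns."""
    theta = np.zeros(design.X.shape[1])
    for j, (name, b) in enumerate(zip(design.column_names,
                                      design.column_basis)):
        if b == "continuous":
            theta[j] = truth.continuous_gains.get(name, 0.0)
        else:
            theta[j] = truth.kernel_coefs[name][b]
    return theta


def synthesize_trace(
    session: Session,
    truth: GroundTruth,
    latents: LatentSeries,
    head_velocity: Optional[tuple[np.ndarray, np.ndarray]] = None,
    duration: Optional[float] = None,
    seed: int = 0,
    neuron_id: str = "n0",
    pathway_label: str = "A",
) -> tuple[CalciumTrace, DesignMatrix]:
    """Generate one neuron's dF/F trace from the linear generative model.

    Returns the trace and the design matrix used to generate it (which is
    exactly the matrix the encoding model would build for this session).
    Overlapping kernels superpose additively; noise is Gaussian with the
    ground truth's sigma (optionally AR(1) via ``ar1_phi``).
    """
    trials = session.trials
    t_end = max(t.t_outcome for t in session.completed_trials())
    if duration is None:
        duration = t_end + 8.0
    if t_end > duration:
        raise ValueError("session events extend past the requested duration")
    frame_times = np.arange(0.0, duration, 1.0 / truth.frame_rate)
    needs_hv = any(s.name == "head_velocity" for s in truth.specs)
    design = build_design_matrix(
        session, frame_times, predictor_specs=truth.specs, latents=latents,
        head_velocity=head_velocity if needs_hv else None)
    theta = coefficient_vector(truth, design)
    clean = truth.intercept + design.X @ theta
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, truth.noise_sigma, len(frame_times))
    if truth.ar1_phi:
        for i in range(1, len(eps)):
            eps[i] += truth.ar1_phi * eps[i - 1]
    trace = CalciumTrace(frame_times=frame_times, values=clean + eps,
                         neuron_id=neuron_id, pathway_label=pathway_label)
    return trace, design


def synthesize_head_velocity(
    session: Session,
    seed: int = 0,
    duration: Optional[float] = None,
    frame_rate: float = FRAME_RATE,
    burst_amp: float = 15.0,
    baseline_scale: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth stochastic head speed (cm/s) with bursts around port pokes.

    An Ornstein-Uhlenbeck baseline (rectified) plus a Gaussian-shaped
    burst at every initiation and choice poke.  Returned as a
    (times, values) pair ready for interpolation onto imaging frames.
    """
    if duration is None:
        duration = max(t.t_outcome for t in session.completed_trials()) + 8.0
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    t = np.arange(0.0, duration, dt)
    # OU baseline: tau ~1 s fluctuations
    ou = np.zeros(len(t))
    tau = 1.0
    for i in range(1, len(t)):
        ou[i] = ou[i - 1] * (1 - dt / tau) + \
            baseline_scale * np.sqrt(2 * dt / tau) * rng.normal()
    v = np.abs(ou)
    pokes = [tr.t_init for tr in session.trials] + \
        [tr.t_choice for tr in session.completed_trials()]
    for tp in pokes:
        amp = burst_amp * rng.uniform(0.5, 1.5)
        width = rng.uniform(0.2, 0.4)
        m = np.abs(t - tp) < 4 * width
        v[m] += amp * np.exp(-0.5 * ((t[m] - tp) / width) ** 2)
    return t, v
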