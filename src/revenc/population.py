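"""Pathway-level kernel statistics and tuning comparisons.

The per-lag root-mean-square (RMS) of single-neuron kernels across a
projection-defined population summarizes the magnitude of the
population's modulation by a predictor; confidence bands and
between-pathway differences are assessed by bias-corrected and
accelerated (BCa) bootstrap over neurons, and tuning-index distributions
are compared with two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .encoding import KernelEstimate

__all__ = [
    "PathwayKernel",
    "kernel_matrix",
    "pathway_rms",
    "bootstrap_kernel_ci",
    "kernel_difference_test",
    "compare_tuning",
]


@dataclass
class PathwayKernel:
    predictor: str
    lags: np.ndarray
    rms: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    sig_mask: Optional[np.ndarray] = None
    n_neurons: int = 0
    flags: list[str] = field(default_factory=list)


def kernel_matrix(kernels: Sequence[KernelEstimate]) -> np.ndarray:
    """Stack per-neuron kernels into an (n_neurons, n_lags) array."""
    if not kernels:
        raise ValueError("need at least one kernel")
    lags0 = kernels[0].lags
    for k in kernels[1:]:
        if len(k.lags) != len(lags0) or not np.allclose(k.lags, lags0):
            raise ValueError("kernels are not on a common lag grid")
    return np.stack([k.values for k in kernels])


def _rms(values: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.sqrt(np.mean(np.asarray(values) ** 2, axis=axis))


def pathway_rms(kernels: Sequence[KernelEstimate]) -> PathwayKernel:
    """Per-lag RMS of the kernels of task-relevant neurons in a pathway."""
    K = kernel_matrix(kernels)
    return PathwayKernel(predictor=kernels[0].predictor,
                         lags=kernels[0].lags, rms=_rms(K),
                         n_neurons=K.shape[0])


def bootstrap_kernel_ci(
    kernels: Sequence[KernelEstimate],
    n_boot: int = 10_000,
    seed: int = 0,
    confidence: float = 0.95,
) -> PathwayKernel:
    """95% BCa bootstrap band for the pathway RMS kernel, resampling neurons.

    Falls back to the percentile method (flagged) when the BCa correction
    is degenerate, e.g. when all resamples give an identical statistic.
    """
    K = kernel_matrix(kernels)
    if K.shape[0] < 2:
        raise ValueError("need at least 2 neurons to bootstrap")
    out = pathway_rms(kernels)
    rng = np.random.default_rng(seed)
    flags: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.bootstrap(
                (K,), _rms, axis=0, n_resamples=n_boot, method="BCa",
                confidence_level=confidence, vectorized=True, rng=rng)
        lo, hi = res.confidence_interval
        if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)):
            raise ValueError("degenerate BCa interval")
    except Exception:
        flags.append("BCa degenerate; percentile fallback")
        rng = np.random.default_rng(seed)
        idx = rng.integers(K.shape[0], size=(n_boot, K.shape[0]))
        boots = _rms(K[idx], axis=1)  # (n_boot, n_lags)
        a = (1 - confidence) / 2
        lo = np.quantile(boots, a, axis=0)
        hi = np.quantile(boots, 1 - a, axis=0)
    out.ci_low, out.ci_high = np.asarray(lo), np.asarray(hi)
    # numerical guard: the point estimate lies inside the band
    out.ci_low = np.minimum(out.ci_low, out.rms)
    out.ci_high = np.maximum(out.ci_high, out.rms)
    out.flags = flags
    return out


def kernel_difference_test(
    kernels_a: Sequence[KernelEstimate],
    kernels_b: Sequence[KernelEstimate],
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Per-lag two-sided BCa bootstrap test of RMS_A(lag) != RMS_B(lag).

    Neurons are resampled with replacement independently within the two
    pathways; a lag is significant when the (1-alpha) BCa interval of the
    RMS difference excludes zero.
    """
    A = kernel_matrix(kernels_a)
    B = kernel_matrix(kernels_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("pathways must share a lag grid")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 neurons per pathway")

    def diff(a, b, axis=0):
        return _rms(a, axis=axis) - _rms(b, axis=axis)

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.bootstrap(
            (A, B), diff, axis=0, n_resamples=n_boot, method="BCa",
            confidence_level=1 - alpha, vectorized=True, rng=rng)
    lo = np.asarray(res.confidence_interval.low)
    hi = np.asarray(res.confidence_interval.high)
    # degenerate lags (e.g. both pathways exactly zero) are not significant
    sig = np.nan_to_num(lo, nan=-1.0) > 0
    sig |= np.nan_to_num(hi, nan=1.0) < 0
    return {
        "lags": kernels_a[0].lags,
        "difference": diff(A, B),
        "ci_low": lo,
        "ci_high": hi,
        "sig_mask": sig,
    }


def compare_tuning(indices_a: np.ndarray, indices_b: np.ndarray,
                   threshold: float = 0.05) -> dict:
    """Compare tuning-index distributions between two pathways.

    Two-sample two-sided Kolmogorov-Smirnov test on the index
    distributions, a Welch t test on the means, and the proportion of
    tuned neurons (index above the 5% threshold) per group.
    """
    a = np.asarray(indices_a, dtype=float)
    b = np.asarray(indices_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    tt = stats.ttest_ind(a, b, equal_var=False)
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "mean_difference": float(a.mean() - b.mean()),
        "t_pvalue": float(tt.pvalue),
        "prop_tuned_a": float(np.mean(a > threshold)),
        "prop_tuned_b": float(np.mean(b > threshold)),
    }
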