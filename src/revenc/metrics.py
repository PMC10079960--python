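"""Behavioral summary statistics for reversal-task sessions.

Covers win-stay / lose-stay probabilities, the relative reward stay
(log odds-ratio of win-stay against lose-stay, with a value above 2 used
as the training criterion before recording), optogenetic
delta-win-stay / delta-lose-stay contrasts, the local reward rate used as
an encoding-model predictor, and task-engagement summaries.

"Stay" is always defined with respect to the previous *completed* trial;
"lose" means any completed trial that was not rewarded (punishment tone
or no outcome delivered).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .task import Session, TrialRecord

__all__ = [
    "StayTable",
    "EngagementSummary",
    "stay_probabilities",
    "relative_reward_stay",
    "delta_stay",
    "local_reward_rate",
    "engagement_metrics",
]


@dataclass
class StayTable:
    """Counts and conditional stay probabilities for one condition."""

    n_win_stay: int
    n_win_shift: int
    n_lose_stay: int
    n_lose_shift: int
    condition: str = "all"

    @property
    def p_winstay(self) -> float:
        n = self.n_win_stay + self.n_win_shift
        return self.n_win_stay / n if n else float("nan")

    @property
    def p_losestay(self) -> float:
        n = self.n_lose_stay + self.n_lose_shift
        return self.n_lose_stay / n if n else float("nan")


@dataclass
class EngagementSummary:
    total_trials_normalized: float
    initiation_latency: float  # mean t_init - t_cue, seconds
    baseline_initiation_latency: float


def _stay_events(session: Session):
    """Yield (prev_trial, cur_trial, stay) over consecutive completed trials."""
    prev: Optional[TrialRecord] = None
    for t in session.trials:
        if not t.completed:
            continue
        if prev is not None:
            yield prev, t, t.choice == prev.choice
        prev = t


def stay_probabilities(
    session: Session | Sequence[Session],
    condition_filter: Optional[Callable[[TrialRecord], bool]] = None,
    condition: str = "all",
) -> StayTable:
    """Win-stay and lose-stay probabilities over consecutive completed trials.

    ``condition_filter`` selects transitions by the *previous* trial (e.g.
    its light status); a "win" is a rewarded previous trial, a "lose" any
    unrewarded one.  Empty cells yield NaN probabilities rather than zero.
    """
    sessions = [session] if isinstance(session, Session) else list(session)
    counts = {("win", True): 0, ("win", False): 0,
              ("lose", True): 0, ("lose", False): 0}
    n_events = 0
    for s in sessions:
        for prev, cur, stay in _stay_events(s):
            n_events += 1
            if condition_filter is not None and not condition_filter(prev):
                continue
            key = "win" if prev.outcome == "reward" else "lose"
            counts[(key, stay)] += 1
    if n_events == 0:
        raise ValueError("need at least 2 completed trials")
    return StayTable(n_win_stay=counts[("win", True)],
                     n_win_shift=counts[("win", False)],
                     n_lose_stay=counts[("lose", True)],
                     n_lose_shift=counts[("lose", False)],
                     condition=condition)


def relative_reward_stay(stay: StayTable,
                         haldane: bool = True) -> tuple[float, bool]:
    """Log odds-ratio of win-stay versus lose-stay.

    ln[(p_ws/(1-p_ws)) / (p_ls/(1-p_ls))].  When any count is zero the
    odds are undefined; with ``haldane`` a 0.5-count correction is applied
    to all four cells and the result is flagged.  Returns (value, corrected).
    """
    cells = np.array([stay.n_win_stay, stay.n_win_shift,
                      stay.n_lose_stay, stay.n_lose_shift], dtype=float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        if not haldane:
            return float("nan"), True
        cells = cells + 0.5
    ws, wsh, ls, lsh = cells
    value = math.log((ws / wsh) / (ls / lsh))
    return value, corrected


def delta_stay(
    sessions: Session | Sequence[Session],
    epoch: str = "choice",
) -> dict:
    """Light-ON minus light-OFF conditional stay probabilities.

    Conditions on the optogenetic status of the *previous* trial for the
    named epoch.  Returns a dict with delta_winstay, delta_losestay, the
    per-condition StayTables, and flags for undefined cells.
    """
    sessions = [sessions] if isinstance(sessions, Session) else list(sessions)

    def on_filter(prev: TrialRecord) -> bool:
        return prev.light_on and prev.light_epoch == epoch

    def off_filter(prev: TrialRecord) -> bool:
        return not on_filter(prev)

    on = stay_probabilities(sessions, on_filter, condition="light_on")
    off = stay_probabilities(sessions, off_filter, condition="light_off")
    if on.n_win_stay + on.n_win_shift + on.n_lose_stay + on.n_lose_shift == 0:
        raise ValueError(f"no light-ON trials for epoch {epoch!r}")
    d_ws = on.p_winstay - off.p_winstay
    d_ls = on.p_losestay - off.p_losestay
    return {
        "delta_winstay": d_ws,
        "delta_losestay": d_ls,
        "on": on,
        "off": off,
        "undefined": bool(np.isnan(d_ws) or np.isnan(d_ls)),
    }


def local_reward_rate(session: Session, window: int = 5) -> np.ndarray:
    """Reward rate (microliters/minute) over the previous ``window`` trials.

    For trial t, the rewards delivered on trials t-window..t-1 times the
    reward volume, divided by the elapsed time from the start of trial
    t-window to the start of trial t.  Early trials use the shorter
    available history; the first trial has rate 0 by convention.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vol = session.config.reward_volume
    trials = session.trials
    n = len(trials)
    rate = np.zeros(n)
    for t in range(1, n):
        lo = max(0, t - window)
        rewarded = sum(1 for tr in trials[lo:t] if tr.outcome == "reward")
        elapsed_min = (trials[t].t_cue - trials[lo].t_cue) / 60.0
        rate[t] = rewarded * vol / elapsed_min if elapsed_min > 0 else 0.0
    return rate


def engagement_metrics(
    sessions: Session | Sequence[Session],
    baseline_sessions: Session | Sequence[Session],
) -> EngagementSummary:
    """Task-engagement proxies: normalized trial counts, initiation latency.

    The trial count of the manipulated sessions is normalized to the mean
    of the baseline sessions; initiation latency is mean t_init - t_cue
    over completed trials per group.
    """
    def aslist(x):
        return [x] if isinstance(x, Session) else list(x)

    sessions = aslist(sessions)
    baseline = aslist(baseline_sessions)
    if not sessions or not baseline:
        raise ValueError("need at least one session per group")

    def mean_trials(group: Iterable[Session]) -> float:
        return float(np.mean([len(s.completed_trials()) for s in group]))

    def mean_latency(group: Iterable[Session]) -> float:
        lat = [t.t_init - t.t_cue for s in group
               for t in s.completed_trials()]
        return float(np.mean(lat))

    return EngagementSummary(
        total_trials_normalized=mean_trials(sessions) / mean_trials(baseline),
        initiation_latency=mean_latency(sessions),
        baseline_initiation_latency=mean_latency(baseline),
    )
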