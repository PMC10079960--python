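"""Serial-reversal two-alternative forced-choice (2AFC) task simulator.

Implements the probabilistic reversal task used to probe value-based choice
in mice: on every trial one side port is "correct"; choosing it yields a
liquid reward with probability ``p_outcome`` (default 0.85) while choosing
the other side yields a punishment tone with the same probability.  The
remaining trials deliver no outcome at all.  Whenever 8 of the last 10
completed choices within the current block were to the rewarded port, the
contingency silently reverses and a new block begins.

Simulated agents (Q-learning with forgetting, win-stay/lose-shift with
lapse, or unbiased random choice) play the task, producing trial tables
with realistic event timestamps that are structurally identical to what an
operant session would log.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

Side = Literal["left", "right"]

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "Session",
    "TaskState",
    "AgentParams",
    "check_reversal",
    "step_environment",
    "simulate_agent",
    "assign_light_trials",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the 2AFC serial-reversal task.

    Durations are in seconds, reward volume in microliters.
    """

    p_outcome: float = 0.85
    reward_volume: float = 12.0
    switch_n_correct: int = 8
    switch_window: int = 10
    choice_window: float = 3.0
    outcome_delay: float = 0.5
    iti: float = 3.0
    hold: float = 0.5
    timeout_punish: float = 3.0
    p_omission: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_outcome <= 1.0:
            raise ValueError("p_outcome must be in (0, 1]")
        if self.switch_n_correct > self.switch_window:
            raise ValueError("switch_n_correct cannot exceed switch_window")
        if not 0.0 <= self.p_omission < 1.0:
            raise ValueError("p_omission must be in [0, 1)")
        for name in ("choice_window", "outcome_delay", "iti", "hold",
                     "timeout_punish"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TrialRecord:
    """One trial of a session: timing, choice, outcome and block identity."""

    trial_index: int
    block_index: int
    rewarded_side: Side
    choice: str  # left | right | omission
    outcome: str  # reward | punish | none
    t_cue: float
    t_init: float
    t_choice: float
    t_outcome: float
    light_on: bool = False
    light_epoch: str = "na"  # choice | outcome | na

    @property
    def completed(self) -> bool:
        return self.choice != "omission"

    @property
    def correct(self) -> bool:
        return self.choice == self.rewarded_side


@dataclass
class Session:
    """An ordered sequence of trials plus the configuration that produced it."""

    trials: list[TrialRecord]
    config: TaskConfig
    seed: int
    agent_params: Optional["AgentParams"] = None
    session_id: str = "sim"
    animal_id: str = "agent"
    hemisphere: Side = "left"  # recording hemisphere, for ipsi/contra mapping

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def completed_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.completed]


@dataclass(frozen=True)
class AgentParams:
    """Policy name and parameters of a simulated agent.

    ``qforget``: Q-learning with forgetting (alpha, beta, phi).
    ``wsls``: win-stay/lose-shift with lapse rate epsilon.
    ``random``: unbiased coin flip.
    """

    policy: str = "qforget"
    alpha: float = 0.6
    beta: float = 5.0
    phi: float = 0.2
    epsilon: float = 0.1


@dataclass
class TaskState:
    """Mutable environment state carried across trials."""

    rewarded_side: Side = "left"
    block_index: int = 1
    block_history: list[bool] = field(default_factory=list)  # correct flags


def check_reversal(
    block_choices: Sequence[bool] | Sequence[str],
    n_correct: int = 8,
    window: int = 10,
) -> bool:
    """Decide whether the reversal criterion fires.

    ``block_choices`` holds the completed choices of the *current block only*
    (the window resets at each contingency switch), either as booleans or as
    ``{"correct", "incorrect"}`` strings, oldest first.  Returns True iff at
    least ``n_correct`` of the last ``min(len, window)`` entries were to the
    currently rewarded port.
    """
    flags = [c if isinstance(c, (bool, np.bool_)) else c == "correct"
             for c in block_choices]
    if not flags:
        return False
    recent = flags[-window:]
    return sum(recent) >= n_correct


def step_environment(
    state: TaskState,
    choice: Side,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
) -> tuple[str, TaskState]:
    """Resolve one completed choice: assign the outcome, then check reversal.

    Correct choices are rewarded with probability ``p_outcome``; incorrect
    choices are punished with the same probability; otherwise no outcome is
    delivered.  The reversal criterion is evaluated after the outcome on the
    block's completed-choice history; when it fires the rewarded side flips,
    the block index increments and the window resets.
    """
    if choice not in ("left", "right"):
        raise ValueError(f"choice must be left or right, got {choice!r}")
    config = config or TaskConfig()
    correct = choice == state.rewarded_side
    delivered = rng.random() < config.p_outcome
    if correct:
        outcome = "reward" if delivered else "none"
    else:
        outcome = "punish" if delivered else "none"

    new_state = TaskState(
        rewarded_side=state.rewarded_side,
        block_index=state.block_index,
        block_history=state.block_history + [correct],
    )
    if check_reversal(new_state.block_history, config.switch_n_correct,
                      config.switch_window):
        new_state = TaskState(
            rewarded_side="right" if state.rewarded_side == "left" else "left",
            block_index=state.block_index + 1,
            block_history=[],
        )
    return outcome, new_state


def _agent_choice(
    policy: str,
    params: AgentParams,
    q: np.ndarray,
    prev_choice: Optional[Side],
    prev_rewarded: bool,
    rng: np.random.Generator,
) -> Side:
    if policy == "random":
        return "right" if rng.random() < 0.5 else "left"
    if policy == "qforget":
        # softmax on Q_right - Q_left
        from .choice_models import softmax_p

        p_right = softmax_p(q[1] - q[0], params.beta)
        return "right" if rng.random() < p_right else "left"
    if policy == "wsls":
        if prev_choice is None or rng.random() < params.epsilon:
            return "right" if rng.random() < 0.5 else "left"
        if prev_rewarded:
            return prev_choice
        return "right" if prev_choice == "left" else "left"
    raise ValueError(f"unknown policy {policy!r}")


def simulate_agent(
    agent_params: AgentParams | dict,
    task_config: TaskConfig | None = None,
    n_trials: int = 500,
    seed: int = 0,
) -> Session:
    """Simulate one session of an agent playing the reversal task.

    Timestamps are generated from the task's fixed delays plus log-normal
    animal latencies; identical arguments always give an identical Session.
    """
    if isinstance(agent_params, dict):
        agent_params = AgentParams(**agent_params)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = task_config or TaskConfig()
    rng = np.random.default_rng(seed)

    state = TaskState(rewarded_side="left" if rng.random() < 0.5 else "right")
    q = np.zeros(2)  # [left, right]
    prev_choice: Optional[Side] = None
    prev_rewarded = False

    trials: list[TrialRecord] = []
    t = 0.0
    for i in range(1, n_trials + 1):
        t_cue = t
        # latency to poke the lit center port, then the hold period
        t_init = t_cue + rng.lognormal(np.log(0.4), 0.4) + config.hold
        if config.p_omission > 0 and rng.random() < config.p_omission:
            trials.append(TrialRecord(
                trial_index=i, block_index=state.block_index,
                rewarded_side=state.rewarded_side, choice="omission",
                outcome="none", t_cue=t_cue, t_init=t_init,
                t_choice=np.nan, t_outcome=np.nan))
            t = t_init + config.timeout_punish + config.iti
            continue

        choice = _agent_choice(agent_params.policy, agent_params, q,
                               prev_choice, prev_rewarded, rng)
        played_side = state.rewarded_side
        played_block = state.block_index
        outcome, state = step_environment(state, choice, rng, config)
        latency = min(rng.lognormal(np.log(0.8), 0.4), config.choice_window)
        t_choice = t_init + latency
        t_outcome = t_choice + config.outcome_delay
        trials.append(TrialRecord(
            trial_index=i, block_index=played_block,
            rewarded_side=played_side, choice=choice, outcome=outcome,
            t_cue=t_cue, t_init=t_init, t_choice=t_choice,
            t_outcome=t_outcome))
        t = t_outcome + config.iti
        if outcome == "punish":
            t += config.timeout_punish

        R = 1.0 if outcome == "reward" else 0.0
        idx = 1 if choice == "right" else 0
        q[idx] += agent_params.alpha * (R - q[idx])
        q[1 - idx] *= 1.0 - agent_params.phi
        prev_choice = choice
        prev_rewarded = outcome == "reward"

    return Session(trials=trials, config=config, seed=seed,
                   agent_params=agent_params)


def assign_light_trials(
    session: Session,
    fraction: float = 0.3,
    epoch: str = "choice",
    seed: int = 0,
) -> Session:
    """Mark a uniformly random subset of trials as optogenetic-light trials.

    Returns a new Session; ``light_on`` is set on round(fraction * n) trials
    and ``light_epoch`` records the manipulated epoch on those trials.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if epoch not in ("choice", "outcome"):
        raise ValueError("epoch must be 'choice' or 'outcome'")
    rng = np.random.default_rng(seed)
    n = session.n_trials
    n_light = int(round(fraction * n))
    chosen = set(rng.choice(n, size=n_light, replace=False).tolist())
    out = copy.deepcopy(session)
    out.trials = [
        replace(t, light_on=i in chosen,
                light_epoch=epoch if i in chosen else "na")
        for i, t in enumerate(out.trials)
    ]
    return out
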