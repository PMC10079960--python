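"""Hand-session builders and brute-force oracles shared across tests."""

from __future__ import annotations

import numpy as np

from revenc.task import Session, TaskConfig, TrialRecord


def make_session(choices, outcomes, rewarded_sides=None, light_on=None,
                 light_epoch="choice", trial_spacing=12.0,
                 config=None) -> Session:
    """Build a session from explicit per-trial choices and outcomes.

    Timestamps are laid out on a regular grid (one trial every
    ``trial_spacing`` seconds) so elapsed-time arithmetic is easy to do
    by hand in tests.
    """
    config = config or TaskConfig()
    n = len(choices)
    if rewarded_sides is None:
        rewarded_sides = ["left"] * n
    if light_on is None:
        light_on = [False] * n
    trials = []
    for i in range(n):
        t0 = i * trial_spacing
        trials.append(TrialRecord(
            trial_index=i + 1, block_index=1,
            rewarded_side=rewarded_sides[i], choice=choices[i],
            outcome=outcomes[i], t_cue=t0, t_init=t0 + 1.0,
            t_choice=t0 + 2.0 if choices[i] != "omission" else np.nan,
            t_outcome=t0 + 2.5 if choices[i] != "omission" else np.nan,
            light_on=light_on[i],
            light_epoch=light_epoch if light_on[i] else "na"))
    return Session(trials=trials, config=config, seed=0)


def brute_force_stay_counts(session, prev_filter=None):
    """Exhaustive enumeration of (win/lose, stay/shift) transition counts."""
    completed = [t for t in session.trials if t.choice != "omission"]
    counts = {"win_stay": 0, "win_shift": 0, "lose_stay": 0, "lose_shift": 0}
    for prev, cur in zip(completed, completed[1:]):
        if prev_filter is not None and not prev_filter(prev):
            continue
        win = prev.outcome == "reward"
        stay = cur.choice == prev.choice
        key = ("win" if win else "lose") + ("_stay" if stay else "_shift")
        counts[key] += 1
    return counts


def replay_block_structure(session):
    """Naive sliding-window replay of the reversal rule.

    Returns per-trial (block_index, rewarded_side) computed independently
    of the simulator's own bookkeeping.
    """
    cfg = session.config
    side = session.trials[0].rewarded_side
    block, hist = 1, []
    expected = []
    for t in session.trials:
        expected.append((block, side))
        if t.choice == "omission":
            continue
        hist.append(t.choice == side)
        if sum(hist[-cfg.switch_window:]) >= cfg.switch_n_correct:
            side = "left" if side == "right" else "right"
            block += 1
            hist = []
    return expected


def explicit_rho_sum(r, beta, tau):
    """Brute-force exponentially weighted sum defining the state estimate."""
    r = np.asarray(r, dtype=float)
    rho = np.zeros(len(r))
    for t in range(len(r)):
        rho[t] = beta * sum(np.exp(-i / tau) * r[t - i]
                            for i in range(t + 1))
    return rho
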