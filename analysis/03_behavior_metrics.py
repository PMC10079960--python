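#!/usr/bin/env python
"""Behavioral metrics: stay probabilities and optogenetic-style contrasts.

Computes win-stay/lose-stay probabilities and the relative reward stay
per session, then demonstrates the delta-win-stay / delta-lose-stay
contrast on a session with a random 30% light assignment and a
light-insensitive agent (the null case: both deltas should hover near
zero).  Writes results/behavior_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from revenc import io
from revenc.metrics import delta_stay, relative_reward_stay, \
    stay_probabilities
from revenc.task import assign_light_trials

OUT = Path(__file__).resolve().parent.parent / "results"
sessions = io.read_trial_table(OUT / "trial_table.csv")

rows = []
for s in sessions:
    st = stay_probabilities(s)
    rrs, corrected = relative_reward_stay(st)
    lit = assign_light_trials(s, fraction=0.3, epoch="choice", seed=99)
    d = delta_stay(lit, epoch="choice")
    rows.append({
        "session_id": s.session_id,
        "p_winstay": st.p_winstay, "p_losestay": st.p_losestay,
        "relative_reward_stay": rrs, "haldane_corrected": corrected,
        "delta_winstay_null": d["delta_winstay"],
        "delta_losestay_null": d["delta_losestay"],
    })
    print(f"{s.session_id}: P(stay|win)={st.p_winstay:.3f} "
          f"P(stay|lose)={st.p_losestay:.3f} RRS={rrs:.2f} "
          f"null dWS={d['delta_winstay']:+.3f} "
          f"dLS={d['delta_losestay']:+.3f}")

pd.DataFrame(rows).to_csv(OUT / "behavior_metrics.csv", index=False)
print(f"wrote {OUT / 'behavior_metrics.csv'}")
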