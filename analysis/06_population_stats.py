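#!/usr/bin/env python
"""Pathway-level kernel statistics with BCa bootstrap inference.

Reads the per-neuron kernels from 05_fit_encoding.py, restricts to
task-tuned neurons, computes each pathway's RMS kernel with a 95% BCa
bootstrap band, tests the per-lag pathway difference for the reward
kernel, and compares the outcome tuning-index distributions between
pathways with a two-sample KS test.  Writes
results/pathway_kernels.csv and results/pathway_difference.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from revenc.encoding import KernelEstimate
from revenc.population import (bootstrap_kernel_ci, compare_tuning,
                               kernel_difference_test)

OUT = Path(__file__).resolve().parent.parent / "results"
fve = pd.read_csv(OUT / "encoding_fve.csv")
kernels = pd.read_csv(OUT / "encoding_kernels.csv")
tuned_ids = set(fve.loc[fve["task_tuned"], "neuron_id"])
kernels = kernels[kernels["neuron_id"].isin(tuned_ids)]

N_BOOT = 2000  # scaled down from the 10,000 used for final inference

rows = []
groups = {}
for predictor in ("o_plus", "o_minus"):
    sub = kernels[kernels["predictor"] == predictor]
    for pathway, g in sub.groupby("pathway"):
        ks = [KernelEstimate(predictor, gg["lag"].to_numpy(),
                             gg["value"].to_numpy())
              for _, gg in g.groupby("neuron_id")]
        groups[(predictor, pathway)] = ks
        pk = bootstrap_kernel_ci(ks, n_boot=N_BOOT, seed=0)
        peak = pk.rms.max()
        print(f"{predictor} / pathway {pathway}: {pk.n_neurons} neurons, "
              f"peak RMS {peak:.3f} dF/F")
        rows.extend({"predictor": predictor, "pathway": pathway,
                     "lag": lag, "rms": r, "ci_low": lo, "ci_high": hi}
                    for lag, r, lo, hi in zip(pk.lags, pk.rms, pk.ci_low,
                                              pk.ci_high))
pd.DataFrame(rows).to_csv(OUT / "pathway_kernels.csv", index=False)

diff_rows = []
for predictor in ("o_plus", "o_minus"):
    a = groups.get((predictor, "A"))
    b = groups.get((predictor, "P"))
    if not a or not b or len(a) < 2 or len(b) < 2:
        print(f"{predictor}: not enough tuned neurons in both pathways")
        continue
    res = kernel_difference_test(a, b, n_boot=N_BOOT, seed=0)
    frac = res["sig_mask"].mean()
    print(f"{predictor}: A vs P differs at {frac:.0%} of lags "
          f"(per-lag BCa bootstrap, 5% level)")
    diff_rows.extend({"predictor": predictor, "lag": lag, "difference": d,
                      "sig": s}
                     for lag, d, s in zip(res["lags"], res["difference"],
                                          res["sig_mask"]))
pd.DataFrame(diff_rows).to_csv(OUT / "pathway_difference.csv", index=False)

tuning = compare_tuning(
    fve.loc[fve["pathway"] == "A", "outcome_tuning_index"].to_numpy(),
    fve.loc[fve["pathway"] == "P", "outcome_tuning_index"].to_numpy())
print(f"outcome tuning A vs P: KS={tuning['ks_statistic']:.2f} "
      f"(p={tuning['ks_pvalue']:.3g}); tuned proportions "
      f"A={tuning['prop_tuned_a']:.0%} P={tuning['prop_tuned_b']:.0%}")
print(f"wrote {OUT / 'pathway_kernels.csv'} and "
      f"{OUT / 'pathway_difference.csv'}")
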