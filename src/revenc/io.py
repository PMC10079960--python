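"""File formats, configuration and run manifests.

Trial tables are delimited text (CSV, one row per trial) shared by every
stage; calcium traces live in an HDF5 container (one dataset per neuron
plus shared frame timestamps); run configuration is a single YAML file
whose defaults reproduce the task and fitting constants (85% outcome
probability, 8-of-10 reversal rule, elastic-net mixing 0.95, 50 folds,
200 ms chunks, 5% thresholds, 10,000 bootstrap samples).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .neural_sim import CalciumTrace
from .task import Session, TaskConfig, TrialRecord

__all__ = [
    "TRIAL_TABLE_COLUMNS",
    "DEFAULT_CONFIG",
    "read_trial_table",
    "write_trial_table",
    "read_traces",
    "write_traces",
    "load_config",
    "write_manifest",
]

TRIAL_TABLE_COLUMNS = [
    "session_id", "animal_id", "trial_index", "block_index",
    "rewarded_side", "choice", "outcome", "t_cue", "t_init", "t_choice",
    "t_outcome", "light_on", "light_epoch",
]

_SIDES = {"left", "right"}
_CHOICES = {"left", "right", "omission"}
_OUTCOMES = {"reward", "punish", "none"}
_EPOCHS = {"choice", "outcome", "na"}


def write_trial_table(sessions: Session | Sequence[Session],
                      path: str | Path) -> None:
    """Write one or more sessions as a delimited trial table."""
    sessions = [sessions] if isinstance(sessions, Session) else list(sessions)
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append({
                "session_id": s.session_id, "animal_id": s.animal_id,
                "trial_index": t.trial_index, "block_index": t.block_index,
                "rewarded_side": t.rewarded_side, "choice": t.choice,
                "outcome": t.outcome, "t_cue": t.t_cue, "t_init": t.t_init,
                "t_choice": t.t_choice, "t_outcome": t.t_outcome,
                "light_on": t.light_on, "light_epoch": t.light_epoch,
            })
    pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS).to_csv(path, index=False)


def read_trial_table(path: str | Path,
                     config: Optional[TaskConfig] = None) -> list[Session]:
    """Parse a trial table into Sessions, validating schema and ordering.

    The task configuration is not stored in the table; pass the one the
    sessions were recorded (or simulated) under, else defaults are used.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} missing column(s): "
                         f"{', '.join(missing)}")
    for col, vocab in (("rewarded_side", _SIDES), ("choice", _CHOICES),
                       ("outcome", _OUTCOMES), ("light_epoch", _EPOCHS)):
        bad = df.loc[~df[col].isin(vocab)]
        if len(bad):
            raise ValueError(
                f"invalid {col} value {bad[col].iloc[0]!r} at row "
                f"{bad.index[0] + 2}")  # +2: header + 1-based
    sessions = []
    for sid, g in df.groupby("session_id", sort=False):
        t_cue = g["t_cue"].to_numpy()
        if np.any(np.diff(t_cue) <= 0):
            row = int(np.nonzero(np.diff(t_cue) <= 0)[0][0])
            raise ValueError(
                f"non-monotone t_cue in session {sid!r} near row "
                f"{g.index[row + 1] + 2}")
        trials = [
            TrialRecord(
                trial_index=int(r.trial_index),
                block_index=int(r.block_index),
                rewarded_side=r.rewarded_side, choice=r.choice,
                outcome=r.outcome, t_cue=float(r.t_cue),
                t_init=float(r.t_init), t_choice=float(r.t_choice),
                t_outcome=float(r.t_outcome), light_on=bool(r.light_on),
                light_epoch=r.light_epoch)
            for r in g.itertuples()
        ]
        sessions.append(Session(trials=trials,
                                config=config or TaskConfig(), seed=-1,
                                session_id=str(sid),
                                animal_id=str(g["animal_id"].iloc[0])))
    return sessions


def write_traces(traces: Sequence[CalciumTrace], path: str | Path,
                 ground_truths: Optional[dict] = None) -> None:
    """Store traces in HDF5: shared /frame_times plus /neurons/<id>.

    ``ground_truths`` optionally maps neuron_id to a GroundTruth whose
    kernels and gains are stored alongside for recovery tests.
    """
    traces = list(traces)
    n_frames = {len(t.frame_times) for t in traces}
    if len(n_frames) != 1:
        raise ValueError("all traces in one file must share frame counts")
    with h5py.File(path, "w") as f:
        f.create_dataset("frame_times", data=traces[0].frame_times)
        grp = f.create_group("neurons")
        for t in traces:
            d = grp.create_dataset(t.neuron_id, data=t.values)
            d.attrs["pathway_label"] = t.pathway_label
            if ground_truths and t.neuron_id in ground_truths:
                gt = ground_truths[t.neuron_id]
                d.attrs["ground_truth"] = json.dumps({
                    "intercept": gt.intercept,
                    "noise_sigma": gt.noise_sigma,
                    "kernel_coefs": {k: v.tolist()
                                     for k, v in gt.kernel_coefs.items()},
                    "continuous_gains": gt.continuous_gains,
                })


def read_traces(path: str | Path) -> tuple[list[CalciumTrace], dict]:
    """Read a trace container; returns (traces, ground_truth_json_by_id)."""
    traces, gts = [], {}
    with h5py.File(path, "r") as f:
        ft = f["frame_times"][:]
        for nid, d in f["neurons"].items():
            traces.append(CalciumTrace(frame_times=ft, values=d[:],
                                       neuron_id=nid,
                                       pathway_label=d.attrs.get(
                                           "pathway_label", "A")))
            if "ground_truth" in d.attrs:
                gts[nid] = json.loads(d.attrs["ground_truth"])
    return traces, gts


DEFAULT_CONFIG: dict = {
    "task": {
        "p_outcome": 0.85, "reward_volume": 12.0, "switch_n_correct": 8,
        "switch_window": 10, "choice_window": 3.0, "outcome_delay": 0.5,
        "iti": 3.0, "hold": 0.5, "timeout_punish": 3.0, "p_omission": 0.0,
    },
    "agents": {
        "policy": "qforget", "alpha": 0.6, "beta": 5.0, "phi": 0.2,
        "epsilon": 0.1, "n_trials": 500, "n_sessions": 1,
    },
    "encoding": {
        "alpha_mixing": 0.95, "n_folds": 50, "chunk_ms": 200,
        "n_lambda": 30, "lambda_min_ratio": 1.0e-3,
        "fve_threshold": 0.05, "tuning_threshold": 0.05,
    },
    "bootstrap": {"n_boot": 10000, "confidence": 0.95},
    "seeds": {"task": 1, "neural": 2, "encoding": 3, "bootstrap": 4},
}


def load_config(path: Optional[str | Path] = None) -> dict:
    """Load a YAML run configuration over the defaults.

    A user-provided file must carry an explicit ``seeds`` section — seeds
    are never silently defaulted for user runs.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    if "seeds" not in user:
        raise ValueError("config file must declare a 'seeds' section")
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for k, v in values.items():
            if k not in cfg[section]:
                raise ValueError(f"unknown config key {section}.{k}")
            cfg[section][k] = v
    return cfg


def task_config_from(cfg: dict) -> TaskConfig:
    return TaskConfig(**cfg["task"])


def write_manifest(out_dir: str | Path, cfg: dict, stage: str,
                   artifacts: Sequence[str]) -> Path:
    """Write a JSON manifest (config hash, seeds, versions) for one stage."""
    from . import __version__

    payload = yaml.safe_dump(cfg, sort_keys=True).encode()
    manifest = {
        "stage": stage,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "config": cfg,
        "seeds": cfg.get("seeds", {}),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "artifacts": list(artifacts),
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
    return path
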