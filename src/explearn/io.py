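"""Session file formats and run configuration.

A participant session is stored as plain text next to a JSON sidecar:

``<id>_sessions.csv``
    One row per attempt: task, target_alpha, target_beta, condition, t,
    planned_alpha, planned_beta, executed_alpha, executed_beta, raw_score,
    pooled_score.  Episodes are the consecutive rows sharing (task,
    target_alpha, target_beta).
``<id>_traces.csv``
    Tracing-task table: target_alpha, target_beta, trace_idx, alpha_hat,
    beta_hat.
``<id>.json``
    Participant parameters (true and, when present, fitted), tau0, seed and
    a schema version.

CSV dialect: comma-separated, UTF-8, dot decimals, mandatory header.  Run
configurations load from YAML or JSON by file extension.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agent import AttemptRecord, Episode, MotorNoiseProfile
from .cohort import ParticipantSession, ParticipantSpec
from .task import ActionPair, TargetSpec

__all__ = [
    "SCHEMA_VERSION",
    "episodes_to_frame",
    "episodes_from_frame",
    "write_session",
    "read_session",
    "load_config",
]

SCHEMA_VERSION = 1

SESSION_COLUMNS = [
    "task", "target_alpha", "target_beta", "condition", "t",
    "planned_alpha", "planned_beta", "executed_alpha", "executed_beta",
    "raw_score", "pooled_score",
]
TRACE_COLUMNS = ["target_alpha", "target_beta", "trace_idx", "alpha_hat", "beta_hat"]


def episodes_to_frame(episodes, task: str) -> pd.DataFrame:
    rows = []
    for ep in episodes:
        for rec in ep.attempts:
            rows.append({
                "task": task,
                "target_alpha": ep.target.pair.alpha,
                "target_beta": ep.target.pair.beta,
                "condition": ep.target.condition,
                "t": rec.t,
                "planned_alpha": rec.planned.alpha,
                "planned_beta": rec.planned.beta,
                "executed_alpha": rec.executed.alpha,
                "executed_beta": rec.executed.beta,
                "raw_score": rec.raw_score,
                "pooled_score": rec.pooled_score,
            })
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def _validate_session_frame(df: pd.DataFrame, horizon: int = 25):
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session file missing columns: {sorted(missing)}")
    bad = df.index[(df["t"] < 1) | (df["t"] > horizon)]
    if len(bad):
        raise ValueError(
            f"attempt index out of range [1, {horizon}] at rows {bad.tolist()[:5]}")
    for col in ("raw_score", "pooled_score", "t"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r}")


def episodes_from_frame(df: pd.DataFrame, task: str, horizon: int = 25) -> list:
    """Rebuild Episode objects for one task from a session frame."""
    _validate_session_frame(df, horizon)
    sub = df[df["task"] == task]
    episodes = []
    for (ta, tb, cond), g in sub.groupby(
            ["target_alpha", "target_beta", "condition"], sort=False):
        g = g.sort_values("t")
        target = TargetSpec(pair=ActionPair(float(ta), float(tb)),
                            condition=str(cond), task=task)
        attempts = [
            AttemptRecord(
                t=int(r.t),
                planned=ActionPair(float(r.planned_alpha), float(r.planned_beta)),
                executed=ActionPair(float(r.executed_alpha), float(r.executed_beta)),
                raw_score=int(r.raw_score),
                pooled_score=int(r.pooled_score))
            for r in g.itertuples()
        ]
        terminated = len(attempts) < horizon and attempts[-1].pooled_score == 50
        episodes.append(Episode(target=target, attempts=attempts,
                                terminated_early=terminated))
    return episodes


def write_session(session: ParticipantSession, directory) -> Path:
    """Write a session's CSV files and JSON sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = session.spec.id
    frames = [episodes_to_frame(session.dm_episodes, "DM"),
              episodes_to_frame(session.mo_episodes, "MO")]
    if session.exp2_mo_episodes:
        frames.append(episodes_to_frame(session.exp2_mo_episodes, "EXP2_MO"))
    if session.exp2_dm_episodes:
        frames.append(episodes_to_frame(session.exp2_dm_episodes, "EXP2_DM_NOISE"))
    # %.17g guarantees float64 round-trips bit-exactly through the CSV
    pd.concat(frames, ignore_index=True).to_csv(
        directory / f"{pid}_sessions.csv", index=False, float_format="%.17g")
    if session.noise_traces is not None:
        session.noise_traces.to_csv(directory / f"{pid}_traces.csv", index=False,
                                    float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "id": pid,
        "gamma_true": session.spec.gamma_true,
        "sigma_dir_true": session.spec.sigma_dir_true,
        "sigma_cur_true": session.spec.sigma_cur_true,
        "seed": session.spec.seed,
        "non_explorer": session.spec.non_explorer,
        "tau0": session.tau0,
        "gamma_hat": session.gamma_hat,
        "noise_hat": (None if session.noise_hat is None else
                      [session.noise_hat.sigma_dir, session.noise_hat.sigma_cur]),
    }
    path = directory / f"{pid}.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def read_session(sidecar_path) -> ParticipantSession:
    """Load a participant session written by :func:`write_session`."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    pid = meta["id"]
    directory = sidecar_path.parent
    spec = ParticipantSpec(
        id=pid,
        gamma_true=float(meta["gamma_true"]),
        sigma_dir_true=float(meta["sigma_dir_true"]),
        sigma_cur_true=float(meta["sigma_cur_true"]),
        tau0=meta.get("tau0"),
        seed=int(meta.get("seed", 0)),
        non_explorer=bool(meta.get("non_explorer", False)))
    sess_path = directory / f"{pid}_sessions.csv"
    dm, mo = [], []
    exp2_mo = exp2_dm = None
    if sess_path.exists():
        df = pd.read_csv(sess_path, float_precision="round_trip")
        if len(df):
            dm = episodes_from_frame(df, "DM")
            mo = episodes_from_frame(df, "MO")
            if (df["task"] == "EXP2_MO").any():
                exp2_mo = episodes_from_frame(df, "EXP2_MO")
            if (df["task"] == "EXP2_DM_NOISE").any():
                exp2_dm = episodes_from_frame(df, "EXP2_DM_NOISE")
    traces = None
    trace_path = directory / f"{pid}_traces.csv"
    if trace_path.exists():
        traces = pd.read_csv(trace_path, float_precision="round_trip")
        missing = set(TRACE_COLUMNS) - set(traces.columns)
        if missing:
            raise ValueError(f"trace file missing columns: {sorted(missing)}")
    noise_hat = meta.get("noise_hat")
    return ParticipantSession(
        spec=spec, dm_episodes=dm, mo_episodes=mo, noise_traces=traces,
        exp2_mo_episodes=exp2_mo, exp2_dm_episodes=exp2_dm,
        tau0=meta.get("tau0"),
        gamma_hat=meta.get("gamma_hat"),
        noise_hat=None if noise_hat is None else MotorNoiseProfile(*noise_hat))


def load_config(path) -> dict:
    """Load a run configuration from YAML or JSON, by file extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
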