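"""Behavioural statistics computed from episode data.

These analyses apply equally to simulated sessions and to human-format
session files: learning curves, attempt-to-attempt action change (and its
dependence on the preceding score), per-dimension error reduction,
across-episode movement variance, motor-noise estimation from tracing
traces, the curvature-non-explorer outlier filter, and the gain/loss
analysis relative to the running-maximum reference point.

Conventions: pooled (positive-equivalent) scores throughout; attempts after
an early termination contribute the maximal score to learning curves and
zero to error curves, but are excluded from action-change statistics (no
action was taken); the first attempt of an episode has no reference point
and is excluded from gain/loss labelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agent import Episode, MotorNoiseProfile

__all__ = [
    "action_change",
    "action_change_by_score",
    "error_curves",
    "learning_curve",
    "motor_noise_estimate",
    "MotorNoiseEstimate",
    "curvature_outliers",
    "reference_point_analysis",
    "ReferencePointResult",
    "variance_curve",
    "pearson_r",
]


def action_change(a_t, a_next) -> float:
    """Euclidean distance between two successive actions in (alpha, beta)."""
    a = np.asarray(a_t, dtype=float)
    b = np.asarray(a_next, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("actions must be finite")
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def _episode_actions(ep: Episode, use: str) -> np.ndarray:
    if use == "planned":
        return np.array([[r.planned.alpha, r.planned.beta] for r in ep.attempts])
    return np.array([[r.executed.alpha, r.executed.beta] for r in ep.attempts])


def _episode_scores(ep: Episode) -> np.ndarray:
    return np.array([r.pooled_score for r in ep.attempts], dtype=int)


def action_change_by_score(episodes: Iterable[Episode], use: str = "executed",
                           n_bins: int = 10) -> pd.DataFrame:
    """Mean action change on attempt t+1 grouped by the score at attempt t.

    Returns a tidy frame with one row per observed score value (columns
    ``score``, ``mean_change``, ``n``) plus a decile-bin summary in
    ``bin_mid`` / ``bin_mean_change`` merged via a second frame attribute;
    the overall mean change is stored in ``df.attrs["overall_mean"]``.
    Actions default to the executed pair (identical to the planned one in
    the decision-making task).
    """
    scores, changes = [], []
    for ep in episodes:
        if len(ep) < 2:
            continue
        acts = _episode_actions(ep, use)
        sc = _episode_scores(ep)
        d = np.hypot(np.diff(acts[:, 0]), np.diff(acts[:, 1]))
        scores.append(sc[:-1])
        changes.append(d)
    if not scores:
        df = pd.DataFrame(columns=["score", "mean_change", "n"])
        df.attrs["overall_mean"] = np.nan
        return df
    s = np.concatenate(scores)
    c = np.concatenate(changes)
    df = (pd.DataFrame({"score": s, "change": c})
          .groupby("score")["change"].agg(["mean", "size"]).reset_index()
          .rename(columns={"mean": "mean_change", "size": "n"}))
    edges = np.linspace(0, 50, n_bins + 1)
    bin_idx = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    binned = (pd.DataFrame({"bin": bin_idx, "change": c})
              .groupby("bin")["change"].mean())
    df.attrs["overall_mean"] = float(c.mean())
    df.attrs["binned"] = pd.DataFrame({
        "bin_mid": (edges[:-1] + edges[1:])[binned.index.to_numpy()] / 2,
        "mean_change": binned.to_numpy(),
    })
    return df


def learning_curve(episodes: Iterable[Episode], horizon: int = 25) -> np.ndarray:
    """Mean pooled score per attempt, padding post-termination with 50."""
    rows = []
    for ep in episodes:
        sc = _episode_scores(ep)
        padded = np.full(horizon, 50, dtype=float)
        padded[: sc.size] = sc[:horizon]
        rows.append(padded)
    if not rows:
        raise ValueError("no episodes supplied")
    return np.mean(rows, axis=0)


def error_curves(episodes: Iterable[Episode], horizon: int = 25,
                 use: str = "executed") -> pd.DataFrame:
    """Per-attempt mean |d_alpha| and |d_beta| against each episode's target.

    Post-termination attempts count as zero error (the target was found).
    """
    rows_a, rows_b = [], []
    for ep in episodes:
        acts = _episode_actions(ep, use)
        ta, tb = ep.target.pair.alpha, ep.target.pair.beta
        da = np.zeros(horizon)
        db = np.zeros(horizon)
        n = min(len(ep), horizon)
        da[:n] = np.abs(acts[:n, 0] - ta)
        db[:n] = np.abs(acts[:n, 1] - tb)
        rows_a.append(da)
        rows_b.append(db)
    if not rows_a:
        raise ValueError("no episodes supplied")
    return pd.DataFrame({
        "attempt": np.arange(1, horizon + 1),
        "error_alpha": np.mean(rows_a, axis=0),
        "error_beta": np.mean(rows_b, axis=0),
    })


@dataclass(frozen=True)
class MotorNoiseEstimate:
    """Tracing-task summary: per-dimension error SDs and mean |error|."""

    profile: MotorNoiseProfile
    mean_abs_dir: float
    mean_abs_cur: float
    n_errors: int


def motor_noise_estimate(traces: pd.DataFrame) -> MotorNoiseEstimate:
    """Estimate motor noise from fitted tracing-task parameters.

    ``traces`` needs columns target_alpha, target_beta, alpha_hat, beta_hat
    (one row per trace; the standard design is 10 targets x 5 traces = 50
    errors per dimension).  Noise is the sample SD (ddof=1) of the signed
    per-dimension errors, pooled across targets.
    """
    required = {"target_alpha", "target_beta", "alpha_hat", "beta_hat"}
    missing = required - set(traces.columns)
    if missing:
        raise ValueError(f"traces missing columns: {sorted(missing)}")
    if len(traces) < 2:
        raise ValueError("need at least 2 traces to estimate an SD")
    err_a = traces["alpha_hat"].to_numpy() - traces["target_alpha"].to_numpy()
    err_b = traces["beta_hat"].to_numpy() - traces["target_beta"].to_numpy()
    return MotorNoiseEstimate(
        profile=MotorNoiseProfile(
            sigma_dir=float(np.std(err_a, ddof=1)),
            sigma_cur=float(np.std(err_b, ddof=1))),
        mean_abs_dir=float(np.mean(np.abs(err_a))),
        mean_abs_cur=float(np.mean(np.abs(err_b))),
        n_errors=len(traces))


def curvature_outliers(values: Sequence[float], k: float = 0.15) -> set:
    """Flag curvature non-explorers by narrow quartile fences.

    ``values`` are per-participant mean absolute curvatures; indices of
    entries outside [q1 - k*(q3-q1), q3 + k*(q3-q1)] are returned, with
    quartiles computed by linear interpolation between order statistics.
    The deliberately small multiplier (default 0.15, versus Tukey's 1.5)
    catches participants who barely explored the curvature dimension.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 participants for quartile fences")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return set(np.flatnonzero((v < lo) | (v > hi)).tolist())


@dataclass
class ReferencePointResult:
    """Gain/loss action-change aggregates under the running-max reference."""

    mean_change_after_gain: float
    mean_change_after_loss: float
    by_reference: pd.DataFrame
    labels: pd.DataFrame


def reference_point_analysis(episodes: Iterable[Episode],
                             use: str = "executed") -> ReferencePointResult:
    """Action change after gains versus losses, by reference level.

    The reference point at attempt t is the maximum pooled score achieved up
    to attempt t-1; the score at t is a gain if it strictly exceeds the
    reference, otherwise a loss.  The subsequent action change (t -> t+1) is
    aggregated by label and by reference level.  Attempt 1 has no reference
    and is excluded.
    """
    recs = []
    for ei, ep in enumerate(episodes):
        if len(ep) < 3:
            continue
        acts = _episode_actions(ep, use)
        sc = _episode_scores(ep)
        running_max = np.maximum.accumulate(sc)
        for t in range(2, len(ep)):  # attempt index t (1-based), change at t+1
            ref = int(running_max[t - 2])
            score_t = int(sc[t - 1])
            label = "gain" if score_t > ref else "loss"
            change = float(np.hypot(acts[t, 0] - acts[t - 1, 0],
                                    acts[t, 1] - acts[t - 1, 1]))
            recs.append({"episode": ei, "t": t, "reference": ref,
                         "score": score_t, "label": label, "change": change})
    labels = pd.DataFrame(recs)
    if labels.empty:
        return ReferencePointResult(np.nan, np.nan,
                                    pd.DataFrame(columns=["reference", "label",
                                                          "mean_change", "n"]),
                                    labels)
    by_ref = (labels.groupby(["reference", "label"])["change"]
              .agg(["mean", "size"]).reset_index()
              .rename(columns={"mean": "mean_change", "size": "n"}))
    means = labels.groupby("label")["change"].mean()
    return ReferencePointResult(
        mean_change_after_gain=float(means.get("gain", np.nan)),
        mean_change_after_loss=float(means.get("loss", np.nan)),
        by_reference=by_ref,
        labels=labels)


def variance_curve(episodes: Iterable[Episode], horizon: int = 25,
                   use: str = "executed") -> pd.DataFrame:
    """Across-episode variance of the action parameters per attempt.

    Post-termination attempts carry no action and are excluded, so the
    per-attempt sample size may shrink toward the end of the horizon.
    """
    episodes = list(episodes)
    if len(episodes) < 2:
        raise ValueError("need at least 2 episodes for a variance curve")
    rows = []
    for t in range(1, horizon + 1):
        acts = [
            _episode_actions(ep, use)[t - 1]
            for ep in episodes if len(ep) >= t
        ]
        if len(acts) < 2:
            rows.append({"attempt": t, "var_alpha": np.nan, "var_beta": np.nan,
                         "var_total": np.nan, "n": len(acts)})
            continue
        arr = np.asarray(acts)
        va = float(np.var(arr[:, 0], ddof=1))
        vb = float(np.var(arr[:, 1], ddof=1))
        rows.append({"attempt": t, "var_alpha": va, "var_beta": vb,
                     "var_total": va + vb, "n": len(acts)})
    return pd.DataFrame(rows)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
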