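"""Task environments for the hidden-target search tasks.

Two experimental tasks share one underlying structure: an agent searches for
a hidden target defined by a direction parameter (alpha) and a curvature
parameter (beta), each ranging over a discrete grid from -1 to 1 in steps of
0.1 (21 x 21 = 441 cells).  In the decision-making (DM) task an attempt is a
click on a grid cell; in the reaching (MO) task an attempt is a drawn
trajectory x = alpha*y + beta*sin(pi*y) (y normalised to [0, 1] over the
15 cm reach depth), whose direction and curvature are estimated by least
squares.  Both tasks score an attempt by its proximity to the target:

    eps = 1 - (0.5*|d_alpha| + 0.5*|d_beta|)
    S   = max(0, round(50*eps))            (positive feedback condition)
    S   = -(50 - max(0, round(50*eps)))    (negative feedback condition)

so an exact match earns 50 points (positive) or 0 points (negative).  Scores
from the negative condition map onto the positive scale by adding 50
("pooled" scores), which is how the two conditions are aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "REACH_DEPTH_CM",
    "MOVEMENT_DURATION_WINDOW_MS",
    "GridSpec",
    "ActionPair",
    "TargetSpec",
    "Trajectory",
    "ScoreRecord",
    "build_grid",
    "default_grid",
    "target_preset",
    "targets_to_frame",
    "targets_from_frame",
    "true_score",
    "pooled_score",
    "dm_noise_score",
    "trajectory_points",
    "fit_trajectory",
    "score_table",
]

#: Reach depth of the drawing workspace, in centimetres.
REACH_DEPTH_CM = 15.0

#: Valid movement-duration window (ms) used to accept reaching attempts in
#: the original apparatus.  Recorded for documentation; simulated attempts
#: are always treated as valid.
MOVEMENT_DURATION_WINDOW_MS = (700, 1500)

_CONDITIONS = ("positive", "negative")


class ActionPair(NamedTuple):
    """A (direction, curvature) coordinate: a planned or executed action."""

    alpha: float
    beta: float


@dataclass(frozen=True)
class GridSpec:
    """The discrete parameter grid shared by states (targets) and actions.

    Cells are indexed state-major: cell ``k`` has alpha index ``k // n_beta``
    and beta index ``k % n_beta``.  At the interface grid indices are
    conventionally 1-based (i, j in 1..21); internal arrays are 0-based.
    """

    values_alpha: tuple
    values_beta: tuple

    def __post_init__(self):
        for vals in (self.values_alpha, self.values_beta):
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError("grid needs at least two values per dimension")
            if not np.all(np.diff(arr) > 0):
                raise ValueError("grid values must be strictly increasing")

    @property
    def n_alpha(self) -> int:
        return len(self.values_alpha)

    @property
    def n_beta(self) -> int:
        return len(self.values_beta)

    @property
    def n_cells(self) -> int:
        return self.n_alpha * self.n_beta

    def pairs(self) -> np.ndarray:
        """All cells as an (n_cells, 2) array of (alpha, beta), alpha-major."""
        a = np.repeat(self.values_alpha, self.n_beta)
        b = np.tile(self.values_beta, self.n_alpha)
        return np.column_stack([a, b])

    def index_of(self, pair: Sequence[float]) -> int:
        """Flat cell index of an on-grid (alpha, beta) pair."""
        alpha, beta = float(pair[0]), float(pair[1])
        ia = int(np.argmin(np.abs(np.asarray(self.values_alpha) - alpha)))
        ib = int(np.argmin(np.abs(np.asarray(self.values_beta) - beta)))
        if abs(self.values_alpha[ia] - alpha) > 1e-9 or abs(self.values_beta[ib] - beta) > 1e-9:
            raise ValueError(f"pair {pair!r} is not on the grid")
        return ia * self.n_beta + ib

    def pair_at(self, index: int) -> ActionPair:
        return ActionPair(
            float(self.values_alpha[index // self.n_beta]),
            float(self.values_beta[index % self.n_beta]),
        )


def build_grid(step: float = 0.1, lo: float = -1.0, hi: float = 1.0) -> GridSpec:
    """Build the square parameter grid; defaults give 21 values per dimension.

    ``hi - lo`` must be an integer multiple of ``step``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    n_steps = (hi - lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("(hi - lo) must be an integer multiple of step")
    n = int(round(n_steps)) + 1
    values = tuple(float(v) for v in np.round(lo + step * np.arange(n), 12))
    return GridSpec(values_alpha=values, values_beta=values)


_DEFAULT_GRID = build_grid()


def default_grid() -> GridSpec:
    """The standard 21 x 21 grid from -1 to 1 in steps of 0.1."""
    return _DEFAULT_GRID


@dataclass(frozen=True)
class TargetSpec:
    """A hidden target: its (alpha, beta) pair, feedback condition and task."""

    pair: ActionPair
    condition: str = "positive"
    task: str = "DM"

    def __post_init__(self):
        if self.condition not in _CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class Trajectory:
    """Sampled (x, y) points of a reaching trajectory; y runs 0..depth."""

    points: np.ndarray
    depth: float = REACH_DEPTH_CM


@dataclass(frozen=True)
class ScoreRecord:
    """One scored attempt: raw and pooled points plus the error breakdown."""

    raw_score: int
    condition: str
    pooled_score: int
    error_alpha: float
    error_beta: float
    epsilon: float


# ---------------------------------------------------------------------------
# Target sets

# Experiment-1 Cartesian products.
_MO_A = (-0.8, -0.4, 0.4, 0.8)
_MO_B = (-0.9, -0.6, -0.3, 0.3, 0.6, 0.9)
_DM_A = (-1.0, -0.5, 0.5, 1.0)
_DM_B = (-1.0, -0.6, -0.2, 0.2, 0.6, 1.0)
_NOISE_A = (-0.7, 0.7)
_NOISE_B = (-0.8, -0.4, 0.0, 0.4, 0.8)

# Experiment-2 target lists (12 per task; positive feedback only).
_EXP2_MO = (
    (-0.8, -0.6), (-0.8, -0.3), (-0.8, 0.3),
    (-0.4, -0.6), (-0.4, -0.3), (-0.4, 0.3),
    (0.4, -0.3), (0.4, 0.3), (0.4, 0.6),
    (0.8, -0.3), (0.8, 0.3), (0.8, 0.6),
)
_EXP2_DM_NOISE = (
    (-0.8, -0.6), (-0.8, -0.3), (-0.8, 0.3),
    (-0.4, -0.6), (-0.4, -0.3), (-0.4, 0.3),
    (0.4, -0.6), (0.4, -0.3), (0.4, 0.3),
    (0.8, -0.6), (0.8, -0.3), (0.8, 0.3),
)


def _product(A: Iterable[float], B: Iterable[float]) -> list[ActionPair]:
    return [ActionPair(float(a), float(b)) for a in A for b in B]


_PRESETS = {
    "MO24": ([ActionPair(*p) for p in _product(_MO_A, _MO_B)], "MO"),
    "DM24": ([ActionPair(*p) for p in _product(_DM_A, _DM_B)], "DM"),
    "NOISE10": ([ActionPair(*p) for p in _product(_NOISE_A, _NOISE_B)], "noise-task"),
    "EXP2_MO12": ([ActionPair(*p) for p in _EXP2_MO], "MO"),
    "EXP2_DM12": ([ActionPair(*p) for p in _EXP2_DM_NOISE], "DM"),
}


def target_preset(name: str, conditions: Sequence[str] | None = None,
                  rng: np.random.Generator | None = None) -> list[TargetSpec]:
    """Return one of the named target sets as a list of :class:`TargetSpec`.

    Presets: ``MO24`` and ``DM24`` (Experiment-1 reaching / decision-making
    sets, 4 x 6 Cartesian products), ``NOISE10`` (motor-noise tracing set,
    2 x 5), ``EXP2_MO12`` / ``EXP2_DM12`` (Experiment-2 lists).

    ``conditions`` assigns a feedback condition per target.  If omitted, the
    24-target presets are split half positive / half negative (randomised if
    ``rng`` is given, interleaved otherwise); the Experiment-2 and noise-task
    presets are all positive.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    pairs, task = _PRESETS[name]
    n = len(pairs)
    if conditions is None:
        if name in ("MO24", "DM24"):
            conds = ["positive", "negative"] * (n // 2)
            if rng is not None:
                conds = list(rng.permutation(conds))
        else:
            conds = ["positive"] * n
    else:
        conds = list(conditions)
        if len(conds) != n:
            raise ValueError("conditions length must match the target count")
    return [TargetSpec(pair=p, condition=c, task=task) for p, c in zip(pairs, conds)]


def targets_to_frame(targets: Sequence[TargetSpec]):
    """Serialise a target list to a tidy DataFrame (task, alpha, beta, condition)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "task": [t.task for t in targets],
            "alpha": [t.pair.alpha for t in targets],
            "beta": [t.pair.beta for t in targets],
            "condition": [t.condition for t in targets],
        }
    )


def targets_from_frame(frame) -> list[TargetSpec]:
    return [
        TargetSpec(pair=ActionPair(float(r.alpha), float(r.beta)),
                   condition=str(r.condition), task=str(r.task))
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# Score function

def _round_half_up(x):
    # np.round rounds halves to even; the grid spacing makes exact .5 values
    # common (50*eps is a multiple of 2.5 on-grid), so fix a half-up rule.
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def positive_points(d_alpha, d_beta):
    """Positive-condition points from absolute per-dimension errors.

    Vectorised; returns integers as floats (clamped to [0, 50]).
    """
    eps = 1.0 - (0.5 * np.abs(d_alpha) + 0.5 * np.abs(d_beta))
    return np.maximum(0.0, _round_half_up(50.0 * eps))


def _as_pair(obj) -> ActionPair:
    if isinstance(obj, TargetSpec):
        return obj.pair
    return ActionPair(float(obj[0]), float(obj[1]))


def true_score(target, attempt, condition: str | None = None) -> ScoreRecord:
    """Score an attempt against a target under a feedback condition.

    ``target`` may be a :class:`TargetSpec` (whose condition is used unless
    overridden) or a bare (alpha, beta) pair, in which case ``condition``
    must be supplied (defaulting to positive).
    """
    if condition is None:
        condition = target.condition if isinstance(target, TargetSpec) else "positive"
    if condition not in _CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    tp, ap = _as_pair(target), _as_pair(attempt)
    if not (np.isfinite(ap.alpha) and np.isfinite(ap.beta)):
        raise ValueError("attempt parameters must be finite")
    d_alpha = abs(tp.alpha - ap.alpha)
    d_beta = abs(tp.beta - ap.beta)
    eps = 1.0 - (0.5 * d_alpha + 0.5 * d_beta)
    pooled = int(positive_points(d_alpha, d_beta))
    raw = pooled if condition == "positive" else pooled - 50
    return ScoreRecord(raw_score=raw, condition=condition, pooled_score=pooled,
                       error_alpha=d_alpha, error_beta=d_beta, epsilon=eps)


def pooled_score(raw: int, condition: str) -> int:
    """Map a raw score onto the positive-equivalent [0, 50] scale.

    Positive scores are returned unchanged; negative-condition scores are
    shifted up by 50 (e.g. -40 in the negative condition pools to 10).
    """
    if condition == "positive":
        if not 0 <= raw <= 50:
            raise ValueError("positive-condition score must lie in [0, 50]")
        return int(raw)
    if condition == "negative":
        if not -50 <= raw <= 0:
            raise ValueError("negative-condition score must lie in [-50, 0]")
        return int(raw) + 50
    raise ValueError(f"unknown condition {condition!r}")


def dm_noise_score(target, attempt, noise, rng: np.random.Generator,
                   condition: str | None = None) -> ScoreRecord:
    """Experiment-2 noisy decision-making feedback.

    The clicked pair is perturbed by independent Gaussian draws with the
    participant's measured motor-noise SDs before the error computation, so
    the feedback carries execution-like noise although the click itself
    lands where intended.
    """
    if noise.sigma_dir < 0 or noise.sigma_cur < 0:
        raise ValueError("noise SDs must be non-negative")
    ap = _as_pair(attempt)
    perturbed = ActionPair(
        ap.alpha + rng.normal(0.0, noise.sigma_dir),
        ap.beta + rng.normal(0.0, noise.sigma_cur),
    )
    return true_score(target, perturbed, condition=condition)


def score_table(grid: GridSpec | None = None) -> np.ndarray:
    """Pooled-score lookup table over the grid: entry [s, a] is the
    positive-condition score of clicking cell ``a`` when the target is cell
    ``s`` (alpha-major flat indices).  Negative-condition scores are this
    table minus 50."""
    grid = grid or default_grid()
    va = np.asarray(grid.values_alpha)
    vb = np.asarray(grid.values_beta)
    da = np.abs(va[:, None] - va[None, :])  # (n_alpha, n_alpha)
    db = np.abs(vb[:, None] - vb[None, :])  # (n_beta, n_beta)
    # states (i, j) x actions (k, l): d_alpha[i, k] + d_beta[j, l]
    total = da[:, None, :, None] + db[None, :, None, :]
    pts = np.maximum(0.0, _round_half_up(50.0 * (1.0 - 0.5 * total)))
    return pts.reshape(grid.n_cells, grid.n_cells)


# ---------------------------------------------------------------------------
# Trajectory geometry

def trajectory_points(pair, depth: float = REACH_DEPTH_CM, n: int = 101) -> Trajectory:
    """Sample the trajectory x = alpha*yhat + beta*sin(pi*yhat).

    ``yhat`` is the normalised reach fraction y/depth in [0, 1], so curvature
    produces a single arc over the reach regardless of the physical depth.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n < 3:
        raise ValueError("need at least 3 sample points")
    ap = _as_pair(pair)
    yhat = np.linspace(0.0, 1.0, n)
    x = ap.alpha * yhat + ap.beta * np.sin(np.pi * yhat)
    return Trajectory(points=np.column_stack([x, yhat * depth]), depth=float(depth))


def fit_trajectory(traj: Trajectory) -> ActionPair:
    """Least-squares (alpha, beta) estimate of a recorded trajectory.

    The trajectory model is linear in its parameters given the normalised
    depth fraction, so this is an ordinary linear regression on the basis
    {yhat, sin(pi*yhat)}.
    """
    pts = np.asarray(traj.points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(y) <= 0:
        raise ValueError("degenerate trajectory: y values do not vary")
    yhat = y / traj.depth
    X = np.column_stack([yhat, np.sin(np.pi * yhat)])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("degenerate design: basis functions are collinear")
    coef, *_ = np.linalg.lstsq(X, x, rcond=None)
    return ActionPair(float(coef[0]), float(coef[1]))
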