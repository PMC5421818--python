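"""Synthetic participant cohorts.

A synthetic participant is the QMDP agent itself with participant-specific
parameters: a likelihood uncertainty Gamma drawn around the empirical cohort
mean (8.63, SD 2.46, truncated to the 1..15 fitting range) and motor-noise
SDs drawn around the tracing-task means (direction 0.10 +/- 0.05, curvature
0.12 +/- 0.04, truncated at zero).  Each participant contributes one
decision-making episode per DM target (no execution noise), one reaching
episode per MO target (with their noise), and a 10-target x 5-trace tracing
session whose fitted parameters scatter around the displayed targets with
their noise SDs.  This is the strongest available stand-in for human data
because the scientific claim under test is precisely that the model
generates the behaviour; idiosyncrasies such as curvature non-explorers are
not injected unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .agent import (
    AgentParams,
    MotorNoiseProfile,
    ScoreModel,
    optimize_tau0,
    run_experiment,
)
from .behavior import learning_curve, motor_noise_estimate
from .task import target_preset

__all__ = [
    "COHORT_GAMMA",
    "COHORT_SIGMA_DIR",
    "COHORT_SIGMA_CUR",
    "ParticipantSpec",
    "ParticipantSession",
    "generate_participant",
    "generate_cohort",
    "generate_noise_task_traces",
    "generate_exp2_session",
    "fit_cohort",
]

#: Cohort moments (mean, SD) that the generator emulates by default.
COHORT_GAMMA = (8.63, 2.46)
COHORT_SIGMA_DIR = (0.10, 0.05)
COHORT_SIGMA_CUR = (0.12, 0.04)

GAMMA_RANGE = (1.0, 15.0)


@dataclass(frozen=True)
class ParticipantSpec:
    """Generating parameters of one synthetic participant."""

    id: str
    gamma_true: float
    sigma_dir_true: float
    sigma_cur_true: float
    tau0: int | None = None
    seed: int = 0
    non_explorer: bool = False

    def __post_init__(self):
        if self.gamma_true <= 0:
            raise ValueError("gamma_true must be positive")
        if self.sigma_dir_true < 0 or self.sigma_cur_true < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def noise(self) -> MotorNoiseProfile:
        return MotorNoiseProfile(self.sigma_dir_true, self.sigma_cur_true)


@dataclass
class ParticipantSession:
    """One participant's data: DM/MO episodes, tracing traces, fit slots."""

    spec: ParticipantSpec
    dm_episodes: list = field(default_factory=list)
    mo_episodes: list = field(default_factory=list)
    noise_traces: pd.DataFrame | None = None
    exp2_mo_episodes: list | None = None
    exp2_dm_episodes: list | None = None
    tau0: int | None = None
    gamma_hat: float | None = None
    noise_hat: MotorNoiseProfile | None = None

    @property
    def dm_curve(self) -> np.ndarray:
        return learning_curve(self.dm_episodes)

    @property
    def mo_curve(self) -> np.ndarray:
        return learning_curve(self.mo_episodes)


def _resolve_tau0(spec: ParticipantSpec, library, model, rng) -> int:
    if spec.tau0 is not None:
        return int(spec.tau0)
    if library is not None:
        nearest = min(library.gamma_grid, key=lambda g: abs(g - spec.gamma_true))
        return library.tau0(nearest)
    return optimize_tau0(spec.gamma_true, target_preset("DM24"), rng=rng, model=model)


def generate_noise_task_traces(noise: MotorNoiseProfile,
                               rng: np.random.Generator,
                               n_traces: int = 5) -> pd.DataFrame:
    """Tracing-task table: 10 displayed targets x ``n_traces`` fitted pairs.

    Fitted trace parameters equal the displayed target parameters plus
    independent Gaussian execution error per dimension, giving the standard
    50 errors per dimension at the default design.
    """
    targets = target_preset("NOISE10")
    rows = []
    for tgt in targets:
        for k in range(n_traces):
            rows.append({
                "target_alpha": tgt.pair.alpha,
                "target_beta": tgt.pair.beta,
                "trace_idx": k + 1,
                "alpha_hat": tgt.pair.alpha + rng.normal(0.0, noise.sigma_dir),
                "beta_hat": tgt.pair.beta + rng.normal(0.0, noise.sigma_cur),
            })
    return pd.DataFrame(rows)


def _non_explorer_mask(model: ScoreModel, limit: float = 0.1) -> np.ndarray:
    pairs = model.pairs
    return np.abs(pairs[:, 1]) <= limit + 1e-9


def generate_participant(spec: ParticipantSpec,
                         model: ScoreModel | None = None,
                         library=None,
                         with_exp2: bool = False) -> ParticipantSession:
    """Simulate one participant's full Experiment-1 session.

    DM episodes run without execution noise; MO episodes carry the spec's
    noise; 24 targets per task are split 12/12 between positive and negative
    feedback (randomised per participant).  The softmax constant tau0 comes
    from the spec, from the library entry at the nearest grid Gamma, or from
    a fresh optimisation, in that order of preference.  A ``non_explorer``
    participant has reaching actions restricted to near-zero curvature,
    mimicking participants who never explored that dimension.
    """
    model = model or ScoreModel()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31)]))
    tau0 = _resolve_tau0(spec, library, model, rng)
    params = AgentParams(gamma=spec.gamma_true, tau0=tau0)

    dm_targets = target_preset("DM24", rng=rng)
    mo_targets = target_preset("MO24", rng=rng)
    dm = run_experiment(dm_targets, params, n_runs=1, rng=rng, model=model)
    action_mask = _non_explorer_mask(model) if spec.non_explorer else None
    mo = run_experiment(mo_targets, params, spec.noise, n_runs=1, rng=rng,
                        model=model, action_mask=action_mask)
    traces = generate_noise_task_traces(spec.noise, rng)
    session = ParticipantSession(spec=spec, dm_episodes=dm.episodes(),
                                 mo_episodes=mo.episodes(),
                                 noise_traces=traces, tau0=tau0)
    if with_exp2:
        exp2 = generate_exp2_session(spec, model=model, library=library, rng=rng,
                                     tau0=tau0)
        session.exp2_mo_episodes = exp2.exp2_mo_episodes
        session.exp2_dm_episodes = exp2.exp2_dm_episodes
    return session


def generate_exp2_session(spec: ParticipantSpec,
                          model: ScoreModel | None = None,
                          library=None,
                          rng: np.random.Generator | None = None,
                          tau0: int | None = None) -> ParticipantSession:
    """Experiment-2 session: 12 MO targets plus 12 noisy-feedback DM targets.

    Both target lists are the printed Experiment-2 sets, positive feedback
    only.  The noisy-feedback DM task perturbs only the scored pair (clicks
    land where intended); the reaching task perturbs the executed action.
    """
    model = model or ScoreModel()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), 2]))
    if tau0 is None:
        tau0 = _resolve_tau0(spec, library, model, rng)
    params = AgentParams(gamma=spec.gamma_true, tau0=tau0)
    mo = run_experiment(target_preset("EXP2_MO12"), params, spec.noise,
                        n_runs=1, rng=rng, model=model)
    dmn = run_experiment(target_preset("EXP2_DM12"), params, spec.noise,
                         n_runs=1, rng=rng, model=model, noise_mode="feedback")
    return ParticipantSession(spec=spec, exp2_mo_episodes=mo.episodes(),
                              exp2_dm_episodes=dmn.episodes(), tau0=tau0,
                              noise_traces=generate_noise_task_traces(spec.noise, rng))


def generate_cohort(n: int = 24,
                    gamma_mean: float = COHORT_GAMMA[0],
                    gamma_sd: float = COHORT_GAMMA[1],
                    sigma_dir_mean: float = COHORT_SIGMA_DIR[0],
                    sigma_dir_sd: float = COHORT_SIGMA_DIR[1],
                    sigma_cur_mean: float = COHORT_SIGMA_CUR[0],
                    sigma_cur_sd: float = COHORT_SIGMA_CUR[1],
                    seed: int = 0,
                    noise_correlation: float = 0.0,
                    model: ScoreModel | None = None,
                    library=None,
                    tau0: int | None = None) -> list:
    """Generate ``n`` synthetic participants with dispersed parameters.

    Gamma is drawn from a normal truncated to the 1..15 fitting range; the
    noise SDs from normals truncated at zero, optionally correlated within
    participants via ``noise_correlation``.  Everything is deterministic
    given ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    for sd in (gamma_sd, sigma_dir_sd, sigma_cur_sd):
        if sd < 0:
            raise ValueError("SDs must be non-negative")
    if not -1.0 <= noise_correlation <= 1.0:
        raise ValueError("noise_correlation must lie in [-1, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 99]))
    gammas = _truncated_normal(rng, n, gamma_mean, gamma_sd, *GAMMA_RANGE)
    z1 = rng.standard_normal(n)
    z2 = noise_correlation * z1 + np.sqrt(1 - noise_correlation**2) * rng.standard_normal(n)
    s_dir = _clip_positive_normal(sigma_dir_mean, sigma_dir_sd, z1)
    s_cur = _clip_positive_normal(sigma_cur_mean, sigma_cur_sd, z2)
    sessions = []
    for i in range(n):
        spec = ParticipantSpec(
            id=f"S{i + 1:02d}",
            gamma_true=float(gammas[i]),
            sigma_dir_true=float(s_dir[i]),
            sigma_cur_true=float(s_cur[i]),
            tau0=tau0,
            seed=int(rng.integers(0, 2**31 - 1)))
        sessions.append(generate_participant(spec, model=model, library=library))
    return sessions


def _truncated_normal(rng, n, mean, sd, lo, hi):
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _clip_positive_normal(mean, sd, z):
    # one-sided truncation at zero via rejection-free folding of the
    # standard draws: resample magnitudes below zero to their reflection
    vals = mean + sd * z
    return np.abs(vals)


def fit_cohort(cohort: Sequence[ParticipantSession], library) -> list:
    """Fill each session's fitted Gamma and estimated noise in place.

    Gamma comes from the DM learning-curve grid search against the shared
    curve library; the noise estimate from the tracing traces.  Returns the
    cohort for chaining.
    """
    from .fitting import fit_gamma

    for s in cohort:
        fit = fit_gamma(s.dm_curve, library=library)
        s.gamma_hat = fit.gamma_hat
        s.noise_hat = motor_noise_estimate(s.noise_traces).profile
    return list(cohort)
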