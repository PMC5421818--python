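# Methods

This note documents the model, the numerical choices behind the simulator,
what the synthetic-data generator does and does not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Task model

Both tasks share one structure. The parameter space is a square grid from
−1 to 1 in steps of 0.1 per dimension (21 values, 441 cells); a hidden
target is one cell, an attempt is one cell (decision-making) or one drawn
trajectory whose direction/curvature pair is estimated by linear least
squares on the basis {ŷ, sin(πŷ)} (reaching, with ŷ the normalised reach
fraction). The score of an attempt with absolute errors (Δα, Δβ) is

    ε = 1 − (0.5·Δα + 0.5·Δβ),    S⁺ = max(0, round(50·ε)),

with the negative feedback condition reporting S⁺ − 50. Analyses pool the
two conditions by mapping negative scores back to the 0–50 scale; because
the negative condition is a constant shift, the agent's posterior and
policy are identical in the two conditions, and the simulator works on the
pooled scale internally while recording condition-correct raw scores.

Rounding convention: `round` is half-up (`floor(x + 0.5)`). On-grid values
of 50·ε are exact multiples of 2.5, so ties at .5 are common and a fixed
convention matters; banker's rounding would map 42.5 → 42 but 47.5 → 48.

Target sets are the printed Cartesian products: reaching
{−0.8, −0.4, 0.4, 0.8} × {−0.9, −0.6, −0.3, 0.3, 0.6, 0.9} (24),
decision-making {−1, −0.5, 0.5, 1} × {−1, −0.6, −0.2, 0.2, 0.6, 1} (24),
tracing task {−0.7, 0.7} × {−0.8, −0.4, 0, 0.4, 0.8} (10), plus the two
12-target lists of the noisy-feedback experiment. The movement-duration
validity window (700–1500 ms) of the original apparatus is recorded as a
constant but not simulated; synthetic attempts are always valid.

## Agent

The agent maintains a belief b(s) over the 441 candidate targets, starting
uniform. After an attempt with planned action a and observed score o, the
posterior is b(s) ∝ b(s)·N(o; trueScore(s, a), Γ) — the state transition is
the identity, and Γ (points) is the likelihood uncertainty, the single free
parameter. The belief update conditions on the *planned* action: in the
reaching task the executed trajectory is not visually available, so the
agent cannot condition on it; the execution discrepancy surfaces only
through the observed score.

Action values are QMDP: with a static state, the post-attempt continuation
value is action-independent, so Q(b, a) = Σ_s b(s)·r(s, a) with
r(s, a) = trueScore(s, a) + N(0, Γ) (decision-making) or
trueScore(s, a + δ) + N(0, Γ) with δ ~ N(0, diag(σ_dir², σ_cur²))
(reaching). Action selection is softmax, p(a) ∝ exp(τ·Q(b, a)), with
τ = τ₀/t over attempts t = 1..25. τ₀ is an integer in 1..15 chosen per Γ to
maximise the model's mean points across attempts (ties to the smaller τ₀);
it is optimised against model reward, never fitted to behavioural data.
Episodes terminate early when the executed attempt scores the maximum;
learning curves pad subsequent attempts with the maximal score, matching
how participants' curves plateau after a find.

### Reward-noise realisation

The sampled reward noise enters Q(b, a) only through its belief-weighted
sum, which for the N(0, Γ) term is exactly N(0, Γ·‖b‖₂) independently per
action; the simulator draws that aggregate directly rather than 441² fresh
values per attempt. The motor-noise term trueScore(s, a + δ) is aggregated
the same way from its exact per-(state, action) mean and variance,
precomputed per noise profile by Gauss–Hermite quadrature (64 nodes per
dimension, cached; the integrand depends only on the absolute coordinate
differences, so only 441 distinct pairs are evaluated). The aggregate is
realised as a Gaussian with the exact mean and variance: this is exact for
the Γ term, and an excellent approximation for the motor term while the
belief is spread (sum of many independent bounded terms); when the belief
concentrates on few states the true aggregate is a pushforward of δ through
the piecewise-linear score rather than Gaussian, a shape difference with no
visible effect on action ranking. The literal per-draw form is kept as
`agent.q_values(mode="sampled")` and the two are verified to agree in mean
and SD in the tests. An `expected` mode (noise-free rewards) is available
on `AgentParams`.

### Numerical choices

- Beliefs in the episode simulator are float32 log-masses, max-shifted each
  attempt and floored at −40 (≈4·10⁻¹⁸ relative mass) — the floor exists
  because subnormal float32 beliefs slow the downstream matrix products by
  ~5×. Belief sums hold to ~10⁻⁶ in the simulator; the float64 public
  functions `update_belief`/`q_values` hold to 10⁻¹² and match an
  independent explicit-loop implementation to 10⁻¹⁰.
- Softmax sampling uses the Gumbel-max trick (shift-invariant, so no
  overflow at τ·Q up to 750); the scalar `softmax_select` computes
  probabilities explicitly with max-subtraction.
- All randomness flows from `numpy.random.Generator` objects; every
  experiment, library entry and synthetic participant is seeded, and seeded
  runs are bit-reproducible.
- Executed actions are continuous: never snapped to the grid, never clipped
  to [−1, 1]; the clamped score function handles any real pair.

## Fitting and prediction

Γ is fitted per participant by grid search over the integers 1..15: for
each candidate, the decision-making experiment (24 targets × 100 runs at
the candidate's optimised τ₀) yields a mean model curve, and the candidate
maximising R² = 1 − SS_res/SS_tot against the participant's 25-point mean
curve wins (ties to the smaller Γ). Simulated curves are cached per
(Γ, τ₀) in a `DMCurveLibrary` keyed by a base seed, so one library serves a
whole cohort deterministically. Zero-variance data curves take R² = 1 when
reproduced exactly and 0 otherwise (documented convention).

Reaching curves are predicted, not fitted: the reaching experiment is
simulated with the DM-fitted Γ, the tracing-task noise estimate
(sample SD, ddof = 1, of the 50 signed per-dimension errors), and the τ₀
the DM model would use at that Γ. The alternative-model comparison swaps in
group-mean noise (alternative 1) or group-mean Γ (alternative 2) and scores
each variant by the MSE between predicted and observed reaching curves.

Learning curves are summarised by y = a·e^(−b·x) + c, fitted by bounded
nonlinear least squares (b ∈ [0, 10]) from multiple starts (a = first −
last, c = last, b ∈ {0.05, 0.2, 0.5, 1}); the best-R² solution is returned
and non-convergence of all starts raises rather than returning silently.

## Behavioural analyses

Action change is the Euclidean distance between successive (α, β) pairs;
post-termination attempts (no action taken) are excluded from change
statistics. The gain/loss analysis uses the running maximum pooled score up
to attempt t−1 as the reference point: the score at t is a gain if it
strictly exceeds the reference, a loss otherwise (ties are losses); attempt
1 has no reference and is unlabelled. Error curves report mean |Δα| and
|Δβ| per attempt against the episode's target (zero after termination).
Curvature non-explorers are flagged by narrow quartile fences
q3 + 0.15·(q3 − q1) / q1 − 0.15·(q3 − q1), quartiles by linear
interpolation (the convention is stated because it is not standardised).
Score-binning for the change-by-score analysis is reported both per integer
score and in decile bins, since the original binning is not specified.

## Synthetic cohorts

A synthetic participant is the model itself with dispersed parameters:
Γ ~ N(8.63, 2.46²) truncated to [1, 15] (the fitting grid's support, so
recovery is well-posed), σ_dir ~ N(0.10, 0.05²) and σ_cur ~ N(0.12, 0.04²)
folded at zero, independently by default with an optional within-participant
correlation knob. Each participant contributes one episode per target
(24 DM without execution noise, 24 MO with their noise, 12/12 positive/
negative), and a 10 × 5 tracing table whose fitted pairs scatter around the
displayed targets with their σ. A `non_explorer` option restricts reaching
actions to |β| ≤ 0.1 to exercise the outlier filter.

What passing tests on these cohorts do show: the full pipeline — generate,
fit Γ from DM curves, estimate noise from traces, predict MO — is
self-consistent, recovers parameters at grid resolution, and reproduces the
qualitative signatures (Γ-monotone learning speed, lower reaching plateau,
larger action changes after losses, individual parameters beating group
averages). What they do not show: anything about human idiosyncrasies the
generator omits — reaction times, kinematic detail beyond (α, β),
non-stationary strategies, or the curvature non-explorers that arise
spontaneously in real cohorts.

## Problem sizes

Default experiment size is the study design: 24 targets × 100 runs × 25
attempts; the Γ library simulates 15 × 15 such experiments once per seed
(about two minutes on one core thanks to the batched simulator). Synthetic
cohorts used in the end-to-end checks have 4–8 participants.

## Known limitations

- The QMDP policy carries no information-gain term: with a very sharp
  likelihood (Γ → 0) the agent can spend a few attempts probing
  high-expected-score cells that do not disambiguate tied candidates before
  the softmax breaks the tie. Consequently even the Γ = 0.1 agent needs a
  median of ~6 attempts, and the Γ = 1 agent first achieves the maximal
  score at a mean attempt of ~5.4 while its mean curve saturates visually
  around attempt 7.
- The motor-noise aggregation in Q is Gaussian-matched in mean and variance
  rather than per-draw exact (see above); the belief update itself is exact.
- The likelihood treats scores as continuous observations; a
  discretised-over-integers variant would differ negligibly at Γ ≥ 1 and is
  not implemented.
- Human data ingestion expects the package's session CSV dialect; raw
  kinematic files must be converted by the user (only `fit_trajectory` is
  provided for trajectory-to-parameter reduction).
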