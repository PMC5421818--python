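# explearn

Explorative motor learning as belief-state decision making.

`explearn` simulates and analyses a pair of hidden-target search tasks used
to study reward-based motor learning. In the **decision-making (DM)** task
an agent clicks cells on a 21 × 21 grid to find a hidden target cell; in the
**reaching (MO)** task the agent draws trajectories
x = α·ŷ + β·sin(πŷ) whose direction (α) and curvature (β) live on the
same grid, but execution is corrupted by motor noise. Each attempt earns a
score from the shared proximity rule

    ε = 1 − (0.5·|Δα| + 0.5·|Δβ|),   S = max(0, round(50·ε))

(0–50 points in the positive feedback condition; −50–0, shifted by −50, in
the negative condition). An episode is one target search of up to 25
attempts, ending early when the maximum score is reached.

The package is written for computational-neuroscience researchers who want
to (re)use the model, generate synthetic cohorts, or run the behavioural
analyses on their own session data.

## The model

The search is a POMDP: the hidden state s is the target cell (441
candidates, identity transition within an episode), actions a are grid
cells, and the observation is the feedback score. The agent's observation
model is Gaussian around the true score,

    p(o | s, a) = N(trueScore(s, a), Γ),

where the likelihood uncertainty **Γ** (in points) is the *only free
parameter*, capturing how precisely a participant can relate scores to
target positions. Beliefs b(s) update by Bayes' rule; action values use the
QMDP approximation

    Q(b, a) = Σ_s b(s) · r(s, a),    r(s, a) = trueScore(s, a) + N(0, Γ),

with the reaching model additionally perturbing the action inside r by the
participant's measured motor noise (σ_dir, σ_cur). Actions are sampled
softmax-wise with p(a) ∝ exp(τ·Q(b, a)) and a decaying gain τ = τ₀/t; τ₀ is
chosen per Γ by maximising the model's own mean points on an integer grid
1..15 (never fitted to behaviour).

The scientific logic the package reproduces end to end: fit Γ per
participant from DM learning curves alone, measure (σ_dir, σ_cur) in an
independent 10-target × 5-trace tracing task, then **predict** reaching
learning curves with no parameter fitted to reaching data — and show that
individual parameters predict better than group averages.

## Worked example

```python
import numpy as np
import explearn as ex

model = ex.ScoreModel()                      # 441x441 score tables
lib = ex.DMCurveLibrary(seed=11, model=model)  # cached model curves per Gamma

# a synthetic participant: Gamma = 6, motor noise (0.10, 0.12)
spec = ex.ParticipantSpec(id="P1", gamma_true=6.0, sigma_dir_true=0.10,
                          sigma_cur_true=0.12, seed=42)
session = ex.generate_participant(spec, model=model, library=lib)

fit = ex.fit_gamma(session.dm_curve, library=lib)
est = ex.motor_noise_estimate(session.noise_traces)
pred = ex.predict_mo(fit.gamma_hat, est.profile, n_runs=100,
                     rng=np.random.default_rng(0), library=lib, model=model)

print(f"gamma_hat = {fit.gamma_hat:g}  (R2 vs DM curve: {fit.r_squared:.3f})")
print(f"noise_hat = ({est.profile.sigma_dir:.3f}, {est.profile.sigma_cur:.3f})")
print(f"MO prediction R2: {ex.curve_r2(pred, session.mo_curve):.3f}")
```

prints (exact values depend on the seeds):

```
gamma_hat = 6  (R2 vs DM curve: 0.996)
noise_hat = (0.093, 0.109)
MO prediction R2: 0.957
```

i.e. the likelihood uncertainty is recovered from decision-making behaviour
alone, the tracing task recovers the injected motor noise to sampling
precision, and the transferred parameters predict most of the variance in
the reaching learning curve.

A thin CLI wraps the same functions:

```bash
explearn simulate --task DM --gamma 8 --n-runs 100 --seed 1 --out runs/dm
explearn recover --seed 1          # parameter-recovery pass/fail table
explearn fixtures --n 3 --seed 0 --out fixtures/
```

## Layout

- `explearn.task` — grids, target sets, score function, trajectory geometry
- `explearn.agent` — belief updates, QMDP values, softmax policy, episode
  and experiment simulators
- `explearn.fitting` — exponential curve summaries, Γ grid search, MO
  prediction, alternative-model comparison
- `explearn.behavior` — action change, error/variance curves, motor-noise
  estimation, outlier fences, gain/loss reference-point analysis
- `explearn.cohort` — synthetic participants and cohorts, tracing-task
  traces, the noisy-feedback (Experiment-2) variant
- `explearn.io` / `explearn.cli` — session CSV/JSON formats and the
  command-line surface

See `docs/methods.md` for the model's assumptions, numerical choices and
known limitations.
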