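# Methods

## Model

### State, features and value

Spatial environments are uniform square-grid discretizations of a
continuous allocentric plane (cell size 1 length unit; origin at the arena
center).  The agent occupies cell centers, carries a heading (the last
movement direction), and moves to the adjacent cell in one of 8 compass
directions (4 in corridor mazes); moves into a boundary leave the position
unchanged but still turn the heading.  A trial ends on entering the
circular goal region (reward drawn Bernoulli with the goal's reward
probability) or at a step cap (default 1000; 500 in the blocking protocol,
200 on the linear track and plus maze).  Nonspatial tasks are discrete
graphs whose terminal outcome probabilities follow a Gaussian random walk
(SD 0.025) clipped to [0.25, 0.75] after every trial.

Two feature populations observe the state:

* **Landmark cells (LCs)** — egocentric input to the striatal system.  A
  cell tuned to landmark identity ℓ, preferred distance d\* and egocentric
  bearing θ\* fires `exp(−½[(d−d*)²/σ_d² + wrap(θ−θ*)²/σ_θ²])` (peak rate
  normalized to 1; the proportionality constant of the underlying Gaussian
  response is not empirically constrained).  The default bank is a polar
  grid of 4 preferred distances × 8 bearings per identity; absent
  landmarks silence their cells.  Within half a cell of a landmark its
  bearing is undefined, so the angular factor is dropped there (the
  landmark is "underfoot" and visible in every direction); this keeps the
  population exactly egocentric, which the plus-maze response strategy
  depends on.  Distance tuning width is constant (σ_d = 2.5 by default);
  whether it should grow with distance, as for BVCs, is not constrained.

* **Boundary-vector cells (BVCs) and place cells** — allocentric input to
  the hippocampal system.  A BVC tuned to allocentric direction φ\* and
  distance d\* integrates a radial × angular Gaussian over all boundary
  segments, each wall element weighted by its subtended angle (dl/r), so
  the cell is additive over segments and responds more to nearer wall
  sections.  Radial width grows with preferred distance,
  σ_rad = σ₀(1 + d\*/β) with σ₀ = 0.5, β = 8; angular width 0.35 rad.
  Place cells are thresholded-linear sums of BVC inputs.  Banks are built
  by tiling candidate field centers (spacing 2 cells): *conjunctive* banks
  attach one BVC per wall to each center (compact fields in enclosed
  boxes); *per-wall* banks make one cell per (center, wall) pair whose
  BVCs are all tuned to that wall (nearest point plus distinct endpoints),
  so every cell lives and dies with its own boundary — the configuration
  used for open arenas with isolated walls.  Thresholds are set per cell
  to half that cell's peak drive under the full wall configuration, and
  population rates are scaled once at construction to unit mean squared
  norm, keeping TD step sizes comparable across bank layouts.

The **striatal learner** reads action values linearly from its features
and updates by Q-learning with eligibility traces:

    δ_r = r + γ max_a′ Q(s′, a′) − Q(s, a)         (0 bootstrap at terminals)
    e ← λ e;  e[:, a] += f                         (executed action only)
    Δw = α_Q δ_r e / max(1, ‖f‖²)

The step-size floor stabilizes learning when the sensory population grows
(e.g. a second landmark's cells appearing mid-experiment) and is a no-op
for one-hot features.  In spatial tasks striatal actions are egocentric
(rotations relative to heading) and are rotated into the shared
allocentric frame before mixing; in graph tasks they are the task's
buttons.  Traces reset between trials.

The **hippocampal learner** comes in two interchangeable forms.  The
tabular SR updates row s of `M` on every transition by the successor
prediction error `δ_M(s′) = 𝟙[s = s′] + γ M(s′′, s′) − M(s, s′)` and the
reward vector by a delta rule `R(s′′) ← R(s′′) + α_R (r − R(s′′))`; value
is `V = M·R` and action values use one-step lookahead through the known
movement model, `Q(s, a) = R(s) + γ E[V(s′)]`.  At a terminal successor
the bootstrap is the one-hot of the terminal state: a terminal state is
occupied once and predicts nothing further.  (Zeroing the bootstrap
instead would erase `M(s, terminal)` and make value blind to terminal
outcome states — the two-step task would have no learnable root values and
platform entry would be unlearnable.)  The successor-feature (SF) form
replaces states by feature vectors: `ψ(s) = Wᵀf(s)`, `V = ψᵀu`, with the
linear-TD rule `δ = f + γψ(s′) − ψ(s)`, `W += α_M outer(z, δ)/max(1, ‖z‖²)`
where `z = γλ_SF z + f` is an optional eligibility trace over features
(λ_SF = 0 recovers the plain one-step rule and, under one-hot features,
exactly the tabular update — a tested identity).  The feature-reward
weights u follow a normalized delta rule and are constrained nonnegative:
in appetitive-only tasks reward expectations cannot go negative (the
tabular R never does), and unconstrained LMS acquires compensatory
negative weights along unrewarded stretches that surface as spurious
repulsive value when co-active features are later removed.

For spatial protocols preceded by free exploration the SR is initialized
at the random-walk closed form `M = (I − γT)⁻¹`; task graphs start at the
identity (each state predicts only itself).

The **arbitrator** tracks each system's reliability from a running average
of absolute prediction errors (Ω, learning rate η; reward-prediction
errors for the striatal system, successor prediction errors for the SR
system) with δ_max = 1, and evolves the SR influence by

    α = A_α / (1 + exp(B_α χ_MF)),  β = A_β / (1 + exp(B_β χ_SR))
    P_SR ← P_SR + dt [α (1 − P_SR) − β P_SR],  dt = 1 per environment step,

clamped to a lesion interval: a hippocampal lesion of severity s lowers
the upper clamp to 1 − s, a striatal lesion raises the lower clamp to s.
The SPE scalar fed to Ω_SR is the max-norm of `(1 − γ)·δ_M` — the error on
the *normalized* occupancy distribution — because raw SR entries scale as
1/(1 − γ) and would saturate the clip at δ_max, pinning χ_SR at 0.
Defaults A_α = A_β = 1, B_α = 10, B_β = 6: both rates are steep in their
own reliability, with the MF→SR rate much steeper, so the crossover sits
near χ_MF ≈ 0.6 and, when both systems are reliable, influence drains to
the computationally cheaper striatal system.  Ω_MF starts at δ_max
(maximal ignorance before any reward learning) and Ω_SR at 0.1 (the prior
SR's mismatch at episode start is small); η sets the window over which
that initial ignorance decays and is a per-protocol timescale (below).
Actions are drawn from a softmax over `Q_net` with inverse temperature
β_softmax; both learners and both reliability trackers update on every
step regardless of which system dominated the choice.

## Protocols and parameters

Shared defaults: γ = 0.95, α_M = 0.1, α_R = 0.3, λ = 0.9, δ_max = 1,
softmax β = 30 (spatial) / 5 (graph).  Protocol-specific settings, chosen
so each protocol's arbitration dynamics play out over its own step budget:

| protocol | η | α_Q | other |
|---|---|---|---|
| linear track (5 states, p = 0.8, 30 trials) | 0.01 | 0.1 | one-hot features, β = 5 |
| moving-platform water maze (20×20, 11 sessions × 4 trials) | 2·10⁻⁴ | 0.3 | platform radius 1.2, landmark offset (0, 2) |
| plus maze (arm length 3, 16 days × 6 trials, probes day 8/16) | 0.003 | 0.25 | 4 actions, center landmark, lesion severity 0.9 |
| blocking (3 × 10 trials, cap 500) | — (P_SR pinned) | 0.1 | landmark arm: striatal control, β = 50; boundary arm: SF control, α_M = 0.1, λ_SF = 0.9, α_R = 0.6 |
| two-step (common transition 0.7, 300 trials) | 0.01 | 0.3 | identity SR, α_M = 0.3, α_R = 0.6 |

Water-maze platform locations are a deterministic golden-angle scatter
(alternating radii 3 and 5.5) standing in for the original study's
graphically specified location set; the landmark sits at a constant offset
from the platform in every session.  Blocking geometry: platform at
(2, 1), radius 1.5; landmarks at platform + (3, 0) and (−2, 2); boundary
walls are vertical segments at x = ±6 spanning |y| ≤ 5.  In the landmark
arm there are no boundaries, so place-cell input is absent and behavior is
carried by the striatal system (P_SR pinned 0); in the boundary arm there
are no landmarks and behavior is carried by the SF system (P_SR pinned 1).
Start positions alternate round-robin over the two midline starts, as
behavioral protocols counterbalance them.  Plus-maze probes classify each
agent by which absorbing arm end is reached (trained goal arm = place,
same egocentric turn = response; timeouts are excluded), and devaluation
scales the hippocampal reward representation by 0 for the probe while
striatal weights are untouched.

The two-step task uses common-transition probability 0.7.  (The source
figure caption for this task transposes the labels, reading "rare (70%) or
common (30%)"; the standard task and the accompanying text make 0.7 the
common probability, which is what is implemented.)

### Correlation study

Twenty intact and twenty partially hippocampus-lesioned agents (upper
P_SR clamp 0.1) each run the two-step task (500 trials) and the full
water-maze schedule.  Heterogeneity in the hippocampal–striatal tradeoff
is sampled as the log ratio x = ln(A_α/A_β) ~ U(−5, 5) (amplitudes capped
at 1) plus softmax β ~ U(8, 12): the equilibrium P_SR = α/(α + β) is
strictly increasing in x in *every* task, so one draw yields
task-consistent reliance from striatally to hippocampally dominated
agents.  Sampling the steepnesses B_α, B_β instead does not preserve the
cross-task ordering, because each task's error statistics place the
reliabilities at different operating points.  The per-agent model-based
index is the reward × transition interaction from a logistic regression of
stay on previous reward, previous transition type and their product (±1
coding; agents with degenerate fits are excluded); a pooled fixed-effects
variant is available (`pooled_mb_index`).  The place-memory score is the
mean distance from the previous platform center to the argmax of the
agent's net value map at the next session start (ties broken toward the
arena centroid); memory *strength* is its negative.  Associations are
reported as Fisher's z = atanh(r) with p from z·√(n−3), and the arms are
compared by the Fisher r-to-z difference test (cross-checked against a
label-permutation oracle in the test suite).  The water-maze arm of this
study uses η = 10⁻³, α_R = 0.5 and β_softmax = 50 so that every agent's
arbitration reaches its equilibrium within the protocol and the value-map
argmax is estimated from a well-performing trajectory.

## What the simulations do and do not show

The environments are deliberately minimal: grid worlds with deterministic
movement, a handful of landmarks, straight walls, and Bernoulli rewards.
They reproduce the *mechanistic signatures* of the dual-system account —
which system controls behavior when, what each lesion removes, how
prediction-error-gated learning produces blocking and how successor
learning evades it — not quantitative fits to animal trajectories.
Latencies are step counts, not seconds; "lesions" are clamps on the
arbitration variable, not circuit manipulations; swimming dynamics,
vision, and motor noise are absent.  Passing tests therefore certify the
model logic and its qualitative behavioral predictions, not agreement
with any particular animal's data.

Two statistics deserve a variance warning.  With 20 agents per arm, a
sample correlation of independent noise has SD ≈ 1/√17 ≈ 0.24, so the
lesioned arm's near-zero association is reproducible in sign and
significance but not in its third decimal.  The intact arm's association
depends on how much per-agent estimation noise (logistic-fit error in the
MB index, argmax jitter in the memory score) dilutes the shared reliance
factor; this implementation typically lands around z ≈ 0.5–1.1 with a
clearly significant between-arm difference.

## Numerical choices and degenerate inputs

Angles are radians wrapped to [−π, π); egocentric 0 is straight ahead,
positive counterclockwise.  Boundary integrals discretize segments at one
cell of arc length.  Ties in softmax action selection are broken uniformly
at random (exact argmax in the zero-temperature limit); flat value maps in
the memory score fall back to the centroid tie-break; transition-matrix
rows are validated to sum to 1 within 1e−12; the reward-probability random
walk clips at its bounds.  Step-cap exhaustion is flagged on the trial
record, never raised.  All randomness flows through a single
`numpy.random.Generator` per agent, so identical configuration + seed
reproduces trial records exactly (tested).

## Known limitations

* The SR is learned on-policy with TD only: transition revaluation,
  replay-based updates and default-representation corrections are out of
  scope.
* Arbitration parameters are declared defaults, not fits to behavioral
  data; the reliability timescale η must be chosen per protocol because
  the running-average window is tied to environment steps.
* The per-wall place-cell construction is a purpose-built reduction of
  boundary-vector models: fields are band-like along long walls and only
  endpoint tunings localize them; enclosed-box banks behave more like
  classical place fields.
* Graph tasks share the spatial agent's machinery but use one-hot
  features; generalization across second-stage states is therefore purely
  through the SR, not through feature overlap.
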