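# dualsys

A reinforcement-learning model of how the brain trades off two decision
systems during spatial and nonspatial behavior:

* a **hippocampal** system that learns a *successor representation* (SR) —
  a predictive map `M(s, s′)` of discounted future state occupancy over
  allocentric place-cell features — and computes value as `V = M·R` from a
  separately learned reward vector;
* a **dorsolateral-striatal** system that learns action values model-free,
  `Q(s, a) = Σᵢ wᵢₐ fᵢ(s)`, by Q-learning with eligibility traces over
  egocentric landmark-cell features;
* an **arbitrator** that tracks each system's reliability from the recent
  average of its absolute prediction errors, `Ω ← Ω + η(|δ| − Ω)`,
  `χ = (δ_max − Ω)/δ_max`, and mixes the two value functions,
  `Q_net = P_SR·Q_HPC + (1 − P_SR)·Q_DLS`, where the SR influence follows
  the push–pull dynamics `dP_SR/dt = α(χ_MF)(1 − P_SR) − β(χ_SR)P_SR` with
  logistic transition rates.

The package is aimed at computational-neuroscience researchers studying
place-versus-response learning, model-based/model-free arbitration and
hippocampal–striatal interactions.  It ships the model together with five
simulated behavioral protocols and their analyses: a linear-track
arbitration demo, the moving-platform water maze with lesions, the
plus-maze place/response task with reinforcer devaluation,
landmark-versus-boundary blocking, the probabilistic two-step decision
task, and a cross-task correlation study linking model-based planning to
allocentric place memory.

## Worked example

```sh
python examples/linear_track_arbitration.py
```

```
trial  steps  P_SR   Omega_MF
    1     18   0.95     0.91
    5      7   0.95     0.70
   10     14   0.83     0.46
   20     30   0.40     0.09
   30      4   0.27     0.07

mean P_SR, first 5 trials: 0.96
mean P_SR, last 5 trials:  0.28
reward rate, last 10 trials: 0.80
```

One agent learns a five-state track with a terminal reward delivered with
probability 0.8.  `P_SR` is the proportion of influence of the
hippocampal SR system on the mixed action values; `Omega_MF` is the
striatal system's running average absolute reward-prediction error.  The
agent starts under hippocampal control (its random-walk SR prior is
reliable after pre-exposure), and as striatal reward predictions improve,
the arbitrator hands control to the cheaper model-free system — `P_SR`
falls from 0.96 to 0.28 while the final reward rate matches the 0.8
delivery probability.

The other scripts in `examples/` each run one protocol and print the
statistics the corresponding analyses are built on (escape-latency curves
and place-memory scores for the water maze, strategy proportions for the
plus maze, phase means and blocking tests for the two blocking conditions,
stay-probability tables for the two-step task, and the cross-task
association).  A thin command-line front end is also available:

```sh
dualsys run pearce --seed 0 --out out/
```

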