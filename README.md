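# sceptic

Information-compressing reinforcement learning on the clock task: a tested
simulator and analysis toolkit for value maps over a continuous response
interval.

## The problem

On the clock task an agent chooses *when* to respond within a 4-s trial;
reward probability p(t) and magnitude m(t) vary monotonically with the
chosen response time under four contingencies (IEV, DEV, CEV, CEVR — two
learnable, two not). Resolving exploration versus exploitation in this
continuous space requires a spatially structured value map, and the
dynamics of that map's information content (how many good options compete)
are the quantity of scientific interest.

This package is for computational cognitive scientists who want to
simulate, fit, and build analysis datasets for this family of models
without reimplementing the machinery: the SCEPTIC radial-basis
representation, its traditional-RL and information-compressing
(selective-maintenance) learning rules, a representationally matched
working-memory comparator, hierarchical model fitting, and the behavioral
and neural dataset builders that sit between the model and external
mixed-model / survival / GLM engines.

## The model

The interval [0, T] is tiled with B = 24 Gaussian radial basis functions
φ_b(x) = exp[−(x−μ_b)²/2s_b²], evenly spaced, with s_b chosen so adjacent
density-normalized elements share ≈50% of their area. Weights w_b scale
element heights; the value function is V(x) = Σ_b w_b φ_b(x) on a 40-bin
(0.1-s) response grid.

A response at time t generalizes to nearby elements through the
eligibility e_b(t) = ∫ min[g̃(τ), φ̃_b(τ)] dτ ∈ [0, 1], the shared area
between the density-normalized generalization curve g (centered at t,
variance s_g² = s_b²) and the element's receptive field. Learning rules:

* traditional RL:  w_b ← w_b + e_b α (reward − w_b)
* selective maintenance:  the same, plus decay −γ (1 − e_b)(w_b − h) of
  low-eligibility (unchosen, distant) elements toward a prior h = 0.

Choices follow a softmax over the response bins, p(j) ∝ exp(V_j / β).
The information content of the map is Shannon's entropy (log10) of the
normalized weights, H(w̃) = −Σ w̃_b log10 w̃_b; selective maintenance
compresses H as preferred options are retained and alternatives decay,
driving the transition from exploration to exploitation. The
working-memory comparator stores the last k = 4 choices as summed
unit-height Gaussians on the same basis plus an outcome buffer, with joint
entropy H(w̃^WM) + H(õ).

Fitting is empirical Bayes: per-subject MAP (logit/log-transformed
parameters, multistart L-BFGS) with Laplace posterior SDs, alternated with
population moment updates that shrink individuals toward the group; models
are compared by summed AIC. Dataset builders produce RT swings, the KLD
selection-history statistic, buffer-regression tables, within-trial
survival data with time-varying value (100-ms risk bins on [1.0, 3.5) s),
HRF-convolved and peak-renormalized parametric regressors, FSL-style
high-pass filtering, feedback-aligned epoching, and per-timepoint
model-comparison tables with Benjamini–Yekutieli correction.

## Worked example

```python
from sceptic import AgentParams, BasisConfig, make_contingency, run_agent

cfg = BasisConfig()                      # 24 elements, 40 bins over 4 s
env = make_contingency("DEV")            # earlier responses are better
params = AgentParams(alpha=0.1, beta=5.0, gamma=0.3)
log, traj = run_agent(cfg, params, env, 100, rule="selective", seed=42)
print(log["rt"][:10].median(), log["rt"][-10:].median())
print(log["entropy"][10:20].mean(), log["entropy"][-10:].mean())
```

prints

```
2.0500000000000003 0.8
0.691188331056164 0.61505720806707
```

— the agent's median response time moves from 2.05 s toward the early
value maximum (0.80 s), and value-map entropy falls from 0.69 to 0.62
log10 units as the map is compressed. The scripts in `examples/` walk
through each capability (basis geometry, simulation, hierarchical fitting
and AIC model comparison, behavioral datasets, neural design) and print a
line explaining every number they produce. A thin CLI covers the common
pipelines: `sceptic simulate`, `sceptic cohort`, `sceptic fit`,
`sceptic recover` — all byte-reproducible under `--seed`.

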