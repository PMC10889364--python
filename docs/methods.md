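# Methods

## Model

### Basis representation

The response interval [0, T] (T = 4 s by default, 5 s in the replication
design) is covered by B = 24 unnormalized Gaussian radial basis functions
with centers evenly spaced on [0, T] inclusive (spacing δ = T/(B−1)) and a
shared variance s_b². The width is not a free parameter: s_b is solved by
1-D root-finding (Brent) so that two adjacent *density-normalized*
elements share exactly 50% of their area. For equal-width normal
densities the shared area is 2·Φ(−δ/2s), so the default solution is
s_b ≈ δ/1.349 ≈ 0.129 s; the root is found on the quadrature overlap
rather than the closed form so the width and the eligibility integral use
one numerical convention. `overlap_target` is exposed for sensitivity
analyses.

Value evaluation uses the unit-height (height-form) elements:
V(x_j) = Σ_b w_b φ_b(x_j) on an n_bins = T/0.1 grid, with x_j the bin
center (j + 0.5)·0.1 s. Density normalization enters only where the
bounded-overlap interpretation requires it — inside the eligibility
integral and the WM projection. A `value_normalized` switch selects the
density form for V should a user want it; nothing else in the package
depends on that choice because the softmax is invariant to positive
rescaling of V only through β, which is a fitted parameter.

### Eligibility

e_b(t) = ∫ min[g̃(τ), φ̃_b(τ)] dτ with both curves probability densities
(g centered at the response time t, variance s_g² = s_b² by default).
The integral is evaluated by fixed-grid trapezoid quadrature with 60,001
points on the support extended 6·s_b beyond [0, T]. Extending the support
(rather than truncating at the printed interval) is deliberate: truncation
would make e_b < 1 for a response exactly at a boundary element's center,
breaking the identity that a perfectly centered response produces a
maximal update. With this grid the quadrature agrees with the
equal-Gaussian closed form 2·Φ(−δ/2s) to better than 1e−6 everywhere,
including boundary elements (tail mass beyond 6 SD is ~1e−9). Eligibility
vectors are cached per (configuration, response time); they do not depend
on the learning parameters, so model fitting computes them once per
subject log.

### Learning rules

* Traditional RL: w_b ← w_b + e_b(t)·α·[reward − w_b].
* Selective maintenance: the same update plus −γ·(1 − e_b(t))·(w_b − h),
  decay of low-eligibility elements toward the prior h (default 0).

With γ = 0 the second rule reduces to the first *bit-exactly* (the decay
term is skipped rather than multiplied by zero, so no floating-point
residue is introduced). With h = 0, nonnegative rewards and nonnegative
initial weights, weights remain nonnegative because the per-step
contraction factor 1 − e_b α − γ(1 − e_b) is bounded below by 0.

Per-element prediction errors (reward − w_b) drive the update, exactly as
in the learning rule; the scalar `pe` column in trial logs is a summary
(reward − V at the chosen bin) for use as a regression covariate, and is
not used inside the model.

### Choice rule and entropy

Choices are multinomial over the n_bins grid, p(j) ∝ exp(V_j/β), computed
with max-subtraction. β is a temperature: higher values give flatter,
less value-sensitive choice. Entropy is Shannon's H (log10 base, so the
24-element maximum is log10 24 ≈ 1.380) of the weights normalized to sum
to one *for this computation only*. Conventions for degenerate inputs:
0·log 0 = 0; an all-zero weight vector has H = log10 B (zero evidence =
maximal uncertainty — matching the high-entropy state of a fresh agent
with near-zero priors), except in the working-memory model where an empty
buffer carries no information and contributes 0. Entropy recorded before
the update (`entropy`) is decision-aligned; the change produced by the
update (`entropy_change`) is feedback-aligned. RT_Vmax is the bin-center
time of the global maximum of V, ties broken toward the earliest bin for
determinism.

### Working-memory comparator

The WM model stores the last k = 4 response times and reward/omission
flags. Selection history s(x) is the sum of unit-height Gaussians
(variance s_g²) at the buffered RTs; WM weights are the projection
w_b^WM = ∫ s(τ) φ̃_b(τ) dτ with φ density-normalized, making w^WM linear
in the buffer content and bounded by k per element. Its information
content is the joint entropy H(w̃^WM) + H(õ). k defaults to 4 (the
buffer-length regression estimate this family of models uses) although
the summation bounds in some statements of the model imply 5; k is a
plain argument.

## Task environments

The four contingencies are linear-monotone magnitude schedules with
affine expected value and p(t) = ev(t)/m(t) clipped to [0.05, 0.95]:
CEV (m 50→150, ev 40), CEVR (m 150→50, ev 40 — the probability gradient
reverses against CEV), IEV (ev 25→65), DEV (ev 65→25). Endpoints were
chosen once to keep expected value in the tens of points with p inside
the clip bounds for the whole interval (parameters producing p outside
[0, 1] raise rather than clip silently); they are plumbing, overridable
per call, since only the four qualitative regimes matter to the analyses.

Session presets: `fmri_original` (8 runs × 50 trials × 4 s),
`meg_original` (8 × 63 × 4 s), `replication` (one continuous 240-trial
session, 5-s trials, unsignaled contingency reversal every 40 trials
alternating IEV/DEV — switch points at trials 41, 81, 121, 161, 201,
giving 6 blocks). Agent state is never reset at a reversal; weights
re-initialize at run boundaries (runs are separate blocks). ITIs are
exponential with configurable mean, truncated at a maximum; design
efficiency optimization is out of scope. The replication generator keeps
all trials; dropping the first 10 trials per block is an analysis-stage
filter in the dataset builders.

Cohorts draw (α, β, γ) per subject from independent normals on the
transformed scales (logit α, log β, logit γ), defaults
(−2.2, 0.4), (2.1, 0.35), (−0.85, 0.5) — i.e. α ≈ 0.10, β ≈ 8, γ ≈ 0.30
at the medians with realistic heterogeneity. Initial weights default to
uniform-random on [0, 1] (an all-zero option exists); the value scale
(tens of points) makes this a weak prior.

### What the synthetic data does and does not emulate

`synth_neural` produces trial × peri-feedback-time responses as a linear
mixture of trial-level model signals with known effect curves, subject
random intercepts, and i.i.d. Gaussian noise. It emulates the structure
of deconvolved, feedback-aligned BOLD summaries (trials × time × region)
— enough to validate regressor construction, epoch alignment, and
model-comparison bookkeeping. It does not emulate temporal
autocorrelation of hemodynamic signals, spatial correlation across
regions, heteroscedastic noise, or subject random slopes; passing
recovery tests therefore demonstrate correctness of the pipeline, not
expected effect sizes or error rates in real neural data. Likewise the
behavioral generator produces stationary-parameter agents; it does not
model lapses, missed responses, or within-session parameter drift, so
fits to real data should expect lower recovery than the simulation
benchmarks.

## Fitting

The likelihood is the softmax probability of each observed response bin
under the deterministically replayed pre-choice value function, with
weights starting at zero per run (a `reinit_per_run=False` switch folds a
session into one continuous replay). Trials without a response carry no
likelihood term. Subject-level estimation is MAP with a Gaussian prior on
the transformed scale, multistart L-BFGS-B (5 starts by default, drawn
around the prior mean, box-bounded at ±20 to keep the inverse transforms
in floating range), and Laplace SDs from the inverse finite-difference
Hessian at the mode (falling back to the prior SD when the curvature is
not positive definite, e.g. at a boundary-ish mode). The population loop
alternates subject fits with moment updates — mean of posterior modes;
variance = mean of posterior variances + variance of modes — until the
population means move less than `tol` (default 0.01 transformed units,
max 50 iterations); after the first iteration subject fits warm-start
from their previous modes with a single start. This MAP + Laplace
empirical-Bayes scheme is a deliberate, fully specified stand-in for the
variational toolboxes usually used with these models: it reproduces the
shrinkage structure at desk scale but is not a reproduction of any
particular toolbox's evidence approximation.

AIC = 2k − 2 log L (k = 2 for traditional, 3 for selective) is summed
over subjects for model comparison; `compare_models` refuses to compare
fits whose data fingerprints differ. `refit_at_group_means` recomputes
latent trajectories only (no optimization) at shared parameters so
regression coefficients on model signals are comparable across subjects.

## Dataset builders

* KLD selection-history statistic: each RT window becomes a density on
  the response grid (normalized mixture of unit-height Gaussians,
  bandwidth s_g² by default, floored at ε = 1e−6 and renormalized);
  the statistic is the discrete KL divergence (natural log) of the source
  window from the reference window. Three presets encode the three window
  recipes in use: `behavioral` ({t−4..t−2} vs {t−7..t−5}), `meg`
  ({t−3, t−2} vs {t−1}), `fmri` ({t} vs {t−3..t−1}, log-transformed,
  with log(max(KLD, ε)) so identical windows sit at the floor). Bandwidth
  and windows are arguments because no single canonical definition
  exists.
* Survival dataset: discrete 100-ms risk bins on [1.0, 3.5) s (window and
  extra front/back censoring configurable), half-open [start, stop)
  records in milliseconds, one event record per uncensored trial. An RT
  exactly on a bin edge belongs to the earlier bin. The time-varying
  covariate is the pre-choice value function sampled at each bin's
  midpoint on the response grid. Estimation (mixed-effects Cox) is
  delegated to external engines.
* Neural design: double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6 —
  implementation defaults, configurable), peak-normalized to 1. Event
  regressors are duration-modulated unit-height boxcars convolved on a
  50-ms internal grid; the peak-renormalized variant rescales each
  trial's convolved boxcar to unit peak before amplitude modulation, so
  decision-time differences do not masquerade as parametric effects.
  Parametric values are mean-centered before convolution by default.
  High-pass filtering is a Gaussian-weighted running-line detrend with
  σ = 1/(2·cutoff) s (62.5 s at the 0.008-Hz default) applied identically
  to data and design; a Butterworth alternative sits behind a flag.
  Epoching linearly interpolates onto a feedback-anchored grid (a sample
  sits exactly at onset) and masks cells overlapping the previous or next
  trial's span. Benjamini–Yekutieli adjustment and per-timepoint OLS AIC
  summaries support the neural model-comparison workflow; the OLS hook is
  bookkeeping for engine-agnostic tables, not a substitute for the
  multilevel models used on real data.

## Numerical choices and degenerate inputs

* Quadrature: 60,001-point trapezoid, support padded 6·s_b; accuracy vs
  the closed form ≤ 1e−6 (tested).
* Argmax ties: earliest bin. RT→bin mapping: floor(rt/0.1), clamped;
  rewards are computed from the continuous RT, not the bin center.
* Transforms: logit/log with inputs clipped to ±60 before inversion and
  α, γ kept strictly inside (0, 1) at the 1e−12 level so saturated
  optimizer excursions cannot produce invalid parameters.
* All-zero weights: H = log10 B (value map) vs 0 (WM buffers), as above.
* Negative weights to `entropy`, out-of-range eligibility times,
  overlapping design events, mismatched data fingerprints, and p(t)
  outside [0, 1] all raise instead of silently correcting.

## Test and benchmark problem sizes

Simulation-based checks use sizes chosen to make their statistical
criteria stable while keeping the default suite quick: parameter recovery
runs 40 subjects × 400 trials (8 runs × 50, all four contingencies) and
requires truth–estimate r ≥ 0.5 per parameter; rule recovery uses 50
replicates of 3-subject × 150-trial cohorts; neural signal recovery uses
50 replicates of 4-subject × 100-trial cohorts with effect curves peaking
+1 s post-feedback and noise SD 0.5; entropy-compression and RT-shift
dynamics use 50 seeded 100-trial runs with the well-tuned agent
(α = 0.1, β = 5, γ = 0.3). Seeds are fixed throughout; every simulation
in the package is reproducible from a single integer seed.

## Known limitations

* The MAP + Laplace empirical-Bayes fitter approximates posterior SDs by
  local curvature; strongly skewed subject posteriors (short logs, high
  β) are summarized optimistically.
* `gaussian_line` high-pass builds an n × n weight matrix; it is intended
  for run-length series (hundreds to a few thousand samples).
* The WM comparator has no free parameters by design; it is a comparator,
  not a fitted account of behavior.
* Contingency schedules are a declared stand-in family; analyses that
  depend on the exact historical p/m curves should supply them via
  `ev_params` or custom `Contingency` objects.
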