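# Methods

## Model

The package implements the optimal belief filter for a two-state
generative process with abrupt switches.  In discrete time the posterior
log odds obey `L_n = psi(L_{n-1}, H) + LLR_n` with
`psi(L, H) = L + log[(1-H)/H + e^{-L}] - log[(1-H)/H + e^{L}]`; this is
the log-odds form of the hidden-Markov forward recursion
`q_i' ∝ p(x|z_i) [(1-H) q_i + H q_j]`, which the test suite uses as an
independent oracle.  `psi` is evaluated through `logaddexp` identities
with `r = log((1-H)/H)`, so beliefs up to |L| ≈ 1e4 neither overflow nor
lose the saturation value `±r`.  `H = 0`, `H = 0.5`, and `H = 1` are
handled as exact analytic branches (`psi = L`, `0`, `-L`); elsewhere the
general expression applies.  The first-order expansion
`psi ≈ (1-K) L + theta` uses the analytic derivative
`dpsi/dL = 1 - sigmoid(-(L+r)) - sigmoid(L-r)`; it gives leak `K = 2H`
and zero bias at `L = 0`, and `K = 1`, `theta = ±r` for strong beliefs.

The continuous-time filter is `dL = -2 lambda sinh(L) dt + A dx` with
`A = 2 mu / sigma^2`.  Its stationary density during a stable signal
stretch is `p(L) ∝ exp((-2 lambda cosh L + gamma L) / |gamma|)` with
`gamma = A h` the signed mean evidence flow.  The `|gamma|` denominator is
the diffusion coefficient `(A sigma)^2 / 2 = |gamma|` of the associated
Fokker–Planck equation; it is the only normalization consistent with the
extreme-value limit having unit scale, and the simulation-vs-density
Kolmogorov–Smirnov check in the test suite confirms it.  For
`gamma / lambda >> 1` the density is a reflected Gumbel with location
`log(gamma/lambda)` and scale 1; `scipy.stats.gumbel_l` is the matching
family for positive evidence.

## Numerical choices

* **Prior-map integration** (`prior_map_continuous`): the drift grows as
  `e^{|L|}`, so the no-evidence flow is stiff; it is integrated with
  LSODA at `rtol = atol = 1e-12`, which is sub-step independent below
  1e-8.  Start values beyond |L| = 30 are clipped to the sinh guard — the
  flow forgets its start point at double-exponential order there.
* **Euler–Maruyama** (`simulate_em`): explicit scheme with the stability
  guard `2 lambda dt < 0.5`; simulated beliefs are clipped at |L| = 50
  (stationary mass never approaches this in the regimes exercised).
  Stationary sampling discards a burn-in of `max(10/lambda, 5/gamma)`
  seconds; where near-independent draws matter (KS tests) samples are
  thinned by ~2 local relaxation times (`thin = 20` at
  `gamma = 7, lambda = 0.1`).
* **Belief grid** (dots fitting): the belief distribution is propagated
  through Gaussian transition kernels whose columns are the Gaussian
  *integrated over node cells*, with Sheppard's correction (kernel
  variance `s^2 - h^2/12`) so the binned transition keeps the prescribed
  mean and variance even when the frame noise std is below the grid step.
  The original procedure's grid runs −10..10 in steps of 0.4 log-odds; at
  the gain/coherence regime of this package's synthetic observers that
  step is not fully converged (choice probabilities move by up to ~0.03
  when halved), so the default step is 0.2, where halving again changes
  results by under 1e-3.  The 0.4 grid remains available via the `step`
  argument.  The probability of a positive choice reads out all mass
  above zero plus a share of the zero cell given by a local linear
  density reconstruction (exactly 1/2 for symmetric distributions).
  Fitting uses banded kernels (±6 sd) with identical numerics; a dense
  reference implementation (`grid_trial_probability`) backs the tests.

## Tasks and synthetic observers

The **triangles** generator normalizes the source separation to `d = 1`
and draws star positions from `N(±1/2, sigma)` with
`sigma = sigma_over_d ∈ {0.24, 0.33, 0.41}`; the stored log-likelihood
ratio is the exact Gaussian value `x / sigma^2`, whose conditional mean is
`1/(2 sigma^2)` = 8.68 / 4.59 / 2.97 for the three ratios.  Sources
switch as a Bernoulli chain at the block hazard, blocks default to 1000
trials with a (400 feedback / 400 no-feedback / 200 feedback) layout.

The **dots-reversal** generator draws trial durations `min(10, 5 + tau)`
seconds with `tau` exponential (mean 2.5 s, configurable; the
distribution's mean is not pinned by the task description), quantized to
the 60 Hz frame grid.  Direction switches form a Poisson process at
`lambda ∈ {0.1, 2}` Hz; per-frame coherence magnitude is realized as a
binomial fraction of 100 coherently displaced dots around the nominal
level (high 0.8 on 25% of trials, low 0.15 on 75%), since the physical
stimulus realizes coherence stochastically frame by frame; a
fixed-coherence ablation is available.

Synthetic observers run any implemented prior map (normative, leaky,
bounded, or trial-shuffled hazard) with their own subjective hazard, an
evidence gain (`beta` on star position; `k` on signed coherence), and
noise: triangles choices are `sign(L + zeta)` with `zeta ~ N(0, upsilon)`;
dots observers add signal-dependent frame noise `sqrt(2 k <|C|>) eta` and
report the sign of the final belief.  The default dots gain `k = 0.13`
calibrates a 500-ms stable low-coherence stimulus to ~65% accuracy — the
threshold rule by which the low coherence level is set in the task.

What the generators do **not** emulate: learning (subjective hazards are
fixed within a block), lapses or bias in the choice rule, sequential
effects outside the belief recursion, and visual front-end noise beyond
the binomial coherence model.  Passing recovery tests therefore show that
the inference machinery is correct and well-conditioned at realistic
sizes, not that real observers satisfy the model.

## Fitting

All models are fit by minimizing cross-entropy plus a negative log prior
(MAP).  Priors (weakly regularizing, configurable, `priors="flat"`
disables them): Beta(1.1, 1.1) on H and on K/2; a Gaussian on the *log*
of gains and noise (sd 2) — a log-normal density with its Jacobian would
pull any scale-degenerate ridge toward zero gain; Normal(0, 5^2) on
log theta.  Parameters are optimized in unconstrained space
(logit/log/scaled-logit transforms) with L-BFGS-B and random restarts for
the triangles recursion (jit-compiled) and Nelder–Mead for the dots grid
objective (banded kernels make it piecewise smooth).  Trials are excluded
from the likelihood (while still propagating belief) by a per-block
burn-in, 200 trials by default, with an optional feedback-trial filter.
`BIC = k log n - 2 logL` on included trials; the block-independent
control permutes the per-trial hazard-condition labels and refits, 50
times for triangles and 20 for dots by default.

Identifiability: the leaky and bounded triangles likelihoods are exactly
invariant under joint rescaling of (gain, noise, boundary), so only
scale-free quantities — K, theta/upsilon, H — are identified; reported
absolute gains sit where the priors place the scale.  The leaky family is
also the small-scale limit of the normative family (H = K/2), which is
why BIC separation of those two models on leaky-generated data is
intrinsically marginal.

## Study sizes used in the validation suites

Chosen as the smallest sizes at which the checks are well-powered:
triangles hazard recovery uses 20 replicates of 3 blocks x 1000 trials
(`sigma/d = 0.33`, `upsilon = 1`); dots switch-rate ordering uses 20
replicates of two 40-trial sessions; model recovery uses 7 replicates per
generating model at n = 2000 (`sigma/d = 0.41`, the weak-evidence
condition, which best separates the hard boundary from the leaky and
normative maps; suboptimal generators use the normative-matched
parameters K = 2H and theta = log((1-H)/H)); the nonparametric prior-map
recovery uses one 20,000-trial weak-evidence block, where the estimator's
node-level wiggle mode (weakly damped by the gamma = 1/20 Tikhonov
penalty) is overcome by data.  The behavioral analyses keep the
field-standard settings: psychometric fits restricted to trials after
strong evidence (|LLR| > 4), duration bins (0–0.2, 0.2–0.5, 0.5–1,
1–1.5, 1.5–3 s) with the ≥1-switch and ≥300-ms penultimate-duration
inclusion rule, 1000 bootstrap samples resampling subjects then trials.

## Known limitations

Two-alternative sources only; no hierarchical (group-level) fitting; no
learning dynamics within blocks; the stationary-density machinery assumes
a stable signal stretch (no direct Fokker–Planck time stepping — time
evolution is Monte-Carlo, as in the ensemble statistics); nonparametric
prior-map estimates are only trustworthy where beliefs visit and evidence
is weak enough to make choices informative.
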