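# normacc — normative evidence accumulation in unpredictable environments

`normacc` implements, simulates, and fits the Bayes-optimal belief filter
for two-alternative decisions when the source generating the evidence can
switch sides at any moment.  It is aimed at computational and cognitive
neuroscientists who study evidence accumulation (drift-diffusion-style
models) in change-point environments: the package provides the model in
both discrete and continuous time, generators for two psychophysical
tasks, synthetic observers, the full choice-model fitting machinery
(maximum a posteriori cross-entropy fits, belief-grid propagation for
latent noise, BIC comparison), and the accompanying behavioral analyses.

## The model

Let `L_n` be the log posterior odds of the two sources after `n` samples
and `LLR_n` the log-likelihood ratio of the current sample.  If the source
switches between samples with hazard rate `H`, the optimal update is

    L_n = psi(L_{n-1}, H) + LLR_n
    psi(L, H) = L + log[(1-H)/H + e^{-L}] - log[(1-H)/H + e^{L}]

`psi` is a leaky, saturating prior mapping: near `L = 0` it behaves like a
leaky accumulator with leak `K = 2H`; for strong beliefs it saturates at
the *non-absorbing* boundary `± log((1-H)/H)`, suspending accumulation
without terminating the decision.  `H = 0` gives perfect integration,
`H = 0.5` makes history irrelevant, and `H > 0.5` produces damped
oscillations of belief.

In continuous time, for a telegraph signal `h(t) = ±mu` switching at
Poisson rate `lambda` (Hz) observed through Gaussian noise
(`dx = h dt + sigma dW`, gain `A = 2 mu / sigma^2`):

    dL = -2 lambda sinh(L) dt + A dx(t)

During a stable stretch with mean evidence flow `gamma = A|h|` the
stationary belief density is `p(L) ∝ exp((-2 lambda cosh L + gamma L) /
gamma)` — for `gamma/lambda >> 1` an extreme-value (reflected Gumbel)
distribution with location `log(gamma/lambda)` and scale 1, heavy-tailed
toward zero so that subsequent changes are detected quickly.

## Worked example

Simulate a three-block "triangles" session (one Gaussian sample per trial,
block-wise hazard rates), let a normative observer with matched subjective
hazards and choice noise `upsilon = 1` make the choices, then fit the
normative model and two suboptimal alternatives:

```python
import normacc as na
from normacc.fitting import FitSpec

hazards = (0.1, 0.3, 0.7)
trials = na.gen_triangles(na.TrianglesConfig(hazard_set=hazards, n_trials_per_block=1000,
                                             sigma_over_d=0.33, seed=0))
observer = na.ObserverParams(model="normative",
                             subjective_hazard={b: h for b, h in enumerate(hazards)},
                             gain=1 / 0.33**2, noise=1.0, seed=1)
data = na.observe(trials, observer)

fit = na.fit_triangles_normative(data, FitSpec(n_restarts=5, seed=2))
for b, h in enumerate(hazards):
    print(f"block {b}: true H = {h:.2f}, fitted H = {fit.params['H'][b]:.3f}")

comparison = na.compare_models({
    "normative": fit,
    "leaky": na.fit_leaky(data, FitSpec(n_restarts=5, seed=3)),
    "bounded": na.fit_bounded(data, FitSpec(n_restarts=5, seed=4)),
})
print(comparison[["model", "bic", "delta_bic"]].to_string(index=False))
```

prints

```
block 0: true H = 0.10, fitted H = 0.208
block 1: true H = 0.30, fitted H = 0.356
block 2: true H = 0.70, fitted H = 0.657
    model       bic  delta_bic
normative 333.50861   0.000000
    leaky 359.25226  25.743649
  bounded 386.54659  53.037980
```

The fitted block-wise hazards track the generating values (a single
800-trial-per-block replicate carries sampling error of roughly ±0.05–0.1;
the test suite checks medians over 20 replicates), and the generating
normative model beats both the hazard-specific leaky accumulator and the
perfect accumulator with a stabilizing boundary by a wide BIC margin.

The same machinery is available from the shell: `normacc simulate`,
`normacc observe`, `normacc fit`, `normacc analyze`, and `normacc
pipeline --config run.yaml` for a reproducible end-to-end run.

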