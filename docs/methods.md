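# Methods

## Forward model

The generative model is a three-population neural mass model of an
event-related potential. States x₁–x₉ comprise three second-order synaptic
filters (potential + derivative pairs) for the spiny-stellate (x₁, x₄),
excitatory-to-pyramidal (x₂, x₅) and inhibitory-to-pyramidal (x₃, x₆)
pathways, the inhibitory population (x₇, x₈), and the pyramidal membrane
voltage x₉ = x₂ − x₃ in integrated form (ẋ₉ = x₅ − x₆). Firing rates are
the shifted logistic S(v) = 1/(1+e^(−0.56v)) − ½, odd and bounded in
(−½, ½). Axonal/synaptic delays appear as the first-order surrogate
x(t−δ) ≈ x(t) − δ ẋ(t) applied to the three delayed states (x₁, x₇, x₉)
inside the sigmoids; the derivative of each delayed state is itself a plain
state (ẋ₁ = x₄, ẋ₇ = x₈, ẋ₉ = x₅ − x₆), so the substitution is closed-form
and the system remains an ODE. A Heaviside step input of intensity u,
active from t = 0 over the whole window, drives the stellate population.

Ten parameters: gains g₁…g₄ (dimensionless), delay δ (ms), rate constants
τₑ, τᵢ (ms), amplitudes hₑ, hᵢ (mV), input u (dimensionless). Units of δ,
τₑ, τᵢ are taken as ms, consistent with the millisecond integration grid;
the source material does not state them explicitly.

Integration is forward Euler from x(0) = 0 (the input-free equilibrium)
with dt = 0.1 ms over 200 ms (2001 samples); both are configurable. Euler
is deliberate — the discrete map is cheap, deterministic, and exactly
differentiable, and the inference targets the discretized model, not the
continuous limit. First-order convergence is verified by Richardson
refinement in the tests.

### Stability

Two notions are kept deliberately separate.

* **Blow-up guard** (`classify_stability`, the `stable` flag): a
  trajectory is unstable if any state is non-finite or exceeds 10³ in
  magnitude — far above the order-1 signal scale. During inference such
  draws map to log-density −∞, so samplers reject them instead of
  crashing. Because the sigmoid saturates, this guard essentially never
  fires for prior draws; it exists to keep optimizers and samplers safe in
  extreme parameter corners (e.g. τ → 0 making Euler stiffly divergent).
* **Dynamical classification** (`classify_dynamics`): the scientifically
  meaningful instability of this bounded system is a trajectory that fails
  to decay back to rest — a sustained limit-cycle oscillation instead of a
  transient evoked response. The system is integrated for 2000 ms and
  labelled oscillatory if the peak-to-peak excursion of x₉ over the final
  400 ms exceeds 0.05 (half the observation-noise sd). The outcome is
  insensitive to this threshold because draws are sharply bimodal (late
  excursions below 0.01 or above 0.5). Linear stability analysis is not
  usable here: the model possesses a structural line of equilibria (the
  steady state leaves x₉ free, the same degeneracy that makes g₁
  non-identifiable), so the leading eigenvalue is identically zero.

Under the default priors roughly one third of prior draws are oscillatory
by this criterion. Note that shrinking the settling horizon inflates the
rate smoothly (a 200 ms horizon calls almost every draw unstable, because
even the true parameters have not settled inside the observation window);
the asymptotic horizon is the defensible choice and is the one reported.

## Priors, likelihood, reduced models

Each parameter carries an independent Gamma(shape, scale) prior; the
built-in table gives prior means within tens of percent of the generative
values with weakly informative spread. The likelihood is Gaussian,
y_i ~ N(x₉(t_i; θ), σ²) with σ fixed at the generative 0.1; the noise sd
is not inferred (a deliberate design choice — the workflow studies
parameter inversion, not noise estimation; user-specified σ is accepted).

Inference runs in unconstrained space via the componentwise log map with
log-Jacobian Σζ. Gradients of the log-joint are exact for the discrete
simulator: forward sensitivities S = ∂x/∂θ are propagated through the
Euler loop (S_{k+1} = S_k + dt (J_x S_k + J_θ)) in the same numba kernel
that integrates the states, which is what makes hand-rolled HMC practical
at ~0.25 ms per gradient.

A reduced model clamps one connectivity gain to exactly zero and removes
it from the sampled vector, so the parameter count k drops by one — the
bookkeeping that AIC/BIC and the Laplace evidence see.

Chains can be initialized from the prior ("random"), from a supplied
value, or uniformly from the prior tails: per parameter, a side is chosen
fairly, a quantile level is drawn uniformly below 0.025 or above 0.975
(with guards at 10⁻⁶ mass from either end), and the Gamma CDF is inverted.
Tail draws occasionally land on blow-up-guarded corners; initialization
redraws until the log-joint is finite and fails loudly after a bounded
number of attempts.

## Posterior engines

All engines consume the same model object and return constrained-space
draws shaped chains × iterations × parameters plus the pointwise
log-likelihood matrix, so diagnostics and model comparison are
engine-agnostic.

* **NUTS.** Dynamic HMC with recursive trajectory doubling, multinomial
  sampling of the trajectory (biased toward the newer subtree), a
  divergence cut at energy error 1000, dual-averaging step-size adaptation
  toward the target acceptance statistic, and a *dense* metric — the
  regularized empirical covariance from expanding warm-up windows
  (75-iteration initial buffer, 25/50/… windows, 50-iteration terminal
  buffer scaled for short warm-ups). A dense metric matters here: the
  posterior carries pairwise correlations up to ~0.98, and a diagonal
  metric roughly doubles tree depth (2⁸ vs 2⁵ leapfrogs per iteration) for
  half the effective sample size. With defaults (4 chains, 200 + 200,
  depth ≤ 10, target 0.8) a converged run yields mean R̂ ≈ 1.006, zero
  divergences, and relative bulk ESS ≈ 0.5–0.6.
* **ADVI.** Mean-field (free means + log-sds) and full-rank (free Cholesky
  factor, log diagonal) Gaussian guides in unconstrained space, trained by
  Adam (default learning rate 5·10⁻⁴, 10⁵ iterations, one ELBO sample per
  step — all configurable; experiments scale the budget down). The ELBO
  uses the reparametrization trick; draws with −∞ log-joint contribute
  nothing to that iteration's gradient, and a run aborts if the ELBO stays
  non-finite for 500 consecutive iterations. The recorded trace is the
  per-iteration one-sample ELBO estimate; an optional plateau stop
  (relative change < 10⁻⁸ over 5000 iterations) is off by default.
* **Laplace.** MAP by L-BFGS (analytic gradients, gradient tolerance
  10⁻⁸) restarted from 8 prior-tail draws, keeping the best optimum; the
  Hessian at the MAP by central differences of the exact gradient; the
  Gaussian N(μ, (−H)⁻¹) sampled and mapped back through exp. The evidence
  approximation uses the entropy-consistent form
  log p(y, μ) + (k/2) log 2π − ½ log|−H|, which is exact for a Gaussian
  joint (verified against the closed-form evidence of a conjugate
  normal–normal model). The variant that adds +½ log|Σ| with Σ defined as
  the negative Hessian — as sometimes printed — differs by k/2 + log|−H|;
  it is recorded alongside as `elbo_literal` rather than silently
  corrected.

Seed handling: every engine derives all randomness from the supplied seed
(chains from spawned seed sequences), so identical seeds give bitwise
identical draws.

## Diagnostics

Split rank-normalized R̂ and bulk/tail ESS follow the modern split-chain
definitions (fractional ranks (r − 3/8)/(S + ¼) through the inverse normal
map; tail ESS is the minimum over the 5% and 95% quantile indicator
series); these are delegated to arviz, which implements exactly those
estimators, and are cross-checked in the tests against direct
between/within-variance and AR(1) oracles. Constant chains yield NaN with
a warning rather than an exception.

Accuracy metrics: posterior z-score (mean − truth)/sd per parameter; fit
RMSE — the root-mean-square deviation between the observations and the
noise-free prediction at the posterior mean (an unstable posterior mean
reports ∞); parameter RMSE — root-mean-square of *relative* errors, since
parameter magnitudes span 0.15–27.9 and absolute errors would be dominated
by hᵢ and δ. A fit is "faithful" when fit RMSE ≤ 0.25, a threshold about
2.5× the noise floor; the value is exposed in configuration.

## Model comparison and stacking

All criteria are reported on the deviance scale (−2×, smaller is better),
with positive elpd stored alongside. WAIC uses the log-pointwise-
predictive-density (stable log-mean-exp over draws) minus the variance
penalty. PSIS-LOO builds per-point importance ratios 1/p(y_i|θ_s),
replaces the largest 20% (at least 5) by expected order statistics of a
generalized Pareto fitted to the tail exceedances (Zhang–Stephens
estimator, shape shrunk toward 0.5), truncates at the raw maximum, and
reports the per-point shape k̂ as a reliability diagnostic; with too few
draws it falls back to unsmoothed importance sampling with a warning. The
implementation is cross-checked against exact leave-one-out refits of a
conjugate model and against arviz.

For AIC/BIC the maximum likelihood is obtained by L-BFGS on the likelihood
alone, started from the posterior mean and the best posterior draw,
keeping the better optimum. VI fits contribute their final smoothed ELBO
(mean of the last 1000 recorded values) as a free-energy score.

Stacking maximizes the average leave-one-out log score of the mixture
Σ w_k p(y_i|y₋ᵢ, M_k) over the simplex, with member predictive densities
estimated per chain by PSIS-LOO. The optimizer works through a softmax
reparametrization with analytic gradients and multiple starts; exact ties
are broken toward uniform weights by an L2 ridge of 10⁻⁸. The optimum is
certified in tests against a dense simplex grid and must dominate every
vertex and the uniform weighting. Naive pooling concatenates chains with
equal weight; stacked/pooled predictive traces use the mixture of
per-chain posterior-mean predictions.

One caveat worth stating: for this model WAIC/PSIS-LOO cannot
systematically separate the full model from the g₁ = 0 reduction. The g₁
direction is structurally non-identified, its posterior stays
prior-dominated, and the pointwise log-likelihood is nearly flat along it,
so the variance-based effective parameter count is the same for both
models and their WAIC difference is Monte-Carlo noise (order ±1 deviance
unit). AIC/BIC, whose penalty counts parameters explicitly, favour the
reduced model robustly, and every criterion agrees that cutting g₂ — the
stellate→pyramidal drive — is catastrophic (ΔWAIC ≈ 10⁵).

## Experiments and problem sizes

The experiment layer reproduces the study designs: a 20-setting NUTS grid
(target acceptance {0.6, 0.7, 0.8, 0.9, 0.95} × max tree depth
{5, 6, 7, 8}) with 4 chains per setting under random or prior-tail
initialization; the stacking-vs-pooling comparison on randomly initialized
chains; the four-method benchmark (NUTS, mean-field, full-rank, Laplace,
all tail-initialized); the five-model comparison; and the prior-predictive
stability census. Every experiment takes a seed and a `--scale` factor
dividing chain counts and iteration budgets, writes CSV tables plus a JSON
manifest (config echo, package version, seed) into its output directory,
and is byte-reproducible from the same seed. The test suite exercises the
experiments at scale factors 4–10 and the acceptance script runs the
census at 1000 draws and the NUTS checks at the study's full 200 + 200
sampling settings with 8 (convergence rate) and 4 (fit RMSE) chains —
sizes chosen so the whole suite completes in minutes on one CPU while
leaving the per-chain configuration identical to the study's.

## What the synthetic conditions do and do not show

All data are generated by the package's own simulator under the exact
stated conditions (true parameters, Gamma priors, σ = 0.1, N = 201), so
passing tests demonstrate correct *inversion of the assumed model* —
well-specified likelihood, known noise level, single trial, no lead-field
mixing, no model error. They do not demonstrate robustness to empirical
MEG/EEG features: trial averaging artifacts, correlated or non-Gaussian
noise, channel forward models, or misspecified dynamics. The
multi-modality probed here is the genuine kind induced by the model's
degeneracy (many parameter sets explain the data comparably), which is why
remedies that inject information — tail initialization — or that reweight
by predictive quality — stacking — work; conclusions about other sources
of multi-modality (e.g. label switching) are out of scope.

## Known limitations

* Euler with fixed step only; no adaptive or higher-order integrators, no
  true delay-differential solver (the first-order delay surrogate is part
  of the model definition).
* σ_obs fixed; hierarchical/noise inference is out of scope.
* The Laplace Hessian is finite-differenced from gradients (exact to
  ~10⁻⁶ here); a second-order sensitivity propagation would be exact.
* PSIS-LOO tail fits need a few hundred draws to be trustworthy; with
  fewer the fallback is plain importance sampling.
* The dynamical stability census classifies asymptotic behaviour at a
  2000 ms horizon; regimes with decay times beyond that horizon would be
  (conservatively) labelled oscillatory.
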