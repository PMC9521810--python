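# Methods

## The regression problem

An isothermal titration calorimetry (ITC) experiment injects a titrant
solution into a sample cell containing a receptor and records, per
injection, the integrated heat `q_n` (cal). `itcmix` fits thermodynamic
binding models to the heat vector `D = {q_1, …, q_N}` when the titrant may
contain **two competing ligands** — typically a pair of enantiomers whose
affinities may differ. Three nested models are supported:

* **2C** (two-component): one ligand binds.
  θ = (ΔG, ΔH, ΔH₀, [R]₀, [L]s, σ), 6 parameters.
* **RM** (racemic mixture): two competing ligands at a fixed 1:1 syringe
  ratio. θ = (ΔG₁, ΔΔG, ΔH₁, ΔH₂, ΔH₀, [R]₀, [L]s, σ), 8 parameters.
* **EM** (enantiomeric mixture): the syringe mole fraction of ligand 1,
  ρ ∈ [0, 1], is free. 9 parameters; RM is the slice ρ = 0.5.

ΔG, ΔH are standard binding free energy/enthalpy (kcal/mol); ΔΔG = ΔG₂ −
ΔG₁ ≥ 0 labels ligand 1 as the tighter binder and removes the
label-switching degeneracy. ΔH₀ is the per-injection heat of dilution and
stirring (cal), [R]₀ the initial cell receptor concentration, [L]s the
total syringe ligand concentration (mol/L), and σ the i.i.d. Gaussian
measurement noise s.d. (cal). Dissociation constants use the 1 M
standard-state convention, `Kd = exp(ΔG / (R T))`, `R = 1.9872e-3
kcal/(mol·K)`.

## Forward model

Concentrations before reaction follow the perfusion model: an injection of
volume ΔV displaces a fraction ΔV/V₀ of the cell contents, so after
injection n the receptor total is `[R]₀ · d_n` and the accumulated ligand
total `[L]s · (1 − d_n)`, with `d_n = Π_{i≤n}(1 − ΔV_i/V₀)`. Both ligands
dilute identically, so the cell ligand pool keeps the syringe composition
ρ.

Equilibrium complex concentrations come from mass action. For one ligand
the quadratic root is evaluated in the cancellation-safe form
`[RL] = 2 Rt Lt / (s + sqrt(s² − 4 Rt Lt))`, `s = Rt + Lt + Kd`. For two
competing ligands the free receptor concentration is the physically
admissible root of a cubic, computed with the trigonometric closed form
and polished by a few Newton steps on the (monotone) receptor balance;
mass balances are verified to 1e-10 relative, with a bisection fallback
for any point the polished root misses. The closed form plus residual
check keeps the solver fast enough for MCMC inner loops while controlling
error explicitly.

The heat of injection n differences the cell's complex content against the
once-diluted previous content:

    q*_n = V₀ · Σ_i ΔH_i ([RL_i]_n − d'_n [RL_i]_{n−1}) + ΔH₀,
    d'_n = 1 − ΔV_n / V₀.

This convention (no discarded first half-injection, no mid-injection ΔV/2
correction) is fixed here and isolated in `models.heats`; alternative
bookkeeping variants exist in the literature and would only require
changing that one function.

## Priors and posterior

The likelihood is Gaussian i.i.d. with unknown σ. Component priors:

| parameter | prior | rationale |
|---|---|---|
| ΔG, ΔG₁ | Uniform(−40, 40) kcal/mol | generous physical range |
| ΔΔG | Uniform(0, 40) kcal/mol | ligand-1-is-tighter convention |
| ΔH, ΔH₁, ΔH₂ | Uniform(−100, 100) kcal/mol | generous physical range |
| ΔH₀ | Uniform(q_min − Δq, q_max + Δq) cal | data-driven; Δq = q_max − q_min |
| [R]₀, [L]s (stated) | ln[X] ~ Normal(ln stated, 0.1) | ~10% preparation uncertainty |
| [R]₀, [L]s (unknown) | Uniform 0.001–1 mM / 0.01–10 mM | instrument-plausible ranges |
| ρ | Uniform(0, 1) | uninformative composition |
| σ | Jeffreys, p(σ) ∝ σ₀/σ, σ₀ = 1 cal | uninformative scale |

The lognormal concentration prior is parameterized as a normal on the log
with s.d. 0.1 (a 10% multiplicative width); the uniform fallback ranges
are in mM, consistent with the stated-value scale of typical experiments
(0.05 and 1.0 mM). All proper priors carry their normalization constants
so Bayes factors across models are meaningful; the improper Jeffreys
factor is common to all models and cancels in ratios.

Samplers operate on an unconstrained reparameterization — log for σ, the
concentrations and ΔΔG, logit for ρ — with Jacobians folded into the
kernel. Densities reported to users are always in the original
parameterization.

## Sampling

The backend is a seeded affine-invariant ensemble sampler (emcee) behind a
kernel-in/draws-out contract; `warmup` and `draws` count total density
evaluations across walkers, so the retained matrix has `draws/thin` rows.
Desk-scale defaults are 2,000 warmup / 20,000 draws / thin 10 with 32
walkers (more for high-dimensional kernels); publication-scale settings
(an order of magnitude longer) are plain config overrides. Walkers start
in a small per-coordinate ball around the initial point — a prior draw by
default, the realized truth for simulation studies, mirroring how the
reference simulations are analysed.

Convergence is monitored with the running-percentile diagnostic: the 5th,
25th, 50th, 75th and 95th percentiles of each marginal as a function of
the cumulative chain fraction, with bootstrap standard deviations (100
resamples by default). Flat traces with negligible errors indicate
converged summaries.

Posterior means converge quickly, but quantile-based summaries (credible-
interval endpoints, medians) decorrelate from the chain's starting point
much more slowly; coverage studies therefore run ~5× longer chains per
fit (10k warmup / 40k draws at desk scale) than recovery studies that
only aggregate means.

Posteriors with a uniform prior on either concentration lie on a broad
concentration–enthalpy compensation ridge (scaling both concentrations and
shrinking the enthalpies leaves the heats nearly unchanged) and can be
multimodal; those fits mix slowly and are run by default with 10× the
warmup and 3× the draws of the informative-prior fits.

## Model selection

AIC = −2 ln L_max + 2k and BIC = −2 ln L_max + k ln N use a multi-start
bounded maximization of the log-likelihood (L-BFGS-B in bound-normalized
coordinates; starts are the top-10 posterior draws by likelihood plus the
MAP draw, because these posteriors can be multimodal). k is 6/8/9 for
2C/RM/EM.

The Bayes factor of a nested pair is the ratio of posterior normalizers.
The smaller model's draws are augmented with i.i.d. draws of the extra
parameters γ (2C→RM: ΔΔG, ΔH₂; RM→EM: ρ; 2C→EM: all three) from a
moment-matched Gaussian proposal f(γ) fitted to the larger model's samples
in unconstrained space, which is what lets a Gaussian respect bounded
parameters such as ρ. Potentials u₁ = −ln[p₁(θ₁)f(γ)] and u₂ = −ln p₂(θ₁,γ)
are evaluated on both sample sets and the log-ratio of normalizers is the
Bennett acceptance ratio (BAR) solution of

    Σ₁ f(M + Δu − c) = Σ₂ f(−(M + Δu − c)),   f(x) = 1/(1+e^x),

with Δu = u₂ − u₁, the sample-size offset M = ln(n₁/n₂), solved by
bracketed root finding to 1e-10 (the root c is −ln(Z₂/Z₁)). A flat-zero
bracket signals non-overlapping sample sets and raises an estimator
failure rather than returning a number. Standard errors bootstrap the Δu
arrays (1000 resamples by default); a convergence trace re-estimates the
ratio on leading fractions of both sets. Bootstrap resampling treats
retained draws as independent, which presumes thinning has removed
autocorrelation.

## Synthetic experiments

`simulate.SimulationDesign` reproduces the reference validation design:
truth ΔG₁ = −11.5, ΔΔG = 4, ΔH₁ = −7, ΔH₂ = −2 kcal/mol, ΔH₀ = 0.5 µcal,
ρ = 0.5; stated concentrations 0.05 mM (cell) and 1.0 mM (syringe) with
realized values drawn lognormally at 10% multiplicative uncertainty per
replicate; i.i.d. Gaussian heat noise. The injection schedule (24 × 12 µL
into 1.3513 mL at 300 K) and the noise s.d. (0.5 µcal per injection, the
same order as ΔH₀) are this package's choices of realistic instrument
conditions — they give a well-formed two-step isotherm with ~4.8× ligand
excess at the end of the titration. Because the original study did not
record its injection schedule or noise level, across-replicate standard
deviations and RMSEs are reproducible in pattern only; aggregated
posterior means are the digit-level quantities.

What the generator does **not** emulate: baseline drift, injection-to-
injection carryover, active-volume corrections, correlated or
heteroscedastic noise, digitization error of published figures. Passing
recovery and calibration tests therefore demonstrate internal consistency
of the inference under the stated noise model, not robustness to real
instrument artifacts.

## Calibration

`calibration.coverage_curve` scores, per parameter and confidence level,
the fraction of replicates whose equal-tailed credible interval contains
the realized truth (the drawn concentrations plus the fixed thermodynamic
values), with bootstrap-over-replicates standard deviations. Exactly
calibrated posteriors put every point on the diagonal up to binomial
noise; the package asserts this quantitatively (3 bootstrap/binomial SEs)
rather than by visual inspection.

## Numerical choices and edge cases

* Equilibrium residual tolerance 1e-10 relative; Newton polish capped at 6
  steps with a bisection fallback; zero receptor or ligand totals are
  handled exactly.
* The fold-ratio conversion is `exp(ΔΔG/(R T))` — the dimensionally
  consistent reading of the affinity-ratio formula (4 kcal/mol ↔ ~858-fold
  and 0.15 kcal/mol ↔ ~1.3-fold at 298 K).
* BAR bracketing starts at the median Δu and doubles outward; failure to
  find a strict sign change within a width of 1e8 raises an error with
  guidance to increase overlap.
* MLE optimizations are run in coordinates normalized by the prior-support
  widths; the raw unconstrained variables span ~8 orders of magnitude.
* The heat-file format stores µL/µcal/mM (instrument conventions); the
  library converts to L/cal/(mol/L) at the boundary.

## Known limitations

* Single-chain sampling by default; between-chain diagnostics (R-hat) are
  not computed unless configured.
* The ensemble sampler explores the uniform-prior compensation ridge
  slowly; desk-scale uniform-prior posterior summaries are approximate
  (their breadth is understated relative to exhaustive sampling).
* No kinetic (differential-power) models, no multi-site or cooperative
  binding, no stoichiometry parameter, no vendor raw-file parsing.
* Bayes factors between well-separated models can be astronomically large
  with proportionally large bootstrap SEs; only their sign and order of
  magnitude are meaningful there.
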