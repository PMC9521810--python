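# itcmix

Bayesian regression and model selection for isothermal titration
calorimetry (ITC) when the titrant contains **two competing ligands** —
typically a pair of enantiomers. Written for experimentalists and
modellers who want honest uncertainty estimates (credible intervals that
behave like confidence intervals) and principled answers to "does this
titration actually support a two-ligand model?".

## What it does

Given integrated injection heats `D = {q_1, …, q_N}`, the package fits
three nested thermodynamic binding models by MCMC:

| model | titrant | parameters θ | k |
|---|---|---|---|
| 2C | one ligand | ΔG, ΔH, ΔH₀, [R]₀, [L]s, σ | 6 |
| RM | 1:1 two-ligand (racemic) mixture | ΔG₁, ΔΔG, ΔH₁, ΔH₂, ΔH₀, [R]₀, [L]s, σ | 8 |
| EM | two-ligand mixture, free composition ρ | RM + ρ | 9 |

with a Gaussian likelihood `p(D|θ) ∝ σ^{-N} exp[−Σ(q_n − q*_n(θ))²/2σ²]`,
lognormal priors on the concentrations when stated values exist (10%
multiplicative width) and uniform fallbacks otherwise. Theoretical heats
`q*_n(θ)` come from the perfusion dilution model and exact equilibrium
solutions (quadratic for one ligand, cubic for competitive binding).

Models are compared by AIC, BIC, and log₁₀ Bayes factors estimated with a
nested variant of bridge sampling: the smaller model's posterior draws are
augmented with draws of the extra parameters γ from a moment-matched
Gaussian proposal, and the ratio of posterior normalizers is computed with
the Bennett acceptance ratio, with bootstrap standard errors.

A synthetic-experiment module reproduces the reference simulation design
(two-step EM isotherm, 10% lognormal concentration perturbations, Gaussian
heat noise) for parameter-recovery and credible-interval-calibration
studies.

## Worked example

```python
import numpy as np
from itcmix import ITCRegressor, ddg_to_fold
from itcmix.simulate import SimulationDesign, simulate_experiment

# one simulated titration: 24 x 12 µL injections, EM truth
# (dG1 = -11.5, ddG = 4, dH1 = -7, dH2 = -2 kcal/mol, rho = 0.5)
data, realized = simulate_experiment(SimulationDesign(seed=123), 0)

est = ITCRegressor(model="EM",
                   stated_r0=data.stated_R0, stated_ls=data.stated_Ls,
                   seed=2, init=realized)
est.fit(data.protocol.injection_volumes.reshape(-1, 1), data.heats)
print(est.summary_.loc[["dG1", "ddG", "rho"], ["mean", "sd"]])
print(f"affinity ratio: {ddg_to_fold(est.posterior_mean('ddG'), 300):.0f}-fold")
```

Output:

```
                mean        sd
parameter
dG1       -11.638412  0.173605
ddG         4.102308  0.127823
rho         0.501431  0.005976
affinity ratio: 974-fold
```

The posterior mean of the binding free energy of the tighter ligand is
−11.64 kcal/mol (truth −11.5), the free-energy gap between the two
enantiomers 4.10 kcal/mol (truth 4), and the syringe mole fraction 0.501
(truth 0.5): with stated concentrations and their 10% uncertainty modelled
explicitly, each is recovered within about one posterior s.d. A gap of
~4 kcal/mol corresponds to a roughly 800-fold affinity ratio at 300 K, so
even modest free-energy differences between enantiomers imply large
selectivity.

The same pipeline is available from the shell:

```bash
itcmix simulate --n-replicates 50 --seed 0 --outdir sims/
itcmix fit sims/sim_000.csv --model EM --outdir fit0/
itcmix compare sims/sim_000.csv --outdir cmp0/   # AIC, BIC, log10 BFs
itcmix recover --replicates 20 --seed 1          # aggregate recovery study
itcmix calibrate --replicates 20 --seed 1        # coverage vs stated level
```

Heat files are plain text (µL, µcal) with `#` metadata lines for cell
volume, temperature and stated concentrations; see `itcmix/io.py`.

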