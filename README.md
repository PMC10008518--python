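# pbpm — population-based projection modeling of PET arterial input functions

Kinetic modeling of dynamic PET data needs the arterial input function
(AIF): the time course of tracer concentration in arterial plasma.  Direct
arterial sampling measures it accurately but is invasive and sparse.  This
package estimates individual AIFs by projecting each subject's blood
samples onto a basis of *population-trained* circulation profiles, so that
a new patient's input function is recovered from a handful of samples —
or, prospectively, from image-derived blood-pool signals.

It is aimed at researchers doing tracer-kinetic analysis of dynamic
FDG / [15O]H₂O / FLT PET studies with arterial or venous sampling data.

## Model

Travel time of a tracer atom from the injection site to the right
ventricle is modeled as Gamma(α, β); convolved with the injection boxcar
I(·) of the recorded duration it gives the right-ventricle profile
C_RV = G ⊗ I.  The excess circulation time to the sampling site is
approximated by a mixture of exponential densities e_j(ξ) = φ_j e^(−φ_j ξ)
with population-shared rates φ₁ > … > φ_J, so the model AIF is

    C_P(t) = Σ_j π_j ∫₀ᵗ e_j(t − s) · (G ⊗ I)(s − Δ) ds

with subject-specific nonnegative mixing weights π and delay Δ, and
population-shared θ = (α, β, φ₁…φ_J).  Fitting is nested: π by
positivity-constrained weighted least squares (a convex QP), Δ by grid
search over ±60 s, θ by Gauss–Newton on a logit-transformed scale with
(π, Δ) re-profiled at every evaluation.  For new subjects θ is fixed and
π can be shrunk toward the population mean π₀ with penalty
λ(π − π₀)ᵀΩ⁻¹(π − π₀), λ chosen by generalized cross-validation.  The
number of components J is selected by leave-one-subject-out
cross-validation; absolute scale is regressed from injection dose, Nadler
blood volume and the fitted tail weight via log S = β₀ + β₁X_ID + β₂X_BV
+ β₃π̂_J.  Tri-exponential (TE) and convolved tri-exponential (CTE)
reference models, 1- and 2-tissue compartment kinetics (K1, k2, k3, VB;
Ki = K1k3/(k2+k3), VD = Ki/k3, Vnd = K1/k2), and a synthetic-cohort
simulator complete the toolbox.

## Worked example

```python
import numpy as np
from pbpm import FitConfig, fit_theta, fit_new_patient, population_prior
from pbpm.simulate import SimulationConfig, simulate_aif_cohort

cohort, truth = simulate_aif_cohort(
    SimulationConfig(tracer="fdg", n_subjects=10, noise_level="medium", seed=1))
popfit = fit_theta(cohort, FitConfig.for_tracer("fdg"))
print("theta_hat =", np.round(popfit.pop.theta(), 3))

new, new_truth = simulate_aif_cohort(
    SimulationConfig(tracer="fdg", n_subjects=1, noise_level="medium", seed=99))
prior = population_prior(popfit.pi_matrix())
fit = fit_new_patient(new[0], popfit.pop, prior=prior)
print("pi_hat =", np.round(fit.indiv.pi, 3), " true pi =",
      np.round(new_truth["pi"][0], 3))
print("delta_hat =", round(fit.indiv.delta, 3), " lambda =", fit.lambda_used)
```

prints

```
theta_hat = [2.142 7.451 6.476 0.49  0.015]
pi_hat = [5.708 1.938 8.573]  true pi = [5.404 2.022 8.533]
delta_hat = 0.2  lambda = 0.0
```

`theta_hat` is the trained population parameter vector (α, β, φ₁, φ₂, φ₃;
rates in 1/min): a ~20 s mean travel time to the heart and three
circulation scales (seconds, ~2 min, ~1 h tail).  The new subject's
mixing weights are recovered close to their generating values, the delay
lands on the +12 s grid point, and GCV selects no shrinkage because the
curve alone already pins the weights down at this noise level.

A command-line interface mirrors the library
(`pbpm simulate | fit-population | fit-subject | select-j | scale |
kinetics | baseline`); see `pbpm --help`.

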