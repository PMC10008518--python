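# Methods

## Model

The arterial input function (AIF) is represented as the projection of a
subject's blood-sampling time course onto basis components built from two
physiologic stages:

1. **Injection → right ventricle.** Travel time is Gamma(α, β)
   distributed.  Convolved with the injection profile — a boxcar of the
   recorded infusion duration — it yields the right-ventricle
   concentration C_RV(t) = (F_G(t) − F_G(t − D))/D, computed analytically
   from Gamma CDFs.
2. **Circulation to the sampling site.** A site-specific delay Δ plus an
   excess circulation time whose density is a J-component mixture of
   exponentials with shared rates φ₁ > … > φ_J.

The model curve is C_P(t) = Σ_j π_j A_j(t|Δ,θ) with
A_j(t) = ∫₀ᵗ φ_j e^(−φ_j(t−s)) C_RV(s−Δ) ds.  Weights π ≥ 0 and Δ are
subject-specific; θ = (α, β, φ₁…φ_J) is population-shared.

**Boxcar normalization.** The injection boxcar has unit area (height
1/D), so mixing weights are comparable between 1- and 2-minute infusion
protocols; absolute activity scale is carried by π and the separate scale
factor.  This is a convention — only the scale of π changes under the
unit-height alternative.

**Negative delays.** The defining integral starts at s = 0.  A delayed
component is therefore not a pure time shift of the undelayed one when
Δ < 0: the segment of circulation occurring before the clock started must
be excluded.  This has the exact form
A_j(t|Δ) = A_j(t−Δ|0) − A_j(−Δ|0)·e^(−φ_j t), applied analytically.

## Numerics

C_RV is evaluated on a uniform grid (step 1/480 min = 0.125 s) and
convolved with each exponential kernel by an exact first-order recurrence
(the kernel is integrated in closed form against the piecewise-linear
interpolant of C_RV; the recurrence runs as an IIR filter).  Model values
at sample times come from Catmull–Rom (cubic) interpolation of the grid —
the basis bends sharply at the injection rise, where linear interpolation
would dominate the error budget.  With these choices the forward model
agrees with brute-force quadrature of the defining integrals to better
than 1e−4 relative error on the body of the curve across wide parameter
sweeps; discontinuous inputs (a step at t = 0) carry an O(step) onset
error instead.

Fitting is nested exactly as the objective is defined:

* **π | (Δ, θ):** weighted positivity-constrained least squares.  The QP
  is solved by reduction to NNLS (active-set; exact minimizer).  The
  optional ordering constraint π₁ ≥ π₂ is folded in by the nonnegative
  reparametrization π₁ = u₁ + u₂, π₂ = u₂.
* **Δ | θ:** exhaustive search over 21 delays spanning ±1 min (±60 s).
  Ties within 1e−12 (relative) break toward |Δ| smallest, for
  deterministic output.
* **θ:** trust-region Gauss–Newton (`scipy.optimize.least_squares`,
  numerical Jacobians) on the logit scale
  ς = log(p/(1−p)), p = (θ−θ_L)/(θ_H−θ_L), with (Δ_k, π_k) re-profiled at
  every evaluation.  Returned rates are sorted into the identifiability
  ordering.  Default bounds are wide (α ∈ [0.5, 20], β ∈ [0.1, 60]/min,
  φ ∈ [1e−3, 20]/min) and should be reviewed per tracer.
* **Shrinkage:** the penalty λ(π−π₀)ᵀΩ⁻¹(π−π₀) is folded into the same
  NNLS by augmenting the design with √λ·R, RᵀR = Ω⁻¹.  Ω is the sample
  covariance of training weights, ridge-conditioned (ε·I with
  ε = 1e−8·trace/J) when near-singular.  λ = 0 reproduces the
  unpenalized path bit-for-bit.
* **GCV:** score = MSE / (trace(I − A(AᵀA + mλI)⁻¹Aᵀ)/m)², evaluated at
  the penalized fit's Δ̂ on the ladder {0} ∪ 10^{−4…3} (15 points).  The
  hat-matrix in this formula omits W and Ω (as defined); the penalized
  objective itself does not.

**Component-number selection** leaves one subject out, re-estimates θ on
the rest, and scores the held-out subject's best-case weighted residual
(normalized by its sample count); Err(J) sums over subjects.  Fold fits
are warm-started from a preliminary full-cohort estimate — the fold
objective and minimizer are unchanged; only iterations are saved (checked:
Err values agree to 3 significant digits with cold starts).  The elbow
rule picks the smallest J whose relative error drop to J+1 falls below a
threshold.  The threshold must respect the criterion's stochastic floor:
profiling one extra mixing weight on the held-out curve absorbs roughly
1/(m − p) of residual noise even when the component is redundant (~4–5%
for a 26-sample frame), so a fixed cutoff near that value is a coin toss.
The effective cutoff is therefore max(configured threshold [default 5%],
2/(m̄ − J − 1)) — twice the expected no-gain drop — which separates
genuine circulation scales (observed drops ~90%+) from noise absorption
(~2–8%).  Selection conclusions are still best drawn modally over
replicate cohorts.

**Scale factor.** log S is regressed on injection dose (mCi), total blood
volume (litres, sex-specific Nadler formula from weight and height) and
the fitted tail weight π̂_J, by ordinary least squares with R², residual
sd and design condition number reported.  Units of the covariates are
part of the model definition; coefficients are reported in those units.

**Kinetics.** The 1C/2C compartment systems are solved analytically
through the eigen-decomposition of the rate matrix; each exponential mode
is convolved with the (delay-shifted) input by the same exact-kernel
recurrence.  k₂+k₃ = 0 degenerates to pure accumulation.  The measured
signal is C = (1−V_B)(C₁+C₂) + V_B·C_p(t−delay) — a standard spillover
convention.  Fits estimate (K1, k2[, k3], V_B) with k4 fixed at 0 and the
delay held constant; macro-parameters Ki = K1k3/(k2+k3), VD = Ki/k3,
Vnd = K1/k2 (equal for metabolically inert tracers).  The simulation
scenario delays are 0.25 s (H₂O) and 0.2667 s (FDG) as printed in the
source scenarios — implausibly small for real studies and possibly a
units misprint; they are applied verbatim and are configurable.

## Synthetic-data generator

The generator defines the study conditions; its defaults were chosen once
to emulate clinical arterial curves and are not tuned per experiment.

* **Ground truth.** FDG/FLT: θ = (α=3, β=9/min, φ = 8, 0.5, 0.015/min),
  π ~ N((5, 2, 8), diag((0.2·mean)²)) truncated nonnegative — a ~20 s
  travel time, a sharp first-pass peak, a ~2-min redistribution scale and
  a slow tail at a few percent of peak, matching the canonical FDG AIF
  shape.  H₂O: θ = (3, 9, 6, 0.3), π ~ N((5, 2), ·) on the 5-minute
  frame.  Delays are N(0, 0.15 min) clipped to ±0.9 min.  Sampling frames
  and infusion durations are the tracers' median clinical protocols
  (26-point/90-min FDG frame with 1-min infusion; 30-point/5-min H₂O
  frame with 5-s bolus; 25-point FLT frame).
* **AIF noise** emulates fit residuals of sampled curves: Gaussian with
  sd = level·0.05·(signal + 0.01·peak); medium = level 1, low/high =
  0.5/2.  Curves carry the matching reliability weights w ∝ 1/sd²
  (normalized to mean 1), as clinical sampling curves carry per-sample
  reliability.
* **Tissue curves** are compartment-model templates normalized to unit
  peak with Gaussian noise sd = φ·g(z); g(z) = z by default (the printed
  noise model), g(z) = √z selectable (counting-statistics variant);
  φ = 0.001 (H₂O) and 0.04 (FDG).
* **Determinism.** Every routine takes an explicit seed; per-subject
  streams are spawned from the master seed, so cohorts are bit-identical
  across runs (floating-point results may differ across BLAS builds).

**Delay discretization protocol.** Experiments whose conclusions concern
noise response, component count, or population-vs-individual training
(recovery, selection, population-gain) draw the true delays *on* the
21-point fitting grid.  With off-grid delays the dominant residual at the
steep injection rise is sub-grid delay quantization, which an extra fast
mixture component — or individually re-tuned (α, β) — can absorb; that
confounds exactly the comparisons those experiments make.  The
kinetic-bias experiment keeps continuous delays (realistic AIF estimation
error is its point).  This is a known limitation of grid-based delay
estimation on steeply rising curves, not of the mixture representation.

**Kinetic bias inference.** In the AIF-substitution experiment every
evaluation subject is fitted under the same trained θ̂, so kinetic errors
are cluster-correlated within a cohort.  The experiment therefore
replicates the whole pipeline (training population, evaluation subjects,
tissue noise) over independent cohorts (default 6) and tests the
cohort-level added bias — the per-cohort median difference between
estimated-AIF-driven and true-AIF-driven signed percentage errors — with
a Wilcoxon signed-rank test across cohorts.

**Population-gain cross-validation** follows the leave-one-sample-out
definition strictly: the held-out sample is predicted after refitting
everything a path estimates from the curve itself — (π, Δ) for the
population-trained path, (θ, π, Δ) for the fully individual path
(interior samples strided by 4 to bound cost).  Freezing θ in the
individual path would leak the held-out sample through θ̂ and reverse the
comparison.

**What passing does not show.** The generator draws from the model's own
family with Gaussian noise and known reliabilities.  Real arterial data
add dispersion, metabolite buildup, plasma-to-whole-blood differences,
calibration drift and non-Gaussian counting noise; performance on such
data is not established by these experiments.

## Known limitations

* **Ki bias under the irreversible-fit convention.** FDG tissue templates
  are generated with k₄ = 0.0068/min but fitted with k₄ = 0 (the
  scenario's convention).  Over the 90-min frame this mismatch alone
  biases Ki by about −18% (and k₃ by ~−38%) even on noise-free data, so
  absolute Ki accuracy in the FDG scenario is bounded by the convention,
  not by the AIF.  The bias is common to all AIF sources, so *comparisons
  between* AIFs remain meaningful; it shrinks with shorter fitting
  windows.
* Delay estimation is grid-limited (no continuous Δ refinement), with the
  consequences described above.
* The GCV formula's effective-degrees-of-freedom term ignores the weights
  and the prior covariance; it is implemented as defined.
* Reduced default replication counts (e.g. 20-replicate selection
  studies, 40 evaluation curves in the population-gain comparison) keep
  the experiments desk-scale; all counts are arguments.
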