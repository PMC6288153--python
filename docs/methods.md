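# Methods

## Models

Four ODE models of reporter translation after an mRNA bolus are implemented
in identifiable parameter combinations (mRNA normalized by the transfected
amount m0; the fluorescence scale absorbed into the GFP state g, so the
observable is `y = log(g + offset)` with no free scale):

* **(i) standard**: `dm/dt = −delta·m`, `dg/dt = kappa·m − gamma·g` with
  `kappa ≡ k·m0·scale`.  The bolus raises m by exactly 1 at `t0`; all states
  are zero before `t0` (pools at their initial values).  The solution is
  available in closed form, including the `gamma → delta` limit
  `g = kappa·u·e^{−delta·u}` (used when the relative rate difference is
  below 1e−8, avoiding catastrophic cancellation).
* **(ii) ribosome-limited**: a finite free-ribosome pool `r` (initial
  `r0m0 ≡ R0/m0`) binds mRNA at `k1m0 ≡ k1·m0` into a complex `c` that
  translates at `k2`, producing GFP with amplitude `k2m0scale`; `r + c` is
  conserved.
* **(iii) enzymatic degradation**: an enzyme pool `e` (initial `e0m0`) binds
  mRNA at `delta1m0` and destroys the bound mRNA at `delta2`, recycling the
  enzyme; `e + em` is conserved.
* **(iv)** both extensions combined.

Only free mRNA is subject to the first-order decay `delta` in (ii)/(iv);
complexed mRNA is protected.  A consequence worth stating: in the
ribosome-saturated regime (`k1m0·r0m0 ≫ k2 ≫ gamma`) model (ii) reduces to
model (i) with `kappa = k2m0scale` and an mRNA decay slowed by the bound
fraction, `delta/(1+ρ)` with `ρ = k1m0·r0m0/k2` — the reduction tested in
the suite uses this exact correspondence with a negligible `delta`.

Numerical integration uses LSODA with rtol 1e−8 / atol 1e−10, split at `t0`
with an exact state jump; these tolerances sit well below every test
threshold (the closed form and the integrator agree to < 1e−6 on the default
181-point grid).  Time is in hours, all rates in 1/h.

## STS baseline

Stage 1 maximizes, per cell, a Gaussian likelihood on the log scale with the
noise variance profiled out analytically (`sigma2_hat` = mean squared
residual, divisor n_t — a single cell has no replicates, so no empirical
variance estimator exists).  The concentrated objective is
`(n_t/2)(log(2π·σ̂²)+1)`, minimized over log-parameters in a positive box
(default 1e−4…1e4 per parameter, t0 in 0.05…5 h capped by the observation
window) from Latin-hypercube multi-starts (default 20); ties break by lowest
objective then lowest start index, so fits are reproducible.  A floor of
1e−12 on σ̂² prevents a −∞ objective on degenerate perfect fits, and fits at
a box boundary or at the floor are flagged rather than silently returned.
Stage 2 builds a Gaussian KDE (Silverman bandwidth, floor 1e−3 for
degenerate samples) of the log estimates per parameter and per experiment;
experiments are never pooled.

## NLME estimation

Cell parameters are `φ_i = exp(β^e + b_i)`, `b_i ~ N(0, D^e)` with diagonal
`D = diag(exp(d_log))` (matrix-log parameterization — positive definite with
no constraints).  By default every model parameter carries a random effect;
the sharing map can restrict this, and marks which effects are
experiment-specific (study default: only `gamma`).  Measurement noise is one
log-σ fixed effect per experiment, estimated in the outer problem: per-cell
profiling of σ inside a marginal likelihood is degenerate, and a shared σ
matches the additive-log-noise observation model.

The Laplace marginal per cell is
`ψ(b̂) − (n_b/2)·log 2π + ½·log det H ψ(b̂)` with `b̂ = argmin ψ`, which is
exact for joint densities Gaussian in b (verified against the closed-form
marginal to 1e−8) and accurate to < 1% against adaptive quadrature for
nonlinear single-random-effect cells.  The Hessian is the central finite
difference of the analytic inner gradient (step `1e−4·(1+|b̂|)`), with a
scale-relative jitter ladder (1e−8…1) and an eigenvalue-floor fallback when
it is not positive definite; any jitter is recorded per cell.

For model (i) on a common time grid the whole objective is vectorized across
cells: inner problems are solved jointly by damped Gauss-Newton with
analytic gradients (full Newton steps once a cell's gradient is small —
objective comparisons near the mode fall below floating-point resolution),
and the objective cold-starts the inner modes on every call so it is a pure,
deterministic function of the outer vector.  The transfection-onset
parameter makes ψ piecewise smooth in b; cells whose mode sits at a
sample-time kink retain a small residual gradient, which is structural and
is not counted as a solver failure.  Those same kinks — and occasional
switches between inner modes of near-symmetric cells — make *numerical*
outer gradients unreliable (a finite-difference step can straddle an O(1)
objective discontinuity), so the outer gradient is computed analytically:
the envelope theorem at the inner modes gives the ψ derivatives exactly,
and the Gauss-Newton log-determinant is differentiated exactly in the
random-effect variances and the noise (via `tr(H⁻¹ ∂H)`), neglecting only
the dependence of the data curvature J on the fixed effects — a small,
smooth bias.

During outer exploration the Laplace log-determinant uses the Gauss-Newton
curvature (it coincides with the finite-difference Hessian as residuals
vanish); the winning start is then polished against the finite-difference
curvature (same analytic gradient), and all reported quantities (total NLL,
per-cell results) are recomputed with the finite-difference curvature.  The
outer problem is unconstrained (log coordinates throughout) and solved with
L-BFGS-B from multiple starts: two data-driven centers from a quick STS
pass on a subsample — one per assignment of the first experiment's low/high
rate cluster to delta, resolving the swap ambiguity — plus seeded uniform
perturbations.  Starts with > 20% inner non-convergence are marked crashed
and excluded from ranking.  Desk-scale default is 10 starts; the acceptance
pipeline uses 2 (both informed centers), which on the synthetic design
reach the same basin.

Empirical-Bayes single-cell parameters are `exp(β^e + b̂_i)`; cells whose
inner problem did not converge keep a flag in their result.

## Diagnostics and selection

* **Profiles** fix one parameter on a grid and re-optimize the rest with
  continuation (warm start from the neighboring grid point) plus a restart
  from the global optimum; for model-(i) STS rate profiles the δ↔γ-swapped
  optimum is an additional start, so the mirror branch is always found.
  Continuation can lag behind the true profile (hysteresis), so refinement
  sweeps re-polish every point from any better neighbor until no point
  improves.  The NLME fixed-effect profile warm-starts the inner modes
  along the continuation, drives the re-optimization with the analytic
  outer gradient, and uses the Gauss-Newton curvature (the modality
  conclusion is curvature-insensitive).  Modality counting requires a well
  to sit ≥ 2 objective units below both flanking barriers — deep enough to
  be statistically meaningful, robust to re-optimization noise; a dip at a
  grid endpoint has no outer barrier and is not counted.
* **Residual time profiles** report the cross-cell mean and population-sd of
  observed-minus-fitted log-fluorescence per time point and experiment; a
  systematic temporal trend under model (i) on ribosome-limited data is the
  suite's model-mismatch check.
* **AIC/BIC** use `2·nll + 2k` and `2·nll + k·log(n_obs)` with `k` the
  number of population-level quantities and `n_obs` the total number of
  scalar observations (cells × time points); with random effects integrated
  out, the observations are the likelihood's independent factors, which is
  the convention adopted here.
* **Replicate significance test**: subset log-likelihood standard deviations
  (sample formula) are extrapolated to the full experiment by dividing by
  `sqrt(fraction)` (the log-likelihood is a sum of independent per-cell
  terms, so its *variance* scales with cell count — fraction 1/3 gives the
  factor 1.732); model pairs are compared by a two-sided normal test on the
  log-likelihood difference with the two sds combined in quadrature,
  assuming independence (the conservative simple choice).
* **Batch factors**: for each replicate and each m0-containing combination
  `p` with exponent `s_p` (model (i): kappa → +1; model (ii): k1m0 → +1,
  k2m0scale → +1, r0m0 → −1), `exp(s_p·(β_r,p − β_ref,p))` estimates the
  batch's fold change in transfected mRNA; the consistency score is the
  largest within-replicate coefficient of variation across parameters (0 for
  a pure m0 shift).

## Synthetic data

The generator emulates the study conditions the analysis assumes: two
constructs (eGFP/d2eGFP) differing only in γ, sampling every 10 min over
30 h (181 points), transfection onset near 1 h, lognormal cell-to-cell
variability, additive Gaussian noise on the log observable (the log of
multiplicative intensity noise) over a constant background offset, and three
replicates whose batch effects are a common multiplicative m0 shift applied
exponent-aware to the m0-containing fixed effects (factors 1, 1.5, 0.7).
Default medians — δ 0.2/h, γ_eGFP 0.03/h ≪ γ_d2eGFP 0.3/h, kappa 100 a.u.,
t0 1 h, offset 10 a.u., random-effect sd 0.3 (log scale), σ 0.05 — are
invented desk-scale constants chosen to qualitatively mimic a stable eGFP
plateau versus a declining d2eGFP signal; they are not fitted estimates.
Desk scale means 50 cells per construct (the real assay records hundreds);
the suite's recovery tolerances reflect that size.

What the generator does **not** emulate: time-distributed lipoplex delivery
or GFP maturation (both would smooth the onset), enzyme/ribosome copy-number
noise beyond lognormal parameter variability, image-level artifacts, or
correlated random effects (D is diagonal by assumption).  Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to these real-data features.

## Numerical choices and limitations

* Inner convergence: gradient inf-norm ≤ 1e−8, kink-limited cells accepted
  at ≤ 1e−3 (gradient scale ~1e3); simulation failures inside the joint
  density return a large finite penalty (1e10 + ‖b‖²) so the inner optimizer
  survives.
* Outer optimization: ftol 1e−9 (exploration) / 1e−10 (polish), fd step
  1e−6.
* Laplace with a diagonal-D, unimodal-posterior assumption: for cells whose
  inner posterior is genuinely bimodal (the per-cell swap symmetry within
  one experiment), the Laplace mass at one mode underestimates the marginal;
  this inflates the apparent random-effect variance of the symmetric rate
  pair somewhat — visible in the suite's recovery test, where the δ/γ
  random-effect sds are biased upward while remaining within the factor-2
  recovery band.
* Model (ii)–(iv) fits go through the generic per-cell path (solve_ivp per
  evaluation) and are an order of magnitude slower than model (i); the suite
  exercises them at reduced sizes.
* No stochastic (chemical-master-equation) simulation, no full-D estimation,
  no MCMC beyond the 1-D quadrature oracle, and no SBML import; SBML export
  is not implemented (states/reactions/events are documented here instead).
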