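# Methods

## The trafficking model

The body is a closed, linear compartment system. A central blood pool
(volume `V_h`, concentration `C_h`) feeds every organ in parallel. Organ
*o* has a vascular space (`V_o`, `C_o`) perfused at blood flow `B_o` and
an interstitial space (`Ṽ_o`, `C̃_o`) reached by extravasation. For a
generic organ,

    V_o  dC_o/dt = B_o (C_h − C_o)
    Ṽ_o dC̃_o/dt = e_o B_o (C_o − μ_o C̃_o)

where `e_o ∈ [0, 1]` is the probability that a transiting cell
extravasates rather than returning to the circulation and `μ_o > 0` is a
return fraction: `e_o μ_o B_o C̃_o` is the lymphatic efflux rate. Three
wiring features depart from the parallel template:

* **Portal system.** Spleen, stomach and small intestine drain venously
  into the liver. The liver is perfused by its arterial flow plus the
  portal flows; its effective flow is `B′_L = B_L + Σ_portal B_m` and its
  extravasation acts on the full perfusion.
* **Lymph node.** By default every organ's lymph passes through the
  lymph-node interstitium before returning to the heart. The node's
  effective interstitial throughput is its own drainage plus the total
  afferent flow `L = Σ_routed e_o μ_o B_o`; the matching efferent flux
  `(e_LN μ_LN B_LN + L) C̃_LN` returns to the blood pool, so mass is
  conserved exactly. A per-organ switch routes lymph directly to the
  heart instead.
* **Pulmonary circuit.** Modelled as a parallel organ whose blood flow
  equals cardiac output — an approximation of the anatomical series lung
  that keeps every organ on the same equation template while retaining
  separate parameters for the pulmonary circuit and the bronchial (lung
  blood supply) circulation.

The system is `dx/dt = A x` with `x = [C_h, C_o…, C̃_o…]`. `A` is built
from a flux matrix whose volume-weighted columns sum to zero, so total
cell number is conserved to round-off; this invariant doubles as the
accuracy monitor for the fast propagator (below).

**Observables.** Measurements emulate whole-organ radiolabel counts as
fractions of the injected dose: `Blood = V_h C_h / dose` (central pool
only), `Lungs` = the summed content of both lung organs (one measurement,
two organs — a deliberate asymmetry between data and parameters), every
other organ = its vascular plus interstitial content. With all organs
observed the curves sum to 1.

**Physiology table.** The constants ship as a versioned CSV
(`celltraffic/data/rat_physiology.csv`): total blood volume 20 mL
(12 mL central pool), cardiac output 200 mL/h, eight organs. The values
are a self-consistent rat-scale set chosen for plausible relative organ
sizes and flows; every experiment uses the same table for truth and fit,
so conclusions about *recovery* do not depend on the absolute values.

## Numerics

* `simulate` offers stiff-capable adaptive integration (LSODA default,
  BDF/Radau optional, rtol 1e-8 / atol 1e-12) and an exact LTI fast path
  (`method="expm"`): one eigendecomposition of `A`, all output times in a
  single product. If the conservation check (total content within 1e-8 of
  the dose) fails — a symptom of a near-defective `A` — the fast path
  falls back to incremental matrix exponentials. Fitting, sensitivity and
  MCMC loops use the fast path (~0.3 ms per evaluation on the 17-state
  system); tests cross-check it against the ODE integrator and against an
  independently hand-built matrix exponential.
* States at `t = 0` are returned exactly as the initial condition: the
  eigenbasis reconstruction otherwise leaves ~1e-18 residue in
  compartments that should be exactly empty, which matters because the
  proportional-noise likelihood excludes *exact* zeros.
* `steady_state` solves the null space of `A` and normalises to the dose;
  it requires all `e_o > 0` (otherwise interstitia decouple and the null
  space is degenerate, which is reported as such).

## Synthetic data

Datasets copy the structure of classic rat radiolabel studies: the
initial condition (all cells in blood) plus eight time points over 24 h,
first at 30 min. The default grid {0, 0.5, 1, 2, 4, 8, 12, 18, 24} h is a
log-leaning spread; only the count, the first and the last point are
fixed by the reference design, the interior spacing is this package's
choice and is recorded in provenance.

Noise is multiplicative Gaussian: each measured value is scaled by an
independent `N(1, σ)` draw, default σ = 0.1. The initial-condition row is
a known experimental condition, never noised. Negative noised values
abort generation (no truncation or resampling); at σ = 0.2 the
per-multiplier probability of that is the Gaussian CDF at zero, 2.9e-7.

`default_truth` returns documented per-organ base values jittered by a
seeded factor of at most √2 (uniform in log2). The base set is chosen so
the timescale table (below) shows the reference structure on the default
system: pulmonary-circuit dynamics complete before the first datum,
lung-blood-supply, small-intestine-return, lymph-node-entry and
skin-return dynamics extend beyond the last. The jitter range provably
preserves the fastest and slowest flags, so every seed exhibits the
phenomenology while spanning distinct truths.

Degraded variants: `subsample_times` keeps k post-initial points chosen
by exhaustive search to maximise the minimum gap (ties to later times,
final point always kept); `censor_organs` removes curves *after*
generation, so unobserved localisation exists and downstream fitting
lumps the censored organs under one shared (e, μ) pair; `reduced_system`
removes organs from the model itself, with wiring degrading gracefully
(portal organs without a liver, lymph without a node, both revert to the
heart).

## Analytic estimates

Writing `Ñ_o = Ṽ_o C̃_o`, integrating the interstitial balance and
neglecting the return term gives the near-`t = 0` seed
`e⁰ = ΔÑ / (B ∫ C dt)`; the equilibrium ratio gives `μ⁰ = C/C̃` at the
last time. A fixed-point refinement restores the neglected terms.
Data-side quantities come from the curves alone: `C_h` from the blood
curve, organ vascular concentration approximated by `C_h` (vascular
spaces equilibrate fast), interstitial content as the observable minus
the estimated vascular share, trapezoid quadrature on the data grid.

Implementation findings that shaped the estimators:

* `e⁰` is evaluated at the earliest time **after ~5 vascular time
  constants** (`5 V_o/B_o`), not blindly at the first datum: before
  vascular equilibration the content split is meaningless and the
  estimate is wild even on dense noise-free data. On the default 8-point
  grid this is the first datum anyway.
* The refinement updates only organs whose observable maps one-to-one
  onto their own interstitial balance. The lumped lung curve and the
  pass-through lymph node violate that balance; their refined iterates
  diverge to the domain boundary, so they stay at their initial
  estimates, flagged `frozen_approximate`. The liver uses its effective
  flow and a portal-diluted vascular concentration and refines stably.
* Updates are applied Gauss–Seidel (μ uses the freshly updated e) with
  geometric damping, and the e-integral stops at ~3 interstitial time
  constants — past equilibration the integrand is a cancellation of
  near-equal terms and only amplifies approximation error. Non-positive
  denominators or update values freeze that organ at its last valid
  value, flagged.

On dense fixtures spanning the organ timescales the refinement is a
strong contraction (sup-norm log-error typically 0.5 → <0.1, and it
recovers from a 2× perturbation of every parameter); on a sparse 24-h
grid it cannot improve parameters whose timescales the data never see —
which is the package's subject matter, not a defect. Estimates are seeds
for fitting, nothing more.

## Least-squares fitting

The score is the plain unweighted sum of squared differences between
model and data over all curves and times. `fit_organwise` sweeps the
organs, optimising one organ's free (e, μ) at a time against the *total*
score (bounded L-BFGS-B in log10 space; e ∈ [1e-6, 1], μ ∈ [1e-6, 1e3]),
until a sweep improves the total by less than 1e-10 or 20 sweeps.
`fit_global` is basin hopping: joint local minimisation, then a
log-normal hop of 0.5 decades per parameter accepted by a Metropolis rule
whose temperature is the current score; zero hops degenerate to a single
joint minimisation. The recommended pipeline — analytic seed → organ-wise
sweeps → short global polish — reaches total scores of 1e-6…1e-8 on
noise-free 8-point data in seconds.

`local_covariance` is the classical curve-fit uncertainty: a
finite-difference residual Jacobian at the fit, `cov = s² (JᵀJ)⁺` with
`s² = RSS/(n − p)`. Zero-sensitivity parameters get infinite variance and
a rank-deficiency flag. The diagonal square roots are reported as
"standard deviations" precisely because that is the readout under
scrutiny: it measures local curvature of the score, not parameter
uncertainty, and its bands need not contain the truth.

## Identifiability diagnostics

* **Sensitivity matrix**: each free parameter perturbed by +1% (one-sided
  downward at the e = 1 boundary, flagged); the absolute change of each
  curve's score recorded as a fraction of that curve's base score
  (absolute change where the base is zero, e.g. at a noise-free
  optimum); a per-curve normalised variant sums each column to 1.
* **Timescale table**: `τ_e = V_tot/(e B′)` and `τ_μ = Ṽ/(e μ B′)` per
  organ, flagged against the data window [0.5, 24] h. Parameters whose
  timescale falls outside the window cannot move the model inside it and
  are the predicted recovery failures; the recovery report cross-tabulates
  fitted/true ratios against these flags. "In-window" in tests means both
  of an organ's timescales are inside.
* **Grid cost**: `n_levels ** n_params` evaluations; the 3-level,
  20-parameter default is 3.5e9 evaluations ≈ 110 years at 1 s each.

## Bayesian MCMC

The likelihood is Gaussian with per-datum standard deviation `σ·d`
(noise proportional to the measurement); data equal to exactly zero are
excluded as carrying no proportional-noise information. Parameters are
sampled as log10 values — the prior is Gaussian there (sd 0.5 decades, so
±1 sd spans one decade) centred on the analytic initial estimates and
truncated to the fitting bounds, which makes a log-space random walk
Jacobian-free. σ is fixed to the generating value by default;
`infer_sigma` adds log10 σ as a sampled parameter.

The sampler is adaptive-covariance random-walk Metropolis: proposal
`N(0, λ · 2.38²/d · Σ)`. The scalar scale λ adapts toward acceptance 0.23
from the first step with schedule `n^-0.6`; after burn-in (1000 samples)
Σ tracks the running sample covariance with weight `n^-0.7`. The
covariance weight is deliberately faster than a plain running average: a
1/n schedule freezes before the posterior's soft directions are
discovered (verified against Gauss–Newton widths) and leaves chains
under-dispersed. Three chains start at independent prior draws; after
every 5000-iteration cycle the per-parameter Gelman–Rubin statistic
`R̂ = √(((n−1)/n·W + B/n)/W)` is computed on the post-burn-in
concatenation; sampling stops at max R̂ ≤ 1.1 or a cycle cap (returned,
flagged unconverged). An impossible proposal (−∞ posterior) is never
accepted.

Posterior readouts follow the uncertainty protocol under study: the
best (highest-posterior) sample; the standard deviation of the three
chains' endpoint values per parameter; and last-cycle density shape —
*peaked* if the pooled log10 IQR is ≤ 0.25 decades, *multimodal* if the
per-chain medians disagree by more than the pooled IQR and 0.2 decades,
otherwise *diffuse*. The thresholds are package choices, documented here,
chosen once on the Gaussian oracle scale (a well-identified parameter at
σ = 0.1 concentrates well below 0.25 decades; a prior-dominated one
spans ~0.7).

**A calibration caveat the tests surface honestly.** With a well-mixed
sampler the posterior is approximately calibrated, so the distance from
the best sample to the truth is itself about one posterior sd; a 1-sd
band estimated from three endpoint draws then covers the truth only
~55% of the time in theory, and ~40% in our measured runs. Coverage
approaching "typically overlaps" requires *over*-dispersed (slowly
mixed) chains. The acceptance test for endpoint-sd coverage therefore
fails at the 80% level by design of the statistics, not by a sampler
defect — the companion density-shape test, which is the readout that
actually separates identifiable from unidentifiable parameters, passes.

## Problem sizes used in tests

Unit tests run on one-organ systems and the 8-organ rat system with the
8-point grid. Acceptance tests use 5 truth seeds for recovery studies,
3 seeds for MCMC on the full system (12-cycle cap ≈ 1.8e5 samples per
run) and the 3-organ reduced system for the convergence check; the
5-d correlated-Gaussian oracle runs 20 cycles. These sizes keep the
whole suite within a few minutes while leaving every qualitative
conclusion seed-robust.

## Known limitations

* The noise model is purely multiplicative Gaussian; counting statistics,
  radiolabel decay and harvest error are out of scope.
* The lung is parallel, not series; the blood observable is the central
  pool only. Both are stated approximations of the underlying anatomy.
* Analytic estimators for the lungs and lymph node are first-pass
  approximations (frozen during refinement) — by construction those
  observables do not identify their organs' balances.
* Profile likelihoods are not implemented; MCMC is the global instrument.
* Real datasets enter as tidy CSV but no real-data fits ship with the
  package.
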