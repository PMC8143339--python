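# Methods

This note documents the model, the numerical and statistical conventions the
package fixes, and the design decisions taken where the published description
leaves the choice open.

## Model structure and assumptions

The system has 24 states: drug depot and central amounts; the shared
precursor T₁; the pathway transit compartments T₁a (TNF-α), T₁b–T₇b (IFN-γ),
T₁c (IL-10), T₁d–T₆d (IL-6); four cytokine concentrations; and the two
transaminase activities.  Units are fixed package-wide: drug mg·L⁻¹,
cytokines ng·L⁻¹, transaminases U·L⁻¹, time h, doses mg·kg⁻¹.

Key structural assumptions, kept exactly as in the published model:

* **The drug acts early.** Inhibition (Imax/IC50 on the serum drug
  concentration, Imax fixed at 1) applies only to the *input* of the first
  compartment of the TNF-α, IFN-γ and IL-6 pathways — consistent with
  PDE4/7 inhibitors suppressing cytokine gene transcription rather than
  clearing circulating protein.
* **Dimensional asymmetry of the pathway input.** T₁ feeds the first pathway
  compartments *without* a 1/τ factor, while every downstream transfer (and
  the IL-10 precursor) carries 1/τ.  This is deliberately not "fixed": the
  published parameter values were estimated under this exact form, and for
  the linear cytokine responses any constant rescaling of the input is
  absorbed by the stimulation coefficient S without changing the dynamics'
  shape or timing.
* **Baseline constraint.** Every production constant is derived as
  kin = R0·kout, so the unchallenged system is exactly stationary at its
  baselines.  The unperturbed steady state is conserved to solver tolerance
  over arbitrary horizons (tested to 100 h).
* **IL-10.** After the challenge an additional zero-order production
  kin_IL10(dis) switches on, modulated by F = 1 + T₁c·S_IL10 − C_IFNγ·I.
  F is *not* clamped — its transient negative excursion (IFN-γ inhibition
  outrunning the precursor stimulus) is what produces the observed IL-10 dip
  near 5 h — but the *total* IL-10 production rate is floored at zero so the
  concentration cannot be driven negative.  The switch is tied to the ConA
  event actually occurring, not to the clock: simulations without the
  challenge keep IL-10 at baseline.
* **Disease part.** The ALT/AST driving excesses (C − R0) are clamped at
  zero before the power/linear stimulation terms.  In exact arithmetic the
  cytokines never fall below baseline (production is stimulated, never
  inhibited, below R0), so the clamp only guards against transient solver
  undershoot producing non-real powers with α = β = 1.5.
* **PK.** Bioavailability F is not separately identifiable after IP dosing
  and is folded into Vd/F; amounts are per kg body weight.  The closed-form
  Bateman solution is used wherever only the drug is needed (generator,
  PK fit) and agrees with the integrated ODEs to ≤1e−8 relative (tested).

## Event handling and integration

The ConA challenge is a discontinuity: T₁ jumps from 0 to 1 at
`cona_time` (0.5 h after dosing).  The integrator is restarted at the event
(integrate [0, cona_time], set T₁ := 1, continue), which is the only correct
treatment of a state jump; all other states are continuous across it
(tested).  The default integrator is LSODA with rtol 1e−8 / atol 1e−10,
both configurable.  Under control conditions the transit chains have the
closed form Tₙ(s) = sⁿ/(n!·τⁿ⁻¹)·e^(−s/τ) (s counted from the challenge),
which the numerical solution matches to ≤1e−6 relative at the peak — the
package's main solver-correctness oracle.

Peak times are located on a 0.01 h output grid and refined by a quadratic
fit through the three points bracketing the grid maximum (ties broken toward
the earliest time); the result is stable to ±0.01 h under tenfold tighter
tolerances.  Cytokine peak *times* are provably invariant to the choice of
baselines and to any constant rescaling of the pathway input (the response
is R0 + const·convolution), so they are comparable across laboratories;
ALT/AST peak times do depend on the absolute baselines, which were not
published — with the package's default baselines they fall at 7.1 h (ALT)
and 8.2 h (AST), after all cytokine peaks, and only this qualitative
ordering/window is asserted.  The control group is used for predicted peak
times: drug lowers cytokine amplitudes and (numerically verified) shifts
their peaks slightly *later*, so the vehicle simulation is the cleanest
definition.

## Estimation conventions

* **Objective.** WLS on naively pooled animal-level data:
  Σ wᵢ(yᵢ−ŷᵢ)² with prediction-based weights wᵢ = 1/max(ŷᵢ, ε)^(2·we),
  ε = 1e−8, and weight exponent we = 1 by default (relative error, 1/ŷ²).
  The exact variance model used in the original ADAPT fits is unpublished;
  this convention is fixed and documented here, so absolute objective/AIC
  values are not comparable across software (none were published either).
* **Sequential stages.** PK (Vd/F, ka, ke) on pooled drug concentrations of
  both dose groups; then the 14 cytokine parameters (τ, 4 kout, 3 IC50, 4 S,
  kin_IL10(dis), I_IL10(IFNγ)) jointly with PK fixed, Imax fixed at 1 and
  baselines fixed at healthy-animal means; then the 6 disease parameters
  with everything upstream fixed and α = β = 1.5 fixed.
* **Optimizer.** scipy's bounded trust-region-reflective least squares on
  log-transformed parameters (the estimates span seven orders of magnitude;
  log-space equalises scaling and enforces positivity).  Default bounds are
  (init/100, init·100); finite-difference Jacobians use a 1e−6 relative
  step.  Optional seeded multi-start perturbs the start ±50% in log space.
* **Identifiability guards.** A PK dataset with fewer than three distinct
  sampling times is rejected; without any treated group the IC50s are
  flagged unidentifiable and held at their initial values; without the
  challenge the transaminases have no driving force and the disease
  stimulation coefficients are flagged.
* **Flip-flop ambiguity.** The Bateman curve is invariant under swapping
  (ka, ke) with Vd/F rescaled by ke/ka, so concentration data alone cannot
  distinguish the branches; the fit converges to the branch of its initial
  guess.  The package default init (ka = 1 < ke = 3) selects the flip-flop
  branch, matching the reported regime.
* **Precision.** CV% comes from the Gauss–Newton curvature at the optimum:
  cov = s²(JᵀJ)⁻¹ with s² = WSS/(n−p), J the weighted-residual Jacobian in
  log space — so SE(ln p) is directly the relative SE and CV% = 100·SE(ln p).
  Singular curvature yields "unavailable" (None) rather than an exception.
* **Information criteria.** The least-squares convention
  AIC = n·ln(WSS/n) + 2p, BIC = n·ln(WSS/n) + p·ln n (WSS floored at a tiny
  positive value so exact fits stay finite).

## Synthetic-study generator

The generator reproduces the trial layout: PK groups at 50 and 100 mg·kg⁻¹
sampled destructively at 5, 15, 30, 60, 90, 120 min (4 mice/time point); PD
groups (vehicle control, 50, 100 mg·kg⁻¹, all challenged at 0.5 h) sampled
at 1, 2, 4, 8, 24 h post-ConA (5 mice/time point — the reported "n = 4–5"
is resolved to 5, overridable in the design); and 4 healthy baseline
animals.  Noise is multiplicative log-normal,
value·exp(σZ − σ²/2) with σ² = ln(1+cv²), mean-preserving with coefficient
of variation exactly `cv`; the default CV of 20% reflects typical
immunoassay/enzymatic serum readouts.  Drug records use the closed-form
concentration (exact and strictly positive at any finite time); the vehicle
control contributes no drug records, since there is no drug to measure.

What the generator does *not* emulate: assay censoring below the LLOQ
(values are never censored; tiny late-time drug concentrations are emitted
as-is), between-animal biological variability beyond the residual noise
(the data are naively pooled anyway), and any measurement-process detail of
the ELISA/Luminex assays.  Passing recovery tests therefore demonstrate the
correctness and stability of the estimation machinery under the stated
noise model — not robustness to model misspecification or to real assay
artefacts.

## Problem sizes used in the shipped checks

Noise-free round trips run one study (572 records) through the full
sequential fit; the stochastic recovery check uses 20 seeded replicates at
10% proportional noise with 5 mice per time point and asserts a median
relative error ≤15% for the PK parameters and IC50s.  These sizes give
stable medians while keeping the whole suite comfortably interactive.

## Known limitations

* The printed peak times of the source study (1.6, 3.5, 4.4 h for TNF-α,
  IL-6, IFN-γ) are not exactly reproducible from its printed parameters:
  with the reported τ, kout and chain lengths the model yields 1.70, 3.60
  and 4.58 h, and cytokine timing depends on nothing else.  TNF-α and IL-6
  agree within 0.1 h; IFN-γ differs by 0.18 h.  The package implements the
  printed equations and parameters verbatim and reports the computed values.
* IC50 units are taken as mg·L⁻¹ (the parameter table's units); the same
  numerals appear elsewhere as µM, a discrepancy recorded but not resolved.
* β is described in the parameter table as acting on AST, but the printed
  ALT equation applies it to IFN-γ in the ALT stimulation function; the
  equation is followed.
* Baselines are required inputs; the shipped defaults are assumptions for
  synthetic data, not measured values.
* Alternative model variants reported as tested-and-rejected (direct drug
  effect on transaminase production; IL-6/IL-10 terms in the disease part)
  are out of scope, as are mixed-effects estimation and Bayesian inference.
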