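# Methods

This note records the models implemented in `fgphase`, the parameter choices
that matter, what the synthetic-data generators do and do not emulate, and the
numerical decisions a maintainer would want to know about.

## Hydrodynamic desk calculations (`seqthermo`)

Molecular masses are average (isotope-abundance-weighted) residue masses plus
one water (18.02 Da); the constructs are quantified by dry weight, so average
rather than monoisotopic masses are the appropriate scale. The anhydrous
equivalent-sphere radius follows from the partial specific volume,
r₀ = (3·MW·v̄ / 4πN_A)^{1/3}, with v̄ = 0.73 cm³/g (the standard protein
value; configurable) and a hydration shell added as a fixed thickness
(default 3.2 Å). Rotational and translational mobility of the equivalent
sphere follow Stokes–Einstein–Debye and Stokes–Einstein:

    τ_c = 4πηr³ / (3 k_B T),    D = k_B T / (6πηr),

which obey D·τ_c = 2r²/9 identically — asserted as a test invariant.

Water viscosity comes from the Vogel-type correlation
η = 2.414·10⁻⁵ × 10^{247.8/(T−140)} Pa·s, which matches handbook values to
well under 1% between 0 and 40 °C. Buffer additives are ignored; at the salt
concentrations involved the viscosity correction is below the other
uncertainties of the rigid-sphere idealization. Temperatures are accepted in
°C at the interfaces and converted to kelvin internally.

These predictions intentionally model a *compact* hydrated sphere. Their
value for a disordered repeat protein is as a reference point: the measured
rotational correlation times sit far below them, which quantifies the absence
of whole-body tumbling. No disordered-chain R_h scaling law or shape
correction is applied — that comparison is the point, not a deficiency.

## TRACT analysis (`tract`)

The two ¹⁵N doublet components (α = TROSY, β = anti-TROSY) relax at rates
whose difference is twice the dipole–CSA cross-correlated rate:
η_xy = (R_β − R_α)/2. The rate–correlation-time relation is

    η_xy = 2 p δ_N (3cos²θ − 1)(4J(0) + 3J(ω_N)),
    p = μ₀γ_Hγ_N h / (16π²√2 r_NH³),
    δ_N = γ_N B₀ Δδ_N / (3√2),
    J(ω) = 0.4 τ_c / (1 + ω²τ_c²),

implemented exactly in this form (Planck h, these prefactors). Conventions
for this relation differ across the literature by factors of 2π; all such
scale choices are isolated in `SpinParameters`, and the pipeline's guarantee
is exact forward/inverse self-consistency, verified to 1e-6 relative across
four decades of τ_c. Constants not fixed by the experiment use the standard
values of the cross-correlated relaxation literature: r_NH = 1.02 Å,
Δδ_N = 160 ppm, θ = 17°, B₀ for a 600 MHz spectrometer; all configurable.
With real data, absolute τ_c values shift by a few percent under alternative
constant choices; relative (residue-to-residue, condition-to-condition)
comparisons do not.

Decay fitting: I(t) = I₀e^{−Rt}, two free parameters, no baseline offset
(difference data are assumed baseline-corrected). Residuals are weighted by
1/|I| — peak-intensity noise is proportional to signal, and under that model
relative weighting is the efficient estimator *and* the one whose
covariance-based rate SD matches the empirical replicate scatter (an
unweighted fit underestimates it by ~16% at this 7-point design, which would
silently degrade the Monte-Carlo intervals below nominal coverage).

Inversion uses bracketed root finding (Brent) on τ_c ∈ [1 ps, 10 µs]. Because
τ_c is of order 10⁻⁹ s, the absolute x-tolerance is set near machine epsilon
(1e-20) — a default-tolerance root finder would silently limit accuracy to
~10⁻³ relative. Below the bracket the spectral densities are linear in τ_c
(ω_N τ_c ≪ 1), so vanishing η maps to the analytic linear limit rather than
an error. η_xy ≤ 0 (α and β rates equal within error) is not an exception
but an *indeterminate* result: τ_c is reported missing in tables and 0 in
plotting output.

Uncertainties: both rates are resampled from normal distributions
(N = 10000 by default), each draw inverted to τ_c; draws with R_β ≤ R_α are
discarded and counted, and more than 50% discards marks the residue
indeterminate. Fixed seeds give bit-identical SDs.

## FRAP (`frap`)

Normalization divides the ROI trace by the unbleached reference trace
rescaled to its first value (exactly cancelling shared acquisition
photobleaching), then by the prebleach level, so prebleach = 1 and C(0)
reflects bleach depth. If no reference is supplied, no correction model is
invented — correction is skipped with a warning, because an assumed
correction is worse than a documented omission. With 5% acquisition bleaching
over a record the uncorrected τ fits short and D comes out high by ~8%; the
correction removes this bias exactly for shared multiplicative decay.

The recovery fraction (C − C₀)/(1 − C₀), measured from the first postbleach
frame with t = 0 there, is fitted to C(t) = A(1 − e^{−t/τ}); A is then the
mobile fraction. Traces recovering less than 10% of the bleach depth are
flagged immobile rather than fitted. The algebraic steps t₁/₂ = −ln 0.5·τ
and D = 0.224·R²/t₁/₂ are exact and tested as identities. The effective
bleach radius is the half-width of the postbleach radial profile at 86% of
bleach depth (the contour where 14% of the depth remains), located by linear
interpolation; for a Gaussian dip this equals σ√(2·ln(1/0.14)) ≈ 1.98σ,
used as the analytic oracle. Replicates (typically n = 5) are fitted
independently and D reported as mean ± sample SD.

## DLS (`dls`)

Transition detection: baseline = median of the first quartile of the ramp;
the transition is the first temperature where the radius exceeds 10× baseline
and stays above for 3 consecutive samples; the result is rounded **up** to
the nearest 0.1 °C, so the reported T_p is never below the raw crossing and
within 0.1 °C of it. Threshold multiple and persistence are config keys —
"sharp increase" is not otherwise quantified. At the standard 1 °C/min ramp
the detection resolution is one sample (1 °C); finer synthetic sampling
tightens it proportionally. Radius-based detection is the default, matching
the ramp traces analyzed; an intensity trace can be passed through the same
detector.

Phase diagrams are per-salt series sorted by concentration, with an
`lcst_consistent` flag (T_p strictly decreasing with concentration) and a
`salt_enhancement` flag (higher NaCl lowers T_p at every shared
concentration). Correlogram radii use a first-cumulant fit
g₂ − 1 = βe^{−2Γτ}, D = Γ/q², R_h = k_BT/(6πηD), with
q = 4πn·sin(θ/2)/λ from configurable optics (defaults 658 nm, 90°, n = 1.33
— typical instrument values; the optics are not data). Polydispersity
(second-cumulant, CONTIN) analysis is out of scope.

## Peak bookkeeping, CSP, NOESY (`spectra`)

Expected amide peaks = non-proline residues of the repeat unit (11 of 12 for
`GGLFGGNTQPAT`). A fast-flipping Phe ring gives three CH environments at
2:2:1 (δ, ε, ζ). CSP uses the conventional weighted combination
√(Δδ_H² + (0.2·Δδ_N)²) with configurable nitrogen weight; positions above
the profile mean are flagged.

NOESY classification matches each cross peak against all atom pairs whose
tabulated shifts fall within tolerance on both axes (defaults 0.03 ppm ¹H);
*all* candidates are listed, never resolved — with a dynamic, averaged system
distance quantification from NOE intensities is not attempted and contacts
are categorical only. Peaks with |w1 − w2| < 0.05 ppm are diagonal
(untransferred magnetization) and excluded, which also means contacts between
equivalent groups (Phe–Phe) are invisible by construction. Sequence
separation treats the repeat as circular (position 12 adjoins position 1 of
the next repeat), since repeats are NMR-indistinguishable: separation 1 is
sequential, ≥2 long-range. Ambiguous peaks take the category of the smallest
candidate separation — the conservative choice, since a contact is only
called long-range when no sequential explanation exists. Every input peak
lands in exactly one of contacts / diagonal / orphans.

## Centrifugation assay (`phase_assay`)

After separation the dilute phase sits at the critical concentration, so
sup = min(total, c_crit). A point counts as separated when its supernatant
fell below (1 − margin)·total; the margin (default 5%) must exceed the
readout noise, otherwise near-saturation points fluctuate into the separated
set and bias the mean low — analyses at known noise pass a wider margin
explicitly. Separated points are averaged; with none, the largest total is a
lower bound and flagged as such. Partition coefficients are in/out signal
ratios, with a detection-floor bound (default 0.1% of the inside signal)
when the outside signal is zero.

## Synthetic data (`simulate`)

Each generator inverts its analyzer exactly at zero noise, which makes
recovery tests true round trips. Acquisition designs mirror the study
conditions: 7 relaxation delays auto-scaled so the last α-state point retains
~30% of the first; FRAP frames every 2 s over 300 s; DLS ramps at 1 °C/min
over 2–40 °C with a logistic 5 → 1000 nm radius jump; assay supernatants
obeying sup = min(total, c_crit). Noise is Gaussian — multiplicative on
intensities, radii and concentrations, additive on normalized FRAP signal —
the simplest model consistent with the least-squares estimators. Default
magnitudes (1.5–2% relaxation intensities, 2% FRAP, 5% DLS radii, 3–5%
assay) are typical of the respective instruments at these signal levels.

What the generators do *not* emulate: spectral overlap and peak-picking
errors, baseline and phasing artifacts, temperature gradients in the sample,
polydisperse or multi-modal DLS populations, bleaching during the bleach
pulse beyond a fixed effective radius, and gel-densitometry nonlinearity.
Passing recovery tests therefore demonstrates correctness of the estimators
under their stated noise model, not robustness to every instrumental
pathology; real-data use retains the configurable tolerances and flags for
exactly that reason. The synthetic chemical-shift tables are labelled as
such and carry realistic magnitudes only; real analyses require a measured
shift table.

## Problem sizes in the test suite

Statistical tests run at sizes chosen to make their assertions sharp but
cheap: rate-recovery oracles use 200 replicate decays; the τ_c
profile-recovery and interval-coverage check uses 100 replicates of the
11-residue profile with 400 Monte-Carlo draws per residue (coverage is
assessed at the 1.96σ normal interval); FRAP bias checks use 100 replicate
curves. The analysis scripts run single demonstrations at the full
N = 10000 Monte-Carlo setting.

## Known limitations

- Absolute τ_c from real TRACT data depends on the CSA/geometry constants;
  only self-consistency is guaranteed here.
- The FRAP model is the simple exponential one; reaction-dominant recovery
  or Bessel-function diffusion profiles are out of scope.
- The rigid-sphere hydrodynamics are reference predictions, not models of
  disordered-chain behaviour.
- LCST behaviour is detected and mapped, not thermodynamically modelled (no
  Flory–Huggins or equation-of-state fit).
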