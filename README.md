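# fgphase

Quantitative analysis toolkit for phase-separating FG-repeat domains — the
intrinsically disordered, Phe-Gly-motif-rich nucleoporin regions that form the
permeability barrier of nuclear pore complexes. The package targets the
engineered *perfect repeat* construct (52 copies of the 12-mer
`GGLFGGNTQPAT`), whose NMR-indistinguishable repeats collapse the assignment
problem to a single repeat unit, and covers the full quantitative chain from
raw-style instrument tables to biophysical parameters:

- **seqthermo** — sequence construction and closed-form hydrodynamics:
  average molecular mass, molar/mass conversions, FG-motif molarity,
  sphere-confined local concentrations, and rigid hydrated-sphere predictions
  τ_c = 4πηr³/(3k_BT) (Stokes–Einstein–Debye) and D = k_BT/(6πηr)
  (Stokes–Einstein) with r = (3·MW·v̄/4πN_A)^{1/3} + hydration shell.
- **tract** — residue-specific rotational correlation times from TRACT
  ¹⁵N relaxation: exponential fits of the TROSY/anti-TROSY (α/β) decays,
  cross-correlated rate η_xy = (R_β − R_α)/2, inversion of
  η_xy = 2pδ_N(3cos²θ − 1)(4J(0) + 3J(ω_N)) with
  J(ω) = 0.4τ_c/(1 + ω²τ_c²), and Monte-Carlo error propagation
  (N = 10000 by default).
- **frap** — fluorescence-recovery fitting C(t) = A(1 − e^{−t/τ}),
  t₁/₂ = −ln 0.5·τ, D = 0.224·R²/t₁/₂, with acquisition-photobleaching
  correction and effective bleach-radius extraction from the postbleach
  profile (half-width at 86% of bleach depth).
- **dls** — phase-transition temperatures from radius-vs-temperature ramps
  (sharp 5 nm → 1000 nm jump, rounded up to 0.1 °C), replicate averaging,
  LCST phase-diagram assembly, and first-cumulant correlogram radii.
- **spectra** — amide/aromatic peak bookkeeping (11 amide peaks per repeat
  unit, 2:2:1 Phe ring pattern), chemical-shift-perturbation mapping
  (Δδ = √(Δδ_H² + (0.2·Δδ_N)²)), and NOESY cross-peak classification into
  intra-residue / sequential / long-range contacts under the circular repeat
  convention, with explicit ambiguity listing and diagonal exclusion.
- **phase_assay** — critical (saturation) concentrations from centrifugation
  supernatants (sup = min(total, c_crit)) and partition-coefficient
  arithmetic.
- **simulate** — synthetic-data generators for every input above, each the
  exact inverse of its analyzer at zero noise, with seeded determinism.

There is no public deposition of the underlying spectrometer/microscope raw
data, so the generators double as the test harness: every analyzer is
validated by recovery of programmed ground truth under realistic acquisition
designs (7-delay relaxation series, 2 s FRAP frames, 1 °C/min DLS ramps).

## Worked example

The headline desk calculation — how fast *would* the constructs tumble if
they were compact hydrated spheres?

```sh
$ fgphase predict --repeats 52 --temp-c 24
       quantity    value     units
     length_res   624.00  residues
             mw 57279.60        Da
      fg_motifs    52.00 per chain
hydrated_radius    28.70  angstrom
          tau_c    21.99        ns
              D    83.24    um^2/s

$ fgphase predict --repeats 7 --temp-c 24
          tau_c     4.01        ns   (among the same columns)
```

The rigid-sphere predictions are ~22 ns (full-length) and ~4 ns (7-repeat
fragment). Measured aqueous-state values are an order of magnitude shorter
(~1.4 and ~0.7 ns), which is the quantitative signature that the disordered
chains do not tumble as compact particles — local segmental motion dominates.

The same library drives a scripted analysis sequence under `analysis/`
(`01_hydrodynamics.py` … `06_nmr_contacts.py`), each step writing its table
under `results/`: concentration bookkeeping (4.5 mM ≙ ~258 mg/ml condensed
phase, 234 mM FG motifs, ~215-fold enrichment), TRACT profile recovery,
FRAP replicate fits (D = 0.060 ± 0.002 µm²/s against a programmed 0.06),
an LCST phase diagram with salt enhancement, critical-concentration series
(90 µM at 7 °C → 1 µM at 37 °C), and CSP/NOESY contact maps.

An end-to-end CLI round trip:

```sh
fgphase simulate tract --seed 1 --out demo/
fgphase tract --input demo/tract_decays.csv --seed 1 --out demo/tract.csv
```

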