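# Methods

## Model

### Speciation oracle

`nmrpka.core.solve_speciation` solves the exact equilibrium of a slice:
mass action for every dissociable site of every acid (the indicator's
conjugate acid included), water autoionization, and charge balance over all
species including fully dissociated co-ions (Na⁺, Cl⁻, DSS⁻, all treated as
|z| = 1). The charge balance is strictly monotone in [H⁺], so the root on
[10⁻¹⁴, 1] M is unique; it is located by Brent's method in log₁₀[H⁺]
(machine-precision bracketing) and polished with up to three Newton steps,
leaving a charge residual below 10⁻¹² mol/L (asserted by test).

Activity corrections use the Davies form, log₁₀γ_z = −A·z²·(√I/(1+√I) −
0.3·I) with A = 0.509 at 298 K. Thermodynamic site constants pKa,0 convert
to concentration quotients as pKc = pKa,0 − A·f(I)·(1 − Δz²) with Δz² the
charge-squared change of that site; the ionic strength is iterated to a
fixed point (|ΔpH| < 10⁻⁹, plain iteration with late damping, typically
< 10 rounds). pH is reported on the activity scale, −log₁₀(γ₁[H⁺]).
Kw = 1.0×10⁻¹⁴ is applied to concentrations without its own activity
correction: in the working range pH 1–10 the hydroxide concentration never
exceeds ~10⁻⁵ M and the refinement is far below every tolerance used here.
Temperature dependence, ion pairing and Pitzer-level models are out of
scope.

### pH from the indicator shift

Fast proton exchange makes the observed indicator shift the
population-weighted mean of the protonated (δ_H) and deprotonated (δ_L)
limits, so f_H = (δ_obs − δ_L)/(δ_H − δ_L) and

pH = pKa,0 + Δz²·A·f(I) + log₁₀((δ_H − δ_obs)/(δ_obs − δ_L)).

The ratio form is orientation-agnostic (formate has δ_H < δ_L). The sign
of the Davies term follows from the mixed-constant definition: pKa_mixed =
pKa,0 + Δz²·A·f(I); the speciation oracle and this formula are verified
against each other to 10⁻⁹ in the tests.

Since I is itself composition-dependent, `ph_selfconsistent` iterates
pH → I → pH to 10⁻⁶. The ionic-strength estimate uses only quantities an
experimenter knows: declared strong co-ions, the measured indicator
concentration and its protonated fraction (plus the Na⁺ accompanying a
carboxylate-type indicator salt), and — when the analyte is declared with
its nominal total concentration — the analyte's ionization state
reconstructed from charge balance (each transferred proton creates one
unit of negative charge). No knowledge of the analyte's pKa is used or
needed; on simulated data this reconstruction reproduces the oracle's
ionic strength exactly for a single active site, and the pipeline pH
matches the oracle pH to better than 10⁻⁴ (test-asserted).

### κ and the linearized fit

κ = f_H·C_indicator + [H⁺]_free counts the protons the analyte has
surrendered: those parked on the indicator plus those free in solution.
10^-pH is an activity, so the free-proton term divides by γ₁(I); the term
matters for low-pKa analytes (for 60 mM phosphoric acid it reaches ~30% of
κ at the acid end of the gradient). Protonation of the indicator by water
is neglected (the indicators are weak bases, pKa ≤ 8), and no
free-proton baseline is subtracted for analytes supplied as salts of
strong acids — their counter-ions enter only through ionic strength and
charge balance. C_analyte is taken as homogeneous across the tube; analyte
migration is deliberately not modelled.

For one site, κ = C·K_a/(K_a + a_H) with K_a mixed, i.e.

1/κ = 1/C + a_H/(K_a·C).

K_a drifts with the slice ionic strength (pKa_mixed = pKa,0 + Δz²·A·f(I)),
which makes a plot against raw a_H very slightly curved. The fit therefore
regresses 1/κ on the corrected abscissa **x = a_H·10^(Δz²·A·f(I_slice))**,
which is exactly linear with slope 1/(K_a,0·C) and intercept 1/C and
returns the thermodynamic pKa,0 directly. This matters more than it
looks: correcting only once, at the median I after an uncorrected fit,
leaves a curvature that the long extrapolation to the intercept amplifies
into a ~0.07 pKa / ~14% C bias on a noise-free boric-acid gradient,
whereas the per-point form leaves < 10⁻³ pKa / 0.3% (the remainder being
the neglected hydroxide contribution to κ at pH ≈ 9). The analyte's Δz²
must be supplied by the caller (−1 neutral acid, +1 cationic acid such as
glycinium or ammonium, −3 for H₂PO₄⁻ → HPO₄²⁻); it is part of knowing
what is being titrated.

The regression is unweighted ordinary least squares, deliberately: the
line through 1/κ vs 10^-pH is the method's defining simplicity. 95%
confidence intervals are t-intervals (n − 2 df); those of C = 1/intercept
and pKa = −log₁₀(intercept/slope) follow by the delta method from the
(slope, intercept) covariance, an approximation that degrades if the
intercept approaches zero. A nonlinear least-squares fit of
κ = C·K_a,0/(K_a,0 + x) (scipy `curve_fit`, seeded from the linear fit)
serves as a cross-check; on noise-free monoprotic data the two agree to
10⁻⁴ pKa.

Validity filtering: slices are rejected — each with a logged reason, never
silently — when δ_obs lies at/beyond a limiting shift, when f_H is outside
[0.05, 0.95] (shift too close to a limit for the shift uncertainty), when
the pH falls outside the indicator's tabulated window (±~1 unit around its
pKa), or when κ ≤ 0. Fitting requires ≥ 3 retained points and an a_H
spread of at least 3×.

### Protein quantities

For a protein, the fit returns the total concentration of titratable
acidic groups; dividing by the protein molarity (mass concentration / MW)
gives acidic sites per molecule, with the C confidence interval propagated
linearly. The value is returned unrounded; rounding to whole sites is
presentation. The single effective pKa of the whole molecule estimates the
isoelectric point.

## Synthetic data

The simulator emulates the tube geometry: 64 slices × 0.41 mm of
NMR-active region, offset 4 mm from the diffusion source (solid base at
the bottom; for 2,6-lutidine, a liquid layered on top — the profile is
mirrored from the surface). The base concentration follows semi-infinite
diffusion, C(h) = C₀·erfc(h/(2√(Dt))), with defaults D = 1×10⁻⁹ m²/s and
t = 6×10⁴ s (≈17 h, a diffusion length of ~8 mm). This profile is a simple
stand-in for the gradient-development model used to schedule real
experiments; it reproduces the one feature the analysis needs — a smooth
monotone sweep of the indicator through its pH window — not tube
hydrodynamics. Scenario presets set C₀ = 5 × the analyte concentration
(50 mM; 300 mM for 60 mM phosphoric acid), a design rule chosen so the
indicator window is traversed inside the active region, playing the role
the optimal-time prediction plays at the spectrometer.

Per slice the oracle supplies the equilibrium; the emitted shift is
δ_L + f_H·(δ_H − δ_L), and the integrals are scaled so the per-proton
indicator:reference ratio encodes C_indicator through the declared
reference concentration and correction factor (dioxane 1.17 mM and DMSO
1.41 mM at 0.01% v/v; correction factor defaults to 1 and is divided out
by the pipeline, so any declared value round-trips). Noise is Gaussian:
shift sd 0.002 ppm and relative integral sd 2% by default — chosen to
represent a well-shimmed 500 MHz CSI measurement and matching the scale of
the benchmark confidence intervals — from a generator seeded by the
scenario seed, so output is bitwise reproducible. DSS (0.2 mM, with its
Na⁺) and salt counter-ions are included in every preset's composition.
Ground truth (pH, C_indicator, κ, ionic strength, per-slice speciation) is
retained next to the measurements.

What the simulator does **not** emulate: lineshapes and peak overlap,
water-suppression artefacts, B₀/B₁ inhomogeneity, convection, analyte
migration and signal loss of entangling polymers, temperature drift.
Passing round-trip tests therefore demonstrates the correctness and
internal consistency of the analysis chain under the stated noise model,
not robustness to every pathology of real spectra. A minimal Lorentzian
spectrum synthesizer (`synthesize_spectrum`) exists purely as a demo that
the declared integrals correspond to a plausible spectrum.

The limiting-shift calibration scenario reproduces the strong-acid
procedure: a gradient of the indicator over 0.01 M HCl, where κ is known
and equal to the acid concentration. `calibrate_limits` computes each
slice's f_H as (κ_known − [H⁺])/C_indicator with [H⁺] from the slice
equilibrium at the indicator's literature pKa,0 (its shift limits are not
needed), then regresses δ_obs on f_H: intercept δ_L, intercept + slope
δ_H. Noise-free recovery is exact to < 10⁻³ ppm; at 0.002 ppm shift noise
the limits stay within 0.01 ppm across 50 seeds (both test-asserted).

## Numerical choices and degenerate inputs

- Root bracket [10⁻¹⁴, 1] M; non-bracketing compositions (> 1 M net strong
  acid/base) raise a convergence error naming the bracket.
- Ionic-strength fixed points: plain iteration, damped after 30 rounds,
  hard iteration caps with informative errors.
- Ties/degeneracies: all-flat κ raises a no-titration error; a negative
  extrapolated intercept raises an unphysical-fit error carrying
  diagnostics; < 3 usable slices raises insufficient-data; a calibration
  dataset whose f_H barely varies is flagged ill-conditioned.
- Measurement tables are validated with line-numbered schema errors; CSV
  dialect is fixed (comma, dot-decimal, UTF-8 header) to avoid locale
  drift.

## Benchmark sizes

The test suite and the acceptance benchmark run the nine preset analytes
at full experimental size (64 slices each) — the whole sweep takes under a
second — and Monte-Carlo checks use 200 replicates (CI coverage) and 50
seeds (calibration noise), sizes at which the binomial uncertainty on a
90% coverage bound is a few percent.

## Known limitations

- **Estimator bias at the validity edge.** Shift noise maps into pH with a
  sensitivity that diverges as f_H → 0 or 1. For indicators whose window
  admits slices near f_H ≈ 0.95 (acetate, formate), the unweighted
  linearized fit acquires a systematic bias of order +0.1 pKa at 0.002 ppm
  noise, comparable to its own confidence interval, so CI coverage of the
  true value degrades (measured per-analyte coverage over 80–200 seeded
  replicates: boric 0.94, glycinium 0.96, 4-cyanophenol 0.90, glycolate
  0.86, benzoate 0.75). This mirrors the behaviour of the method on real
  data, where fitted values can sit ~0.1 above literature with smaller
  CIs, and is inherent to the prescribed estimator rather than to this
  implementation. All nine analytes still recover within 0.3 pKa units.
- The delta-method CI for C is unreliable when the gradient barely reaches
  the κ plateau (intercept near zero) — visible in wide C intervals for
  high-pKa analytes.
- Multi-site analytes are summarized by a single effective pKa by design;
  the linear plot then shows systematic residual curvature, which the
  tests detect with a sign-runs statistic.
- The indicator-from-water protonation pathway is assumed negligible and
  is not corrected for.
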