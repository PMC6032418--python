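# Methods

## Physical model

A ligand proton at distance r from the heme iron of a ferric P450
experiences dipolar relaxation by the iron's unpaired electrons.  Under
fast exchange between free and bound ligand, and with the ligand in
large excess over enzyme, the observed relaxation rate is the
population-weighted average of the two environments, so the bound-state
enhancement can be isolated and converted to a distance:

- **Paramagnetic relaxation time.**
  `1/T₁P = 1/T₁(Fe³⁺) − 1/T₁(Fe²⁺–CO)`.  The ferrous-CO complex is
  diamagnetic and stands in for *all* diamagnetic contributions; this
  assumes the CO complex perturbs neither binding nor dynamics.

- **Bound fraction.**  `α_m = [P450]/(K_s + [S])`, valid when one
  substrate is present and exchange is fast.  α_m is dimensionless and
  depends only on concentration ratios, so any consistent unit works;
  the package uses µM throughout.  Values above 0.1 trigger a warning
  (the dilute approximation weakens).

- **Spin factor.**  Ferric heme is a temperature- and ligand-dependent
  mixture of low-spin (S = 1/2) and high-spin (S = 5/2) states.  The
  S(S+1) factor entering the dipolar equation is population-weighted:
  `S(S+1) = 8.75·f_HS + 0.75·f_LS` (35/4 and 3/4 for the pure states).

- **Distance.**
  `r = [9.78×10¹⁶ · T₁P · α_m · S(S+1) · τ_c]^(1/6)` Å, with T₁P and
  τ_c in seconds.  The prefactor carries implicit units Å⁶ s⁻² and
  absorbs the gyromagnetic ratios, g-factor and spectral-density terms
  of the Solomon–Bloembergen equation evaluated at the measurement
  field.  τ_c is the effective correlation time of the electron–nuclear
  dipolar interaction; for CYP1A2 the shipped value is 3.38×10⁻¹⁰ s.
  (Sources sometimes print this constant with units s⁻¹; dimensional
  analysis of the distance equation requires seconds, and only seconds
  reproduce the published distances.)

## Stage-by-stage estimation choices

### Inversion recovery (T₁)

Three-parameter model `H(d₂) = H∞(1 − 2B·e^(−d₂/T₁))` rather than the
ideal two-parameter form, because real 180° pulses are imperfect; B is
bounded to (0.4, 1.1].  Initial guesses: H∞ = max |height|, B = 1, and
T₁ = t₀/ln 2 from the zero-crossing delay t₀ (median delay if the
series never changes sign).  Up to five restarts rescale the T₁ guess
by {0.3, 0.5, 2, 3, 5} before a fit-failure error naming the proton.
The standard error is taken from the least-squares covariance.  Input
is already-extracted peak heights; FID processing, line broadening and
peak picking are upstream of this package.

### Binding isotherm (K_s)

Unweighted least squares of `ΔA = B_max[S]/(K_s+[S])` (no weights are
justified by the data model).  A fitted K_s above 10× the highest
titrated concentration is returned but flagged — the plateau is then
extrapolation.  Solvent-dilution corrections for the titrant are
ignored (≤ ~2 % volume in the emulated protocol).  Difference spectra
are classified type I when the global maximum falls in 385–400 nm and
the minimum in 415–425 nm (the canonical 390/417 nm pair ± ~8 nm),
type II for the mirrored windows, otherwise indeterminate.

### Soret deconvolution (spin fractions)

Three Gaussians on the wavelength axis (the band positions are reported
in nm and no energy-axis transform is implied), with center windows
δ 350–372 nm, high-spin 385–407 nm, low-spin 412–424 nm, plus an
optional linear baseline (default on).  Band widths are parameterised
as FWHM; starting values 20/14/12 nm with σ bounded to 1.5–30 nm.
`f_HS = A_HS/(A_HS + A_LS)`: the δ band is a separate component of the
Soret envelope, not a spin marker, and is excluded from the ratio.
Fractions are stored in [0, 1]; percentages are display formatting.
Any parameter pinned at a bound flags the result rather than failing.

### Distance errors

First-order propagation from the two T₁ standard errors only:
`var(1/T₁P) = (se_f/T₁_f²)² + (se_co/T₁_co²)²`, relative error of T₁P
is `T₁P·sd(1/T₁P)`, and `se(r) = (r/6)·relerr(T₁P)` since r ∝ T₁P^{1/6}.
Uncertainty in K_s, the spin fractions and τ_c is deliberately not
propagated (those are treated as fixed experiment-level parameters).
A Monte-Carlo cross-check (`monte_carlo_distance_se`) resamples the T₁
pair from independent normals, discards unphysical draws
(T₁_ferric ≥ T₁_ferrous-CO), and takes the SD of the recomputed r.

**Known limitation.**  The first-order formula is accurate only while
the relative T₁P error is modest (≲ 25 %).  For pairs whose two T₁
values nearly coincide — e.g. the WT methylene with 1.54 ± 0.15 vs
1.85 ± 0.18 s, giving ~75 % relative T₁P error — the sixth-root map is
visibly nonlinear, ~9 % of Monte-Carlo draws are unphysical, and the
Monte-Carlo SD (≈ 1.1 Å) exceeds the analytic value (≈ 0.83 Å) by
~25–35 %.  The analytic number is reported in the tables (it is the
convention the emulated study used); the Monte-Carlo SD is the better
uncertainty when the contrast is weak.

### Fast exchange

Ordinary least squares of 1/T₁P on 1/T (≥ 3 temperatures; the study
used 283, 298, 310 K).  Pass requires slope > 0 **and** R² ≥ 0.95:
faster relaxation at lower temperature is the fast-exchange signature,
while slow exchange reverses the slope.

## Pipeline conventions

- When both raw inputs (titration, spectrum, recovery series) and
  summary parameters (K_s, spin fractions, T₁ table) are supplied, the
  raw inputs are fitted and reported as cross-checks with their
  discrepancy, but the summary values drive the distance calculation —
  mirroring studies where K_s and spin state come from dedicated
  experiments.
- Protons without paramagnetic contrast are skipped with a warning, not
  fatal.  All stage warnings surface exactly once in the report.
- Reports are deterministic: identical inputs give byte-identical
  `report.json`, per-enzyme `distances_*.csv`, and `warnings.log`.
- Display precision is 2 decimals for distances and T₁; JSON keeps full
  precision.

## The shipped CYP1A2/phenacetin inputs

`hemedist.datasets` encodes the study conditions: per-proton T₁ pairs
for four enzymes (WT, L382V, N312L, L382V/N312L) with phenacetin;
[P450]/[S]/K_s per enzyme (0.017/171/17.1, 0.0007/7/0.7, 0.011/102/10.2,
0.004/35/3.5 µM); bound-state high-spin fractions 0.27/0.21/0.14/0.17;
τ_c = 3.38×10⁻¹⁰ s.  Two published inconsistencies are handled openly:

1. **L382V enzyme concentration.**  The source footnote prints
   0.007 µM, which reproduces none of the published L382V distances;
   every other enzyme's concentration equals 10⁻³·K_s, and 0.0007 µM
   (= 10⁻³·0.7) reproduces all four.  The corrected value is the
   default; the printed one is kept as `L382V_PRINTED_P450_UM`.
2. **N312L –COCH₃ distance.**  The stated inputs give 7.93 Å against a
   published 8.19 Å, and no rounding of the two-decimal T₁ inputs can
   close the gap (the cell tops out near 7.94 Å).  The package reports
   the recomputed value; the corresponding acceptance check is left
   failing rather than special-cased.  The other 19 table cells
   reproduce within ±0.06 Å.

## Synthetic data: what it does and does not emulate

Generators produce mono-exponential recovery curves, hyperbolic
isotherms, three-Gaussian Soret mixtures, and whole studies inverted
from target distances (T₁P = r⁶/(9.78×10¹⁶·α_m·S(S+1)·τ_c), with the
ferrous-CO T₁ drawn from 1–5 s to bracket observed values).  Noise is
additive i.i.d. Gaussian everywhere — measured data only report fit
SEs, so this is an assumption.  Not emulated: spectrometer artifacts,
baseline drift, exchange-regime violations, J-coupling or overlap in
the NMR dimension, and correlated residuals in spectra.  Passing
round-trip tests therefore validates the estimators under the assumed
noise model, not instrument systematics.

Recovery performance under these conditions: T₁ ±2 SE coverage ≈ 0.91
(500 replicates at σ = 1 % of H∞); K_s bias < 2 % at 2 % noise;
f_HS mean absolute error ≈ 0.003 at 1 % spectral noise.  Distance
round trips at 1 % T₁ noise recover targets in the 5.9–7.0 Å range
within 2 %; beyond ~7.5 Å (T₁P ≳ 30 s) the ferric/ferrous-CO contrast
shrinks toward the noise floor and precision degrades roughly as
r⁶/T₁-contrast — visible in the published table as the larger SEs of
the N312L column.

## Problem sizes

The test and analysis suites use 100–500 replicates per stochastic
suite, 10,000–20,000 Monte-Carlo draws for uncertainty cross-checks,
181-point spectra (1 nm grid over 320–500 nm), 8-point titrations and
10–12-delay recovery ladders — sizes chosen to match the emulated
bench protocols while keeping every suite interactive.
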