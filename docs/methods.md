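# Methods

## Scope and model

`bsabind` analyses ligand binding to serum albumin from steady-state
optical spectroscopy. The chain of models, in the order a study runs them:

1. **Inner-filter correction.** Observed fluorescence is attenuated by any
   species absorbing at the excitation (280 nm) or emission (~340 nm)
   wavelength. The standard half-path correction is applied:
   F_cor = F_obs · 10^((A_ex + A_em)/2). Absorbances are non-negative, so
   the correction never decreases an intensity. A series is corrected at
   most once; the `corrected` flag on `TitrationSeries` enforces this, and
   the fitting routines refuse a series that carries absorbances but has
   not been corrected.

2. **Stern–Volmer quenching.** F₀/F = 1 + K_SV[Q]. The fit is ordinary
   least squares of F₀/F against [Q] over the nonzero-concentration
   points, with F₀ the measured zero-ligand intensity (not a fitted
   parameter) and the intercept left free rather than pinned to 1 — the
   reported R² then describes the actual line through the data. [Q] is
   total added ligand, uncorrected for the bound fraction, matching how
   such titrations are conventionally plotted; ligand-depletion models are
   out of scope. The bimolecular rate is k_q = K_SV/τ₀ with
   τ₀ = 10⁻⁸ s, the unquenched lifetime of the protein fluorophore.

3. **Binding constant.** For static quenching with m equivalent sites,
   log₁₀((F₀−F)/F) = log₁₀ K_b + n·log₁₀[Q]. OLS gives the intercept
   (log K_b) and slope (n). Points with F ≥ F₀ carry no quenching signal
   and are dropped with a warning; at least three usable points are
   required. On noise-free synthetic data this inversion is exact to
   machine precision across K_b ∈ [10³, 10⁶] L·mol⁻¹ and n ∈ [0.8, 1.3].

4. **Mechanism call.** Two independent diagnostics: (A) K_SV strictly
   decreasing with temperature (a ground-state complex dissociates on
   heating, so static quenching weakens), and (B) every k_q above the
   maximum diffusional collision rate 2×10¹⁰ L·mol⁻¹·s⁻¹ (too fast for a
   purely collisional process). Either rule alone or both give "static";
   neither gives "dynamic"; rule B combined with a strictly *increasing*
   K_SV trend is contradictory and returns "ambiguous" with both
   observations listed. The call always reports its rule firings rather
   than hiding them, because real systems do show mixed signatures (e.g.
   K_b rising with temperature while k_q stays far above the collision
   limit).

5. **Thermodynamics.** ln K_b regressed on 1/T (R = 8.314 J·mol⁻¹·K⁻¹)
   gives ΔH = −slope·R and ΔS = intercept·R; ΔG = −RT ln K_b at a
   reference temperature, 297 K by default — the room temperature at which
   the single-temperature assays (CD, competition) are run. When the
   reference temperature is one of the measured points its measured K_b is
   used; otherwise K_b comes from the fitted line. Force classification by
   the Ross–Subramanian sign rules: ΔH>0, ΔS>0 hydrophobic; ΔH<0, ΔS<0
   van der Waals + hydrogen bonds; ΔH<0, ΔS>0 electrostatic; ΔH>0, ΔS<0
   (not covered by the rules) is reported as "unclassified". Note the
   identity ΔG = ΔH − TΔS holds exactly only when ΔG is evaluated from the
   Van't Hoff line itself; evaluating it from a measured K_b at one
   temperature can differ by the scatter of that point about the line.

6. **Energy transfer.** The overlap of donor emission F(λ) and acceptor
   molar absorptivity ε(λ) is the discrete sum the field's convention
   writes, J = ΣF(λ)ε(λ)λ⁴Δλ / ΣF(λ)Δλ, evaluated with λ in cm so J
   carries cm³·L·mol⁻¹; a trapezoidal variant is available behind a flag.
   Both spectra are resampled onto the union of their grid points inside
   the overlapping window, which makes J stable (≲0.1%) under grid
   refinement of smooth spectra. R₀⁶ = 8.8×10⁻²⁵·k²·N⁻⁴·Φ·J with
   k² = 2/3 (isotropic dipole averaging), N = 1.336 (aqueous buffer) and
   donor quantum yield Φ = 0.118; E = 1 − F/F₀ and r = R₀((1−E)/E)^(1/6).
   The result flags whether r lies in the 2–8 nm window where resonance
   transfer is probable, whether 0.5R₀ < r < 1.5R₀, and whether r > R₀
   (E < 50%, consistent with the static-quenching picture). Which
   titration point supplies F/F₀ is the caller's choice; `run_study` uses
   the endpoint of the reference-temperature titration (the 1:6
   protein:ligand ratio at which the acceptor spectra are recorded).

7. **CD helicity.** MRE = CD(mdeg)/(10·n·l·C_p) with n = 583 residues for
   the bovine protein, l the path in cm (1 mm cell → 0.1; the formula's
   units are consistent only with l in cm) and C_p the molar protein
   concentration. Helicity from the 208 nm point by the two-point linear
   map between −4000 (0% helix) and −33000 (100%); the signal at exactly
   208 nm is linearly interpolated between bracketing grid points (1 nm
   sampling). Estimates are never clamped — values outside [0, 100] are
   returned with an `out_of_range` flag, since clamping would silently
   hide a calibration error. Full secondary-structure deconvolution is out
   of scope.

8. **Synchronous shifts.** Per-spectrum peak positions are refined by a
   quadratic through the three points around the discrete maximum, and the
   net shift (last − first spectrum) is labelled red/blue/unchanged with a
   1 nm tolerance, roughly the instrument step; shifts are inherently
   qualitative at that sampling.

9. **Competition.** A site marker "competes" when the apparent log₁₀ K_b
   in its presence drops by more than 0.05 relative to the marker-free
   fit — smaller than any real displacement effect worth reporting
   (≥0.3 log units in practice) but larger than fit noise at R² ≈ 0.99.
   If both markers compete, the primary site is the one whose marker
   depresses K_b further.

10. **Reversal folds.** RF = IC₅₀(cytotoxic drug alone)/IC₅₀(with
    modulator). IC₅₀ estimation itself (four-parameter logistic fitting of
    MTT dose–response curves) is deliberately out of scope; the module
    consumes IC₅₀ summaries.

## Synthetic-data generator

The generator emulates the statistical structure these analyses assume,
not the photophysics: a Gaussian tryptophan-like emission band (340 nm,
40 nm FWHM), static quenching F = F₀/(1 + K_b[Q]ⁿ) (or a collisional
variant F = F₀/(1 + K_SV[Q])), a Gaussian ligand absorbance band at
350 nm overlapping the emission, a CD curve whose 208 nm point is pinned
exactly to the helicity scale, and additive Gaussian intensity noise of
constant standard deviation. Defaults are the study design the analyses
expect: 5 µM protein, ligand at molar ratios 0, 1, 1.5, 2, 3, 4, 5, 6
(0–30 µM), temperatures 289/297/307 K, K_b(297 K) = 4.592×10⁴ L·mol⁻¹,
n = 1.08, ΔH = −38 kJ·mol⁻¹, ΔS = −38.1 J·mol⁻¹·K⁻¹ (mutually consistent
through the Van't Hoff line), native helicity 58.61% and bound 64.17%.
F₀ = 1000 a.u. is arbitrary, as fluorescence scales are. The default CLI
noise of 2 a.u. (0.2% of F₀) reproduces the near-unity R² typical of
careful titrations; the library default is zero so that closed-form
round trips are exact. Inner-filter coefficients default to 5×10³ and
2×10³ absorbance units per mol·L⁻¹ at the excitation and emission
wavelengths — flavonoid-scale absorptivities giving A_ex ≈ 0.15 at the
top of the titration. The competition files scale K_b by 0.04 (site I
marker) and 0.45 (site II marker), mirroring the order of magnitude of a
strong and a moderate displacement. All generators are deterministic
given the seed.

What the generator does *not* emulate — photobleaching, scattering,
instrument drift, wavelength-dependent noise, ligand depletion at high
affinity — bounds what passing tests show: they demonstrate that the
inverse analyses recover the forward model's parameters under the stated
noise model, not that the forward model captures every artifact of real
instruments.

## Numerical choices

- All regressions are two-parameter OLS via `scipy.stats.linregress`;
  with exactly two Van't Hoff points the line is solved directly and
  R² = 1 by convention. A perfectly flat Stern–Volmer series returns
  slope 0 with R² = 1 rather than an undefined correlation.
- Wavelengths are nm everywhere except inside the overlap integral
  (converted to cm); energies are J·mol⁻¹ internally, converted to
  kJ·mol⁻¹ only in reports.
- Per-point grid spacing in the Riemann sums uses central differences
  (`numpy.gradient`), so non-uniform grids are handled and refinement
  converges.
- Text round trips write `repr(float)` so read∘write is bit-for-bit.
- Peak refinement falls back to the discrete maximum at grid edges or on
  degenerate (non-concave) neighbourhoods.
- `run_study` isolates stage failures: each stage's exception is recorded
  and the remaining stages still run; reports are byte-identical across
  reruns on the same inputs.

## Known limitations

- The refractive index default is 1.336; published values for aqueous
  buffer near 1.33–1.37 exist and the parameter is configurable, but the
  Förster-radius reproduction checks in the test suite are calibrated to
  1.336.
- The double-log K_b is an apparent constant (total, not free, ligand);
  at K_b[P] ≫ 1 the approximation degrades. The defaults here
  (K_b·5 µM ≈ 0.2) are safely inside its validity.
- Mechanism and force labels are rule-based sign checks, not model
  selection; conflicting evidence is surfaced, not resolved.
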