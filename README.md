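# bsabind

Quantitative analysis of small-molecule binding to serum albumin from
optical spectroscopy, with a synthetic-data generator that makes every
stage verifiable against known ground truth.

Serum albumin carries most drugs in plasma, so the strength and mode of a
ligand's albumin binding shapes its free concentration, distribution and
elimination. The standard bench characterisation is a fluorescence
titration: the protein's intrinsic tryptophan emission (excited at 280 nm,
peaking near 340 nm) is quenched as ligand is added, and a family of
classical linear analyses turns those intensities into binding constants,
thermodynamics and geometry. `bsabind` implements that whole chain:

- **Inner-filter correction** — F_cor = F_obs · 10^((A_ex + A_em)/2),
  undoing attenuation by absorbing species at the excitation and emission
  wavelengths.
- **Stern–Volmer analysis** — F₀/F = 1 + K_SV[Q]; the bimolecular
  quenching rate k_q = K_SV/τ₀ (τ₀ = 10⁻⁸ s) and the temperature trend of
  K_SV classify the quenching as static (ground-state complex) or dynamic
  (collisional).
- **Binding constant and stoichiometry** — the double-log plot
  log₁₀((F₀−F)/F) = log₁₀ K_b + n·log₁₀[Q].
- **Van't Hoff thermodynamics** — ln K_b = −ΔH/RT + ΔS/R, ΔG = −RT ln K_b,
  and the Ross–Subramanian sign rules for the dominant binding force.
- **Förster energy transfer** — overlap integral
  J = ΣF(λ)ε(λ)λ⁴Δλ / ΣF(λ)Δλ, Förster radius
  R₀⁶ = 8.8×10⁻²⁵ k² N⁻⁴ Φ J, efficiency E = 1 − F/F₀ and donor–acceptor
  distance r = R₀((1−E)/E)^(1/6) with validity flags.
- **CD helicity** — mean residue ellipticity at 208 nm mapped linearly to
  α-helix % between the −4000 (0%) and −33000 (100%) anchors.
- **Synchronous-fluorescence shifts** — peak trajectories at Δλ = 15 nm
  (tyrosine) and Δλ = 60 nm (tryptophan) with red/blue/unchanged calls.
- **Site-marker competition** — warfarin (site I) and ibuprofen (site II)
  displacement of the apparent K_b to name the principal binding pocket.
- **MDR reversal folds** — RF = IC₅₀(drug alone)/IC₅₀(drug + modulator).

All inputs are plain-text CSV (wavelength/value spectra, concentration/
intensity titration tables with `#` metadata lines); everything is usable
as a library or through the `bsabind` CLI.

## Worked example

Generate a noise-free synthetic study (three titration temperatures with
inner-filter attenuation, donor/acceptor spectra, a CD pair and a marker
competition set), then fit one titration:

```sh
$ bsabind simulate --outdir demo --seed 1 --noise-sd 0
$ bsabind quench --titration demo/titration_297K.csv
{
  "binding": {
    "kb": 49345.73812921174,
    "log_kb": 4.6932496496724685,
    "n": 1.0799999999999996,
    "n_points": 7,
    "r_squared": 1.0,
    "temperature": 297.0
  },
  "stern_volmer": {
    "intercept": 0.9779467314736605,
    "kq": 2203897458983.2285,
    "ksv": 22038.974589832287,
    "r_squared": 0.9997040784967778,
    "temperature": 297.0
  }
}
```

The double-log fit recovers the generator's ground truth exactly
(K_b(297 K) = 49345.7 L·mol⁻¹, n = 1.08, R² = 1): with the inner filter
corrected and no noise, the static quenching law is exactly log-linear.
The Stern–Volmer line is only approximately straight on static 1:1-to-Hill
data, hence its R² slightly below 1; its k_q ≈ 2.2×10¹² L·mol⁻¹·s⁻¹ sits
two orders of magnitude above the 2×10¹⁰ diffusional limit — a static
quenching signature.

Running every stage at once:

```sh
$ bsabind run-study --config study.yaml --out report
quenching: ok
mechanism: ok
thermodynamics: ok
fret: ok
cd: ok
competition: ok
```

`report/report.json` then contains, for this synthetic study: mechanism
`static` (K_SV decreasing with temperature and k_q above the collision
limit), ΔH = −38.0 kJ·mol⁻¹, ΔS = −38.1 J·mol⁻¹·K⁻¹ and
ΔG(297 K) = −26.7 kJ·mol⁻¹ with force label `vdw_hbond` (hydrogen bonding
/ van der Waals), a donor–acceptor distance r = 2.74 nm with R₀ = 2.54 nm
(inside the 2–8 nm transfer window, r > R₀), helicity 58.61% → 64.17%
(Δ = +5.56 points) on ligand binding, and primary binding pocket `site I`
— each matching the generator's ground-truth YAML. `report/
binding_table.csv` holds the per-temperature summary (T, K_SV, R², k_q,
log K_b, K_b, n, R², ΔG, ΔH, ΔS).

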