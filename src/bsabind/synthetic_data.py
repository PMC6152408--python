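"""Forward models that generate titrations and spectra with known truth.

The generators emulate a tryptophan-dominated serum-albumin emission band
(excitation 280 nm, emission maximum near 340 nm) quenched by a flavonoid-like
ligand that also absorbs in the 300-400 nm window, so that every analysis
stage in the package has a recoverable ground truth.

Defaults mirror the study design the analyses assume: 5 µM protein titrated
with ligand at molar ratios 0, 1, 1.5, 2, 3, 4, 5, 6 (0-30 µM), measured at
289, 297 and 307 K; a 1:1 binding stoichiometry with Kb of order 10⁴-10⁵
L·mol⁻¹; and a native α-helicity near 59% for the free protein.

Noise is additive Gaussian on intensities with constant standard deviation,
the simplest model consistent with the near-unity regression R² these
titrations show in practice.  ``noise_sd = 0`` reproduces the closed-form
models exactly.  The quencher concentration entering the forward model is
total added ligand, not free ligand, matching how the fits are performed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core_io import Spectrum, TitrationSeries, write_spectrum, write_titration
from .errors import ValidationError

R_GAS = 8.314  # J·mol⁻¹·K⁻¹

#: 5 µM protein at drug:protein molar ratios 0, 1, 1.5, 2, 3, 4, 5, 6
DEFAULT_PROTEIN_CONC = 5e-6
DEFAULT_LIGAND_CONCS = tuple(r * DEFAULT_PROTEIN_CONC for r in (0, 1, 1.5, 2, 3, 4, 5, 6))
DEFAULT_TEMPERATURES = (289.0, 297.0, 307.0)
BSA_N_RESIDUES = 583
NATIVE_ALPHA_HELIX = 0.5861


@dataclass
class GroundTruth:
    """Forward-model parameters for one synthetic binding study.

    ``model`` selects the quenching law: ``static_hill`` gives
    F = F₀ / (1 + Kb·[Q]ⁿ); ``dynamic_sv`` gives F = F₀ / (1 + Ksv·[Q])
    with ``kb`` playing the role of Ksv.  ``ife_ex``/``ife_em`` are ligand
    absorbances per mol·L⁻¹ at the excitation and emission wavelengths
    (an effective molar absorptivity × 1 cm path); nonzero values attenuate
    the observed signal by 10^{-(A_ex+A_em)/2} and record the per-point
    absorbances so the inner-filter correction can undo them.
    """

    model: str = "static_hill"
    kb: float = 4.592e4          # L·mol⁻¹, mid-affinity flavonoid-albumin binding
    n: float = 1.08              # Hill stoichiometry
    delta_h: float = -38.0e3     # J·mol⁻¹
    delta_s: float = -38.1       # J·mol⁻¹·K⁻¹
    f0: float = 1000.0           # a.u.
    ife_ex: float = 5.0e3        # absorbance per mol·L⁻¹ at 280 nm
    ife_em: float = 2.0e3        # absorbance per mol·L⁻¹ at 340 nm
    alpha_helix: float = 0.6417  # helicity of the ligand-bound protein
    noise_sd: float = 0.0        # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("static_hill", "dynamic_sv"):
            raise ValidationError("model must be 'static_hill' or 'dynamic_sv'")
        if self.kb <= 0 or self.n <= 0 or self.f0 <= 0:
            raise ValidationError("kb, n and f0 must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.alpha_helix <= 1.0:
            raise ValidationError("alpha_helix must lie in [0, 1]")
        if self.ife_ex < 0 or self.ife_em < 0:
            raise ValidationError("inner-filter coefficients must be >= 0")

    def kb_at(self, temperature: float) -> float:
        """Binding constant from the Van't Hoff line at ``temperature``."""
        return float(np.exp(-self.delta_h / (R_GAS * temperature) + self.delta_s / R_GAS))


def gaussian_band(
    center: float,
    fwhm: float,
    amplitude: float,
    grid,
    kind: str = "emission",
    **meta,
) -> Spectrum:
    """A Gaussian band: ``amplitude`` at ``center``, half maximum at ±fwhm/2."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty wavelength grid")
    if fwhm <= 0:
        raise ValidationError("fwhm must be positive")
    values = amplitude * np.exp(-4.0 * np.log(2.0) * (grid - center) ** 2 / fwhm**2)
    return Spectrum(kind=kind, wavelengths=grid, values=values, **meta)


def _quench_law(truth: GroundTruth, kb: float, concs: np.ndarray) -> np.ndarray:
    if truth.model == "static_hill":
        return truth.f0 / (1.0 + kb * concs**truth.n)
    return truth.f0 / (1.0 + kb * concs)


def simulate_titration(
    truth: GroundTruth,
    ligand_concs=DEFAULT_LIGAND_CONCS,
    temperature: float = 297.0,
    kb: float | None = None,
    seed: int | None = None,
) -> TitrationSeries:
    """Generate one titration from the chosen quenching law.

    ``kb`` overrides ``truth.kb`` (used by the temperature series, where the
    binding constant follows the Van't Hoff line).  With nonzero inner-filter
    coefficients the observed intensities are attenuated and the per-point
    absorbances recorded, so the returned series has ``corrected=False``;
    otherwise it is already on the corrected scale.
    """
    concs = np.asarray(ligand_concs, dtype=float)
    if np.any(concs < 0):
        raise ValidationError("ligand concentrations must be >= 0")
    if concs[0] != 0.0:
        raise ValidationError("titration must start at zero ligand")
    f_true = _quench_law(truth, truth.kb if kb is None else kb, concs)

    has_ife = truth.ife_ex > 0 or truth.ife_em > 0
    if has_ife:
        a_ex = truth.ife_ex * concs
        a_em = truth.ife_em * concs
        observed = f_true * 10.0 ** (-(a_ex + a_em) / 2.0)
    else:
        a_ex = a_em = None
        observed = f_true

    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        observed = observed + rng.normal(0.0, truth.noise_sd, size=observed.shape)
        if np.any(observed <= 0):
            raise ValidationError("noise_sd too large: produced nonpositive intensity")

    return TitrationSeries(
        ligand_concs=concs,
        intensities=observed,
        temperature=temperature,
        protein_conc=DEFAULT_PROTEIN_CONC,
        a_ex=a_ex,
        a_em=a_em,
        corrected=not has_ife,
    )


@dataclass
class TemperatureStudy:
    """Per-temperature ground-truth Kb values and simulated titrations."""

    kb_by_temperature: dict[float, float]
    titrations: dict[float, TitrationSeries]


def simulate_temperature_series(
    truth: GroundTruth, temperatures=DEFAULT_TEMPERATURES, ligand_concs=DEFAULT_LIGAND_CONCS
) -> TemperatureStudy:
    """Titrations at several temperatures with Kb(T) = exp(-ΔH/RT + ΔS/R)."""
    temps = [float(t) for t in temperatures]
    if len(temps) < 2:
        raise ValidationError("need at least 2 temperatures")
    if len(set(temps)) != len(temps):
        raise ValidationError("temperatures must be distinct")
    if any(t <= 0 for t in temps):
        raise ValidationError("temperatures must be positive (kelvin)")
    kb_by_t = {t: truth.kb_at(t) for t in temps}
    titrations = {
        t: simulate_titration(
            truth, ligand_concs, temperature=t, kb=kb_by_t[t], seed=truth.seed + i
        )
        for i, t in enumerate(temps)
    }
    return TemperatureStudy(kb_by_temperature=kb_by_t, titrations=titrations)


def simulate_cd(
    alpha_fraction: float,
    protein_conc: float = DEFAULT_PROTEIN_CONC,
    n_residues: int = BSA_N_RESIDUES,
    path_cm: float = 0.1,
    grid=None,
) -> Spectrum:
    """A far-UV CD spectrum with the α-helix double minimum at 208/222 nm.

    The 208 nm signal is pinned exactly to the two-point helicity scale:
    MRE₂₀₈ = −(4000 + 29000·α), converted to millidegrees via
    CD = MRE · 10 · n_residues · path_cm · protein_conc.  Band shapes are
    two negative Gaussian lobes; only the 208 nm point is quantitative.
    """
    if not 0.0 <= alpha_fraction <= 1.0:
        raise ValidationError("alpha_fraction must lie in [0, 1]")
    if protein_conc <= 0 or path_cm <= 0 or n_residues <= 0:
        raise ValidationError("protein_conc, path_cm and n_residues must be positive")
    if grid is None:
        grid = np.arange(200.0, 261.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    mre_208 = -(4000.0 + 29000.0 * alpha_fraction)
    cd_208 = mre_208 * 10.0 * n_residues * path_cm * protein_conc
    lobe_208 = np.exp(-4.0 * np.log(2.0) * (grid - 208.0) ** 2 / 11.0**2)
    lobe_222 = np.exp(-4.0 * np.log(2.0) * (grid - 222.0) ** 2 / 13.0**2)
    shape = lobe_208 + 0.92 * lobe_222
    at_208 = np.exp(-4.0 * np.log(2.0) * (208.0 - 208.0) ** 2 / 11.0**2) + 0.92 * np.exp(
        -4.0 * np.log(2.0) * (208.0 - 222.0) ** 2 / 13.0**2
    )
    values = (cd_208 / at_208) * shape
    return Spectrum(
        kind="cd", wavelengths=grid, values=values, protein_conc=protein_conc
    )


def simulate_absorbance(
    band_center: float = 350.0,
    band_width: float = 50.0,
    epsilon_max: float = 1.2e4,
    conc: float = 3e-5,
    grid=None,
) -> Spectrum:
    """Ligand absorbance A(λ) = ε(λ)·conc·1 cm with a Gaussian ε profile."""
    if epsilon_max <= 0:
        raise ValidationError("epsilon_max must be positive")
    if conc < 0:
        raise ValidationError("concentration must be >= 0")
    if grid is None:
        grid = np.arange(300.0, 401.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    eps = epsilon_max * np.exp(-4.0 * np.log(2.0) * (grid - band_center) ** 2 / band_width**2)
    return Spectrum(
        kind="absorbance", wavelengths=grid, values=eps * conc, ligand_conc=conc
    )


def simulate_study(
    truth: GroundTruth,
    outdir,
    alpha_free: float = NATIVE_ALPHA_HELIX,
    warfarin_kb_factor: float = 0.04,
    ibuprofen_kb_factor: float = 0.45,
) -> dict:
    """Write a complete synthetic study to ``outdir`` as CSVs + truth YAML.

    Emits: one titration per temperature, donor emission and acceptor
    absorbance spectra for the energy-transfer stage, a free/bound CD pair,
    and a reference-temperature competition set in which each site marker
    lowers the apparent binding constant by the given factor.  Returns the
    ground-truth dictionary that was written.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    study = simulate_temperature_series(truth)
    files: dict[str, str] = {}
    for t, series in study.titrations.items():
        name = f"titration_{int(round(t))}K.csv"
        write_titration(series, outdir / name)
        files[f"titration_{int(round(t))}K"] = name

    emission_grid = np.arange(300.0, 451.0, 1.0)
    donor = gaussian_band(340.0, 40.0, truth.f0, emission_grid, kind="emission",
                          protein_conc=DEFAULT_PROTEIN_CONC)
    write_spectrum(donor, outdir / "donor_emission.csv")
    acceptor = simulate_absorbance(conc=DEFAULT_LIGAND_CONCS[-1])
    write_spectrum(acceptor, outdir / "acceptor_absorbance.csv")

    write_spectrum(simulate_cd(alpha_free), outdir / "cd_free.csv")
    write_spectrum(simulate_cd(truth.alpha_helix), outdir / "cd_complex.csv")

    ref_t = 297.0
    kb_ref = truth.kb_at(ref_t)
    for label, factor in (
        ("base", 1.0),
        ("warfarin", warfarin_kb_factor),
        ("ibuprofen", ibuprofen_kb_factor),
    ):
        series = simulate_titration(
            truth, temperature=ref_t, kb=kb_ref * factor, seed=truth.seed + 100
        )
        write_titration(series, outdir / f"competition_{label}.csv")

    truth_doc = {
        "ground_truth": asdict(truth),
        "derived": {
            "kb_by_temperature": {f"{t:g}": kb for t, kb in study.kb_by_temperature.items()},
            "alpha_free": alpha_free,
            "warfarin_kb_factor": warfarin_kb_factor,
            "ibuprofen_kb_factor": ibuprofen_kb_factor,
        },
    }
    with open(outdir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)
    return truth_doc
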