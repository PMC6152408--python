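"""End-to-end study orchestration.

``run_study`` composes the individual stages — inner-filter correction and
quenching fits per temperature, mechanism call, Van't Hoff thermodynamics,
energy transfer, CD helicity and marker competition — into one
machine-readable report.  Stages are independent: a failure in one is
recorded in the report and the remaining stages still run.  Given the same
input files and constants the report is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cd_analysis, fret, quenching, thermodynamics
from .core_io import read_spectrum, read_titration
from .errors import ValidationError


@dataclass
class StudyConstants:
    tau0: float = quenching.TAU_0
    k2: float = fret.K2_ISOTROPIC
    refractive_index: float = fret.REFRACTIVE_INDEX
    quantum_yield: float = fret.QUANTUM_YIELD
    n_residues: int = cd_analysis.BSA_N_RESIDUES
    path_cm: float = 0.1
    protein_conc: float = 5e-6
    reference_t: float = 297.0

    def __post_init__(self) -> None:
        for name in ("tau0", "k2", "refractive_index", "quantum_yield",
                     "n_residues", "path_cm", "protein_conc", "reference_t"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"constant {name} must be positive")


@dataclass
class StudyConfig:
    """File layout and constants for one complete binding study.

    ``titrations`` maps temperature (K) to a titration CSV.  The FRET, CD
    and competition blocks are optional; missing blocks are reported as
    skipped stages.
    """

    titrations: dict[float, Path] = field(default_factory=dict)
    donor_emission: Path | None = None
    acceptor_absorbance: Path | None = None
    acceptor_conc: float | None = None
    cd_free: Path | None = None
    cd_complex: Path | None = None
    competition_base: Path | None = None
    competition_site1: Path | None = None
    competition_site2: Path | None = None
    constants: StudyConstants = field(default_factory=StudyConstants)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(key):
            value = doc.get(key)
            return (base / value) if value else None

        titrations = {
            float(t): base / p for t, p in (doc.get("titrations") or {}).items()
        }
        constants = StudyConstants(**(doc.get("constants") or {}))
        cfg = cls(
            titrations=titrations,
            donor_emission=resolve("donor_emission"),
            acceptor_absorbance=resolve("acceptor_absorbance"),
            acceptor_conc=doc.get("acceptor_conc"),
            cd_free=resolve("cd_free"),
            cd_complex=resolve("cd_complex"),
            competition_base=resolve("competition_base"),
            competition_site1=resolve("competition_site1"),
            competition_site2=resolve("competition_site2"),
            constants=constants,
        )
        missing = [str(p) for p in cfg.iter_paths() if not p.exists()]
        if missing:
            raise ValidationError(f"missing input files: {', '.join(missing)}")
        return cfg

    def iter_paths(self):
        yield from self.titrations.values()
        for p in (
            self.donor_emission,
            self.acceptor_absorbance,
            self.cd_free,
            self.cd_complex,
            self.competition_base,
            self.competition_site1,
            self.competition_site2,
        ):
            if p is not None:
                yield p


def _corrected(series):
    if series.a_ex is not None and not series.corrected:
        return quenching.inner_filter_correct(series)
    if series.a_ex is None:
        return dataclasses.replace(series, corrected=True)
    return series


def _fit_titration_file(path, temperature, constants):
    series = read_titration(path)
    if series.temperature is None:
        series = dataclasses.replace(series, temperature=float(temperature))
    series = _corrected(series)
    sv = quenching.stern_volmer_fit(series)
    binding = quenching.double_log_fit(series)
    return series, sv, binding


def run_study(config: StudyConfig) -> dict:
    """Execute every configured stage; see the module docstring."""
    constants = config.constants
    report: dict = {"constants": dataclasses.asdict(constants), "stages": {}}

    sv_fits, binding_fits = [], []
    endpoint = None  # (f, f0) at the highest ligand ratio, reference temperature

    def stage(name, fn, skip_if=False, skip_reason="inputs not configured"):
        if skip_if:
            report["stages"][name] = {"status": "skipped", "reason": skip_reason}
            return None
        try:
            result = fn()
        except Exception as exc:  # failure isolation between stages
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            return None
        report["stages"][name] = {"status": "ok", **result}
        return result

    def quench_stage():
        per_t = {}
        for t in sorted(config.titrations):
            series, sv, binding = _fit_titration_file(
                config.titrations[t], t, constants
            )
            sv_fits.append(sv)
            binding_fits.append(binding)
            per_t[f"{t:g}"] = {
                "stern_volmer": dataclasses.asdict(sv),
                "binding": dataclasses.asdict(binding),
            }
            nonlocal endpoint
            if abs(t - constants.reference_t) < 1e-9 or endpoint is None:
                endpoint = (float(series.intensities[-1]), series.f0)
        return {"per_temperature": per_t}

    stage("quenching", quench_stage, skip_if=not config.titrations)

    stage(
        "mechanism",
        lambda: dataclasses.asdict(quenching.classify_mechanism(sv_fits)),
        skip_if=len(sv_fits) < 2,
        skip_reason="needs Stern-Volmer fits at >= 2 temperatures",
    )

    def thermo_stage():
        pairs = [(fit.temperature, fit.kb) for fit in binding_fits]
        params = thermodynamics.thermo_params(pairs, reference_t=constants.reference_t)
        doc = dataclasses.asdict(params)
        doc["delta_h_kj_mol"] = params.delta_h / 1e3
        doc["delta_g_kj_mol"] = params.delta_g / 1e3
        return doc

    stage(
        "thermodynamics",
        thermo_stage,
        skip_if=len(binding_fits) < 2,
        skip_reason="needs binding fits at >= 2 temperatures",
    )

    def fret_stage():
        donor = read_spectrum(config.donor_emission, kind="emission")
        acceptor = read_spectrum(config.acceptor_absorbance, kind="absorbance")
        conc = config.acceptor_conc or acceptor.ligand_conc
        if conc is None:
            raise ValidationError("acceptor concentration required to derive molar absorptivity")
        if endpoint is None:
            raise ValidationError("energy transfer needs a titration for F/F0")
        f, f0 = endpoint
        result = fret.fret_analysis(
            donor,
            acceptor,
            f=f,
            f0=f0,
            acceptor_conc=conc,
            k2=constants.k2,
            refractive_index=constants.refractive_index,
            quantum_yield=constants.quantum_yield,
        )
        return dataclasses.asdict(result)

    stage(
        "fret",
        fret_stage,
        skip_if=config.donor_emission is None or config.acceptor_absorbance is None,
    )

    def cd_stage():
        free = read_spectrum(config.cd_free, kind="cd")
        bound = read_spectrum(config.cd_complex, kind="cd")
        change = cd_analysis.helix_change(
            free,
            bound,
            protein_conc=constants.protein_conc,
            n_residues=constants.n_residues,
            path_cm=constants.path_cm,
        )
        return {
            "free": dataclasses.asdict(change.free),
            "complex": dataclasses.asdict(change.complex),
            "delta_percent": change.delta_percent,
        }

    stage("cd", cd_stage, skip_if=config.cd_free is None or config.cd_complex is None)

    def competition_stage():
        fits = {}
        for label, path in (
            ("base", config.competition_base),
            ("site1", config.competition_site1),
            ("site2", config.competition_site2),
        ):
            series = _corrected(read_titration(path))
            fits[label] = quenching.double_log_fit(series)
        verdict = quenching.competitive_site_assignment(
            fits["base"], fits["site1"], fits["site2"]
        )
        return {
            "fits": {k: dataclasses.asdict(v) for k, v in fits.items()},
            **dataclasses.asdict(verdict),
        }

    stage(
        "competition",
        competition_stage,
        skip_if=any(
            p is None
            for p in (
                config.competition_base,
                config.competition_site1,
                config.competition_site2,
            )
        ),
    )

    return report


def binding_table(report: dict) -> pd.DataFrame:
    """Per-temperature summary table mirroring a standard binding-parameters layout:
    T, Ksv, R², kq, log Kb, Kb, n, R², ΔG, ΔH, ΔS (energies in kJ·mol⁻¹)."""
    quench = report["stages"].get("quenching", {})
    thermo = report["stages"].get("thermodynamics", {})
    rows = []
    for t_key, fits in (quench.get("per_temperature") or {}).items():
        sv, bind = fits["stern_volmer"], fits["binding"]
        row = {
            "T_K": float(t_key),
            "Ksv_L_mol": sv["ksv"],
            "sv_r_squared": sv["r_squared"],
            "kq_L_mol_s": sv["kq"],
            "log_Kb": bind["log_kb"],
            "Kb_L_mol": bind["kb"],
            "n": bind["n"],
            "binding_r_squared": bind["r_squared"],
            "delta_G_kJ_mol": None,
            "delta_H_kJ_mol": None,
            "delta_S_J_mol_K": None,
        }
        if thermo.get("status") == "ok" and abs(float(t_key) - thermo["reference_t"]) < 1e-9:
            row["delta_G_kJ_mol"] = thermo["delta_g"] / 1e3
            row["delta_H_kJ_mol"] = thermo["delta_h"] / 1e3
            row["delta_S_J_mol_K"] = thermo["delta_s"]
        rows.append(row)
    return pd.DataFrame(sorted(rows, key=lambda r: r["T_K"]))


def write_report(report: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    table = binding_table(report)
    table.to_csv(outdir / "binding_table.csv", index=False)
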