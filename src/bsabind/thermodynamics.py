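"""Binding thermodynamics: Van't Hoff regression, Gibbs energy, force type.

ln Kb is regressed on 1/T; the slope gives −ΔH/R and the intercept ΔS/R
(R = 8.314 J·mol⁻¹·K⁻¹).  ΔG = −RT ln Kb at a stated reference
temperature.  The Ross-Subramanian sign rules classify the dominant
interaction: ΔH > 0, ΔS > 0 hydrophobic; ΔH < 0, ΔS < 0 van der Waals +
hydrogen bonding; ΔH < 0, ΔS > 0 electrostatic.  All energies are joules
internally; report layers convert to kJ·mol⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitError, ValidationError

R_GAS = 8.314  # J·mol⁻¹·K⁻¹


@dataclass
class VantHoffFit:
    delta_h: float  # J·mol⁻¹
    delta_s: float  # J·mol⁻¹·K⁻¹
    r_squared: float


@dataclass
class ThermoParams:
    delta_h: float  # J·mol⁻¹
    delta_s: float  # J·mol⁻¹·K⁻¹
    delta_g: float  # J·mol⁻¹ at reference_t
    reference_t: float  # K
    r_squared: float
    force_label: str


def vant_hoff(kb_by_temperature) -> VantHoffFit:
    """OLS of ln Kb on 1/T.

    Parameters
    ----------
    kb_by_temperature:
        Mapping or iterable of (temperature K, Kb) pairs; at least two
        distinct temperatures with positive Kb.
    """
    pairs = _as_pairs(kb_by_temperature)
    if len(pairs) < 2:
        raise FitError("Van't Hoff regression needs >= 2 (T, Kb) pairs")
    temps = np.array([p[0] for p in pairs], dtype=float)
    kbs = np.array([p[1] for p in pairs], dtype=float)
    if np.any(temps <= 0):
        raise ValidationError("temperatures must be positive kelvin")
    if len(set(temps.tolist())) != temps.size:
        raise ValidationError("temperatures must be distinct")
    if np.any(kbs <= 0):
        raise ValidationError("binding constants must be positive")
    x = 1.0 / temps
    y = np.log(kbs)
    if temps.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0
    return VantHoffFit(delta_h=-slope * R_GAS, delta_s=intercept * R_GAS, r_squared=r2)


def _as_pairs(kb_by_temperature) -> list[tuple[float, float]]:
    if hasattr(kb_by_temperature, "items"):
        return sorted((float(t), float(k)) for t, k in kb_by_temperature.items())
    return sorted((float(t), float(k)) for t, k in kb_by_temperature)


def gibbs(kb: float, temperature: float) -> float:
    """ΔG = −RT ln Kb in J·mol⁻¹."""
    if kb <= 0:
        raise ValidationError("kb must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive kelvin")
    return -R_GAS * temperature * float(np.log(kb))


def classify_forces(delta_h: float, delta_s: float) -> str:
    """Dominant binding force from the signs of ΔH and ΔS."""
    if not (np.isfinite(delta_h) and np.isfinite(delta_s)):
        raise ValidationError("delta_h and delta_s must be finite")
    if delta_h > 0 and delta_s > 0:
        return "hydrophobic"
    if delta_h < 0 and delta_s < 0:
        return "vdw_hbond"
    if delta_h < 0 and delta_s > 0:
        return "electrostatic"
    return "unclassified"


def thermo_params(kb_by_temperature, reference_t: float = 297.0) -> ThermoParams:
    """Full thermodynamic summary from per-temperature binding constants.

    ΔG is evaluated at ``reference_t`` from the measured Kb at that
    temperature when one is supplied; otherwise from the Van't Hoff line.
    """
    pairs = _as_pairs(kb_by_temperature)
    fit = vant_hoff(pairs)
    kb_ref = None
    for t, kb in pairs:
        if abs(t - reference_t) < 1e-9:
            kb_ref = kb
            break
    if kb_ref is None:
        kb_ref = float(
            np.exp(-fit.delta_h / (R_GAS * reference_t) + fit.delta_s / R_GAS)
        )
    return ThermoParams(
        delta_h=fit.delta_h,
        delta_s=fit.delta_s,
        delta_g=gibbs(kb_ref, reference_t),
        reference_t=reference_t,
        r_squared=fit.r_squared,
        force_label=classify_forces(fit.delta_h, fit.delta_s),
    )
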