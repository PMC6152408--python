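"""Fluorescence quenching analysis.

Covers the inner-filter correction, the Stern-Volmer and double-logarithmic
binding regressions, the static/dynamic mechanism call, synchronous-scan
peak-shift tracking, and site-marker competitive displacement.

The Stern-Volmer constant is the slope of F₀/F against quencher
concentration; the bimolecular quenching rate kq = Ksv/τ₀ uses the
unquenched fluorophore lifetime τ₀ = 10⁻⁸ s.  Binding constant and
stoichiometry come from the double-log plot
log₁₀((F₀−F)/F) = log₁₀ Kb + n·log₁₀[Q], with [Q] the total added ligand
and F₀ the measured (corrected) zero-ligand intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_io import Spectrum, TitrationSeries
from .errors import FitError, ValidationError

TAU_0 = 1e-8  # s, unquenched fluorophore lifetime
KQ_DIFFUSION_LIMIT = 2.0e10  # L·mol⁻¹·s⁻¹, maximum diffusional quenching rate
SHIFT_TOLERANCE_NM = 1.0  # below this a peak displacement counts as unchanged
COMPETITION_THRESHOLD = 0.05  # log10 units of Kb drop that count as displacement


@dataclass
class SternVolmerFit:
    """F₀/F = intercept + Ksv·[Q]; kq = Ksv/τ₀."""

    ksv: float
    intercept: float
    r_squared: float
    kq: float
    temperature: float | None = None


@dataclass
class BindingFit:
    """Double-log fit: intercept log₁₀ Kb, slope n."""

    log_kb: float
    kb: float
    n: float
    r_squared: float
    temperature: float | None = None
    n_points: int = 0


@dataclass
class MechanismCall:
    """Verdict plus the individual rule firings that support it."""

    label: str  # static | dynamic | ambiguous
    reasons: list[str]


@dataclass
class SynchronousShift:
    """Peak trajectory of a synchronous-scan series at fixed Δλ."""

    delta_lambda: float
    peak_wavelengths: np.ndarray
    peak_intensities: np.ndarray
    net_shift: float
    label: str  # "red shift" | "blue shift" | "unchanged"


@dataclass
class SiteAssignment:
    """Outcome of marker displacement: which albumin pocket binds the ligand."""

    primary_site: str  # "site I" | "site II" | "neither marker site"
    site1_competes: bool
    site2_competes: bool
    delta_log_kb_site1: float
    delta_log_kb_site2: float


def inner_filter_correct(series: TitrationSeries) -> TitrationSeries:
    """Undo excitation/emission attenuation: F_cor = F_obs·10^{(A_ex+A_em)/2}.

    Requires per-point absorbances and an uncorrected series; absorbances
    are non-negative, so no intensity ever decreases.
    """
    if series.corrected:
        raise ValidationError("series is already inner-filter corrected")
    if series.a_ex is None:
        raise ValidationError("inner-filter correction requires a_ex and a_em")
    factor = 10.0 ** ((series.a_ex + series.a_em) / 2.0)
    return replace(series, intensities=series.intensities * factor, corrected=True)


def _require_corrected(series: TitrationSeries) -> None:
    if series.a_ex is not None and not series.corrected:
        raise ValidationError(
            "series carries absorbances but is not corrected; run inner_filter_correct first"
        )


def stern_volmer_fit(series: TitrationSeries) -> SternVolmerFit:
    """Least-squares line through F₀/F vs [Q] over the nonzero points.

    The intercept is left free (not pinned to 1) and reported alongside R².
    """
    _require_corrected(series)
    f0 = series.f0
    if f0 <= 0:
        raise ValidationError("zero-ligand intensity must be positive")
    q = series.ligand_concs[1:]
    ratio = f0 / series.intensities[1:]
    if q.size < 3:
        raise FitError("Stern-Volmer fit needs at least 3 nonzero-concentration points")
    if np.allclose(ratio, ratio[0]):
        # degenerate (unquenched) series: zero slope, R² undefined -> 1 by convention
        return SternVolmerFit(0.0, float(ratio[0]), 1.0, 0.0, series.temperature)
    res = stats.linregress(q, ratio)
    ksv = float(res.slope)
    return SternVolmerFit(
        ksv=ksv,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        kq=ksv / TAU_0,
        temperature=series.temperature,
    )


def double_log_fit(series: TitrationSeries) -> BindingFit:
    """Fit log₁₀((F₀−F)/F) against log₁₀[Q] by ordinary least squares.

    Points with F >= F₀ carry no quenching signal; they are dropped with a
    warning.  At least 3 usable points are required.
    """
    _require_corrected(series)
    f0 = series.f0
    q = series.ligand_concs[1:]
    f = series.intensities[1:]
    usable = f < f0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} titration point(s) with F >= F0 from the double-log fit",
            stacklevel=2,
        )
    q, f = q[usable], f[usable]
    if q.size < 3:
        raise FitError("double-log fit needs at least 3 usable points")
    x = np.log10(q)
    y = np.log10((f0 - f) / f)
    res = stats.linregress(x, y)
    log_kb = float(res.intercept)
    return BindingFit(
        log_kb=log_kb,
        kb=10.0**log_kb,
        n=float(res.slope),
        r_squared=float(res.rvalue**2),
        temperature=series.temperature,
        n_points=int(q.size),
    )


def classify_mechanism(sv_fits: list[SternVolmerFit]) -> MechanismCall:
    """Static vs dynamic quenching from the temperature trend of Ksv and kq.

    Rule A: Ksv strictly decreasing with temperature (ground-state complex
    dissociates on heating).  Rule B: every kq exceeds the diffusional
    collision limit 2×10¹⁰ L·mol⁻¹·s⁻¹.  Both rules firing, or either one
    alone, gives "static"; neither gives "dynamic"; rule B together with a
    strictly *increasing* Ksv trend is contradictory and gives "ambiguous"
    with both observations recorded.
    """
    if len(sv_fits) < 2:
        raise ValidationError("mechanism call needs fits at >= 2 temperatures")
    if any(fit.temperature is None for fit in sv_fits):
        raise ValidationError("every Stern-Volmer fit needs a temperature")
    temps = [fit.temperature for fit in sv_fits]
    if len(set(temps)) != len(temps):
        raise ValidationError("temperatures must be distinct")
    ordered = sorted(sv_fits, key=lambda fit: fit.temperature)
    ksv = np.array([fit.ksv for fit in ordered])
    kq = np.array([fit.kq for fit in ordered])

    decreasing = bool(np.all(np.diff(ksv) < 0))
    increasing = bool(np.all(np.diff(ksv) > 0))
    above_limit = bool(np.all(kq > KQ_DIFFUSION_LIMIT))

    reasons: list[str] = []
    if decreasing:
        reasons.append("Ksv decreases with temperature")
    if increasing:
        reasons.append("Ksv increases with temperature")
    if above_limit:
        reasons.append(f"all kq exceed the diffusion limit {KQ_DIFFUSION_LIMIT:.1e}")

    if decreasing and above_limit:
        return MechanismCall("static", reasons)
    if decreasing:
        return MechanismCall("static", reasons)
    if above_limit and increasing:
        return MechanismCall("ambiguous", reasons)
    if above_limit:
        return MechanismCall("static", reasons)
    return MechanismCall("dynamic", reasons or ["no static-quenching signature"])


def _parabolic_peak(spectrum: Spectrum) -> tuple[float, float]:
    """Peak position refined by a quadratic through the 3 points around the max."""
    i = int(np.argmax(spectrum.values))
    wl, val = spectrum.wavelengths, spectrum.values
    if i == 0 or i == wl.size - 1:
        return float(wl[i]), float(val[i])
    coeffs = np.polyfit(wl[i - 1 : i + 2], val[i - 1 : i + 2], 2)
    a, b, _ = coeffs
    if a >= 0:  # flat or degenerate neighbourhood
        return float(wl[i]), float(val[i])
    peak_wl = -b / (2 * a)
    peak_val = float(np.polyval(coeffs, peak_wl))
    return float(peak_wl), peak_val


def synchronous_shift(
    spectra: list[Spectrum], delta_lambda: float | None = None
) -> SynchronousShift:
    """Track the emission maximum across a synchronous-scan titration.

    All spectra must share the same Δλ.  The net shift (last − first) is
    labelled "red shift" above +1 nm, "blue shift" below −1 nm, otherwise
    "unchanged".
    """
    if not spectra:
        raise ValidationError("no spectra given")
    dls = {s.delta_lambda for s in spectra}
    if len(dls) != 1:
        raise ValidationError(f"mixed delta_lambda values: {sorted(dls)}")
    dl = dls.pop()
    if dl is None:
        raise ValidationError("spectra must be synchronous scans with delta_lambda set")
    if delta_lambda is not None and delta_lambda != dl:
        raise ValidationError(
            f"spectra have delta_lambda {dl} nm, expected {delta_lambda} nm"
        )
    peaks = [_parabolic_peak(s) for s in spectra]
    wavelengths = np.array([p[0] for p in peaks])
    intensities = np.array([p[1] for p in peaks])
    net = float(wavelengths[-1] - wavelengths[0])
    if net > SHIFT_TOLERANCE_NM:
        label = "red shift"
    elif net < -SHIFT_TOLERANCE_NM:
        label = "blue shift"
    else:
        label = "unchanged"
    return SynchronousShift(
        delta_lambda=float(dl),
        peak_wavelengths=wavelengths,
        peak_intensities=intensities,
        net_shift=net,
        label=label,
    )


def competitive_site_assignment(
    base: BindingFit, with_site1_marker: BindingFit, with_site2_marker: BindingFit
) -> SiteAssignment:
    """Assign the principal binding pocket from marker displacement.

    A marker competes when the apparent log₁₀ Kb in its presence drops by
    more than 0.05 relative to the marker-free fit.  If both markers
    compete, the primary site is the one whose marker depresses Kb more.
    Site 1 is the warfarin pocket (subdomain IIA), site 2 the ibuprofen
    pocket (subdomain IIIA).
    """
    temps = {base.temperature, with_site1_marker.temperature, with_site2_marker.temperature}
    if len(temps) != 1:
        raise ValidationError("all competition fits must share one temperature")
    d1 = base.log_kb - with_site1_marker.log_kb
    d2 = base.log_kb - with_site2_marker.log_kb
    c1 = d1 > COMPETITION_THRESHOLD
    c2 = d2 > COMPETITION_THRESHOLD
    if c1 and c2:
        primary = "site I" if with_site1_marker.log_kb < with_site2_marker.log_kb else "site II"
    elif c1:
        primary = "site I"
    elif c2:
        primary = "site II"
    else:
        primary = "neither marker site"
    return SiteAssignment(
        primary_site=primary,
        site1_competes=c1,
        site2_competes=c2,
        delta_log_kb_site1=float(d1),
        delta_log_kb_site2=float(d2),
    )
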