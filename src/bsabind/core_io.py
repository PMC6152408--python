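"""Spectral and titration containers plus plain-text readers and writers.

Conventions
-----------
Wavelengths are nanometres at every API boundary (the FRET module converts
to centimetres internally).  Concentrations are mol·L⁻¹, temperatures
kelvin, CD signals millidegrees.  Fluorescence intensities are arbitrary
units and are never normalised on input: every downstream quantity is a
ratio (F₀/F) or carries an explicit calibration.

File format
-----------
Two to four delimited columns (comma or tab accepted on read, comma
written), an optional one-line column header, and ``#``-prefixed metadata
lines of the form ``# key = value``.  Recognised keys: ``kind``,
``temperature_K``, ``delta_lambda_nm``, ``ligand_conc_M``,
``protein_conc_M``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable

import numpy as np

from .errors import ParseError, RangeError, ValidationError

SPECTRUM_KINDS = ("emission", "absorbance", "synchronous", "cd")

_META_KEYS = {
    "kind",
    "temperature_K",
    "delta_lambda_nm",
    "ligand_conc_M",
    "protein_conc_M",
}


@dataclass
class Spectrum:
    """A single scan: signal on an ascending wavelength grid.

    Parameters
    ----------
    kind:
        One of ``emission``, ``absorbance``, ``synchronous``, ``cd``.
    wavelengths:
        Strictly increasing grid in nm, length >= 2.
    values:
        Signal per grid point (fluorescence a.u., absorbance unitless,
        CD in mdeg).
    temperature:
        Acquisition temperature in K, optional.
    delta_lambda:
        Excitation/emission offset in nm; present iff ``kind`` is
        ``synchronous``.
    ligand_conc, protein_conc:
        Solution composition in mol·L⁻¹, optional.
    """

    kind: str
    wavelengths: np.ndarray
    values: np.ndarray
    temperature: float | None = None
    delta_lambda: float | None = None
    ligand_conc: float | None = None
    protein_conc: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SPECTRUM_KINDS:
            raise ValidationError(
                f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}"
            )
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValidationError("wavelength grid must be 1-D with at least 2 points")
        if self.wavelengths.shape != self.values.shape:
            raise ValidationError("wavelengths and values must have equal length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("spectrum values must be finite")
        if self.kind == "absorbance" and np.any(self.values < 0):
            raise ValidationError("absorbance values must be >= 0")
        if (self.kind == "synchronous") != (self.delta_lambda is not None):
            raise ValidationError(
                "delta_lambda must be present exactly when kind is 'synchronous'"
            )

    def at(self, wavelength: float) -> float:
        """Linearly interpolated signal at ``wavelength`` (nm)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise RangeError(
                f"wavelength {wavelength} nm outside grid [{lo}, {hi}] nm"
            )
        return float(np.interp(wavelength, self.wavelengths, self.values))


@dataclass
class TitrationSeries:
    """Fluorescence at a fixed observation wavelength across a titration.

    ``ligand_concs`` is total added ligand in mol·L⁻¹, strictly increasing
    and starting at exactly 0 (the ligand-free reference defining F₀).
    ``a_ex``/``a_em`` are per-point absorbances at the excitation and
    emission wavelengths used by the inner-filter correction; they are
    either both present or both absent.  ``corrected`` records whether
    ``intensities`` have already been inner-filter corrected.
    """

    ligand_concs: np.ndarray
    intensities: np.ndarray
    temperature: float | None = None
    protein_conc: float | None = None
    a_ex: np.ndarray | None = None
    a_em: np.ndarray | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        self.ligand_concs = np.asarray(self.ligand_concs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ligand_concs.ndim != 1 or self.ligand_concs.size < 2:
            raise ValidationError("titration needs at least 2 points")
        if self.ligand_concs.shape != self.intensities.shape:
            raise ValidationError("ligand_concs and intensities must have equal length")
        if self.ligand_concs[0] != 0.0:
            raise ValidationError("first ligand concentration must be exactly 0")
        if not np.all(np.diff(self.ligand_concs) > 0):
            raise ValidationError("ligand concentrations must be strictly increasing")
        if np.any(self.intensities <= 0):
            raise ValidationError("intensities must be positive")
        if (self.a_ex is None) != (self.a_em is None):
            raise ValidationError("a_ex and a_em must both be present or both absent")
        if self.a_ex is not None:
            self.a_ex = np.asarray(self.a_ex, dtype=float)
            self.a_em = np.asarray(self.a_em, dtype=float)
            if self.a_ex.shape != self.ligand_concs.shape or self.a_em.shape != self.ligand_concs.shape:
                raise ValidationError("a_ex/a_em must match the number of titration points")
            if np.any(self.a_ex < 0) or np.any(self.a_em < 0):
                raise ValidationError("absorbances must be >= 0")

    @property
    def f0(self) -> float:
        """Fluorescence of the ligand-free point."""
        return float(self.intensities[0])


# ---------------------------------------------------------------------------
# parsing helpers


def _open_maybe(source, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(Path(source), mode), True


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [tok.strip() for tok in line.split(",")]
    if "\t" in line:
        return [tok.strip() for tok in line.split("\t")]
    return line.split()


def _parse_table(stream: IO[str]) -> tuple[dict[str, str], list[list[float]]]:
    """Return (metadata, numeric rows); tolerates one column-header line."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header_allowed = True
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                if key in _META_KEYS:
                    meta[key] = value.strip()
            continue
        tokens = _split_row(line)
        try:
            rows.append([float(tok) for tok in tokens])
        except ValueError:
            if header_allowed and not rows:
                header_allowed = False
                continue
            bad = next(t for t in tokens if not _is_number(t))
            raise ParseError(f"line {lineno}: non-numeric field {bad!r}") from None
        header_allowed = False
    return meta, rows


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _meta_float(meta: dict[str, str], key: str) -> float | None:
    return float(meta[key]) if key in meta else None


# ---------------------------------------------------------------------------
# spectra


def read_spectrum(source, kind: str | None = None) -> Spectrum:
    """Read a two-column (wavelength_nm, value) delimited text spectrum.

    ``kind`` overrides any ``# kind = ...`` header; one of the two must be
    available.  Rows are sorted by wavelength; duplicate wavelengths are
    rejected.
    """
    stream, should_close = _open_maybe(source, "r")
    try:
        meta, rows = _parse_table(stream)
    finally:
        if should_close:
            stream.close()
    if any(len(r) != 2 for r in rows):
        raise ParseError("spectrum files must have exactly 2 columns")
    if len(rows) < 2:
        raise ValidationError("spectrum needs at least 2 data rows")
    data = np.asarray(rows, dtype=float)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        raise ValidationError("duplicate wavelengths in spectrum")
    resolved_kind = kind or meta.get("kind")
    if resolved_kind is None:
        raise ValidationError("spectrum kind not given and no '# kind =' header found")
    return Spectrum(
        kind=resolved_kind,
        wavelengths=data[:, 0],
        values=data[:, 1],
        temperature=_meta_float(meta, "temperature_K"),
        delta_lambda=_meta_float(meta, "delta_lambda_nm"),
        ligand_conc=_meta_float(meta, "ligand_conc_M"),
        protein_conc=_meta_float(meta, "protein_conc_M"),
    )


def write_spectrum(spectrum: Spectrum, destination) -> None:
    """Write CSV with ``#`` metadata header; full float precision round trip."""
    stream, should_close = _open_maybe(destination, "w")
    try:
        stream.write(f"# kind = {spectrum.kind}\n")
        for key, value in (
            ("temperature_K", spectrum.temperature),
            ("delta_lambda_nm", spectrum.delta_lambda),
            ("ligand_conc_M", spectrum.ligand_conc),
            ("protein_conc_M", spectrum.protein_conc),
        ):
            if value is not None:
                stream.write(f"# {key} = {value!r}\n")
        stream.write("wavelength_nm,value\n")
        for wl, val in zip(spectrum.wavelengths, spectrum.values):
            stream.write(f"{float(wl)!r},{float(val)!r}\n")
    finally:
        if should_close:
            stream.close()


def spectrum_to_text(spectrum: Spectrum) -> str:
    buf = io.StringIO()
    write_spectrum(spectrum, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# titrations


def read_titration(source) -> TitrationSeries:
    """Read a titration table: ligand_conc_M,intensity[,a_ex,a_em].

    The returned series has ``corrected=False``; apply the inner-filter
    correction downstream if absorbances are present.
    """
    stream, should_close = _open_maybe(source, "r")
    try:
        meta, rows = _parse_table(stream)
    finally:
        if should_close:
            stream.close()
    if not rows:
        raise ValidationError("empty titration table")
    widths = {len(r) for r in rows}
    if widths == {2}:
        data = np.asarray(rows, dtype=float)
        a_ex = a_em = None
    elif widths == {4}:
        data = np.asarray(rows, dtype=float)
        a_ex, a_em = data[:, 2], data[:, 3]
    else:
        raise ValidationError(
            "titration tables need 2 columns (ligand_conc_M,intensity) or 4 "
            "(..,a_ex,a_em); both absorbance columns or neither"
        )
    return TitrationSeries(
        ligand_concs=data[:, 0],
        intensities=data[:, 1],
        temperature=_meta_float(meta, "temperature_K"),
        protein_conc=_meta_float(meta, "protein_conc_M"),
        a_ex=a_ex,
        a_em=a_em,
        corrected=False,
    )


def write_titration(series: TitrationSeries, destination) -> None:
    stream, should_close = _open_maybe(destination, "w")
    try:
        if series.temperature is not None:
            stream.write(f"# temperature_K = {series.temperature!r}\n")
        if series.protein_conc is not None:
            stream.write(f"# protein_conc_M = {series.protein_conc!r}\n")
        if series.a_ex is None:
            stream.write("ligand_conc_M,intensity\n")
            for q, f in zip(series.ligand_concs, series.intensities):
                stream.write(f"{float(q)!r},{float(f)!r}\n")
        else:
            stream.write("ligand_conc_M,intensity,a_ex,a_em\n")
            for q, f, ax, ae in zip(
                series.ligand_concs, series.intensities, series.a_ex, series.a_em
            ):
                stream.write(f"{float(q)!r},{float(f)!r},{float(ax)!r},{float(ae)!r}\n")
    finally:
        if should_close:
            stream.close()


# ---------------------------------------------------------------------------
# resampling


def resample(spectrum: Spectrum, new_grid: Iterable[float]) -> Spectrum:
    """Linear interpolation onto ``new_grid`` (must lie within the data range).

    Idempotent on the spectrum's own grid and exact for constant spectra.
    """
    grid = np.asarray(list(new_grid) if not isinstance(new_grid, np.ndarray) else new_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValidationError("new grid must be 1-D with at least 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ValidationError("new grid must be strictly increasing")
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise RangeError(
            f"requested grid [{grid[0]}, {grid[-1]}] nm extends beyond data [{lo}, {hi}] nm"
        )
    values = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return replace(spectrum, wavelengths=grid, values=values)
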