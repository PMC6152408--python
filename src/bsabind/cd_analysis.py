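"""α-helix content from far-UV circular dichroism.

The raw ellipticity in millidegrees is normalised to mean residue
ellipticity, MRE = CD(mdeg) / (10 · n · l · Cp) with n the residue count
(583 for the bovine protein), l the cell path in cm and Cp the molar
protein concentration.  The 208 nm value maps linearly to helicity between
the two-point anchors −4000 deg·cm²·dmol⁻¹ (0% helix, disordered/β) and
−33000 (100% helix):

    α-helix(%) = (−MRE₂₀₈ − 4000) / 29000 × 100

No clamping is applied; estimates outside [0, 100] are flagged instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Spectrum
from .errors import ValidationError

BSA_N_RESIDUES = 583
MRE_COIL_208 = -4000.0   # deg·cm²·dmol⁻¹ at 0% helix
MRE_HELIX_208 = -33000.0  # deg·cm²·dmol⁻¹ at 100% helix


@dataclass
class HelixEstimate:
    mre_208: float       # deg·cm²·dmol⁻¹
    alpha_percent: float
    protein_conc: float  # mol·L⁻¹
    n_residues: int
    path_cm: float
    out_of_range: bool   # alpha outside [0, 100]


@dataclass
class HelixChange:
    free: HelixEstimate
    complex: HelixEstimate
    delta_percent: float  # complex − free, percentage points


def mean_residue_ellipticity(
    cd_mdeg: float,
    n_residues: int = BSA_N_RESIDUES,
    path_cm: float = 0.1,
    protein_conc: float = 5e-6,
) -> float:
    if n_residues <= 0 or path_cm <= 0 or protein_conc <= 0:
        raise ValidationError("n_residues, path_cm and protein_conc must be positive")
    return cd_mdeg / (10.0 * n_residues * path_cm * protein_conc)


def helix_percent(mre_208: float) -> float:
    if not np.isfinite(mre_208):
        raise ValidationError("MRE must be finite")
    return (-mre_208 + MRE_COIL_208) / (MRE_COIL_208 - MRE_HELIX_208) * 100.0


def helix_estimate(
    spectrum: Spectrum,
    protein_conc: float,
    n_residues: int = BSA_N_RESIDUES,
    path_cm: float = 0.1,
) -> HelixEstimate:
    """Helicity from the 208 nm point of a CD spectrum (mdeg).

    The signal at exactly 208 nm is linearly interpolated between the
    bracketing grid points; the grid must cover 208 nm.
    """
    cd_208 = spectrum.at(208.0)
    mre = mean_residue_ellipticity(cd_208, n_residues, path_cm, protein_conc)
    alpha = helix_percent(mre)
    return HelixEstimate(
        mre_208=mre,
        alpha_percent=alpha,
        protein_conc=protein_conc,
        n_residues=n_residues,
        path_cm=path_cm,
        out_of_range=not (0.0 <= alpha <= 100.0),
    )


def helix_change(
    free_spectrum: Spectrum,
    complex_spectrum: Spectrum,
    protein_conc: float,
    n_residues: int = BSA_N_RESIDUES,
    path_cm: float = 0.1,
) -> HelixChange:
    """Helicity of the free and ligand-bound protein plus their difference."""
    free = helix_estimate(free_spectrum, protein_conc, n_residues, path_cm)
    bound = helix_estimate(complex_spectrum, protein_conc, n_residues, path_cm)
    return HelixChange(
        free=free, complex=bound, delta_percent=bound.alpha_percent - free.alpha_percent
    )
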