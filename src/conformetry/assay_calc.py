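"""Deterministic calculators for colorimetric and CD readouts.

Three small, pure calculators used around protein thiol chemistry:

* Ellman's (DTNB) assay — free-thiol concentration from A412 against a
  cysteine standard curve, reported as thiols per protein molecule;
* HABA/avidin displacement assay — biotin label density from the drop
  in A500 via the complex's extinction coefficient;
* CD normalisation — mean residue delta epsilon (MRDE), the molar CD
  signal per residue, from raw ellipticity in millidegrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "AssayResult",
    "fit_standard_curve",
    "thiol_ratio",
    "biotin_ratio",
    "mrde",
    "HABA_AVIDIN_EPSILON_M_CM",
    "MDEG_TO_DELTA_EPSILON",
]

#: Extinction coefficient of the HABA/avidin complex at 500 nm
#: (manufacturer convention), 1/(M cm).
HABA_AVIDIN_EPSILON_M_CM = 34000.0
#: theta[mdeg] = 32980 * delta_epsilon * c[M] * l[cm] per residue.
MDEG_TO_DELTA_EPSILON = 32980.0


@dataclass
class StandardCurve:
    """Linear calibration: absorbance = slope * concentration + intercept."""

    slope: float          # absorbance per mM
    intercept: float
    r_squared: float


@dataclass
class AssayResult:
    """An analyte concentration and its per-protein stoichiometry."""

    analyte_uM: float
    protein_uM: float
    ratio: float


def fit_standard_curve(concentrations_mM, absorbances) -> StandardCurve:
    """Ordinary least-squares line through calibration points."""
    c = np.asarray(concentrations_mM, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size or c.size < 2:
        raise ValueError("need >= 2 paired calibration points")
    if np.allclose(c, c[0]):
        raise ValueError("calibration needs at least two distinct concentrations")
    res = stats.linregress(c, a)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def thiol_ratio(sample_A412: float, curve: StandardCurve,
                dilution: float, protein_uM: float) -> AssayResult:
    """Free thiols per protein molecule from an Ellman's assay reading.

    The sample absorbance is inverted through the cysteine standard
    curve (mM), multiplied by the dilution factor applied before the
    reading, and divided by the protein concentration.
    """
    if not (curve.slope > 0):
        raise ValueError("standard-curve slope must be positive")
    if not (protein_uM > 0):
        raise ValueError("protein concentration must be positive")
    if not (dilution > 0):
        raise ValueError("dilution factor must be positive")
    thiol_mM = (sample_A412 - curve.intercept) / curve.slope * dilution
    if thiol_mM < 0:
        warnings.warn("absorbance below intercept: thiol clamped to 0",
                      stacklevel=2)
        thiol_mM = 0.0
    thiol_uM = thiol_mM * 1000.0
    return AssayResult(analyte_uM=float(thiol_uM), protein_uM=float(protein_uM),
                       ratio=float(thiol_uM / protein_uM))


def biotin_ratio(delta_A500: float, protein_uM: float,
                 epsilon_M_cm: float = HABA_AVIDIN_EPSILON_M_CM,
                 path_cm: float = 1.0) -> AssayResult:
    """Biotin labels per protein molecule from a HABA/avidin assay.

    ``delta_A500`` is the absorbance decrease of the HABA/avidin
    complex on biotin addition; Beer-Lambert gives the displaced
    complex (= biotin) concentration.
    """
    if not (epsilon_M_cm > 0 and path_cm > 0):
        raise ValueError("extinction coefficient and path length must be positive")
    if not (protein_uM > 0):
        raise ValueError("protein concentration must be positive")
    if delta_A500 < 0:
        warnings.warn("negative delta A500 clamped to 0", stacklevel=2)
        delta_A500 = 0.0
    biotin_uM = delta_A500 / (epsilon_M_cm * path_cm) * 1.0e6
    return AssayResult(analyte_uM=float(biotin_uM), protein_uM=float(protein_uM),
                       ratio=float(biotin_uM / protein_uM))


def mrde(theta_mdeg, protein_M: float, path_cm: float, n_residues: int):
    """Mean residue delta epsilon from raw (blank-corrected) CD signal.

    ``delta_epsilon = theta / (32980 * c * l * N)`` with theta in
    millidegrees, c the molar protein concentration, l the path length
    in cm and N the residue count — normalising the spectrum for
    concentration, number of amino acids, and cuvette path length.
    Accepts a scalar or a per-wavelength array.
    """
    if not (protein_M > 0):
        raise ValueError("protein concentration must be positive")
    if not (path_cm > 0):
        raise ValueError("path length must be positive")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    theta = np.asarray(theta_mdeg, dtype=float)
    out = theta / (MDEG_TO_DELTA_EPSILON * protein_M * path_cm * n_residues)
    if np.isscalar(theta_mdeg) or out.ndim == 0:
        return float(out)
    return out
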