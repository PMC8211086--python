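"""Modified Beer-Lambert law: extinction coefficients, the age-specific
differential pathlength factor, and the OD <-> concentration conversions
shared by the forward simulator and the preprocessing chain.

Conventions: natural-log optical density (Homer-compatible); concentrations
reported in micromolar (uM); extinction coefficients in cm^-1 / M from the
Prahl hemoglobin compilation (the values tabulated in Homer); source-detector
distances in mm.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EXTINCTION_CM_PER_M",
    "WAVELENGTHS_NM",
    "dpf",
    "extinction_matrix",
    "concentration_to_od",
    "od_to_concentration_pair",
]

#: Standard wavelength pair of the continuous-wave instrument.
WAVELENGTHS_NM = (760.0, 850.0)

#: Molar extinction coefficients (cm^-1 / M): {wavelength: (HbO, HbR)}.
#: Prahl compilation (as shipped with Homer2).
EXTINCTION_CM_PER_M = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}

# General DPF(wavelength, age) polynomial coefficients (Scholkmann & Wolf 2013):
# DPF = a + b*A^c + d*l^3 + e*l^2 + f*l  with age A in years, wavelength l in nm.
_DPF_COEFFS = (223.3, 0.05624, 0.8493, -5.723e-7, 0.001245, -0.9025)


def dpf(wavelength_nm: float, age_years: float) -> float:
    """Age- and wavelength-specific differential pathlength factor."""
    if not 0 <= age_years <= 120:
        raise ValueError("age must be in [0, 120] years")
    a, b, c, d, e, f = _DPF_COEFFS
    lam = float(wavelength_nm)
    return a + b * age_years**c + d * lam**3 + e * lam**2 + f * lam


def extinction_matrix(wavelengths_nm=WAVELENGTHS_NM) -> np.ndarray:
    """2x2 matrix E with E[w] = (eps_HbO, eps_HbR) in cm^-1 / M."""
    rows = []
    for w in wavelengths_nm:
        if float(w) not in EXTINCTION_CM_PER_M:
            raise KeyError(f"no extinction coefficients tabulated at {w} nm")
        rows.append(EXTINCTION_CM_PER_M[float(w)])
    return np.asarray(rows, dtype=float)


def _pathlengths_cm(distance_mm: float, age_years: float, wavelengths_nm):
    return np.array([dpf(w, age_years) for w in wavelengths_nm]) * \
        (distance_mm / 10.0)


def concentration_to_od(hbo_um: np.ndarray, hbr_um: np.ndarray,
                        distance_mm: float, age_years: float,
                        wavelengths_nm=WAVELENGTHS_NM) -> np.ndarray:
    """Forward modified Beer-Lambert: OD change per wavelength.

    Returns an array of shape (n_wavelengths, n_samples) given uM inputs.
    """
    E = extinction_matrix(wavelengths_nm)  # cm^-1 / M
    L = _pathlengths_cm(distance_mm, age_years, wavelengths_nm)  # cm
    conc_m = np.vstack([hbo_um, hbr_um]) * 1e-6  # M
    return (E @ conc_m) * L[:, None]


def od_to_concentration_pair(od: np.ndarray, distance_mm: float,
                             age_years: float,
                             wavelengths_nm=WAVELENGTHS_NM):
    """Invert the 2x2 extinction system per sample.

    ``od`` has shape (2, n_samples); returns (hbo_um, hbr_um).
    """
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    E = extinction_matrix(wavelengths_nm)
    L = _pathlengths_cm(distance_mm, age_years, wavelengths_nm)
    A = E * L[:, None]
    if abs(np.linalg.det(A)) < 1e-12:
        raise np.linalg.LinAlgError("extinction system is singular")
    conc_m = np.linalg.solve(A, np.asarray(od, dtype=float))
    return conc_m[0] * 1e6, conc_m[1] * 1e6
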