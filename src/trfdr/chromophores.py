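"""Chromophore absorption basis and scattering law shared by the generator
and the spectral inversion.

The basis is generic "blood-like" shapes, not literature extinction data:
an oxygenated band pair near 542/576 nm, a single deoxygenated band near
556 nm, and a flat offset.  Because the synthetic ground truth is built
from the same basis, noiseless spectra are exactly representable by the
inversion model.
"""

from __future__ import annotations

import numpy as np

BASIS_NAMES = ("oxy", "deoxy", "offset")


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def oxy_band(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Oxygenated-hemoglobin-like shape: twin bands at 542 and 576 nm (unit scale)."""
    lam = np.asarray(wavelengths_nm, float)
    return (
        _gauss(lam, 542.0, 12.0)
        + 0.8 * _gauss(lam, 576.0, 9.0)
        + 0.25 * np.exp(-(lam - 400.0) / 80.0)
    )


def deoxy_band(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Deoxygenated-hemoglobin-like shape: single band at 556 nm (unit scale)."""
    lam = np.asarray(wavelengths_nm, float)
    return 1.1 * _gauss(lam, 556.0, 15.0) + 0.3 * np.exp(-(lam - 400.0) / 90.0)


def flat_band(wavelengths_nm: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(wavelengths_nm, float))


def absorption_basis(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Stack the three basis shapes into a (3, n_wavelengths) matrix."""
    return np.vstack(
        [oxy_band(wavelengths_nm), deoxy_band(wavelengths_nm), flat_band(wavelengths_nm)]
    )


def absorption_spectrum(wavelengths_nm: np.ndarray, coefficients) -> np.ndarray:
    """mu_a(lambda) = sum_k c_k * basis_k(lambda), coefficients ordered as BASIS_NAMES."""
    c = np.asarray(coefficients, float)
    if c.shape != (len(BASIS_NAMES),):
        raise ValueError(f"expected {len(BASIS_NAMES)} coefficients, got {c.shape}")
    if np.any(c < 0):
        raise ValueError("absorption coefficients must be nonnegative")
    return c @ absorption_basis(wavelengths_nm)


def scattering_spectrum(wavelengths_nm: np.ndarray, amplitude: float, power: float) -> np.ndarray:
    """Reduced scattering power law mu_s'(lambda) = a * (lambda/500)^(-b)."""
    if amplitude <= 0:
        raise ValueError("scattering amplitude must be positive")
    lam = np.asarray(wavelengths_nm, float)
    return amplitude * (lam / 500.0) ** (-power)
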