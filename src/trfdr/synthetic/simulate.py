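"""Raw-measurement simulators for one region of interest.

TRF: multi-exponential decays on a uniform time axis, 11 pulses per
emission wavelength, additive Gaussian noise.  DR: gain- and
background-distorted reflectance counts plus the two reference spectra
(water background and 99% reflectance standard) needed for correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import DR_WAVELENGTHS, EMISSION_WAVELENGTHS, N_PULSES, RHO_MM, DRMeasurement, TRFMeasurement
from .forward import forward_reflectance
from .library import OpticalGroundTruth

__all__ = ["TRFSimConfig", "DRSimConfig", "simulate_trf", "simulate_dr"]


def _resolve_rng(sigma: float, seed, rng):
    if rng is not None:
        return rng
    if sigma > 0 and seed is None:
        raise ValueError("noisy simulation requires a seed (reproducibility contract)")
    return np.random.default_rng(seed)


@dataclass
class TRFSimConfig:
    """Time axis, pulse count and noise level for the TRF simulator.

    ``sigma`` is the Gaussian noise standard deviation in the same
    (arbitrary) units as the noiseless signal amplitudes.
    """

    t_max_ns: float = 25.0
    dt_ns: float = 0.1
    n_pulses: int = N_PULSES
    sigma: float = 0.01
    seed: int | None = None
    wavelengths: np.ndarray = field(default_factory=lambda: EMISSION_WAVELENGTHS.copy())

    @property
    def time_ns(self) -> np.ndarray:
        n = int(round(self.t_max_ns / self.dt_ns)) + 1
        return np.arange(n) * self.dt_ns


def simulate_trf(gt: OpticalGroundTruth, cfg: TRFSimConfig | None = None,
                 rng: np.random.Generator | None = None) -> TRFMeasurement:
    """Simulate the decay stack: sum_f yield_f * S_f(lambda) * exp(-t/tau_f) + noise."""
    cfg = cfg or TRFSimConfig(sigma=0.0)
    rng = _resolve_rng(cfg.sigma, cfg.seed, rng)
    lam = np.asarray(cfg.wavelengths, float)
    t = cfg.time_ns

    clean = np.zeros((lam.size, t.size))
    for f in gt.fluorophores:
        shape = np.interp(lam, gt.emission_wavelengths, f.emission)
        clean += f.yield_ * shape[:, None] * np.exp(-t[None, :] / f.lifetime_ns)

    decays = np.broadcast_to(clean[:, None, :], (lam.size, cfg.n_pulses, t.size)).copy()
    if cfg.sigma > 0:
        decays += rng.normal(0.0, cfg.sigma, size=decays.shape)
    return TRFMeasurement(lam, t, decays)


@dataclass
class DRSimConfig:
    """Instrument model for the DR simulator.

    The gain curve and background are smooth analytic shapes; the emitted
    standard spectrum is ``gain * standard_reflectivity + background`` so
    the standard correction cancels both exactly in the noiseless case.
    ``sigma`` is relative to the mean (standard - background) level.
    """

    wavelengths: np.ndarray = field(default_factory=lambda: DR_WAVELENGTHS.copy())
    rho: float = RHO_MM
    standard_reflectivity: float = 0.99
    gain_amplitude: float = 4000.0
    gain_center_nm: float = 560.0
    gain_width_nm: float = 180.0
    gain_floor: float = 500.0
    background_level: float = 120.0
    background_slope: float = 0.05  # counts per nm
    sigma: float = 0.0
    seed: int | None = None

    def gain(self) -> np.ndarray:
        lam = np.asarray(self.wavelengths, float)
        return self.gain_floor + self.gain_amplitude * np.exp(
            -0.5 * ((lam - self.gain_center_nm) / self.gain_width_nm) ** 2
        )

    def background(self) -> np.ndarray:
        lam = np.asarray(self.wavelengths, float)
        return self.background_level + self.background_slope * (lam - 400.0)


def simulate_dr(gt: OpticalGroundTruth, cfg: DRSimConfig | None = None,
                rng: np.random.Generator | None = None) -> DRMeasurement:
    """Simulate raw reflectance counts plus background and standard spectra."""
    cfg = cfg or DRSimConfig()
    rng = _resolve_rng(cfg.sigma, cfg.seed, rng)
    lam = np.asarray(cfg.wavelengths, float)

    mu_a = np.interp(lam, gt.dr_wavelengths, gt.mu_a)
    mu_s = np.interp(lam, gt.dr_wavelengths, gt.mu_s)
    refl = forward_reflectance(mu_a, mu_s, rho=cfg.rho)

    gain = cfg.gain()
    bkg = cfg.background()
    raw = gain * refl + bkg
    if cfg.sigma > 0:
        scale = cfg.sigma * float(np.mean(gain * cfg.standard_reflectivity))
        raw = raw + rng.normal(0.0, scale, size=raw.shape)
    standard = gain * cfg.standard_reflectivity + bkg
    return DRMeasurement(lam, raw, bkg, standard)
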