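"""TRF feature extraction: pulse averaging, single-exponential lifetime
fitting, band-averaged lifetimes, and peak-normalized band intensities.

Five features come out of a decay stack: band-averaged lifetimes for the
collagen (380-440 nm), NADH (450-500 nm) and FAD (520-570 nm) emission
bands, and the collagen/FAD integrated band intensities normalized by the
time-integrated 460 nm (NADH peak) signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .types import TRFFeatures, TRFMeasurement

__all__ = [
    "BANDS",
    "NORMALIZER_NM",
    "FitConfig",
    "LifetimeFitError",
    "average_pulses",
    "fit_single_exponential",
    "lifetimes_per_wavelength",
    "band_average_lifetime",
    "integrated_band_intensity",
    "integrated_intensity_at",
    "extract_trf_features",
]

#: Emission bands (nm, inclusive) per fluorophore.
BANDS = {
    "collagen": (380.0, 440.0),
    "nadh": (450.0, 500.0),
    "fad": (520.0, 570.0),
}

#: Wavelength of the NADH emission peak used as the intensity normalizer.
NORMALIZER_NM = 460.0


class LifetimeFitError(RuntimeError):
    """A decay (or band) could not produce a usable lifetime."""


@dataclass
class FitConfig:
    """Fit-window rule and options for the lifetime fit.

    The window runs from the peak sample to the last sample whose
    amplitude is at least ``max(window_fraction * peak, noise_floor)``.
    ``refine=True`` follows the log-linear fit with a nonlinear
    least-squares refinement.
    """

    window_fraction: float = 0.05
    noise_floor: float = 0.0
    reweight_iters: int = 1  # model-weighted refits after the first pass
    refine: bool = False
    max_flagged_fraction: float = 0.5  # band average fails above this
    normalizer: str = "integral"  # "integral" or "peak" at 460 nm


def average_pulses(m: TRFMeasurement) -> np.ndarray:
    """Arithmetic mean over the pulse axis -> (n_wavelengths, n_time)."""
    if m.decays.shape[1] < 1:
        raise ValueError("need at least one pulse per wavelength")
    bad = np.argwhere(np.isnan(m.decays).any(axis=2))
    if bad.size:
        pairs = [(int(m.wavelengths[w]), int(p)) for w, p in bad[:20]]
        raise ValueError(f"NaN samples in decays at (wavelength, pulse): {pairs}")
    return m.decays.mean(axis=1)


def fit_single_exponential(decay: np.ndarray, time_ns: np.ndarray,
                           cfg: FitConfig | None = None) -> float:
    """Lifetime (ns) from a single-exponential fit to one averaged decay.

    A least-squares line through log(decay) vs t over the fit window
    (tau = -1/slope): exact for the model class and initialization-free.
    Residuals are amplitude-weighted (plus ``reweight_iters`` refits with
    model-predicted weights) so the objective approximates linear-space
    least squares rather than over-weighting the tail.  Nonpositive
    samples inside the window are dropped before the log; fewer than 3
    usable samples raises LifetimeFitError.
    """
    cfg = cfg or FitConfig()
    decay = np.asarray(decay, float)
    time_ns = np.asarray(time_ns, float)
    peak_idx = int(np.argmax(decay))
    peak = decay[peak_idx]
    if peak <= 0:
        raise LifetimeFitError("decay has no positive peak")
    threshold = max(cfg.window_fraction * peak, cfg.noise_floor)
    above = np.nonzero(decay >= threshold)[0]
    above = above[above >= peak_idx]
    if above.size == 0:
        raise LifetimeFitError("empty fit window")
    window = slice(peak_idx, above[-1] + 1)
    y = decay[window]
    t = time_ns[window]
    usable = y > 0
    if usable.sum() < 3:
        raise LifetimeFitError(f"only {int(usable.sum())} usable samples in fit window")
    t, y = t[usable], y[usable]
    w = y
    for _ in range(1 + max(cfg.reweight_iters, 0)):
        slope, intercept = np.polyfit(t, np.log(y), 1, w=w)
        w = np.exp(intercept + slope * t)
    if slope >= 0:
        raise LifetimeFitError("non-decaying signal in fit window")
    tau = -1.0 / slope
    if cfg.refine:
        try:
            popt, _ = curve_fit(
                lambda tt, a, tau_: a * np.exp(-tt / tau_),
                t, y, p0=(float(np.exp(intercept)), tau), maxfev=2000,
            )
            if popt[1] > 0:
                tau = float(popt[1])
        except RuntimeError:
            pass  # keep the log-linear estimate
    return float(tau)


def lifetimes_per_wavelength(averaged: np.ndarray, time_ns: np.ndarray,
                             cfg: FitConfig | None = None) -> np.ndarray:
    """Fit every wavelength; failures become NaN (flagged, not dropped)."""
    out = np.full(averaged.shape[0], np.nan)
    for i in range(averaged.shape[0]):
        try:
            out[i] = fit_single_exponential(averaged[i], time_ns, cfg)
        except LifetimeFitError:
            pass
    return out


def _band_mask(wavelengths: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no wavelengths")
    return mask


def band_average_lifetime(taus: np.ndarray, wavelengths: np.ndarray,
                          band: tuple[float, float],
                          max_flagged_fraction: float = 0.5) -> float:
    """Mean lifetime over the band, skipping flagged (NaN) fits.

    Raises LifetimeFitError if more than ``max_flagged_fraction`` of the
    band wavelengths are flagged.
    """
    mask = _band_mask(np.asarray(wavelengths, float), band)
    vals = np.asarray(taus, float)[mask]
    flagged = np.isnan(vals)
    if flagged.mean() > max_flagged_fraction:
        raise LifetimeFitError(
            f"{int(flagged.sum())}/{vals.size} flagged fits in band {band}"
        )
    return float(np.mean(vals[~flagged]))


def integrated_band_intensity(averaged: np.ndarray, time_ns: np.ndarray,
                              wavelengths: np.ndarray,
                              band: tuple[float, float]) -> float:
    """Trapezoidal time integral per wavelength, summed over the band."""
    mask = _band_mask(np.asarray(wavelengths, float), band)
    return float(np.trapezoid(averaged[mask], np.asarray(time_ns, float), axis=1).sum())


def integrated_intensity_at(averaged: np.ndarray, time_ns: np.ndarray,
                            wavelengths: np.ndarray, nm: float) -> float:
    """Time-integrated intensity at the wavelength bin nearest ``nm``."""
    idx = int(np.argmin(np.abs(np.asarray(wavelengths, float) - nm)))
    return float(np.trapezoid(averaged[idx], np.asarray(time_ns, float)))


def extract_trf_features(m: TRFMeasurement, cfg: FitConfig | None = None) -> TRFFeatures:
    """All five TRF features for one measurement.

    Lifetime band failures are flagged (NaN lifetime) rather than raised,
    so a partially usable region still yields a record that downstream
    eligibility filtering can drop.  A nonpositive normalizer is an error
    because no intensity feature is then defined.
    """
    cfg = cfg or FitConfig()
    averaged = average_pulses(m)
    taus = lifetimes_per_wavelength(averaged, m.time_ns, cfg)

    flags: list[str] = []
    band_taus = {}
    for name, band in BANDS.items():
        try:
            band_taus[name] = band_average_lifetime(
                taus, m.wavelengths, band, cfg.max_flagged_fraction
            )
        except LifetimeFitError:
            band_taus[name] = float("nan")
            flags.append(f"tau_{name}_fit_failed")

    if cfg.normalizer == "integral":
        norm = integrated_intensity_at(averaged, m.time_ns, m.wavelengths, NORMALIZER_NM)
    elif cfg.normalizer == "peak":
        idx = int(np.argmin(np.abs(m.wavelengths - NORMALIZER_NM)))
        norm = float(averaged[idx].max())
    else:
        raise ValueError(f"unknown normalizer {cfg.normalizer!r}")
    if norm <= 0:
        raise ValueError("normalizer intensity at 460 nm is nonpositive")

    i_col = integrated_band_intensity(averaged, m.time_ns, m.wavelengths, BANDS["collagen"]) / norm
    i_fad = integrated_band_intensity(averaged, m.time_ns, m.wavelengths, BANDS["fad"]) / norm
    return TRFFeatures(
        tau_collagen=band_taus["collagen"],
        tau_nadh=band_taus["nadh"],
        tau_fad=band_taus["fad"],
        i_collagen=i_col,
        i_fad=i_fad,
        flags=flags,
    )
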