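"""Shared domain types for the TRF-DR pipeline.

Measurement containers are deliberately dumb: plain arrays plus an axis,
validated on construction.  All downstream operations take these objects
rather than bare arrays so that axis conventions are checked once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Emission wavelength axis for time-resolved fluorescence: 380-570 nm in 5 nm steps.
EMISSION_WAVELENGTHS = np.arange(380.0, 571.0, 5.0)

#: Wavelength axis for diffuse reflectance: 400-700 nm in 1 nm steps.
DR_WAVELENGTHS = np.arange(400.0, 701.0, 1.0)

#: Number of excitation pulses fired per emission wavelength.
N_PULSES = 11

#: Source-detector separation of the collection row used for analysis (mm).
RHO_MM = 0.64

TISSUES = ("tumor", "fibroglandular", "adipose")
FLUOROPHORES = ("collagen", "nadh", "fad")

LABEL_TUMOR = "tumor"
LABEL_NO_TUMOR = "no_tumor"


@dataclass(frozen=True)
class TissueComposition:
    """Pathologist-style area annotation for one 1 mm x 1 mm region.

    Integer percentages that sum to 100.  The class label is derived:
    a region is ``tumor`` iff it contains any tumor area.
    """

    p_tumor: int
    p_fibro: int
    p_adipose: int

    def __post_init__(self) -> None:
        for name in ("p_tumor", "p_fibro", "p_adipose"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name}={v} outside [0, 100]")
        total = self.p_tumor + self.p_fibro + self.p_adipose
        if total != 100:
            raise ValueError(f"composition percentages sum to {total}, expected 100")

    @property
    def label(self) -> str:
        return LABEL_TUMOR if self.p_tumor > 0 else LABEL_NO_TUMOR

    @property
    def is_homogeneous(self) -> bool:
        return max(self.p_tumor, self.p_fibro, self.p_adipose) == 100

    def as_fractions(self) -> np.ndarray:
        return np.array([self.p_tumor, self.p_fibro, self.p_adipose], float) / 100.0


@dataclass
class TRFMeasurement:
    """Time-resolved fluorescence decay stack for one region.

    ``decays`` has shape (n_wavelengths, n_pulses, n_time).
    """

    wavelengths: np.ndarray
    time_ns: np.ndarray
    decays: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.time_ns = np.asarray(self.time_ns, float)
        self.decays = np.asarray(self.decays, float)
        if self.decays.ndim != 3:
            raise ValueError("decays must be (wavelength, pulse, time)")
        if self.decays.shape[0] != self.wavelengths.size:
            raise ValueError("decay stack does not match wavelength axis")
        if self.decays.shape[2] != self.time_ns.size:
            raise ValueError("decay stack does not match time axis")
        dt = np.diff(self.time_ns)
        if self.time_ns.size < 2 or np.any(dt <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time axis must be uniform")


@dataclass
class DRMeasurement:
    """Raw diffuse reflectance spectrum with its reference spectra (counts)."""

    wavelengths: np.ndarray
    raw: np.ndarray
    background: np.ndarray
    standard: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        for name in ("raw", "background", "standard"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if arr.shape != self.wavelengths.shape:
                raise ValueError(f"{name} spectrum does not match wavelength axis")


@dataclass
class TRFFeatures:
    """The five TRF features (lifetimes in ns, intensities normalized)."""

    tau_collagen: float
    tau_nadh: float
    tau_fad: float
    i_collagen: float
    i_fad: float
    flags: list[str] = field(default_factory=list)


@dataclass
class DRFeatures:
    """The eight DR features: corrected reflectance and inverted optical properties."""

    dr_520: float
    dr_560: float
    mua_540: float
    mua_560: float
    mua_576: float
    mus_540: float
    mus_560: float
    mus_576: float
    flags: list[str] = field(default_factory=list)


#: Canonical column order of the 13-feature vector used throughout.
FEATURE_COLUMNS = [
    "i_collagen",
    "i_fad",
    "tau_collagen",
    "tau_nadh",
    "tau_fad",
    "dr_520",
    "dr_560",
    "mua_540",
    "mua_560",
    "mua_576",
    "mus_540",
    "mus_560",
    "mus_576",
]
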