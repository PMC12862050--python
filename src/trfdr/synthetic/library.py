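"""Pure-tissue optical library and composition mixing.

The library maps each pure tissue type (tumor, fibroglandular, adipose) to
fluorophore yields/lifetimes, absorption-basis coefficients, and a
scattering power law.  A composition is turned into ground truth by
area-fraction-weighted linear mixing; per-fluorophore mixture lifetimes
are yield-weighted averages.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .. import chromophores
from ..types import (
    DR_WAVELENGTHS,
    EMISSION_WAVELENGTHS,
    FLUOROPHORES,
    TISSUES,
    TissueComposition,
)

__all__ = ["TissueLibrary", "TissueEntry", "OpticalGroundTruth", "Fluorophore",
           "composition_to_optics", "ground_truth_from_params"]


@dataclass(frozen=True)
class TissueEntry:
    """Optical parameters of one pure tissue type."""

    yields: dict[str, float]
    lifetimes_ns: dict[str, float]
    absorption: np.ndarray  # basis coefficients, ordered as chromophores.BASIS_NAMES
    scattering_amplitude: float
    scattering_power: float


@dataclass(frozen=True)
class TissueLibrary:
    version: int
    emission_bands: dict[str, tuple[float, float]]  # fluorophore -> (peak, width) nm
    tissues: dict[str, TissueEntry]

    @classmethod
    def default(cls) -> "TissueLibrary":
        text = (
            importlib.resources.files("trfdr.synthetic")
            .joinpath("tissue_library.yaml")
            .read_text()
        )
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, raw: dict) -> "TissueLibrary":
        bands = {
            f: (float(v["peak_nm"]), float(v["width_nm"]))
            for f, v in raw["emission_bands"].items()
        }
        tissues = {}
        for name, t in raw["tissues"].items():
            tissues[name] = TissueEntry(
                yields={f: float(t["yields"][f]) for f in FLUOROPHORES},
                lifetimes_ns={f: float(t["lifetimes_ns"][f]) for f in FLUOROPHORES},
                absorption=np.array(
                    [float(t["absorption"][k]) for k in chromophores.BASIS_NAMES]
                ),
                scattering_amplitude=float(t["scattering"]["amplitude"]),
                scattering_power=float(t["scattering"]["power"]),
            )
        missing = set(TISSUES) - set(tissues)
        if missing:
            raise ValueError(f"library missing tissues: {sorted(missing)}")
        return cls(version=int(raw.get("version", 0)), emission_bands=bands, tissues=tissues)

    def emission_shape(self, fluorophore: str, wavelengths_nm=EMISSION_WAVELENGTHS) -> np.ndarray:
        peak, width = self.emission_bands[fluorophore]
        lam = np.asarray(wavelengths_nm, float)
        return np.exp(-0.5 * ((lam - peak) / width) ** 2)

    def with_contrast(self, contrast: float) -> "TissueLibrary":
        """Shrink the tumor entry toward the fibroglandular/adipose mean.

        ``contrast=1`` is the library as-is; ``contrast=0`` makes tumor
        optically indistinguishable from the average normal tissue.  Used
        to sweep class overlap in synthetic experiments.
        """
        if not 0.0 <= contrast <= 1.0:
            raise ValueError("contrast must be in [0, 1]")
        normals = [self.tissues["fibroglandular"], self.tissues["adipose"]]

        def blend(get):
            vals = [get(e) for e in normals]
            base = sum(vals) / len(vals)
            return base + contrast * (get(self.tissues["tumor"]) - base)

        tumor = TissueEntry(
            yields={f: blend(lambda e, f=f: e.yields[f]) for f in FLUOROPHORES},
            lifetimes_ns={f: blend(lambda e, f=f: e.lifetimes_ns[f]) for f in FLUOROPHORES},
            absorption=blend(lambda e: e.absorption),
            scattering_amplitude=blend(lambda e: e.scattering_amplitude),
            scattering_power=blend(lambda e: e.scattering_power),
        )
        tissues = dict(self.tissues)
        tissues["tumor"] = tumor
        return replace(self, tissues=tissues)


@dataclass
class Fluorophore:
    name: str
    lifetime_ns: float
    yield_: float
    emission: np.ndarray  # shape over EMISSION_WAVELENGTHS


@dataclass
class OpticalGroundTruth:
    """Composition-resolved optical truth for one region."""

    fluorophores: list[Fluorophore]
    mu_a: np.ndarray  # over dr_wavelengths (mm^-1)
    mu_s: np.ndarray  # reduced scattering over dr_wavelengths (mm^-1)
    dr_wavelengths: np.ndarray
    emission_wavelengths: np.ndarray

    def __post_init__(self) -> None:
        for f in self.fluorophores:
            if f.lifetime_ns <= 0:
                raise ValueError(f"lifetime of {f.name} must be positive")
        if np.any(self.mu_a < 0):
            raise ValueError("mu_a must be nonnegative")
        if np.any(self.mu_s <= 0):
            raise ValueError("mu_s must be positive")


def composition_to_optics(
    comp: TissueComposition,
    library: TissueLibrary | None = None,
    dr_wavelengths: np.ndarray = DR_WAVELENGTHS,
    emission_wavelengths: np.ndarray = EMISSION_WAVELENGTHS,
) -> OpticalGroundTruth:
    """Area-fraction-weighted linear mixture of the pure-tissue entries.

    Absorption coefficients mix linearly (hence so do the mu_a spectra);
    mu_s' spectra mix linearly as evaluated curves.  Mixture lifetime of
    each fluorophore is the yield-weighted mean of the pure lifetimes.
    """
    library = library or TissueLibrary.default()
    w = comp.as_fractions()  # tumor, fibro, adipose
    entries = [library.tissues[t] for t in TISSUES]

    fluors = []
    for f in FLUOROPHORES:
        yields = np.array([e.yields[f] for e in entries])
        taus = np.array([e.lifetimes_ns[f] for e in entries])
        mix_yield = float(w @ yields)
        if mix_yield > 0:
            mix_tau = float(w @ (yields * taus) / mix_yield)
        else:  # degenerate: no signal from this fluorophore at all
            mix_tau = float(w @ taus) if w.sum() else taus.mean()
        fluors.append(
            Fluorophore(f, mix_tau, mix_yield, library.emission_shape(f, emission_wavelengths))
        )

    coeffs = w @ np.stack([e.absorption for e in entries])
    mu_a = chromophores.absorption_spectrum(dr_wavelengths, coeffs)
    mu_s = np.zeros_like(np.asarray(dr_wavelengths, float))
    for wi, e in zip(w, entries):
        mu_s += wi * chromophores.scattering_spectrum(
            dr_wavelengths, e.scattering_amplitude, e.scattering_power
        )
    return OpticalGroundTruth(fluors, mu_a, mu_s, np.asarray(dr_wavelengths, float),
                              np.asarray(emission_wavelengths, float))


def ground_truth_from_params(
    absorption_coefficients,
    scattering_amplitude: float,
    scattering_power: float,
    library: TissueLibrary | None = None,
    fluorophore_spec: dict[str, tuple[float, float]] | None = None,
    dr_wavelengths: np.ndarray = DR_WAVELENGTHS,
) -> OpticalGroundTruth:
    """Build ground truth directly from inversion-basis parameters.

    Convenience for round-trip tests: the resulting mu_a/mu_s spectra lie
    inside the span of the default inversion model by construction.
    ``fluorophore_spec`` maps fluorophore name to (lifetime_ns, yield).
    """
    library = library or TissueLibrary.default()
    spec = fluorophore_spec or {"collagen": (4.5, 0.5), "nadh": (1.0, 1.0), "fad": (2.5, 0.5)}
    fluors = [
        Fluorophore(name, tau, y, library.emission_shape(name))
        for name, (tau, y) in spec.items()
    ]
    mu_a = chromophores.absorption_spectrum(dr_wavelengths, absorption_coefficients)
    mu_s = chromophores.scattering_spectrum(dr_wavelengths, scattering_amplitude, scattering_power)
    return OpticalGroundTruth(fluors, mu_a, mu_s, np.asarray(dr_wavelengths, float),
                              EMISSION_WAVELENGTHS.copy())
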