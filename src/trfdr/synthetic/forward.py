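"""Forward reflectance model and the phantom-style look-up table.

The forward model is the steady-state diffusion approximation for a
semi-infinite homogeneous medium with an extrapolated boundary (dipole
source), evaluated at a single radial source-detector separation.  It
stands in for an experimental phantom calibration: the look-up table is
just the forward model tabulated on an (mu_a, mu_s') grid, which keeps
the generator and the inverter self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from ..types import RHO_MM

__all__ = ["forward_reflectance", "build_lut", "default_lut", "PhantomLUT"]

#: Default grid ranges for the look-up table (mm^-1), log-spaced.
DEFAULT_MU_A_RANGE = (1e-3, 1.0)
DEFAULT_MU_S_RANGE = (0.5, 5.0)
DEFAULT_LUT_SIZE = 50


def _boundary_parameter(n_rel: float) -> float:
    # Groenhuis empirical internal-reflection parameter for relative index n.
    r_d = -1.44 / n_rel**2 + 0.71 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_d) / (1.0 - r_d)


def forward_reflectance(mu_a, mu_s_prime, rho: float = RHO_MM, n_rel: float = 1.4):
    """Steady-state radial diffuse reflectance (dimensionless, per mm^2 sr-less).

    Parameters
    ----------
    mu_a, mu_s_prime
        Absorption and reduced scattering coefficients (mm^-1).  May be
        arrays; they broadcast together.
    rho
        Source-detector separation (mm), default the 0.64 mm collection row.
    n_rel
        Relative refractive index setting the extrapolated-boundary distance.

    Raises
    ------
    ValueError
        If ``mu_a`` is negative or ``mu_s_prime``/``rho`` are not positive.
    """
    mu_a = np.asarray(mu_a, float)
    mu_s = np.asarray(mu_s_prime, float)
    if np.any(mu_a < 0):
        raise ValueError("mu_a must be nonnegative")
    if np.any(mu_s <= 0):
        raise ValueError("mu_s_prime must be positive")
    if rho <= 0:
        raise ValueError("rho must be positive")

    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    z0 = 1.0 / mu_t
    diff = 1.0 / (3.0 * mu_t)
    mu_eff = np.sqrt(3.0 * mu_a * mu_t)
    zb = 2.0 * _boundary_parameter(n_rel) * diff

    r1 = np.hypot(z0, rho)
    r2 = np.hypot(z0 + 2.0 * zb, rho)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    out = albedo / (4.0 * np.pi) * (term1 + term2)
    return out if out.ndim else float(out)


@dataclass
class PhantomLUT:
    """Reflectance tabulated on an ascending (mu_a, mu_s') grid at one rho.

    Interpolation is bilinear in (log10 mu_a, log10 mu_s') coordinates,
    matching the log spacing of the default grids.  Queries outside the
    grid are clamped to its edges.
    """

    mu_a_grid: np.ndarray
    mu_s_grid: np.ndarray
    reflectance: np.ndarray  # shape (n_mu_a, n_mu_s)
    rho: float = RHO_MM
    _interp: RegularGridInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mu_a_grid = np.asarray(self.mu_a_grid, float)
        self.mu_s_grid = np.asarray(self.mu_s_grid, float)
        self.reflectance = np.asarray(self.reflectance, float)
        for name, g in (("mu_a_grid", self.mu_a_grid), ("mu_s_grid", self.mu_s_grid)):
            if g.size < 2 or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be ascending with at least 2 nodes")
        if np.any(self.mu_a_grid <= 0) or np.any(self.mu_s_grid <= 0):
            raise ValueError("grids must be strictly positive (log-coordinate LUT)")
        if self.reflectance.shape != (self.mu_a_grid.size, self.mu_s_grid.size):
            raise ValueError("reflectance node matrix does not match grids")
        if not np.all(np.isfinite(self.reflectance)) or np.any(self.reflectance <= 0):
            raise ValueError("LUT nodes must be finite and positive")
        self._interp = RegularGridInterpolator(
            (np.log10(self.mu_a_grid), np.log10(self.mu_s_grid)),
            self.reflectance,
            method="linear",
            bounds_error=False,
            fill_value=None,
        )

    def interpolate(self, mu_a, mu_s_prime):
        """Bilinear LUT lookup; inputs are clamped into the grid ranges."""
        la = np.clip(np.log10(np.maximum(mu_a, 1e-30)),
                     np.log10(self.mu_a_grid[0]), np.log10(self.mu_a_grid[-1]))
        ls = np.clip(np.log10(np.maximum(mu_s_prime, 1e-30)),
                     np.log10(self.mu_s_grid[0]), np.log10(self.mu_s_grid[-1]))
        pts = np.stack(np.broadcast_arrays(la, ls), axis=-1)
        out = self._interp(pts)
        if np.ndim(mu_a) == 0 and np.ndim(mu_s_prime) == 0:
            return float(np.asarray(out).reshape(()))
        return out


def build_lut(mu_a_grid, mu_s_grid, rho: float = RHO_MM) -> PhantomLUT:
    """Tabulate the forward model on the given ascending grids."""
    mu_a_grid = np.asarray(mu_a_grid, float)
    mu_s_grid = np.asarray(mu_s_grid, float)
    aa, ss = np.meshgrid(mu_a_grid, mu_s_grid, indexing="ij")
    nodes = forward_reflectance(aa, ss, rho=rho)
    return PhantomLUT(mu_a_grid, mu_s_grid, nodes, rho=rho)


def default_lut(n: int = DEFAULT_LUT_SIZE, rho: float = RHO_MM) -> PhantomLUT:
    """The 50x50 log-spaced default LUT (mu_a 0.001-1, mu_s' 0.5-5 mm^-1)."""
    mu_a = np.geomspace(*DEFAULT_MU_A_RANGE, n)
    mu_s = np.geomspace(*DEFAULT_MU_S_RANGE, n)
    return build_lut(mu_a, mu_s, rho=rho)
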