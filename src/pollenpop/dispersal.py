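"""Ballistic pollen dispersal from Stokes settling velocity.

A pollen grain of diameter d falling in still air reaches terminal
velocity

    V_set = g d^2 (rho_p - rho_m) / (18 mu)          (Stokes' law)

and, released at height h_r into a uniform horizontal wind u, travels a
ballistic distance

    D = h_r * u / V_set

before settling. Defaults use standard air density and viscosity, a pollen
density of 0.988 g/cm3 (converted once to SI) and a 3 m/s wind. The model
has no turbulence and no Reynolds-number correction, so it is a
small-particle, still-air idealization; d is a Stokes-equivalent sphere
diameter (elongated grains need a caller-chosen effective diameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DispersalParams:
    g: float = 9.81          # m s^-2
    rho_m: float = 1.225     # air density, kg m^-3
    mu: float = 1.78e-5      # air dynamic viscosity, Pa s
    rho_p: float = 988.0     # pollen density, kg m^-3 (0.988 g cm^-3)
    u_bar: float = 3.0       # horizontal wind speed, m s^-1
    h_r: float = 1.5         # release height, m

    def __post_init__(self) -> None:
        for name in ("g", "rho_m", "mu", "rho_p", "u_bar", "h_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # equality allowed: neutral buoyancy gives V_set = 0 exactly
        if self.rho_p < self.rho_m:
            raise ValueError("pollen density must not be below air density")


def settling_velocity(d, params: DispersalParams | None = None):
    """Stokes settling velocity (m/s) for diameter d (m); d may be an array."""
    params = params or DispersalParams()
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("pollen diameter must be positive")
    v = params.g * d**2 * (params.rho_p - params.rho_m) / (18.0 * params.mu)
    return float(v) if v.ndim == 0 else v


def dispersal_distance(d, params: DispersalParams | None = None):
    """Ballistic dispersal distance D = h_r * u / V_set (m)."""
    params = params or DispersalParams()
    v = settling_velocity(d, params)
    out = params.h_r * params.u_bar / np.asarray(v, dtype=float)
    return float(out) if out.ndim == 0 else out


def distance_grid(
    d_range: np.ndarray,
    h_r_range: np.ndarray,
    params: DispersalParams | None = None,
) -> np.ndarray:
    """Dispersal distance over the diameter x release-height grid.

    Rows follow ``d_range``, columns ``h_r_range``; D decreases along d
    and increases along h_r.
    """
    params = params or DispersalParams()
    d_range = np.asarray(d_range, dtype=float)
    h_r_range = np.asarray(h_r_range, dtype=float)
    if d_range.size == 0 or h_r_range.size == 0:
        raise ValueError("diameter and height ranges must be non-empty")
    v = settling_velocity(d_range, params)
    return np.asarray(h_r_range)[None, :] * params.u_bar / np.asarray(v)[:, None]
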