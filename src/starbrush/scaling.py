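"""Scaling-theory overlays and derived structural quantities.

Two theory curves are provided for comparison with fitted parameters:

* the salted polyelectrolyte-brush height, where screened electrostatics
  act as an effective excluded volume per monomer proportional to the
  squared Debye length, giving the exact power law h ∝ Cs^(-1/3) at fixed
  grafting density;
* a screened-polyelectrolyte chain exponent nu(Cs), monotonically
  decreasing with salt towards a neutral-chain plateau.

The literature closed forms behind both curves exist in several
conventions; the implementations here guarantee the properties actually
used downstream (the -1/3 log-log slope, monotone screening decay, the
prefactors acting as pure multipliers) and keep all conventions in one
parameter block, ``BrushTheoryParams``, so alternative forms can be
swapped in without touching callers.

Also here: the core-residue count n = V_core/(phi_aa * Z), the grafting
distance rho from S = 4 pi R^2 = Z rho^2, and the brush-regime ratio
h/rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import UnsupportedGeometryError

__all__ = [
    "BrushTheoryParams",
    "debye_screening_kappa",
    "salt_brush_height",
    "nu_from_brush_height",
    "polyelectrolyte_nu",
    "core_residues",
    "grafting_distance",
    "brush_regime_ratio",
    "fit_grafting_density_trend",
]

#: Debye length prefactor for monovalent salt in water at room temperature:
#: lambda_D [nm] = 0.304 / sqrt(I [M]).
_DEBYE_PREFACTOR_NM = 0.304


@dataclass(frozen=True)
class BrushTheoryParams:
    """Conventions and constants of the theory overlays.

    c_brush
        Brush-height prefactor (dimensionless), default 0.33.
    b_conv
        Segment length used for the h <-> nu conversion h = b N^nu, in nm,
        default 0.38.
    N
        Chain length in residues, default 146 (full-length chain).
    sigma_g0, sigma_g_slope
        Linear model of the grafting density sigma_g(Cs) = sigma_g0 +
        sigma_g_slope * Cs, in nm^-2 (Cs in mM).  Default: constant
        0.44 nm^-2 (grafting distance ~1.5 nm).
    c_poly
        Polyelectrolyte-exponent prefactor, default 1.24, multiplying the
        nu(Cs) curve.
    z_neutral, s_el
        Dimensionless excluded-volume parameters of the screened-chain
        model: total interaction z = z_neutral + s_el/(kappa_s * b_conv)^2.
    buffer_mM
        Ionic strength contributed by the buffer, added to Cs when
        computing the Debye length (0 = added salt only).
    """

    c_brush: float = 0.33
    b_conv: float = 0.38
    N: int = 146
    sigma_g0: float = 0.44
    sigma_g_slope: float = 0.0
    c_poly: float = 1.24
    z_neutral: float = 0.3
    s_el: float = 0.45
    buffer_mM: float = 0.0

    def __post_init__(self) -> None:
        if self.c_brush <= 0 or self.c_poly <= 0:
            raise ValueError("prefactors must be > 0")
        if self.b_conv <= 0 or self.N < 1:
            raise ValueError("b_conv must be > 0 and N >= 1")

    def grafting_density(self, Cs) -> np.ndarray:
        """sigma_g(Cs) in nm^-2 from the fitted linear trend."""
        return self.sigma_g0 + self.sigma_g_slope * np.asarray(Cs, dtype=float)


def debye_screening_kappa(Cs, params: BrushTheoryParams | None = None):
    """Inverse Debye length kappa_s in nm^-1 for total salinity Cs (mM)."""
    p = params or BrushTheoryParams()
    Cs = np.asarray(Cs, dtype=float)
    if np.any(Cs <= 0) and p.buffer_mM <= 0:
        raise ValueError("Cs must be > 0 mM")
    ionic_M = (Cs + p.buffer_mM) / 1000.0
    return np.sqrt(ionic_M) / _DEBYE_PREFACTOR_NM


def salt_brush_height(
    Cs, params: BrushTheoryParams | None = None, sigma_g: float | None = None
):
    """Brush height h (nm) in the salted-brush regime.

    h = c_brush * N * b * (sigma_g * b^2 * w_eff / b^3)^(1/3) with the
    effective excluded volume w_eff = b / kappa_s^2 shrinking as salt
    screens the electrostatic repulsion.  Since kappa_s^2 ∝ Cs, the height
    obeys d ln h / d ln Cs = -1/3 exactly at fixed grafting density; a
    salinity-dependent sigma_g(Cs) adds the sigma_g^(1/3) correction.
    """
    p = params or BrushTheoryParams()
    Cs = np.asarray(Cs, dtype=float)
    if np.any(Cs <= 0):
        raise ValueError("Cs must be > 0 mM")
    kappa2 = debye_screening_kappa(Cs, p) ** 2
    sg = p.grafting_density(Cs) if sigma_g is None else sigma_g
    w_eff = p.b_conv / kappa2  # nm^3
    h = p.c_brush * p.N * p.b_conv * (sg * w_eff / p.b_conv) ** (1.0 / 3.0)
    return h if h.shape else float(h)


def nu_from_brush_height(h, params: BrushTheoryParams | None = None):
    """Convert a brush height to an apparent Flory exponent via h = b N^nu."""
    p = params or BrushTheoryParams()
    h = np.asarray(h, dtype=float)
    if np.any(h <= p.b_conv):
        raise ValueError(
            f"h must exceed b_conv = {p.b_conv} nm (nu <= 0 is unphysical)"
        )
    nu = np.log(h / p.b_conv) / math.log(p.N)
    return nu if nu.shape else float(nu)


def polyelectrolyte_nu(Cs, params: BrushTheoryParams | None = None):
    """Apparent Flory exponent of an isolated screened polyelectrolyte.

    The chain swells by the standard crossover factor (1+z)^(1/5) of a
    chain with total dimensionless excluded volume z; electrostatics
    contribute s_el/(kappa_s b)^2, which is proportional to 1/Cs, on top
    of a neutral-chain part z_neutral.  The apparent exponent is read off
    the end-to-end scaling, nu = c_poly * ln(R/b)/ln N.  The curve is
    monotonically non-increasing in Cs and approaches the neutral-chain
    plateau as Cs -> infinity; c_poly is a pure multiplier.
    """
    p = params or BrushTheoryParams()
    Cs = np.asarray(Cs, dtype=float)
    if np.any(Cs <= 0):
        raise ValueError("Cs must be > 0 mM")
    kb2 = (debye_screening_kappa(Cs, p) * p.b_conv) ** 2
    z = p.z_neutral + p.s_el / kb2
    r_over_b = math.sqrt(p.N) * (1.0 + z) ** 0.2
    nu = p.c_poly * np.log(r_over_b) / math.log(p.N)
    return nu if nu.shape else float(nu)


def core_residues(V_core: float, Z: float, phi_aa: float) -> float:
    """Residues per chain inside the core, n = V_core / (phi_aa * Z)."""
    if V_core <= 0:
        raise ValueError("V_core must be > 0")
    if Z <= 0 or phi_aa <= 0:
        raise ValueError("Z and phi_aa must be > 0")
    return V_core / (phi_aa * Z)


def grafting_distance(R: float, Z: float) -> float:
    """Grafting distance rho (nm) on a spherical core: 4 pi R^2 = Z rho^2."""
    if R <= 0:
        raise ValueError("R must be > 0")
    if Z < 1:
        raise ValueError("Z must be >= 1")
    return R * math.sqrt(4.0 * math.pi / Z)


def grafting_distance_for(geometry, Z: float) -> float:
    """Grafting distance for a core geometry; spheres only."""
    if geometry.shape != "sphere":
        raise UnsupportedGeometryError(
            "grafting distance is defined on the spherical core surface only"
        )
    return grafting_distance(geometry.R, Z)


def brush_regime_ratio(
    h: float, rho: float, threshold: float = 1.0
) -> tuple[float, bool]:
    """Ratio h/rho and whether it exceeds the brush-regime threshold."""
    if h <= 0 or rho <= 0:
        raise ValueError("h and rho must be > 0")
    ratio = h / rho
    return ratio, ratio > threshold


def fit_grafting_density_trend(Cs_values, rho_values) -> tuple[float, float]:
    """Fit sigma_g = 1/rho^2 linearly in salinity; returns (sigma_g0, slope).

    Used to build the continuous grafting-density function entering the
    salt-brush overlay from per-salinity fitted grafting distances.
    """
    Cs = np.asarray(Cs_values, dtype=float)
    rho = np.asarray(rho_values, dtype=float)
    if Cs.size < 2:
        raise ValueError("need >= 2 salinities")
    sigma = 1.0 / rho**2
    slope, intercept = np.polyfit(Cs, sigma, 1)
    return float(intercept), float(slope)
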