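"""Closed-form scattering models for disordered chains and star-like brushes.

Two model families:

* the extended Guinier form factor for a single disordered chain,

  .. math:: I(q) = I_0 \\exp\\{-\\tfrac13 (qR_G)^2
                  + 0.0479(\\nu - 0.212)(qR_G)^4\\},

  valid up to qR_G ~ 2, with the radius of gyration tied to the Flory
  exponent nu through

  .. math:: R_G = \\sqrt{\\frac{\\gamma(\\gamma+1)}
                  {2(\\gamma+2\\nu)(\\gamma+2\\nu+1)}}\\, b N^{\\nu},

  gamma = 1.615, b = 0.55 nm;

* the decorated-micelle ("star-like") form factor: a small dense core of
  aggregation number Z with Gaussian tails grafted to its surface,

  .. math:: F(q) = Z^2\\beta_c^2 F_c + Z\\beta_t^2 F_t
                 + 2Z^2\\beta_c\\beta_t S_{ct} + Z(Z-1)\\beta_t^2 S_{tt},

  where F_c is the core self-term (sphere or orientation-averaged
  cylinder), F_t the Debye function of one tail, and S_ct / S_tt the
  core-tail and tail-tail cross terms of the standard micelle model with
  tails anchored a distance d*Rg_tail outside the core surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import j1, roots_legendre

__all__ = [
    "DEFAULT_SEGMENT_NM",
    "DEFAULT_GAMMA",
    "ChainParams",
    "CoreGeometry",
    "StarParams",
    "chain_intensity",
    "rg_from_nu",
    "nu_from_rg",
    "core_amplitude",
    "core_self_correlation",
    "debye_chain",
    "tail_amplitude",
    "star_intensity",
    "EXCLUDED_FORM_FACTORS",
]

DEFAULT_SEGMENT_NM = 0.55  # per-residue segment length b for the Rg-nu relation
DEFAULT_GAMMA = 1.615

#: Form factors considered for aggregated curves and rejected for this
#: system: vesicle and lamellar models do not reproduce the combination of
#: a low-q aggregation hump with a high-q disordered-chain rise.  Kept as a
#: registry entry only; deliberately not implemented.
EXCLUDED_FORM_FACTORS = {
    "vesicle": "rejected: no bilayer signature; low-q shape fits a decorated core",
    "lamellar": "rejected: no q^-2 plateau; scattering is particulate, not planar",
}


def _check_nu(nu: float) -> None:
    if not (1.0 / 3.0 <= nu <= 1.0):
        raise ValueError(f"nu={nu} outside the physical Flory range [1/3, 1]")


def rg_from_nu(
    N: float,
    nu: float,
    b: float = DEFAULT_SEGMENT_NM,
    gamma: float = DEFAULT_GAMMA,
) -> float:
    """Radius of gyration (nm) of an N-residue chain with Flory exponent nu."""
    if N < 1:
        raise ValueError("N must be >= 1")
    _check_nu(nu)
    pref = math.sqrt(
        gamma * (gamma + 1.0) / (2.0 * (gamma + 2.0 * nu) * (gamma + 2.0 * nu + 1.0))
    )
    return pref * b * N**nu


def nu_from_rg(
    Rg: float,
    N: float,
    b: float = DEFAULT_SEGMENT_NM,
    gamma: float = DEFAULT_GAMMA,
) -> float:
    """Invert the Rg(nu) relation by bracketed root search on [1/3, 1].

    Raises a domain error naming the attainable bracket when Rg lies
    outside [Rg(1/3), Rg(1)].
    """
    lo, hi = 1.0 / 3.0, 1.0
    rg_lo, rg_hi = rg_from_nu(N, lo, b, gamma), rg_from_nu(N, hi, b, gamma)
    if not (rg_lo <= Rg <= rg_hi):
        raise ValueError(
            f"Rg={Rg:.4g} nm outside attainable range "
            f"[{rg_lo:.4g}, {rg_hi:.4g}] nm for N={N} (nu in [1/3, 1])"
        )
    return brentq(lambda nu: rg_from_nu(N, nu, b, gamma) - Rg, lo, hi, xtol=1e-13)


@dataclass(frozen=True)
class ChainParams:
    """Parameters of the extended Guinier disordered-chain model."""

    I0: float
    Rg: float  # nm
    nu: float
    N: int | None = None
    b: float = DEFAULT_SEGMENT_NM
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if not (self.I0 > 0 and self.Rg > 0):
            raise ValueError("I0 and Rg must be positive")
        # evaluation is defined for any nu in (0, 1]; the special value
        # nu = 0.212 cancels the quartic term and recovers the plain
        # Guinier law.  The Flory range [1/3, 1] is enforced by the fits.
        if not (0.0 < self.nu <= 1.0):
            raise ValueError(f"nu={self.nu} outside (0, 1]")

    @classmethod
    def from_nu(
        cls,
        I0: float,
        N: int,
        nu: float,
        b: float = DEFAULT_SEGMENT_NM,
        gamma: float = DEFAULT_GAMMA,
    ) -> "ChainParams":
        """Construct with Rg tied to nu through the Rg(nu) relation."""
        return cls(I0=I0, Rg=rg_from_nu(N, nu, b, gamma), nu=nu, N=N, b=b, gamma=gamma)


def chain_intensity(q, params: ChainParams, *, warn_window: bool = True):
    """Extended Guinier intensity of a disordered chain.

    Evaluates I0*exp(-(qRg)^2/3 + 0.0479(nu-0.212)(qRg)^4).  Points with
    qRg > 2 are outside the model's validity window; they are evaluated
    anyway but trigger a warning.
    """
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite([params.I0, params.Rg, params.nu])):
        raise ValueError("non-finite chain parameters")
    x = q * params.Rg
    if warn_window and np.any(x > 2.0):
        warnings.warn(
            "chain_intensity evaluated at qRg > 2, beyond the model's "
            "validity window",
            stacklevel=2,
        )
    return params.I0 * np.exp(
        -(x**2) / 3.0 + 0.0479 * (params.nu - 0.212) * x**4
    )


@dataclass(frozen=True)
class CoreGeometry:
    """Geometry of the dense aggregation core (sphere or cylinder)."""

    shape: str  # "sphere" | "cylinder"
    R: float  # nm
    L: float | None = None  # nm, cylinder only

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder"):
            raise ValueError("shape must be 'sphere' or 'cylinder'")
        if self.R <= 0:
            raise ValueError("core radius must be > 0")
        if self.shape == "cylinder" and (self.L is None or self.L <= 0):
            raise ValueError("cylinder requires L > 0")

    @property
    def volume(self) -> float:
        """Core volume in nm^3."""
        if self.shape == "sphere":
            return 4.0 * math.pi * self.R**3 / 3.0
        return math.pi * self.R**2 * self.L

    @property
    def equivalent_radius(self) -> float:
        """Radius of the equal-volume sphere, used in the cross terms."""
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def _sphere_amp(x: np.ndarray) -> np.ndarray:
    # 3(sin x - x cos x)/x^3, series below 1e-4 to avoid 0/0
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def _sinc(x: np.ndarray) -> np.ndarray:
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def _j1c(x: np.ndarray) -> np.ndarray:
    # 2 J1(x)/x with J1 series limit -> 1 at x=0
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-8
    out[nz] = 2.0 * j1(x[nz]) / x[nz]
    return out


_GAUSS_NODES: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GAUSS_NODES:
        x, w = roots_legendre(n)
        # map [-1,1] -> alpha in [0, pi/2]
        alpha = 0.25 * math.pi * (x + 1.0)
        _GAUSS_NODES[n] = (alpha, 0.25 * math.pi * w)
    return _GAUSS_NODES[n]


def _cylinder_amp_grid(q: np.ndarray, R: float, L: float, n_quad: int):
    alpha, w = _gauss(n_quad)
    qa = np.outer(q, np.sin(alpha))
    qb = np.outer(q, np.cos(alpha)) * (L / 2.0)
    amp = _j1c(qa * R) * _sinc(qb)
    return amp, np.sin(alpha) * w


def core_amplitude(q, geometry: CoreGeometry, n_quad: int = 64):
    """Normalized core scattering amplitude Phi(q), Phi(0) = 1.

    Sphere: 3(sin x - x cos x)/x^3 with x = qR.  Cylinder: the
    orientation-averaged amplitude, computed by Gauss-Legendre quadrature
    over the tilt angle.
    """
    q = np.asarray(q, dtype=float)
    if geometry.shape == "sphere":
        return _sphere_amp(q * geometry.R)
    amp, weight = _cylinder_amp_grid(q, geometry.R, geometry.L, n_quad)
    return amp @ weight


def core_self_correlation(q, geometry: CoreGeometry, n_quad: int = 64):
    """Core self-term F_c(q): Phi^2 for a sphere, <A^2> for a cylinder."""
    q = np.asarray(q, dtype=float)
    if geometry.shape == "sphere":
        return _sphere_amp(q * geometry.R) ** 2
    amp, weight = _cylinder_amp_grid(q, geometry.R, geometry.L, n_quad)
    return (amp**2) @ weight


def debye_chain(q, Rg_tail: float):
    """Debye function of a Gaussian chain, F_t(0) = 1.

    F_t = 2(exp(-x) + x - 1)/x^2 with x = (q Rg)^2; series expansion below
    x = 1e-4 for the continuous q -> 0 limit.
    """
    if Rg_tail <= 0:
        raise ValueError("Rg_tail must be > 0")
    q = np.asarray(q, dtype=float)
    x = (q * Rg_tail) ** 2
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 12.0
    xl = x[~small]
    out[~small] = 2.0 * (np.exp(-xl) + xl - 1.0) / xl**2
    return out


def tail_amplitude(q, Rg_tail: float):
    """Gaussian-tail form amplitude psi = (1 - exp(-x))/x, x = (q Rg)^2."""
    q = np.asarray(q, dtype=float)
    x = (q * Rg_tail) ** 2
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs**2 / 6.0
    xl = x[~small]
    out[~small] = (1.0 - np.exp(-xl)) / xl
    return out


@dataclass(frozen=True)
class StarParams:
    """Parameters of the star-like (decorated-core) form factor.

    Z is the aggregation number (chains per star), beta_c / beta_t the
    excess scattering lengths of the core block and of one tail, d the
    tail-anchor displacement in units of Rg_tail (tails centred a distance
    d*Rg_tail outside the core surface).
    """

    Z: float
    core: CoreGeometry
    Rg_tail: float  # nm
    beta_c: float
    beta_t: float
    d: float = 1.0
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError("aggregation number Z must be >= 1")
        if self.Rg_tail <= 0:
            raise ValueError("Rg_tail must be > 0")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def forward_intensity(self) -> float:
        """q -> 0 limit: scale * Z^2 (beta_c + beta_t)^2 + background."""
        return (
            self.scale * self.Z**2 * (self.beta_c + self.beta_t) ** 2
            + self.background
        )


def star_intensity(q, params: StarParams, n_quad: int = 64):
    """Four-term star-like intensity.

    The cross terms use the standard micelle forms: with psi the tail
    amplitude and r_a = R + d*Rg_tail the anchor radius,
    S_ct = Phi(qR) psi sinc(q r_a) and S_tt = psi^2 sinc(q r_a)^2.
    For a cylindrical core the self-term keeps the true orientation
    average while the cross terms use the equal-volume sphere radius.
    """
    p = params
    q = np.asarray(q, dtype=float)
    core = p.core
    F_c = core_self_correlation(q, core, n_quad=n_quad)
    F_t = debye_chain(q, p.Rg_tail)
    psi = tail_amplitude(q, p.Rg_tail)
    R_x = core.R if core.shape == "sphere" else core.equivalent_radius
    phi_x = _sphere_amp(q * R_x)
    sinc_a = _sinc(q * (R_x + p.d * p.Rg_tail))
    S_ct = phi_x * psi * sinc_a
    S_tt = (psi * sinc_a) ** 2
    total = (
        p.Z**2 * p.beta_c**2 * F_c
        + p.Z * p.beta_t**2 * F_t
        + 2.0 * p.Z**2 * p.beta_c * p.beta_t * S_ct
        + p.Z * (p.Z - 1.0) * p.beta_t**2 * S_tt
    )
    return p.scale * total + p.background
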