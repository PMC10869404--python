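"""Weighted least-squares fitting of the star-like brush form factor.

Aggregated curves are fit with the four-term decorated-core model.  The
excess scattering lengths are held fixed (they are degenerate with the
overall scale), the aggregation number Z is continuous during optimisation
and additionally reported rounded, and cylindrical-core fits are performed
on the curve rebinned into 100 logarithmic bins to keep the orientation
quadrature affordable.  A small deterministic latin-hypercube multi-start
guards against local minima.

Derived quantities follow the brush picture: tail height h = 2*Rg_tail,
Flory exponent from inverting the Rg(nu) relation at the full chain length,
relative core-volume error dV/V = sqrt(3 (dR/R)^2) and exponent error
d_nu = ln(1 + dRg/Rg)/ln N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .curves import ScatteringCurve, log_rebin
from .exceptions import FitError
from .form_factors import CoreGeometry, StarParams, nu_from_rg, star_intensity
from .scaling import core_residues, grafting_distance

__all__ = [
    "StarFitConfig",
    "StarFitResult",
    "fit_star",
    "derive_nu_from_height",
    "compare_core_models",
]

DEFAULT_BOUNDS = {
    "Z": (1.0, 50.0),
    "Rg_tail": (0.5, 20.0),
    "R": (0.2, 5.0),
    "L": (0.2, 10.0),
}


@dataclass(frozen=True)
class StarFitConfig:
    """Configuration of one star-model fit.

    ``beta_c`` / ``beta_t`` are the fixed excess scattering lengths (per
    chain) of the core block and the tail.  ``R`` and ``L`` seed the core
    dimensions and are held constant when ``fix_core`` is set.  ``fix_n``
    switches to the constrained mode in which the core-residue count n is
    imposed and the core radius is derived from Z instead of being free.
    """

    shape: str = "sphere"
    beta_c: float = 1.0
    beta_t: float = 1.0
    R: float | None = None  # nm; initial (or fixed) core radius
    L: float | None = None  # nm; cylinder length
    fix_core: bool = False
    n_residues: int = 146
    d: float = 1.0
    phi_aa: float = 0.135  # mean amino-acid partial volume, nm^3
    fix_n: float | None = None
    fix_background: bool = False
    n_starts: int = 5
    seed: int = 0
    rebin_bins: int = 100
    bounds: dict = field(default_factory=dict)

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


@dataclass(frozen=True)
class StarFitResult:
    """Fitted star-model parameters with derived brush quantities."""

    params: StarParams
    param_errors: dict
    h: float  # nm, tail height = 2 Rg_tail
    nu: float
    d_nu: float
    V_core: float  # nm^3
    dV_over_V: float
    n_core: float  # residues per chain inside the core
    rho: float | None  # nm, grafting distance (spherical cores only)
    chi2_red: float
    n_points: int
    n_free: int
    success: bool
    message: str = ""

    @property
    def Z(self) -> float:
        return self.params.Z

    @property
    def Z_rounded(self) -> int:
        return int(round(self.params.Z))


def _geometry(shape: str, R: float, L: float | None) -> CoreGeometry:
    return CoreGeometry(shape=shape, R=R, L=L if shape == "cylinder" else None)


def _radius_from_n(n: float, Z: float, phi_aa: float, shape: str, aspect: float):
    """Core radius reproducing V = n*phi_aa*Z for the constrained-n mode."""
    V = n * phi_aa * Z
    if shape == "sphere":
        return (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0), None
    # cylinder: keep the aspect ratio L/R fixed while scaling the volume
    R = (V / (math.pi * aspect)) ** (1.0 / 3.0)
    return R, aspect * R


def _star_from_lmfit(p: lmfit.Parameters, config: StarFitConfig) -> StarParams:
    if config.fix_n is not None:
        aspect = (config.L / config.R) if config.shape == "cylinder" else 1.0
        R, L = _radius_from_n(
            config.fix_n, p["Z"].value, config.phi_aa, config.shape, aspect
        )
    else:
        R, L = p["R"].value, (p["L"].value if "L" in p else None)
    return StarParams(
        Z=p["Z"].value,
        core=_geometry(config.shape, R, L),
        Rg_tail=p["Rg_tail"].value,
        beta_c=config.beta_c,
        beta_t=config.beta_t,
        d=config.d,
        scale=p["scale"].value,
        background=p["background"].value,
    )


def _residual(p: lmfit.Parameters, q, i, s, config: StarFitConfig):
    return (star_intensity(q, _star_from_lmfit(p, config)) - i) / s


def _latin_hypercube(rng: np.random.Generator, n: int, dims: int) -> np.ndarray:
    # stratified uniform draws in [0,1]^dims, one stratum per start
    u = (rng.random((n, dims)) + np.arange(n)[:, None]) / n
    for d in range(dims):
        u[:, d] = u[rng.permutation(n), d]
    return u


def fit_star(
    curve: ScatteringCurve,
    config: StarFitConfig,
    initial: dict | None = None,
) -> StarFitResult:
    """Fit the star-like form factor to one curve.

    Free parameters: Z, Rg_tail, scale, background, plus the core
    dimensions when ``fix_core`` is False and ``fix_n`` is None.  Returns
    the best of ``n_starts`` deterministic starts by chi-square; an
    explicit ``initial`` mapping of parameter values replaces the
    multi-start with that single starting point.
    """
    if config.shape == "cylinder" and len(curve) > config.rebin_bins:
        curve = log_rebin(curve, config.rebin_bins)
    if config.R is None and (config.fix_core or config.fix_n is None):
        pass  # R will start mid-bounds below
    if config.fix_core and config.R is None:
        raise ValueError("fix_core requires an explicit core radius R")
    if config.shape == "cylinder" and config.fix_core and config.L is None:
        raise ValueError("fixed cylindrical core requires an explicit length L")
    q, i, s = curve.q, curve.intensity, curve.sigma
    if np.any(s <= 0):
        raise ValueError("fit_star requires sigma > 0 everywhere")

    zb, gb = config.bound("Z"), config.bound("Rg_tail")
    rb, lb = config.bound("R"), config.bound("L")
    core_free = (not config.fix_core) and config.fix_n is None
    beta_sum2 = (config.beta_c + config.beta_t) ** 2
    i_fwd = max(float(i[0]), float(np.max(i)) * 1e-6)

    rng = np.random.default_rng(config.seed)
    dims = 2 + (1 if core_free else 0) + (1 if core_free and config.shape == "cylinder" else 0)
    starts = _latin_hypercube(rng, max(config.n_starts - 1, 0), dims)

    def make_params(u: np.ndarray | None) -> lmfit.Parameters:
        p = lmfit.Parameters()
        if u is None:  # heuristic central start
            z0 = 0.5 * (zb[0] + zb[1]) / 5.0 + 1.0
            g0 = math.sqrt(gb[0] * gb[1])
            r0 = config.R if config.R is not None else math.sqrt(rb[0] * rb[1])
            l0 = config.L if config.L is not None else math.sqrt(lb[0] * lb[1])
        else:
            z0 = zb[0] + u[0] * (min(zb[1], 20.0) - zb[0])
            g0 = gb[0] * (min(gb[1], 12.0) / gb[0]) ** u[1]
            if core_free:
                r0 = rb[0] * (rb[1] / rb[0]) ** u[2]
                l0 = (
                    lb[0] * (lb[1] / lb[0]) ** u[3]
                    if config.shape == "cylinder"
                    else None
                )
            else:
                r0, l0 = config.R, config.L
        p.add("Z", value=z0, min=zb[0], max=zb[1])
        p.add("Rg_tail", value=g0, min=gb[0], max=gb[1])
        if config.fix_n is None:
            p.add("R", value=r0 if r0 else 1.0, min=rb[0], max=rb[1],
                  vary=core_free)
            if config.shape == "cylinder":
                p.add("L", value=l0 if l0 else 1.0, min=lb[0], max=lb[1],
                      vary=core_free)
        p.add("scale", value=i_fwd / (z0**2 * beta_sum2), min=0.0)
        p.add("background", value=0.0, min=0.0, max=float(np.max(i)),
              vary=not config.fix_background)
        return p

    def minimize_from(params: lmfit.Parameters):
        return lmfit.minimize(
            _residual, params, args=(q, i, s, config), method="least_squares"
        )

    best = None
    if initial is not None:
        start_params = [make_params(None)]
        for p in start_params:
            for name, value in initial.items():
                if name in p:
                    p[name].set(value=value)
    else:
        start_params = [make_params(u) for u in [None] + list(starts)]
    for sp in start_params:
        try:
            res = minimize_from(sp)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("star-model fit failed from every starting point")

    if core_free and config.shape == "cylinder" and initial is None:
        # cylinders sharing volume V and core radius of gyration
        # (R^2/2 + L^2/12) are nearly degenerate at this resolution; the
        # lengths satisfy L^3/12 - G L + V/(2 pi) = 0, so refit from every
        # other positive root of that cubic and keep the deepest minimum
        bp = best.params
        R0, L0 = bp["R"].value, bp["L"].value
        V0 = math.pi * R0**2 * L0
        G0 = R0**2 / 2.0 + L0**2 / 12.0
        roots = np.roots([1.0 / 12.0, 0.0, -G0, V0 / (2.0 * math.pi)])
        rb_, lb_ = config.bound("R"), config.bound("L")
        for root in roots:
            if abs(root.imag) > 1e-9 or root.real <= 0:
                continue
            L1 = float(root.real)
            if abs(L1 - L0) < 1e-6 * max(L0, 1.0):
                continue
            R1 = math.sqrt(V0 / (math.pi * L1))
            if not (rb_[0] < R1 < rb_[1] and lb_[0] < L1 < lb_[1]):
                continue
            alt = best.params.copy()
            alt["R"].set(value=R1)
            alt["L"].set(value=L1)
            try:
                res = minimize_from(alt)
                if res.chisqr < best.chisqr:
                    best = res
            except Exception:
                pass

    params = _star_from_lmfit(best.params, config)
    errs = {
        name: (best.params[name].stderr if best.params[name].stderr else np.nan)
        for name in best.params
        if best.params[name].vary
    }
    rg_err = errs.get("Rg_tail", np.nan)
    r_err = errs.get("R", np.nan)
    V = params.core.volume
    dV_over_V = (
        math.sqrt(3.0 * (r_err / params.core.R) ** 2)
        if np.isfinite(r_err)
        else np.nan
    )
    try:
        nu = nu_from_rg(params.Rg_tail, config.n_residues)
    except ValueError:
        nu = np.nan
    d_nu = (
        math.log(1.0 + rg_err / params.Rg_tail) / math.log(config.n_residues)
        if np.isfinite(rg_err)
        else np.nan
    )
    n_core = core_residues(V, params.Z, config.phi_aa)
    rho = (
        grafting_distance(params.core.R, params.Z)
        if params.core.shape == "sphere"
        else None
    )
    n_free = sum(1 for name in best.params if best.params[name].vary)
    dof = max(len(q) - n_free, 1)
    return StarFitResult(
        params=params,
        param_errors=errs,
        h=2.0 * params.Rg_tail,
        nu=nu,
        d_nu=d_nu,
        V_core=V,
        dV_over_V=dV_over_V,
        n_core=n_core,
        rho=rho,
        chi2_red=float(best.chisqr) / dof,
        n_points=len(q),
        n_free=n_free,
        success=bool(best.success),
        message=str(getattr(best, "message", "")),
    )


def derive_nu_from_height(result: StarFitResult | float, N: int = 146):
    """Flory exponent (and its error) from a fitted tail height h = 2 Rg.

    Accepts either a StarFitResult or a bare height in nm.  Inverts the
    Rg(nu) relation at chain length N (the full-length chain by default);
    raises a domain error when the height is outside the attainable range.
    """
    if isinstance(result, StarFitResult):
        h = result.h
        rel = (
            result.param_errors.get("Rg_tail", np.nan) / result.params.Rg_tail
        )
    else:
        h, rel = float(result), np.nan
    nu = nu_from_rg(h / 2.0, N)
    d_nu = math.log(1.0 + rel) / math.log(N) if np.isfinite(rel) else np.nan
    return nu, d_nu


def fit_star_replicates(
    curves, config: StarFitConfig
) -> list[StarFitResult]:
    """Fit replicate curves of one sample, reconciling the core geometry.

    For small cylindrical cores measured without the form-factor minimum in
    range, cylinders sharing volume and core radius of gyration are nearly
    degenerate, so independent free-core fits of replicate curves scatter
    between discrete (R, L) branches that a single curve cannot separate.
    Replicates of the same sample must share one geometry: this routine
    fits every curve freely, identifies the candidate branches from the
    median fitted volume and core radius of gyration, selects the branch
    with the lowest total chi-square across all replicates (fixed-core
    refits), and finalizes free-core fits started on that branch.  This
    mirrors the practice of determining core dimensions once and holding
    them constant in production fits.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves given")
    results = [fit_star(c, config) for c in curves]
    core_free = (not config.fix_core) and config.fix_n is None
    if config.shape != "cylinder" or not core_free or len(curves) < 2:
        return results

    # pair each free fit with its conjugate-branch refit (equal volume and
    # core radius of gyration), classify the pair members by aspect ratio,
    # and pick the branch whose per-replicate minima sum to the lower total
    # chi-square
    rb_, lb_ = config.bound("R"), config.bound("L")

    def conjugate_refit(curve, r0: StarFitResult) -> StarFitResult | None:
        R0, L0 = r0.params.core.R, r0.params.core.L
        V0 = math.pi * R0**2 * L0
        G0 = R0**2 / 2.0 + L0**2 / 12.0
        for root in np.roots([1.0 / 12.0, 0.0, -G0, V0 / (2.0 * math.pi)]):
            if abs(root.imag) > 1e-9 or root.real <= 0:
                continue
            L1 = float(root.real)
            if abs(L1 - L0) < 1e-3 * max(L0, 1.0):
                continue
            R1 = math.sqrt(V0 / (math.pi * L1))
            if not (rb_[0] < R1 < rb_[1] and lb_[0] < L1 < lb_[1]):
                continue
            start = {
                "Z": r0.params.Z,
                "Rg_tail": r0.params.Rg_tail,
                "R": R1,
                "L": L1,
                "scale": r0.params.scale,
                "background": r0.params.background,
            }
            try:
                return fit_star(curve, config, initial=start)
            except FitError:
                return None
        return None

    pairs: list[tuple[StarFitResult, StarFitResult]] = []
    for curve, r0 in zip(curves, results):
        r1 = conjugate_refit(curve, r0) or r0
        lo, hi = sorted((r0, r1), key=lambda r: r.params.core.L / r.params.core.R)
        pairs.append((lo, hi))

    def total_chi(idx: int) -> float:
        return sum(
            p[idx].chi2_red * max(p[idx].n_points - p[idx].n_free, 1)
            for p in pairs
        )

    winner = 0 if total_chi(0) <= total_chi(1) else 1
    return [p[winner] for p in pairs]


def compare_core_models(
    curve: ScatteringCurve, configs: list[StarFitConfig]
) -> list[tuple[str, StarFitResult, float]]:
    """Fit every candidate core shape and rank by reduced chi-square.

    Ties (chi2_red equal to within 1e-9 relative) are broken toward the
    model with fewer free parameters.  Raises when every candidate fails.
    """
    if len(configs) < 2:
        raise ValueError("need >= 2 candidate core models to compare")
    entries = []
    failures = []
    for cfg in configs:
        try:
            res = fit_star(curve, cfg)
            entries.append((cfg.shape, res, res.chi2_red))
        except Exception as exc:
            failures.append((cfg.shape, exc))
    if not entries:
        raise FitError(f"all candidate core models failed: {failures}")
    scale = max(c for _, _, c in entries) or 1.0

    def key(entry):
        shape, res, chi = entry
        return (round(chi / scale, 9), res.n_free)

    return sorted(entries, key=key)
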