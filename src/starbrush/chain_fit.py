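"""Extended Guinier fitting of isolated disordered chains.

The fit is a weighted nonlinear least-squares of the extended Guinier model
over the window 0.7 < qRg < 2, chosen self-consistently: a provisional Rg
from a plain Guinier fit seeds the window, the model is refit, the window
is recomputed from the fitted Rg, and the loop repeats until the set of
points inside the window stops changing.  Parameter errors come from the
fit covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .curves import CurveSeries, ScatteringCurve
from .exceptions import FitError, InsufficientDataError

__all__ = ["ChainFitResult", "ChainSeriesFit", "fit_chain", "chain_fit_series"]

NU_BOUNDS = (1.0 / 3.0, 1.0)
WINDOW = (0.7, 2.0)  # in units of qRg
MIN_POINTS = 8


@dataclass(frozen=True)
class ChainFitResult:
    """Result of one extended Guinier chain fit."""

    I0: float
    I0_err: float
    Rg: float  # nm
    Rg_err: float
    nu: float
    nu_err: float
    window: tuple[float, float]  # q range used, nm^-1
    n_points: int
    n_iter: int
    chi2_red: float
    concentration: float | None = None
    label: str = ""


@dataclass(frozen=True)
class ChainSeriesFit:
    """Per-curve chain fits over a series; failures are recorded, not raised."""

    results: tuple[ChainFitResult, ...]
    failures: tuple[tuple[str, Exception], ...] = ()


def _model(q, I0, Rg, nu):
    x = q * Rg
    return I0 * np.exp(-(x**2) / 3.0 + 0.0479 * (nu - 0.212) * x**4)


def provisional_guinier(
    curve: ScatteringCurve, qmax_rg: float = 1.3, max_iter: int = 20
) -> tuple[float, float]:
    """Plain Guinier estimate (I0, Rg) from a weighted ln I vs q^2 line.

    The window qRg < ``qmax_rg`` is itself found iteratively, starting from
    the lowest-q fifth of the curve.
    """
    q, i, s = curve.q, curve.intensity, curve.sigma
    usable = (i > 0) & (s > 0)
    if usable.sum() < 5:
        raise InsufficientDataError("need >= 5 positive-intensity points")
    q, i, s = q[usable], i[usable], s[usable]
    n0 = max(5, q.size // 5)
    mask = np.zeros(q.size, dtype=bool)
    mask[:n0] = True
    rg = None
    for _ in range(max_iter):
        x, y = q[mask] ** 2, np.log(i[mask])
        w = (i[mask] / s[mask]) ** 2  # var(ln I) = (sigma/I)^2
        coef, cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov="unscaled")
        slope, intercept = coef
        if slope >= 0:
            raise FitError(
                "Guinier region has non-negative slope (flat or rising curve); "
                "no finite Rg"
            )
        rg = float(np.sqrt(-3.0 * slope))
        new_mask = q * rg < qmax_rg
        if new_mask.sum() < 5:
            new_mask = np.zeros(q.size, dtype=bool)
            new_mask[:5] = True
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return float(np.exp(intercept)), rg


def fit_chain(
    curve: ScatteringCurve,
    initial: tuple[float, float, float] | None = None,
    max_iter: int = 20,
) -> ChainFitResult:
    """Fit the extended Guinier model on the self-consistent 0.7<qRg<2 window.

    Parameters
    ----------
    curve : ScatteringCurve
        Curve with positive uncertainties.
    initial : (I0, Rg, nu), optional
        Starting values; by default seeded from a plain Guinier fit with
        nu = 0.55.
    max_iter : int
        Maximum window-iteration count before declaring non-convergence.
    """
    q, i, s = curve.q, curve.intensity, curve.sigma
    if np.any(s <= 0):
        raise ValueError("fit_chain requires sigma > 0 everywhere")
    if initial is None:
        i0_g, rg_g = provisional_guinier(curve)
        p = np.array([i0_g, rg_g, 0.55])
    else:
        p = np.array(initial, dtype=float)
    lo = np.array([0.0, 1e-6, NU_BOUNDS[0]])
    hi = np.array([np.inf, np.inf, NU_BOUNDS[1]])
    p = np.clip(p, lo + 1e-12, np.where(np.isinf(hi), p, hi - 1e-12))

    def _local_spacing(q0: float) -> float:
        k = int(np.clip(np.searchsorted(q, q0), 1, q.size - 1))
        return q[k] - q[k - 1]

    trace: list[tuple[float, float]] = []
    seen_masks: list[np.ndarray] = []
    popt = pcov = mask = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        x = q * p[1]
        mask = (x >= WINDOW[0]) & (x <= WINDOW[1])
        if mask.sum() < MIN_POINTS:
            raise InsufficientDataError(
                f"only {int(mask.sum())} points inside 0.7 < qRg < 2 "
                f"(Rg = {p[1]:.3g} nm); need >= {MIN_POINTS}"
            )
        popt, pcov = curve_fit(
            _model,
            q[mask],
            i[mask],
            p0=p,
            sigma=s[mask],
            absolute_sigma=True,
            bounds=(lo, hi),
            maxfev=20000,
        )
        trace.append((float(popt[1]), float(popt[2])))
        new_mask = (q * popt[1] >= WINDOW[0]) & (q * popt[1] <= WINDOW[1])
        if np.array_equal(new_mask, mask):
            converged = True
            p = popt
            break
        # self-consistency: both window edges move by less than half the
        # local q spacing between successive Rg estimates
        shift_lo = abs(WINDOW[0] / popt[1] - WINDOW[0] / p[1])
        shift_hi = abs(WINDOW[1] / popt[1] - WINDOW[1] / p[1])
        if (
            shift_lo < 0.5 * _local_spacing(WINDOW[0] / popt[1])
            and shift_hi < 0.5 * _local_spacing(WINDOW[1] / popt[1])
        ):
            converged = True
            p = popt
            break
        if any(np.array_equal(new_mask, m) for m in seen_masks):
            # window alternates between equivalent point sets whose fits
            # agree to within the grid resolution; accept the current one
            converged = True
            p = popt
            break
        seen_masks.append(mask)
        p = popt
    if not converged:
        raise FitError(
            f"fit window did not stabilize in {max_iter} iterations", trace=trace
        )
    resid = (i[mask] - _model(q[mask], *popt)) / s[mask]
    dof = max(int(mask.sum()) - 3, 1)
    perr = np.sqrt(np.diag(pcov))
    qw = q[mask]
    return ChainFitResult(
        I0=float(popt[0]),
        I0_err=float(perr[0]),
        Rg=float(popt[1]),
        Rg_err=float(perr[1]),
        nu=float(popt[2]),
        nu_err=float(perr[2]),
        window=(float(qw[0]), float(qw[-1])),
        n_points=int(mask.sum()),
        n_iter=n_iter,
        chi2_red=float(resid @ resid / dof),
        concentration=curve.meta.protein_concentration,
        label=curve.meta.label,
    )


def chain_fit_series(series: CurveSeries, **kwargs) -> ChainSeriesFit:
    """Fit every curve of a concentration series independently.

    Results are ordered by concentration, highest first.  Per-curve
    failures are contained and recorded rather than aborting the series.
    """
    order = np.argsort([-(c.meta.protein_concentration or 0.0) for c in series])
    results: list[ChainFitResult] = []
    failures: list[tuple[str, Exception]] = []
    for idx in order:
        curve = series.curves[idx]
        name = curve.meta.label or f"curve[{idx}]"
        try:
            results.append(fit_chain(curve, **kwargs))
        except Exception as exc:  # contain per-curve failures; keep going
            failures.append((name, exc))
    return ChainSeriesFit(results=tuple(results), failures=tuple(failures))
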