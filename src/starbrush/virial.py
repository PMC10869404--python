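"""Zimm analysis of concentration series and zero-concentration extrapolation.

The second virial coefficient A2 is obtained from the first-order Zimm
law, C/I(0,C) = (1/KM)(1 + 2 A2 M C): each curve of a concentration
series is extrapolated to q = 0 by a weighted linear fit of 1/I versus
q^2 over its low-q linear run, and the resulting C/I0 values are fit
linearly in C.  In relative (uncalibrated) intensity units the reported
A2 is the virial product A2*M up to the instrument constant; the ratio
slope/(2*intercept) is independent of the overall intensity scale.

The plot spreading constant alpha (default 0.01) shifts the abscissa of a
traditional Zimm plot (q^2 + alpha*C); it never enters any regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .curves import CurveSeries, ScatteringCurve
from .exceptions import InsufficientDataError

__all__ = [
    "GuinierResult",
    "ZimmResult",
    "ExtrapolationResult",
    "guinier_I0",
    "zimm_fit",
    "extrapolate_zero_conc",
]


@dataclass(frozen=True)
class GuinierResult:
    """Forward intensity from a plain Guinier (ln I vs q^2) line."""

    I0: float
    I0_err: float
    Rg: float
    n_points: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ZimmResult:
    """Zimm analysis of one concentration series."""

    A2: float  # virial product A2*M in relative units (ml/mg scale of C)
    A2_err: float
    intercept: float  # apparent 1/(KM)
    intercept_err: float
    per_conc_I0: tuple[tuple[float, float, float], ...]  # (C, I0, err)
    alpha: float = 0.01
    fit_ranges: tuple[tuple[float, float], ...] = ()

    @property
    def interaction_sign(self) -> int:
        """+1 repulsive, 0 neutral (within error), -1 attractive."""
        if abs(self.A2) <= self.A2_err:
            return 0
        return 1 if self.A2 > 0 else -1


@dataclass(frozen=True)
class ExtrapolationResult:
    """Weighted linear extrapolation of a fitted parameter to C = 0."""

    value_at_zero: float
    err: float
    slope: float
    slope_err: float
    points: tuple[tuple[float, float, float], ...]


def _weighted_line(x, y, sigma):
    """Weighted least-squares line y = a + b x; absolute-error covariance."""
    w = 1.0 / np.asarray(sigma, dtype=float) ** 2
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "rank-deficient design (duplicate abscissa values only)"
        ) from None
    beta = cov @ (X.T @ (w * y))
    return beta, cov


def guinier_I0(
    curve: ScatteringCurve, qmax_rg: float = 1.3, min_points: int = 5
) -> GuinierResult:
    """Forward scattering I0 from the Guinier plot ln I vs q^2.

    The window qRg < ``qmax_rg`` is found self-consistently.  An
    upward-curving Guinier region (an aggregation signature) attaches a
    warning but the fit is still returned.
    """
    q, i, s = curve.q, curve.intensity, curve.sigma
    usable = (i > 0) & (s > 0)
    if usable.sum() < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} positive-intensity points"
        )
    q, i, s = q[usable], i[usable], s[usable]
    x_all, y_all = q**2, np.log(i)
    sy_all = s / i
    mask = np.zeros(q.size, dtype=bool)
    mask[: max(min_points, q.size // 5)] = True
    rg = 0.0
    for _ in range(20):
        beta, cov = _weighted_line(x_all[mask], y_all[mask], sy_all[mask])
        slope = beta[1]
        rg = math.sqrt(max(-3.0 * slope, 0.0))
        new_mask = (
            q * rg < qmax_rg if rg > 0 else mask
        )
        if new_mask.sum() < min_points:
            new_mask = np.zeros(q.size, dtype=bool)
            new_mask[:min_points] = True
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    warns: list[str] = []
    if mask.sum() >= 2 * min_points:
        # curvature check: quadratic term in q^4 significantly positive
        coef, ccov = np.polyfit(
            x_all[mask], y_all[mask], 2, w=1.0 / sy_all[mask], cov="unscaled"
        )
        if coef[0] > 2.0 * math.sqrt(max(ccov[0, 0], 0.0)):
            warns.append(
                "upward-curving Guinier region: possible aggregation or "
                "interparticle structure"
            )
    i0 = math.exp(beta[0])
    return GuinierResult(
        I0=i0,
        I0_err=i0 * math.sqrt(cov[0, 0]),
        Rg=rg,
        n_points=int(mask.sum()),
        warnings=tuple(warns),
    )


def _runs_test_p(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs test (normal approximation) on residual signs."""
    signs = residuals >= 0
    n_pos = int(signs.sum())
    n_neg = signs.size - n_pos
    if n_pos == 0 or n_neg == 0 or signs.size < 5:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = signs.size
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return 2.0 * (1.0 - norm.cdf(abs(z)))


def _linear_run_fit(curve: ScatteringCurve, min_run: int = 5):
    """Fit 1/I vs q^2 over the low-q run, extended until linearity breaks.

    The window grows point by point while the next point's standardized
    residual stays below 3 and the runs test on the in-window residuals
    keeps p > 0.01.
    """
    q, i, s = curve.q, curve.intensity, curve.sigma
    good = i > 0
    q, i, s = q[good], i[good], s[good]
    if q.size < min_run:
        raise InsufficientDataError(f"need >= {min_run} points for the Zimm run")
    x = q**2
    y = 1.0 / i
    sy = s / i**2
    n = min_run
    beta, cov = _weighted_line(x[:n], y[:n], sy[:n])
    while n < q.size:
        pred = beta[0] + beta[1] * x[n]
        std_resid = (y[n] - pred) / sy[n]
        if abs(std_resid) >= 3.0:
            break
        trial_beta, trial_cov = _weighted_line(
            x[: n + 1], y[: n + 1], sy[: n + 1]
        )
        resid = y[: n + 1] - (trial_beta[0] + trial_beta[1] * x[: n + 1])
        if _runs_test_p(resid) <= 0.01:
            break
        beta, cov = trial_beta, trial_cov
        n += 1
    return beta, cov, (float(q[0]), float(q[n - 1]))


def zimm_fit(series: CurveSeries, alpha: float = 0.01) -> ZimmResult:
    """Zimm analysis of a concentration series.

    Each curve's 1/I is extrapolated linearly in q^2 to q = 0 over its
    low-q linear run; C/I(0,C) is then fit linearly in C, and
    A2 = slope / (2 * intercept) in relative units.
    """
    if series.axis != "concentration":
        raise ValueError("zimm_fit requires a concentration series")
    if len(series) < 2:
        raise InsufficientDataError("Zimm analysis needs >= 2 concentrations")
    if len(series) == 2:
        warnings.warn(
            "Zimm analysis with only 2 concentrations: slope and intercept "
            "are exactly determined, errors reflect input errors only",
            stacklevel=2,
        )
    per_conc = []
    ranges = []
    for curve in series:
        C = curve.meta.protein_concentration
        if C is None or C <= 0:
            raise ValueError("every curve needs a positive concentration")
        beta, cov, rng = _linear_run_fit(curve)
        inv_i0, inv_i0_var = beta[0], cov[0, 0]
        if inv_i0 <= 0:
            raise ValueError(
                f"non-positive extrapolated 1/I(0) at C = {C} mg/ml"
            )
        i0 = 1.0 / inv_i0
        per_conc.append((float(C), float(i0), float(math.sqrt(inv_i0_var) * i0**2)))
        ranges.append(rng)
    per_conc.sort(key=lambda t: -t[0])
    C_arr = np.array([t[0] for t in per_conc])
    i0_arr = np.array([t[1] for t in per_conc])
    i0_err = np.array([t[2] for t in per_conc])
    y = C_arr / i0_arr
    sy = C_arr * i0_err / i0_arr**2
    beta, cov = _weighted_line(C_arr, y, sy)
    k0, k1 = beta
    if k0 <= 0:
        raise ValueError("negative apparent 1/(KM) intercept")
    a2 = k1 / (2.0 * k0)
    grad = np.array([-k1 / (2.0 * k0**2), 1.0 / (2.0 * k0)])
    a2_var = float(grad @ cov @ grad)
    return ZimmResult(
        A2=float(a2),
        A2_err=math.sqrt(max(a2_var, 0.0)),
        intercept=float(k0),
        intercept_err=float(math.sqrt(cov[0, 0])),
        per_conc_I0=tuple(per_conc),
        alpha=alpha,
        fit_ranges=tuple(ranges),
    )


def extrapolate_zero_conc(points) -> ExtrapolationResult:
    """Error-weighted linear extrapolation of (C, value, err) points to C = 0.

    With exactly two points the line passes through them exactly and the
    quoted error derives from the input errors alone; with more points the
    covariance is still taken at the stated (absolute) input errors.
    """
    pts = [(float(c), float(v), float(e)) for c, v, e in points]
    if len(pts) < 2:
        raise InsufficientDataError("need >= 2 points to extrapolate")
    C = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    e = np.array([p[2] for p in pts])
    if np.unique(C).size < 2:
        raise np.linalg.LinAlgError(
            "duplicate concentration values only; extrapolation is rank-deficient"
        )
    if np.any(e <= 0):
        e = np.ones_like(e)
    beta, cov = _weighted_line(C, v, e)
    return ExtrapolationResult(
        value_at_zero=float(beta[0]),
        err=float(math.sqrt(cov[0, 0])),
        slope=float(beta[1]),
        slope_err=float(math.sqrt(cov[1, 1])),
        points=tuple(pts),
    )
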