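"""Diagnostic plots: fit overlays and the classic Zimm plot.

The Zimm plot uses the spread abscissa q^2 + alpha*C so that different
concentrations do not overlap; alpha (default 0.01) is purely cosmetic
and never enters any regression.
"""

from __future__ import annotations

import numpy as np

from .curves import CurveSeries, ScatteringCurve
from .virial import ZimmResult

__all__ = ["plot_fit", "zimm_plot"]


def plot_fit(curve: ScatteringCurve, model_intensity, ax=None, label="model"):
    """Log-log overlay of a measured curve and a model evaluated on its q."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        curve.q,
        curve.intensity,
        yerr=curve.sigma,
        fmt=".",
        ms=3,
        alpha=0.6,
        label=curve.meta.label or "data",
    )
    ax.plot(curve.q, np.asarray(model_intensity), "-", lw=1.5, label=label)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$q$ [nm$^{-1}$]")
    ax.set_ylabel(r"$I(q)$ [arb.]")
    ax.legend()
    return ax


def zimm_plot(series: CurveSeries, result: ZimmResult, ax=None, q_max=None):
    """Zimm plot: C/I(q,C) against q^2 + alpha*C with the fitted intercepts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    alpha = result.alpha
    for curve in series:
        C = curve.meta.protein_concentration
        mask = np.ones(len(curve), dtype=bool) if q_max is None else curve.q <= q_max
        x = curve.q[mask] ** 2 + alpha * C
        ax.plot(x, C / curve.intensity[mask], ".", ms=4, label=f"C={C:g} mg/ml")
    for C, i0, _ in result.per_conc_I0:
        ax.plot(alpha * C, C / i0, "kx", ms=8)
    ax.plot(0.0, result.intercept, "r*", ms=12, label=r"$C,q \to 0$")
    ax.set_xlabel(rf"$q^2 + {alpha:g}\,C$")
    ax.set_ylabel(r"$C/I(q,C)$")
    ax.legend(fontsize=8)
    return ax
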